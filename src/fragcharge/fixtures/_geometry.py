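"""Internal-coordinate peptide construction.

Atoms are placed with the NeRF rule: given three placed reference atoms
(p1 bonded, p2 angle, p3 torsion) and internal coordinates (r, theta, tau)
the new atom D satisfies |D-p1| = r, angle(D,p1,p2) = theta and
dihedral(D,p1,p2,p3) = tau.

Bond lengths/angles are standard ideal values (Engh-Huber-like); they are
collected here as the single geometry table of the package.
"""

from __future__ import annotations

import numpy as np

# backbone internal coordinates
N_CA = 1.458
CA_C = 1.525
C_N = 1.329
C_O = 1.231
N_H = 1.010
C_H = 1.090
O_H = 0.960

ANG_N_CA_C = 111.2
ANG_CA_C_N = 116.2
ANG_C_N_CA = 121.7
ANG_CA_C_O = 120.8
ANG_H_N_C = 119.3
OMEGA = 180.0


def place_atom(p1, p2, p3, bond, angle_deg, torsion_deg):
    """NeRF placement of one atom from three references."""
    theta = np.deg2rad(angle_deg)
    tau = np.deg2rad(torsion_deg)
    d = np.array([
        -bond * np.cos(theta),
        bond * np.sin(theta) * np.cos(tau),
        bond * np.sin(theta) * np.sin(tau),
    ])
    bc = p1 - p2
    bc /= np.linalg.norm(bc)
    ab = p2 - p3
    n = np.cross(ab, bc)
    nn = np.linalg.norm(n)
    if nn < 1e-10:  # collinear references: any perpendicular works
        n = np.cross(bc, np.array([1.0, 0.0, 0.0]))
        if np.linalg.norm(n) < 1e-10:
            n = np.cross(bc, np.array([0.0, 1.0, 0.0]))
        nn = np.linalg.norm(n)
    n /= nn
    m = np.cross(n, bc)
    rot = np.column_stack([bc, m, n])
    return p1 + rot @ d


def dihedral(p0, p1, p2, p3) -> float:
    """Signed dihedral angle in degrees (IUPAC convention)."""
    b0, b1, b2 = p0 - p1, p2 - p1, p3 - p2
    b1 = b1 / np.linalg.norm(b1)
    v = b0 - np.dot(b0, b1) * b1
    w = b2 - np.dot(b2, b1) * b1
    x = np.dot(v, w)
    y = np.dot(np.cross(b1, v), w)
    return float(np.degrees(np.arctan2(y, x)))


# ---------------------------------------------------------------------------
# side-chain z-matrices
#
# Entries: (atom, ref1, ref2, ref3, bond, angle, torsion)
# A torsion may be "chi1"/"chi2"... (resolved against the residue's chi
# values) or "chiK+off" for a fixed offset.
# ---------------------------------------------------------------------------

SIDE_CHAINS: dict[str, list[tuple]] = {
    "GLY": [],
    "ALA": [
        ("CB", "CA", "C", "N", 1.530, 110.1, "ICB"),
        ("HB1", "CB", "CA", "N", C_H, 109.5, "180"),
        ("HB2", "CB", "CA", "N", C_H, 109.5, "60"),
        ("HB3", "CB", "CA", "N", C_H, 109.5, "-60"),
    ],
    "SER": [
        ("CB", "CA", "C", "N", 1.530, 110.1, "ICB"),
        ("OG", "CB", "CA", "N", 1.417, 110.8, "chi1"),
        ("HB2", "CB", "CA", "N", C_H, 109.5, "chi1+120"),
        ("HB3", "CB", "CA", "N", C_H, 109.5, "chi1-120"),
        ("HG", "OG", "CB", "CA", O_H, 108.5, "180"),
    ],
    "VAL": [
        ("CB", "CA", "C", "N", 1.540, 110.1, "ICB"),
        ("CG1", "CB", "CA", "N", 1.530, 110.5, "chi1"),
        ("CG2", "CB", "CA", "N", 1.530, 110.5, "chi1+120"),
        ("HB", "CB", "CA", "N", C_H, 108.0, "chi1-120"),
        ("HG11", "CG1", "CB", "CA", C_H, 109.5, "180"),
        ("HG12", "CG1", "CB", "CA", C_H, 109.5, "60"),
        ("HG13", "CG1", "CB", "CA", C_H, 109.5, "-60"),
        ("HG21", "CG2", "CB", "CA", C_H, 109.5, "180"),
        ("HG22", "CG2", "CB", "CA", C_H, 109.5, "60"),
        ("HG23", "CG2", "CB", "CA", C_H, 109.5, "-60"),
    ],
    "GLU": [
        ("CB", "CA", "C", "N", 1.530, 110.1, "ICB"),
        ("CG", "CB", "CA", "N", 1.530, 114.1, "chi1"),
        ("HB2", "CB", "CA", "N", C_H, 109.5, "chi1+120"),
        ("HB3", "CB", "CA", "N", C_H, 109.5, "chi1-120"),
        ("CD", "CG", "CB", "CA", 1.516, 112.6, "chi2"),
        ("HG2", "CG", "CB", "CA", C_H, 109.5, "chi2+120"),
        ("HG3", "CG", "CB", "CA", C_H, 109.5, "chi2-120"),
        ("OE1", "CD", "CG", "CB", 1.250, 117.0, "chi3"),
        ("OE2", "CD", "CG", "CB", 1.250, 117.0, "chi3+180"),
    ],
    "LYS": [
        ("CB", "CA", "C", "N", 1.530, 110.1, "ICB"),
        ("CG", "CB", "CA", "N", 1.530, 114.1, "chi1"),
        ("HB2", "CB", "CA", "N", C_H, 109.5, "chi1+120"),
        ("HB3", "CB", "CA", "N", C_H, 109.5, "chi1-120"),
        ("CD", "CG", "CB", "CA", 1.530, 111.3, "chi2"),
        ("HG2", "CG", "CB", "CA", C_H, 109.5, "chi2+120"),
        ("HG3", "CG", "CB", "CA", C_H, 109.5, "chi2-120"),
        ("CE", "CD", "CG", "CB", 1.530, 111.3, "chi3"),
        ("HD2", "CD", "CG", "CB", C_H, 109.5, "chi3+120"),
        ("HD3", "CD", "CG", "CB", C_H, 109.5, "chi3-120"),
        ("NZ", "CE", "CD", "CG", 1.489, 111.9, "chi4"),
        ("HE2", "CE", "CD", "CG", C_H, 109.5, "chi4+120"),
        ("HE3", "CE", "CD", "CG", C_H, 109.5, "chi4-120"),
        ("HZ1", "NZ", "CE", "CD", N_H, 109.5, "180"),
        ("HZ2", "NZ", "CE", "CD", N_H, 109.5, "60"),
        ("HZ3", "NZ", "CE", "CD", N_H, 109.5, "-60"),
    ],
}

#: default chi rotamers per residue
DEFAULT_CHI: dict[str, dict[str, float]] = {
    "ALA": {},
    "GLY": {},
    "SER": {"chi1": -65.0},
    "VAL": {"chi1": 175.0},
    "GLU": {"chi1": -65.0, "chi2": 180.0, "chi3": -10.0},
    "LYS": {"chi1": -65.0, "chi2": 180.0, "chi3": 180.0, "chi4": 180.0},
}

#: improper torsion CB-CA-C-N placing the beta carbon (L configuration)
ICB_TORSION = 122.7
#: improper torsion HA-CA-C-N
IHA_TORSION = -118.3

THREE_LETTER = {"A": "ALA", "G": "GLY", "S": "SER", "V": "VAL",
                "E": "GLU", "K": "LYS"}

ELEMENT_OF_PREFIX = {"C": "C", "N": "N", "O": "O", "H": "H", "S": "S"}


def element_of(name: str) -> str:
    stripped = name.lstrip("0123456789")
    return ELEMENT_OF_PREFIX[stripped[0]]


def resolve_torsion(spec: str, chis: dict[str, float]) -> float:
    if spec == "ICB":
        return ICB_TORSION
    for key, val in chis.items():
        if spec == key:
            return val
        if spec.startswith(key) and spec[len(key)] in "+-":
            return val + float(spec[len(key):])
    return float(spec)
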