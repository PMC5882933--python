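"""Ideal-geometry peptide fixtures with matching reference charges.

Everything the test suite (and the mock pipeline) consumes is generated
here: small polypeptides from a one-letter sequence with chosen backbone
torsions, conformer ensembles with jittered torsions, and folded contact
fixtures guaranteed to contain spatially close non-sequential residue
pairs.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from ..errors import ConstructionError, GeometryError
from ..structure import (Atom, ChargeSet, Residue, Structure, assign_radii,
                         load_reference_charges)
from . import _geometry as geo

__all__ = ["PeptideSpec", "build_peptide", "make_conformers",
           "make_contact_fixture"]

CLASH_DISTANCE = 0.8  # angstrom, any non-bonded pair closer than this fails
_BONDED_CUTOFF = 1.6  # pairs closer than this are treated as bonded


@dataclass
class PeptideSpec:
    """Recipe for one ideal-geometry peptide."""

    sequence: str
    phi: list[float] | float = -135.0
    psi: list[float] | float = 135.0
    termini: str = "neutral"  # neutral | zwitterionic
    seed: int = 0
    chi_jitter: float = 0.0  # stdev (deg) applied to side-chain torsions
    chain_id: str = "A"

    def __post_init__(self):
        if not (2 <= len(self.sequence) <= 12):
            raise ValueError("sequence length must be 2..12")
        bad = [c for c in self.sequence if c not in geo.THREE_LETTER]
        if bad:
            raise ValueError(f"unsupported residues: {bad}")
        if self.termini not in ("neutral", "zwitterionic"):
            raise ValueError("termini must be 'neutral' or 'zwitterionic'")
        self.phi = self._per_residue(self.phi)
        self.psi = self._per_residue(self.psi)
        for t in self.phi + self.psi:
            if not (-180.0 < t <= 180.0):
                raise ValueError("torsions must lie in (-180, 180]")

    def _per_residue(self, tors) -> list[float]:
        n = len(self.sequence)
        if np.isscalar(tors):
            return [float(tors)] * n
        if len(tors) != n:
            raise ValueError("need one torsion per residue")
        return [float(t) for t in tors]


def build_peptide(spec: PeptideSpec, with_charges: bool = True):
    """Build the peptide; returns Structure (and ChargeSet if requested)."""
    rng = np.random.default_rng(spec.seed)
    coords: list[dict[str, np.ndarray]] = []  # per-residue name -> xyz
    names3 = [geo.THREE_LETTER[c] for c in spec.sequence]
    n_res = len(names3)

    for i, res3 in enumerate(names3):
        res_xyz: dict[str, np.ndarray] = {}
        phi, psi = spec.phi[i], spec.psi[i]

        if i == 0:
            res_xyz["N"] = np.zeros(3)
            res_xyz["CA"] = np.array([geo.N_CA, 0.0, 0.0])
            th = np.deg2rad(geo.ANG_N_CA_C)
            res_xyz["C"] = res_xyz["CA"] + geo.CA_C * np.array(
                [-np.cos(th), np.sin(th), 0.0])
        else:
            prev = coords[i - 1]
            res_xyz["N"] = geo.place_atom(prev["C"], prev["CA"], prev["N"],
                                          geo.C_N, geo.ANG_CA_C_N, spec.psi[i - 1])
            res_xyz["CA"] = geo.place_atom(res_xyz["N"], prev["C"], prev["CA"],
                                           geo.N_CA, geo.ANG_C_N_CA, geo.OMEGA)
            res_xyz["C"] = geo.place_atom(res_xyz["CA"], res_xyz["N"], prev["C"],
                                          geo.CA_C, geo.ANG_N_CA_C, phi)

        # carbonyl / C-terminal oxygens
        res_xyz["O"] = geo.place_atom(res_xyz["C"], res_xyz["CA"], res_xyz["N"],
                                      geo.C_O, geo.ANG_CA_C_O, psi + 180.0)
        if i == n_res - 1:
            res_xyz["OXT"] = geo.place_atom(res_xyz["C"], res_xyz["CA"],
                                            res_xyz["N"], 1.25
                                            if spec.termini == "zwitterionic"
                                            else 1.32, 117.0, psi)
            if spec.termini == "neutral":
                res_xyz["HXT"] = geo.place_atom(res_xyz["OXT"], res_xyz["C"],
                                                res_xyz["O"], geo.O_H, 107.0, 0.0)

        # amide hydrogens
        if i == 0:
            hs = ["H1", "H2", "H3"] if spec.termini == "zwitterionic" else ["H1", "H2"]
            for h, tau in zip(hs, (180.0, 60.0, -60.0)):
                res_xyz[h] = geo.place_atom(res_xyz["N"], res_xyz["CA"],
                                            res_xyz["C"], geo.N_H, 109.5, tau)
        else:
            prev = coords[i - 1]
            res_xyz["H"] = geo.place_atom(res_xyz["N"], prev["C"], prev["CA"],
                                          geo.N_H, geo.ANG_H_N_C, 0.0)

        # alpha hydrogens
        if res3 == "GLY":
            res_xyz["HA2"] = geo.place_atom(res_xyz["CA"], res_xyz["C"],
                                            res_xyz["N"], geo.C_H, 109.5,
                                            geo.ICB_TORSION)
            res_xyz["HA3"] = geo.place_atom(res_xyz["CA"], res_xyz["C"],
                                            res_xyz["N"], geo.C_H, 109.5,
                                            geo.IHA_TORSION)
        else:
            res_xyz["HA"] = geo.place_atom(res_xyz["CA"], res_xyz["C"],
                                           res_xyz["N"], geo.C_H, 109.5,
                                           geo.IHA_TORSION)

        # side chain
        chis = dict(geo.DEFAULT_CHI[res3])
        if spec.chi_jitter > 0:
            for key in chis:
                chis[key] += rng.normal(0.0, spec.chi_jitter)
        for name, r1, r2, r3, bond, angle, tors in geo.SIDE_CHAINS[res3]:
            tau = geo.resolve_torsion(tors, chis)
            res_xyz[name] = geo.place_atom(res_xyz[r1], res_xyz[r2],
                                           res_xyz[r3], bond, angle, tau)
        coords.append(res_xyz)

    structure = _to_structure(names3, coords, spec.chain_id)
    _check_clashes(structure)
    assign_radii(structure)
    if not with_charges:
        return structure
    charges = load_reference_charges(structure)
    return structure, charges


def _atom_order(res3: str, first: bool, last: bool, termini: str) -> list[str]:
    names = ["N"]
    if first:
        names += ["H1", "H2"] + (["H3"] if termini == "zwitterionic" else [])
    else:
        names += ["H"]
    names += ["CA"]
    names += ["HA2", "HA3"] if res3 == "GLY" else ["HA"]
    names += [entry[0] for entry in geo.SIDE_CHAINS[res3]]
    names += ["C", "O"]
    if last:
        names += ["OXT"] + (["HXT"] if termini == "neutral" else [])
    return names


def _to_structure(names3, coords, chain_id) -> Structure:
    atoms: list[Atom] = []
    residues: list[Residue] = []
    n_res = len(names3)
    termini = "neutral" if "HXT" in coords[-1] else "zwitterionic"
    for i, res3 in enumerate(names3):
        res = Residue(res3, i + 1, [], chain_id)
        order = _atom_order(res3, i == 0, i == n_res - 1, termini)
        # HA placement differs for GLY side-chain ordering: use what exists
        for name in order:
            atoms.append(Atom(len(atoms), name, geo.element_of(name), i + 1,
                              coords[i][name]))
            res.atom_indices.append(len(atoms) - 1)
        residues.append(res)
    return Structure(atoms, residues, chain_breaks=[])


def _check_clashes(structure: Structure) -> None:
    pos = structure.positions()
    if len(pos) < 2:
        return
    from scipy.spatial.distance import pdist, squareform
    d = squareform(pdist(pos))
    np.fill_diagonal(d, np.inf)
    ii, jj = np.where(d < CLASH_DISTANCE)
    for i, j in zip(ii, jj):
        if i < j:
            a, b = structure.atoms[i], structure.atoms[j]
            raise GeometryError(
                f"steric clash: {a.name}(res {a.residue_index}) - "
                f"{b.name}(res {b.residue_index}) at {d[i, j]:.2f} A; "
                "try different torsions")


def make_conformers(spec: PeptideSpec, n: int, sigma: float, seed: int,
                    max_retries: int = 100) -> list[Structure]:
    """n conformers with Gaussian-jittered backbone torsions (deg)."""
    if n < 1:
        raise ValueError("n must be >= 1")
    rng = np.random.default_rng(seed)
    out: list[Structure] = []
    for _ in range(n):
        for attempt in range(max_retries):
            phi = [p + rng.normal(0.0, sigma) for p in spec.phi]
            psi = [p + rng.normal(0.0, sigma) for p in spec.psi]
            phi = [_wrap(t) for t in phi]
            psi = [_wrap(t) for t in psi]
            try:
                s = build_peptide(
                    PeptideSpec(spec.sequence, phi, psi, spec.termini,
                                spec.seed, spec.chi_jitter, spec.chain_id),
                    with_charges=False)
                out.append(s)
                break
            except GeometryError:
                continue
        else:
            raise ConstructionError(
                f"could not build a clash-free conformer in {max_retries} tries")
    return out


def _wrap(t: float) -> float:
    t = ((t + 180.0) % 360.0) - 180.0
    return 180.0 if t == -180.0 else t


#: torsion sets tried by make_contact_fixture, most compact first
_FOLDS = [
    ("helix", -57.0, -47.0),
    ("tight", -65.0, -40.0),
    ("three_ten", -49.0, -26.0),
]


def make_contact_fixture(min_pairs: int, lam: float, sequence: str = "AAAAAA",
                         termini: str = "neutral"):
    """A folded peptide with >= min_pairs two-body pairs at threshold lam.

    The result is verified post-construction with the pair finder; if no
    candidate fold satisfies the request a ConstructionError is raised.
    """
    from ..fragmentation import find_two_body_pairs

    if min_pairs < 1:
        raise ValueError("min_pairs must be >= 1")
    errors = []
    for name, phi, psi in _FOLDS:
        try:
            structure, charges = build_peptide(
                PeptideSpec(sequence, phi, psi, termini))
        except GeometryError as exc:
            errors.append(f"{name}: {exc}")
            continue
        pairs = find_two_body_pairs(structure, lam)
        if len(pairs) >= min_pairs:
            return structure, charges
        errors.append(f"{name}: only {len(pairs)} pairs at lambda={lam}")
    raise ConstructionError(
        f"no fold of {sequence} yields {min_pairs} pair(s) at lambda={lam} A: "
        + "; ".join(errors))
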