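"""Per-atom charge assembly and total-energy assembly with the
double-count deduction.

Per-atom charges combine subsystem fits as

    q_k = sum_frag q_k - sum_concap q_k
          + sum_pairs [ q_k(A_i A_j) - q_k(A_i) - q_k(A_j) ]

Because every parent atom appears in exactly one more fragment than
concap, the first two sums collapse to a single effective contribution per
atom; the pair terms add the short-range two-body correction.  (The
two-body interaction enters with a sign such that it *replaces* the
classical charge-charge interaction that the embedded one-body terms
already count -- the only sign for which the pairwise double-count
deduction closes; see the bundled docs.)

Link-atom fitted charges never enter any parent atom's ledger.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .constants import BOHR_PER_ANGSTROM
from .errors import FragchargeError
from .espfit import SubsystemFitResult
from .fragmentation import TwoBodyPair
from .structure import ChargeSet, Structure


@dataclass
class AssemblyLedger:
    """Per-atom record of every signed subsystem contribution."""

    #: per atom: list of (subsystem label, sign, fitted value)
    contributions: list[list[tuple[str, int, float]]]
    assembled: np.ndarray
    multiplicity: np.ndarray  # fragment-count minus concap-count per atom

    def to_rows(self):
        rows = []
        for k, entries in enumerate(self.contributions):
            for label, sign, value in entries:
                rows.append((k, label, sign, value))
        return rows


@dataclass
class TwoBodyFits:
    pair: SubsystemFitResult
    mono_i: SubsystemFitResult
    mono_j: SubsystemFitResult
    meta: TwoBodyPair


def assemble_charges(structure: Structure,
                     fragment_fits: list[SubsystemFitResult],
                     concap_fits: list[SubsystemFitResult],
                     pair_fits: list[TwoBodyFits] | None = None,
                     ) -> tuple[ChargeSet, AssemblyLedger]:
    """Combine subsystem fits into one per-atom ChargeSet."""
    n = structure.n_atoms
    q = np.zeros(n)
    contributions: list[list[tuple[str, int, float]]] = [[] for _ in range(n)]
    frag_count = np.zeros(n, dtype=int)
    concap_count = np.zeros(n, dtype=int)

    for fit in fragment_fits:
        vals = fit.parent_values
        for local, k in enumerate(fit.subsystem.member_atoms):
            q[k] += vals[local]
            frag_count[k] += 1
            contributions[k].append((fit.subsystem.label, +1, float(vals[local])))
    for fit in concap_fits:
        vals = fit.parent_values
        for local, k in enumerate(fit.subsystem.member_atoms):
            q[k] -= vals[local]
            concap_count[k] += 1
            contributions[k].append((fit.subsystem.label, -1, float(vals[local])))

    multiplicity = frag_count - concap_count
    if np.any(multiplicity != 1):
        bad = np.where(multiplicity != 1)[0][:5]
        raise FragchargeError(
            "assembly multiplicity check failed for atoms "
            f"{bad.tolist()} (counts {multiplicity[bad].tolist()}); "
            "fragmentation is inconsistent")

    for tb in (pair_fits or []):
        for fit, sign in ((tb.pair, +1), (tb.mono_i, -1), (tb.mono_j, -1)):
            vals = fit.parent_values
            for local, k in enumerate(fit.subsystem.member_atoms):
                q[k] += sign * vals[local]
                contributions[k].append(
                    (fit.subsystem.label, sign, float(vals[local])))

    ledger = AssemblyLedger(contributions, q, multiplicity)
    return ChargeSet(q, provenance="ee_gmfcc"), ledger


def total_charge_report(charges: ChargeSet, formal: float,
                        renormalize: bool = False):
    """Deviation of the assembled total from the formal charge.

    Returns (deviation, charges); with ``renormalize`` the deviation is
    spread uniformly so the total is exact (off by default).
    """
    deviation = charges.total - formal
    if not renormalize:
        return deviation, charges
    shifted = charges.values - deviation / len(charges)
    return deviation, ChargeSet(shifted, provenance=charges.provenance)


@dataclass
class EnergyLedger:
    fragment_energies: list[float]
    concap_energies: list[float]
    two_body_terms: list[float]     # E_ij - E_i - E_j per pair
    e_dc: float
    total: float = field(init=False)

    def __post_init__(self):
        self.total = (sum(self.fragment_energies) - sum(self.concap_energies)
                      + sum(self.two_body_terms) - self.e_dc)


def _pair_count_matrix(structure: Structure, subsystem_members, signs):
    """n_ab = signed number of times the (a, b) interaction is counted.

    An embedded term counts the a-b interaction whenever at least one of
    the two atoms is inside the subsystem (internally at the QM level,
    externally as charge-charge embedding).  Background-background pairs
    are never part of an embedded energy.
    """
    n = structure.n_atoms
    total_sign = float(np.sum(signs))
    outside = np.zeros((len(signs), n))
    for t, members in enumerate(subsystem_members):
        outside[t] = 1.0
        outside[t, members] = 0.0
    m = outside.T @ (np.asarray(signs, dtype=float)[:, None] * outside)
    return total_sign - m


def double_count_energy(structure: Structure, charges: ChargeSet,
                        subsystem_members, signs) -> float:
    """E_DC: pairwise charge-charge energy counted in excess of once (au)."""
    n_ab = _pair_count_matrix(structure, subsystem_members, signs)
    pos = structure.positions()
    d = np.linalg.norm(pos[:, None, :] - pos[None, :, :], axis=2)
    np.fill_diagonal(d, np.inf)
    qq = np.outer(charges.values, charges.values)
    excess = n_ab - 1.0
    np.fill_diagonal(excess, 0.0)
    return float((excess * qq / (d * BOHR_PER_ANGSTROM)).sum() / 2.0)


def assemble_total_energy(structure: Structure, charges: ChargeSet,
                          fragment_fits: list[SubsystemFitResult],
                          concap_fits: list[SubsystemFitResult],
                          pair_fits: list[TwoBodyFits] | None = None,
                          ) -> EnergyLedger:
    """Assemble the fragment energies with the E_DC deduction (hartree)."""
    pair_fits = pair_fits or []
    for group in (fragment_fits, concap_fits):
        for fit in group:
            if fit.energy is None:
                raise FragchargeError(
                    f"subsystem {fit.subsystem.label} has no energy")
    members, signs = [], []
    for fit in fragment_fits:
        members.append(fit.subsystem.member_atoms)
        signs.append(+1)
    for fit in concap_fits:
        members.append(fit.subsystem.member_atoms)
        signs.append(-1)
    for tb in pair_fits:
        for fit, s in ((tb.pair, +1), (tb.mono_i, -1), (tb.mono_j, -1)):
            if fit.energy is None:
                raise FragchargeError(
                    f"subsystem {fit.subsystem.label} has no energy")
            members.append(fit.subsystem.member_atoms)
            signs.append(s)

    e_dc = double_count_energy(structure, charges, members, signs)
    two_body = [tb.pair.energy - tb.mono_i.energy - tb.mono_j.energy
                for tb in pair_fits]
    return EnergyLedger(
        fragment_energies=[f.energy for f in fragment_fits],
        concap_energies=[c.energy for c in concap_fits],
        two_body_terms=two_body,
        e_dc=e_dc)
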