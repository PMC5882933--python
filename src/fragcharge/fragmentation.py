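"""Capped-fragment construction for the generalized conjugate-cap scheme.

A chain of N residues is cut through its peptide bonds.  Fragment i
(i = 2..N-1) is the triplet of residues (i-1, i, i+1); concap i
(i = 2..N-2) is the overlap doublet (i, i+1).  Dangling backbone valences
are saturated by hydrogen link atoms placed along the cut bond.  Spatially
close, sequence-distant residue pairs (j >= i+3) get two-body subsystems:
the two singly-capped residues and their combined pair geometry.

The structural identity that makes per-atom charge assembly exact is
(#fragments containing an atom) - (#concaps containing it) = 1.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy.spatial.distance import cdist

from .constants import LINK_BOND_LENGTH
from .errors import FragmentationError, GeometryError
from .structure import ChargeSet, Structure


@dataclass
class LinkAtom:
    """Hydrogen saturating a cut bond."""

    position: np.ndarray  # angstrom
    donor_index: int      # parent atom the link H is bonded to
    removed_index: int    # parent atom the link H replaces
    description: str = ""


@dataclass
class Subsystem:
    """Common core of fragments, concaps and two-body subsystems."""

    kind: str                       # fragment | concap | pair | monomer
    label: str
    member_atoms: list[int]         # parent atom indices, parent order
    link_atoms: list[LinkAtom] = field(default_factory=list)
    net_charge: int = 0

    def geometry(self, structure: Structure):
        """(positions (m,3), elements, is_link mask) for QM consumption."""
        pos = [structure.atoms[i].position for i in self.member_atoms]
        elements = [structure.atoms[i].element for i in self.member_atoms]
        for la in self.link_atoms:
            pos.append(la.position)
            elements.append("H")
        is_link = np.array([False] * len(self.member_atoms)
                           + [True] * len(self.link_atoms))
        return np.array(pos, dtype=float), elements, is_link

    @property
    def n_sites(self) -> int:
        return len(self.member_atoms) + len(self.link_atoms)


@dataclass
class CappedFragment(Subsystem):
    center_residue_index: int = 0


@dataclass
class Concap(Subsystem):
    residue_index: int = 0
    #: (concap link index, center residue of owning fragment, fragment link index)
    link_correspondence: list[tuple[int, int, int]] = field(default_factory=list)


@dataclass
class TwoBodyPair:
    """Capped A_i, A_j and their combined A_iA_j geometry."""

    i: int
    j: int
    pair: Subsystem
    mono_i: Subsystem
    mono_j: Subsystem
    closest_distance: float


def place_link_hydrogen(donor_pos, removed_pos, donor_element: str) -> np.ndarray:
    """H along the donor->removed unit vector at the standard bond length."""
    donor_pos = np.asarray(donor_pos, dtype=float)
    removed_pos = np.asarray(removed_pos, dtype=float)
    v = removed_pos - donor_pos
    norm = np.linalg.norm(v)
    if norm < 1e-8:
        raise GeometryError("zero-length cut-bond vector")
    length = LINK_BOND_LENGTH.get(donor_element)
    if length is None:
        raise GeometryError(f"no link bond length for donor element {donor_element}")
    return donor_pos + v / norm * length


def _link_for_cut(structure: Structure, donor_res: int, donor_name: str,
                  removed_res: int, removed_name: str) -> LinkAtom:
    donor = structure.find_atom(donor_res, donor_name)
    removed = structure.find_atom(removed_res, removed_name)
    if donor is None or removed is None:
        raise FragmentationError(
            f"cannot cut {donor_name}(res {donor_res})-{removed_name}"
            f"(res {removed_res}): atom missing")
    pos = place_link_hydrogen(structure.atoms[donor].position,
                              structure.atoms[removed].position,
                              structure.atoms[donor].element)
    return LinkAtom(pos, donor, removed,
                    f"{donor_name}{donor_res}-{removed_name}{removed_res}")


def _residue_span_subsystem(structure: Structure, formal: np.ndarray,
                            first: int, last: int, kind: str, label: str,
                            seg: tuple[int, int]) -> Subsystem:
    """Subsystem covering residues first..last, link-capped at both cuts."""
    members = []
    for r in range(first, last + 1):
        members.extend(structure.atoms_of_residue(r))
    links = []
    if first > seg[0]:
        links.append(_link_for_cut(structure, first, "N", first - 1, "C"))
    if last < seg[1]:
        links.append(_link_for_cut(structure, last, "C", last + 1, "N"))
    net = int(round(formal[first - 1:last].sum()))
    return Subsystem(kind, label, members, links, net)


def _formal_charges(structure: Structure, reference: ChargeSet) -> np.ndarray:
    out = np.zeros(structure.n_residues)
    for res in structure.residues:
        out[res.index - 1] = round(
            float(sum(reference.values[ai] for ai in res.atom_indices)))
    return out


def _segment_of(structure: Structure, res: int) -> tuple[int, int]:
    for s, e in structure.segments():
        if s <= res <= e:
            return (s, e)
    raise FragmentationError(f"residue {res} not in any segment")


def build_fragments(structure: Structure, reference: ChargeSet,
                    allow_small: bool = True) -> list[CappedFragment]:
    """Capped fragments, N-2 per continuous segment of N residues.

    Segments with fewer than 3 residues fall back to a single
    whole-segment fragment (no cuts, no link atoms) when ``allow_small``;
    otherwise they raise FragmentationError.
    """
    formal = _formal_charges(structure, reference)
    fragments: list[CappedFragment] = []
    for seg in structure.segments():
        s, e = seg
        n = e - s + 1
        if n < 3:
            if not allow_small:
                raise FragmentationError(
                    f"segment {s}..{e} has {n} residues (< 3)")
            sub = _residue_span_subsystem(structure, formal, s, e,
                                          "fragment", f"frag_{s}", seg)
            fragments.append(CappedFragment(sub.kind, sub.label,
                                            sub.member_atoms, sub.link_atoms,
                                            sub.net_charge,
                                            center_residue_index=s))
            continue
        for i in range(s + 1, e):
            sub = _residue_span_subsystem(structure, formal, i - 1, i + 1,
                                          "fragment", f"frag_{i}", seg)
            fragments.append(CappedFragment(sub.kind, sub.label,
                                            sub.member_atoms, sub.link_atoms,
                                            sub.net_charge,
                                            center_residue_index=i))
    return fragments


def build_concaps(structure: Structure, reference: ChargeSet) -> list[Concap]:
    """Conjugate caps, N-3 per continuous segment of N residues.

    Each concap link atom carries a correspondence to the equivalent link
    atom of a neighbouring fragment: the left cut (N of residue i) is
    shared with fragment i+1, the right cut (C of residue i+1) with
    fragment i.
    """
    formal = _formal_charges(structure, reference)
    concaps: list[Concap] = []
    for seg in structure.segments():
        s, e = seg
        for i in range(s + 1, e - 1):
            sub = _residue_span_subsystem(structure, formal, i, i + 1,
                                          "concap", f"concap_{i}", seg)
            corr: list[tuple[int, int, int]] = []
            for li, la in enumerate(sub.link_atoms):
                donor = structure.atoms[la.donor_index]
                if donor.name == "N":          # left cut, shared w/ fragment i+1
                    corr.append((li, i + 1, _fragment_link_index(
                        structure, seg, i + 1, la)))
                else:                           # right cut, shared w/ fragment i
                    corr.append((li, i, _fragment_link_index(
                        structure, seg, i, la)))
            concaps.append(Concap(sub.kind, sub.label, sub.member_atoms,
                                  sub.link_atoms, sub.net_charge,
                                  residue_index=i, link_correspondence=corr))
    return concaps


def _fragment_link_index(structure: Structure, seg, center: int,
                         la: LinkAtom) -> int:
    """Index of the equivalent link atom within fragment ``center``."""
    s, e = seg
    first, last = center - 1, center + 1
    idx = 0
    if first > s:
        if structure.atoms[la.donor_index].residue_index == first and \
                structure.atoms[la.donor_index].name == "N":
            return idx
        idx += 1
    if last < e:
        if structure.atoms[la.donor_index].residue_index == last and \
                structure.atoms[la.donor_index].name == "C":
            return idx
    raise FragmentationError(
        f"no corresponding link atom in fragment {center} for cut "
        f"{la.description}")


def find_two_body_pairs(structure: Structure, lam: float,
                        reference: ChargeSet | None = None) -> list[TwoBodyPair]:
    """All residue pairs (i, j), j >= i+3, with min atom distance <= lam.

    The minimum is taken over all atoms, hydrogens included.  Returned
    sorted by (i, j) with the closest-contact distance recorded.
    """
    if lam < 0:
        raise ValueError("lambda must be >= 0")
    formal = (np.zeros(structure.n_residues) if reference is None
              else _formal_charges(structure, reference))
    pos_by_res = {r.index: np.array(
        [structure.atoms[ai].position for ai in r.atom_indices])
        for r in structure.residues}
    pairs: list[TwoBodyPair] = []
    if lam == 0:
        return pairs
    n = structure.n_residues
    for i in range(1, n + 1):
        for j in range(i + 3, n + 1):
            d = float(cdist(pos_by_res[i], pos_by_res[j]).min())
            if d <= lam:
                seg_i = _segment_of(structure, i)
                seg_j = _segment_of(structure, j)
                mono_i = _residue_span_subsystem(
                    structure, formal, i, i, "monomer", f"mono_{i}", seg_i)
                mono_j = _residue_span_subsystem(
                    structure, formal, j, j, "monomer", f"mono_{j}", seg_j)
                pair = Subsystem(
                    "pair", f"pair_{i}_{j}",
                    mono_i.member_atoms + mono_j.member_atoms,
                    mono_i.link_atoms + mono_j.link_atoms,
                    mono_i.net_charge + mono_j.net_charge)
                pairs.append(TwoBodyPair(i, j, pair, mono_i, mono_j, d))
    return pairs


def background_charges(structure: Structure, subsystem: Subsystem,
                       reference: ChargeSet,
                       extra: tuple[np.ndarray, np.ndarray] | None = None):
    """Point charges of all parent atoms outside the subsystem.

    ``extra`` optionally appends additional background points (positions,
    values), e.g. induced solvent surface charges.  Link atoms never enter
    the background.  Returns (positions (m,3), values (m,)).
    """
    member = np.zeros(structure.n_atoms, dtype=bool)
    member[subsystem.member_atoms] = True
    pos = structure.positions()[~member]
    q = np.asarray(reference.values)[~member]
    if extra is not None and len(extra[0]):
        pos = np.vstack([pos, np.asarray(extra[0], dtype=float).reshape(-1, 3)])
        q = np.concatenate([q, np.asarray(extra[1], dtype=float)])
    return pos, q


def membership_counts(structure: Structure, fragments: list[CappedFragment],
                      concaps: list[Concap]) -> np.ndarray:
    """Per-atom (#fragments containing it) - (#concaps containing it)."""
    count = np.zeros(structure.n_atoms, dtype=int)
    for f in fragments:
        count[f.member_atoms] += 1
    for c in concaps:
        count[c.member_atoms] -= 1
    return count
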