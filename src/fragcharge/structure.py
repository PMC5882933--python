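"""Molecular structure data model and file I/O (PDB in, PQR out).

The :class:`Structure` is the shared currency of the package: an ordered
list of atoms partitioned into residues, with chain-break bookkeeping so
that downstream fragmentation can treat each continuous peptide segment
independently.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass, field
from importlib import resources
from pathlib import Path

import numpy as np

from .errors import ChargeLookupError, StructuralError

#: Residue names recognised as amino acids (the fixture alphabet plus the
#: remaining standard residues so externally prepared files are accepted).
AMINO_ACIDS = {
    "ALA", "ARG", "ASN", "ASP", "CYS", "GLN", "GLU", "GLY", "HIS", "ILE",
    "LEU", "LYS", "MET", "PHE", "PRO", "SER", "THR", "TRP", "TYR", "VAL",
}

#: Maximum C(i)-N(i+1) distance counted as a peptide bond (angstrom).
PEPTIDE_BOND_CUTOFF = 1.8


@dataclass
class Atom:
    """One atom: PDB naming, element, parent residue and coordinates."""

    serial: int
    name: str
    element: str
    residue_index: int  # 1-based along the whole structure
    position: np.ndarray  # shape (3,), angstrom
    vdw_radius: float | None = None
    reference_charge: float | None = None

    def __post_init__(self):
        self.position = np.asarray(self.position, dtype=float)
        if self.position.shape != (3,) or not np.all(np.isfinite(self.position)):
            raise StructuralError(f"atom {self.serial} ({self.name}): bad position")
        if self.vdw_radius is not None and self.vdw_radius <= 0:
            raise StructuralError(f"atom {self.serial} ({self.name}): vdw_radius <= 0")


@dataclass
class Residue:
    """A residue: name, 1-based index, and the indices of its atoms."""

    name: str
    index: int
    atom_indices: list[int] = field(default_factory=list)
    chain_id: str = "A"

    def atom_names(self, structure: "Structure") -> list[str]:
        return [structure.atoms[i].name for i in self.atom_indices]


class Structure:
    """Ordered atoms partitioned into residues with chain-break records."""

    def __init__(self, atoms: list[Atom], residues: list[Residue],
                 chain_breaks: list[int] | None = None):
        self.atoms = atoms
        self.residues = residues
        # chain_breaks[k] = residue index i meaning: no peptide bond between
        # residue i and residue i+1 (1-based residue indices).
        self.chain_breaks = sorted(chain_breaks or [])
        self.warnings: list[str] = []
        self._validate()

    # -- construction helpers -------------------------------------------------

    def _validate(self) -> None:
        seen = set()
        for res in self.residues:
            for ai in res.atom_indices:
                if ai in seen:
                    raise StructuralError(f"atom {ai} assigned to two residues")
                seen.add(ai)
                if self.atoms[ai].residue_index != res.index:
                    raise StructuralError(
                        f"atom {ai} residue_index disagrees with residue {res.index}")
        if len(seen) != len(self.atoms):
            raise StructuralError("every atom must belong to exactly one residue")
        for k, res in enumerate(self.residues, start=1):
            if res.index != k:
                raise StructuralError("residue indices must be contiguous 1..N")

    # -- array views ----------------------------------------------------------

    @property
    def n_atoms(self) -> int:
        return len(self.atoms)

    @property
    def n_residues(self) -> int:
        return len(self.residues)

    def positions(self) -> np.ndarray:
        return np.array([a.position for a in self.atoms], dtype=float)

    def radii(self) -> np.ndarray:
        out = np.empty(self.n_atoms)
        for i, a in enumerate(self.atoms):
            if a.vdw_radius is None:
                raise StructuralError(f"atom {a.serial} ({a.name}) has no vdW radius")
            out[i] = a.vdw_radius
        return out

    def residue_of_atom(self) -> np.ndarray:
        """1-based residue index per atom."""
        return np.array([a.residue_index for a in self.atoms], dtype=int)

    def atoms_of_residue(self, res_index: int) -> list[int]:
        return list(self.residues[res_index - 1].atom_indices)

    def find_atom(self, res_index: int, name: str) -> int | None:
        for ai in self.residues[res_index - 1].atom_indices:
            if self.atoms[ai].name == name:
                return ai
        return None

    # -- topology -------------------------------------------------------------

    def segments(self) -> list[tuple[int, int]]:
        """Contiguous peptide segments as (first_res, last_res), 1-based."""
        if not self.residues:
            return []
        segs, start = [], 1
        for b in self.chain_breaks:
            segs.append((start, b))
            start = b + 1
        segs.append((start, self.n_residues))
        return segs

    def is_nterm(self, res_index: int) -> bool:
        return any(res_index == s for s, _ in self.segments())

    def is_cterm(self, res_index: int) -> bool:
        return any(res_index == e for _, e in self.segments())

    def translated(self, shift) -> "Structure":
        """A copy rigidly translated by ``shift`` (angstrom)."""
        shift = np.asarray(shift, dtype=float)
        atoms = [Atom(a.serial, a.name, a.element, a.residue_index,
                      a.position + shift, a.vdw_radius, a.reference_charge)
                 for a in self.atoms]
        residues = [Residue(r.name, r.index, list(r.atom_indices), r.chain_id)
                    for r in self.residues]
        return Structure(atoms, residues, list(self.chain_breaks))


@dataclass
class ChargeSet:
    """Per-atom partial charges aligned to a Structure's atom order."""

    values: np.ndarray
    provenance: str  # force_field | ee_gmfcc | mock_reference

    PROVENANCES = ("force_field", "ee_gmfcc", "mock_reference")

    def __post_init__(self):
        self.values = np.asarray(self.values, dtype=float)
        if self.provenance not in self.PROVENANCES:
            raise ValueError(f"unknown provenance {self.provenance!r}")
        if not np.all(np.isfinite(self.values)):
            raise ValueError("charges must be finite")

    @property
    def total(self) -> float:
        return float(self.values.sum())

    def __len__(self) -> int:
        return len(self.values)


# ---------------------------------------------------------------------------
# bundled tables
# ---------------------------------------------------------------------------

def _data_path(name: str) -> Path:
    return Path(str(resources.files("fragcharge").joinpath("data", name)))


def load_charge_table(path: str | Path | None = None) -> dict[tuple[str, str], float]:
    """Read a ``RESNAME ATOMNAME CHARGE`` table (bundled one by default)."""
    path = _data_path("reference_charges.dat") if path is None else Path(path)
    table: dict[tuple[str, str], float] = {}
    for line in path.read_text().splitlines():
        line = line.split("#", 1)[0].strip()
        if not line:
            continue
        res, atom, q = line.split()
        table[(res, atom)] = float(q)
    return table


def load_radius_table(path: str | Path | None = None) -> dict[str, float]:
    """Read an element (or ``ELEMENT:ATOMNAME``) -> radius table."""
    path = _data_path("vdw_radii.dat") if path is None else Path(path)
    table: dict[str, float] = {}
    for line in path.read_text().splitlines():
        line = line.split("#", 1)[0].strip()
        if not line:
            continue
        key, r = line.split()
        table[key] = float(r)
    return table


def assign_radii(structure: Structure, table: dict[str, float] | None = None) -> None:
    """Set every atom's vdW radius from the radius table, in place."""
    table = load_radius_table() if table is None else table
    for atom in structure.atoms:
        key = f"{atom.element}:{atom.name}"
        r = table.get(key, table.get(atom.element))
        if r is None:
            raise StructuralError(
                f"no vdW radius for element {atom.element!r} (atom {atom.name})")
        atom.vdw_radius = r


# ---------------------------------------------------------------------------
# reference charges
# ---------------------------------------------------------------------------

def _patch_for(structure: Structure, res: Residue) -> dict[str, float]:
    """Terminal patch entries (atom name -> charge) for a residue, if any."""
    table = load_charge_table()
    names = set(res.atom_names(structure))
    patch: dict[str, float] = {}
    if structure.is_nterm(res.index):
        key = "NTERM_ZWIT" if "H3" in names else "NTERM_NEUTRAL"
        patch.update({a: q for (r, a), q in table.items() if r == key})
    if structure.is_cterm(res.index):
        key = "CTERM_NEUTRAL" if "HXT" in names else "CTERM_ZWIT"
        if "OXT" in names:
            patch.update({a: q for (r, a), q in table.items() if r == key})
    return patch


def load_reference_charges(structure: Structure,
                           table: dict[tuple[str, str], float] | str | Path | None = None,
                           ) -> ChargeSet:
    """Resolve every atom against the (residue, atom) charge table.

    Terminal residues are resolved through the NTERM_*/CTERM_* patches so
    that per-residue sums stay exactly at the formal charge.
    """
    if table is None or isinstance(table, (str, Path)):
        table = load_charge_table(table)
    values = np.empty(structure.n_atoms)
    unmapped: list[tuple[str, str]] = []
    for res in structure.residues:
        patch = _patch_for(structure, res)
        for ai in res.atom_indices:
            atom = structure.atoms[ai]
            if atom.name in patch:
                values[ai] = patch[atom.name]
            elif (res.name, atom.name) in table:
                values[ai] = table[(res.name, atom.name)]
            else:
                unmapped.append((f"{res.name}{res.index}", atom.name))
    if unmapped:
        raise ChargeLookupError(unmapped)
    cs = ChargeSet(values, provenance="force_field")
    for ai, atom in enumerate(structure.atoms):
        atom.reference_charge = float(values[ai])
    return cs


def residue_formal_charges(structure: Structure, charges: ChargeSet) -> np.ndarray:
    """Formal charge per residue, from rounded reference-charge sums."""
    out = np.zeros(structure.n_residues)
    for res in structure.residues:
        s = sum(charges.values[ai] for ai in res.atom_indices)
        out[res.index - 1] = round(s)
        if abs(s - round(s)) > 1e-6:
            warnings.warn(
                f"residue {res.name}{res.index} charge sum {s:.6f} is not integral")
    return out


# ---------------------------------------------------------------------------
# PDB reading
# ---------------------------------------------------------------------------

def read_pdb(path: str | Path) -> Structure:
    """Parse ATOM records of amino-acid residues into a Structure.

    Non-amino-acid HETATM/ATOM records are skipped and recorded in
    ``structure.warnings``.  Alternate locations resolve to the highest
    occupancy.  A residue missing any of N/CA/C raises StructuralError.
    """
    from Bio.PDB import PDBParser
    from Bio.PDB.PDBExceptions import PDBConstructionWarning

    path = Path(path)
    if not path.exists():
        raise IOError(f"no such file: {path}")
    with warnings.catch_warnings():
        warnings.simplefilter("ignore", PDBConstructionWarning)
        parser = PDBParser(QUIET=True)
        try:
            model = parser.get_structure("s", str(path))[0]
        except (IndexError, ValueError) as exc:
            raise IOError(f"unreadable PDB file {path}: {exc}") from exc

    atoms: list[Atom] = []
    residues: list[Residue] = []
    skipped: list[str] = []
    res_index = 0
    for chain in model:
        for res in chain:
            _, resseq, _ = res.get_id()
            if res.get_resname().strip() not in AMINO_ACIDS:
                skipped.append(f"{res.get_resname().strip()} {chain.id}{resseq}")
                continue
            res_index += 1
            residue = Residue(res.get_resname().strip(), res_index, [], chain.id)
            for name in _ordered_atom_names(res):
                biopy_atom = res[name]
                if biopy_atom.is_disordered():
                    biopy_atom = max(biopy_atom.disordered_get_list(),
                                     key=lambda a: a.get_occupancy() or 0.0)
                element = (biopy_atom.element or _guess_element(name)).strip().capitalize()
                atom = Atom(
                    serial=len(atoms),
                    name=name,
                    element=element,
                    residue_index=res_index,
                    position=np.array(biopy_atom.get_coord(), dtype=float),
                )
                residue.atom_indices.append(len(atoms))
                atoms.append(atom)
            residues.append(residue)

    if not residues:
        raise IOError(f"{path}: no amino-acid ATOM records")

    structure = Structure(atoms, residues, chain_breaks=[])
    structure.chain_breaks = _detect_chain_breaks(structure)
    structure.warnings = [f"skipped non-amino-acid residue {s}" for s in skipped]
    _check_backbone(structure)
    assign_radii(structure)
    return structure


def _ordered_atom_names(res) -> list[str]:
    seen, names = set(), []
    for a in res.get_unpacked_list():
        if a.get_name() not in seen:
            seen.add(a.get_name())
            names.append(a.get_name())
    return names


def _guess_element(name: str) -> str:
    stripped = name.strip()
    if stripped[:1].isdigit():
        stripped = stripped[1:]
    return stripped[:1]


def _detect_chain_breaks(structure: Structure) -> list[int]:
    breaks = []
    for i in range(1, structure.n_residues):
        prev, nxt = structure.residues[i - 1], structure.residues[i]
        if prev.chain_id != nxt.chain_id:
            breaks.append(prev.index)
            continue
        c = structure.find_atom(prev.index, "C")
        n = structure.find_atom(nxt.index, "N")
        if c is None or n is None:
            breaks.append(prev.index)
            continue
        d = math.dist(structure.atoms[c].position, structure.atoms[n].position)
        if d > PEPTIDE_BOND_CUTOFF:
            breaks.append(prev.index)
    return breaks


def _check_backbone(structure: Structure) -> None:
    for res in structure.residues:
        names = set(res.atom_names(structure))
        missing = {"N", "CA", "C"} - names
        if missing:
            raise StructuralError(
                f"residue {res.name}{res.index} missing backbone atom(s) "
                f"{sorted(missing)}")


# ---------------------------------------------------------------------------
# PDB writing (fixtures and round trips)
# ---------------------------------------------------------------------------

def write_pdb(structure: Structure, path: str | Path) -> None:
    """Write plain ATOM records (one chain per segment)."""
    lines = []
    serial = 0
    for res in structure.residues:
        for ai in res.atom_indices:
            a = structure.atoms[ai]
            serial += 1
            name = a.name if len(a.name) >= 4 else f" {a.name:<3s}"
            x, y, z = a.position
            lines.append(
                f"ATOM  {serial:5d} {name:<4s} {res.name:<3s} {res.chain_id}"
                f"{res.index:4d}    {x:8.3f}{y:8.3f}{z:8.3f}"
                f"{1.00:6.2f}{0.00:6.2f}          {a.element:>2s}")
    lines.append("END")
    Path(path).write_text("\n".join(lines) + "\n")


# ---------------------------------------------------------------------------
# PQR
# ---------------------------------------------------------------------------

def write_pqr(structure: Structure, charges: ChargeSet, path: str | Path) -> None:
    """Write whitespace-delimited PQR records (x y z q r)."""
    if len(charges) != structure.n_atoms:
        raise ValueError("charges not aligned to structure")
    lines = []
    serial = 0
    for res in structure.residues:
        for ai in res.atom_indices:
            a = structure.atoms[ai]
            if a.vdw_radius is None:
                raise StructuralError(f"atom {a.serial} ({a.name}): missing radius")
            serial += 1
            x, y, z = a.position
            lines.append(
                f"ATOM  {serial:6d} {a.name:<4s} {res.name:<4s} {res.index:5d} "
                f"{x:10.4f} {y:10.4f} {z:10.4f} {charges.values[ai]:8.4f} "
                f"{a.vdw_radius:7.4f}")
    lines.append("END")
    Path(path).write_text("\n".join(lines) + "\n")


def read_pqr(path: str | Path):
    """Read a PQR file -> (positions (n,3), charges (n,), radii (n,))."""
    pos, q, r = [], [], []
    for line in Path(path).read_text().splitlines():
        if not line.startswith(("ATOM", "HETATM")):
            continue
        parts = line.split()
        pos.append([float(v) for v in parts[-5:-2]])
        q.append(float(parts[-2]))
        r.append(float(parts[-1]))
    return np.array(pos, dtype=float).reshape(-1, 3), np.array(q), np.array(r)
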