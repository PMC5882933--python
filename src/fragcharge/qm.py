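"""QM backend contract: ESP (and optional energy) of an embedded subsystem.

The shipped :class:`MockESPBackend` is the test oracle of the package.  Its
ESP is the Coulomb potential of the subsystem's reference point charges
(link hydrogens carry zero charge), with an optional linear response to the
embedding field so polarization effects are exercisable:

    q_eff(k) = q_ref(k) + gain * (E_bg(r_k) . u_k - mean over subsystem)

where u_k is a fixed per-atom axis (from the whole-structure centroid to
the atom) that does not depend on subsystem composition, and the mean
centring preserves the subsystem's net charge so the charge-constrained
fit can recover q_eff exactly.  gain = 0 gives the exact-recovery oracle.

An optional ab initio backend (pyscf) is provided behind the same contract
for desk-scale peptides; it is inert unless pyscf is installed.
"""

from __future__ import annotations

import hashlib
import json
from dataclasses import dataclass, field

import numpy as np

from .constants import BOHR_PER_ANGSTROM
from .structure import ChargeSet, Structure


@dataclass
class QMTask:
    """One embedded-subsystem ESP request."""

    positions: np.ndarray           # (m, 3) angstrom, link atoms included
    elements: list[str]
    is_link: np.ndarray             # (m,) bool
    net_charge: int
    grid: np.ndarray                # (g, 3) angstrom
    background_positions: np.ndarray = field(
        default_factory=lambda: np.zeros((0, 3)))
    background_charges: np.ndarray = field(default_factory=lambda: np.zeros(0))
    multiplicity: int = 1
    method: str = "mock"
    #: parent atom index per site (-1 for link atoms); used by the mock
    parent_indices: np.ndarray | None = None

    def __post_init__(self):
        if self.multiplicity < 1:
            raise ValueError("multiplicity must be >= 1")
        self.positions = np.asarray(self.positions, dtype=float)
        self.grid = np.asarray(self.grid, dtype=float).reshape(-1, 3)
        if len(self.grid) == 0:
            raise ValueError("ESP task requires a nonempty grid")

    def content_hash(self) -> str:
        h = hashlib.sha256()
        for arr in (self.positions, self.grid, self.background_positions,
                    self.background_charges):
            h.update(np.ascontiguousarray(np.round(arr, 10)).tobytes())
        h.update(json.dumps([self.elements, int(self.net_charge),
                             self.method]).encode())
        return h.hexdigest()


@dataclass
class QMResult:
    esp: np.ndarray                 # atomic units, one per grid point
    total_energy: float | None = None  # hartree
    converged: bool = True
    backend: str = "mock"

    def __post_init__(self):
        self.esp = np.asarray(self.esp, dtype=float)
        if not np.all(np.isfinite(self.esp)):
            raise ValueError("non-finite ESP values")


def coulomb_potential(points: np.ndarray, charge_positions: np.ndarray,
                      charges: np.ndarray) -> np.ndarray:
    """Point-charge potential in atomic units (inputs in angstrom, e)."""
    points = np.asarray(points, dtype=float).reshape(-1, 3)
    if len(charges) == 0:
        return np.zeros(len(points))
    d = np.linalg.norm(points[:, None, :] - charge_positions[None, :, :], axis=2)
    return (np.asarray(charges) / (d * BOHR_PER_ANGSTROM)).sum(axis=1)


def background_field(points: np.ndarray, bg_positions: np.ndarray,
                     bg_charges: np.ndarray) -> np.ndarray:
    """E-field of background point charges, e/angstrom^2 units."""
    points = np.asarray(points, dtype=float).reshape(-1, 3)
    if len(bg_charges) == 0:
        return np.zeros((len(points), 3))
    dv = points[:, None, :] - bg_positions[None, :, :]
    r = np.linalg.norm(dv, axis=2)
    return (np.asarray(bg_charges)[None, :, None] * dv
            / (r ** 3)[:, :, None]).sum(axis=1)


class QMBackend:
    """Backend base: content-hash caching around ``_compute``."""

    name = "abstract"

    def __init__(self):
        self._cache: dict[str, QMResult] = {}
        self.cache_hits = 0

    def compute_esp(self, task: QMTask) -> QMResult:
        key = task.content_hash()
        if key in self._cache:
            self.cache_hits += 1
            return self._cache[key]
        result = self._compute(task)
        self._cache[key] = result
        return result

    def _compute(self, task: QMTask) -> QMResult:  # pragma: no cover
        raise NotImplementedError


class MockESPBackend(QMBackend):
    """Deterministic Coulomb oracle with optional linear embedding response."""

    name = "mock"

    def __init__(self, structure: Structure, reference: ChargeSet,
                 polarization_gain: float = 0.0,
                 atom_constants: np.ndarray | None = None):
        super().__init__()
        if len(reference) != structure.n_atoms:
            raise ValueError("reference charges not aligned to structure")
        self.structure = structure
        self.reference = reference
        self.gain = float(polarization_gain)
        #: per-atom energy constants for the additive mock energy (hartree)
        self.atom_constants = (np.zeros(structure.n_atoms)
                               if atom_constants is None
                               else np.asarray(atom_constants, dtype=float))
        centroid = structure.positions().mean(axis=0)
        axes = structure.positions() - centroid
        norms = np.linalg.norm(axes, axis=1)
        axes[norms < 1e-9] = (1.0, 0.0, 0.0)
        norms = np.linalg.norm(axes, axis=1)
        self.axes = axes / norms[:, None]

    def effective_charges(self, task: QMTask) -> np.ndarray:
        """Per-site charges the mock's ESP corresponds to (links zero)."""
        if task.parent_indices is None:
            raise ValueError("mock backend requires task.parent_indices")
        parents = np.asarray(task.parent_indices)
        q = np.zeros(len(task.positions))
        mask = ~np.asarray(task.is_link, dtype=bool)
        q[mask] = self.reference.values[parents[mask]]
        if self.gain != 0.0 and len(task.background_charges):
            e_field = background_field(task.positions[mask],
                                       task.background_positions,
                                       task.background_charges)
            shift = self.gain * np.einsum(
                "ij,ij->i", e_field, self.axes[parents[mask]])
            # centre per residue: preserves every whole-residue subsystem's
            # net charge AND keeps the response a residue-local linear map,
            # so assembled corrections telescope exactly
            res_of = self.structure.residue_of_atom()[parents[mask]]
            for r in np.unique(res_of):
                sel = res_of == r
                shift[sel] -= shift[sel].mean()
            q[mask] += shift
        return q

    def _compute(self, task: QMTask) -> QMResult:
        q = self.effective_charges(task)
        esp = coulomb_potential(task.grid, task.positions, q)
        return QMResult(esp=esp, total_energy=self._energy(task, q),
                        converged=True, backend=self.name)

    def _energy(self, task: QMTask, q: np.ndarray) -> float:
        """Additive mock energy: constants + internal and embedding Coulomb.

        Constructed so the assembled total (with the pairwise double-count
        deduction) telescopes to the exact whole-molecule value.
        """
        parents = np.asarray(task.parent_indices)
        mask = ~np.asarray(task.is_link, dtype=bool)
        e = float(self.atom_constants[parents[mask]].sum())
        pos = task.positions
        # internal pairs
        for a in range(len(pos)):
            for b in range(a + 1, len(pos)):
                if q[a] == 0.0 or q[b] == 0.0:
                    continue
                r = np.linalg.norm(pos[a] - pos[b]) * BOHR_PER_ANGSTROM
                e += q[a] * q[b] / r
        # embedding pairs
        if len(task.background_charges):
            d = np.linalg.norm(
                pos[:, None, :] - task.background_positions[None, :, :],
                axis=2) * BOHR_PER_ANGSTROM
            e += float((q[:, None] * task.background_charges[None, :] / d).sum())
        return e


class AbInitioBackend(QMBackend):
    """HF ESP via pyscf, for desk-scale peptides.  Optional dependency."""

    name = "ab_initio"

    def __init__(self, basis: str = "6-31g*"):
        super().__init__()
        self.basis = basis
        try:
            import pyscf  # noqa: F401
        except ImportError as exc:  # pragma: no cover
            raise ImportError(
                "the ab initio backend requires pyscf; install it or use "
                "the mock backend") from exc

    def _compute(self, task: QMTask) -> QMResult:  # pragma: no cover
        from pyscf import gto, scf

        mol = gto.M(
            atom=[(el, tuple(p)) for el, p in zip(task.elements, task.positions)],
            charge=task.net_charge, spin=task.multiplicity - 1,
            basis=self.basis, unit="Angstrom")
        mf = scf.RHF(mol)
        if len(task.background_charges):
            from pyscf.qmmm import mm_charge
            mf = mm_charge(mf, task.background_positions,
                           task.background_charges, unit="Angstrom")
        energy = mf.kernel()
        grid_bohr = task.grid * BOHR_PER_ANGSTROM
        # nuclear part
        dv = grid_bohr[:, None, :] - mol.atom_coords()[None, :, :]
        vnuc = (mol.atom_charges() / np.linalg.norm(dv, axis=2)).sum(axis=1)
        # electronic part
        dm = mf.make_rdm1()
        vele = np.empty(len(grid_bohr))
        for g, point in enumerate(grid_bohr):
            with mol.with_rinv_origin(point):
                v = mol.intor("int1e_rinv")
            vele[g] = np.einsum("ij,ij->", v, dm)
        return QMResult(esp=vnuc - vele, total_energy=float(energy),
                        converged=bool(mf.converged), backend=self.name)


def make_backend(kind: str, structure: Structure, reference: ChargeSet,
                 gain: float = 0.0, basis: str = "6-31g*") -> QMBackend:
    if kind == "mock":
        return MockESPBackend(structure, reference, polarization_gain=gain)
    if kind == "ab_initio":
        return AbInitioBackend(basis=basis)
    raise ValueError(f"unknown backend {kind!r}")
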