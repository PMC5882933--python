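"""ESP charge fitting on molecular-surface grids.

The fit minimises || V_model(q) - V_qm ||^2 plus quadratic equality
restraints, subject to a *hard* total-charge constraint.  The constraint
is eliminated exactly (nullspace parametrisation) and the reduced problem
solved by SVD least squares, which keeps the conditioning of the design
matrix rather than of its normal equations; this is algebraically the
same stationary point as the KKT system.

Grids are deterministic Merz-Kollman-style shells built from Fibonacci
sphere lattices -- no randomness anywhere in fitting.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import scipy.linalg

from .constants import BOHR_PER_ANGSTROM
from .errors import FitError, GridError
from .fragmentation import Concap, Subsystem, background_charges
from .qm import QMBackend, QMTask
from .structure import ChargeSet, Structure

#: default Merz-Kollman shell scale factors and surface density (pts/A^2)
DEFAULT_SHELLS = (1.4, 1.6, 1.8, 2.0)
DEFAULT_DENSITY = 1.0
#: default link-atom equality penalty weight (au/e^2)
DEFAULT_W_LINK = 0.1


def fibonacci_sphere(n: int) -> np.ndarray:
    """n near-uniform unit vectors (deterministic golden-angle lattice)."""
    if n < 1:
        raise ValueError("need at least one point")
    k = np.arange(n, dtype=float)
    z = 1.0 - (2.0 * k + 1.0) / n
    phi = k * np.pi * (3.0 - np.sqrt(5.0))
    r = np.sqrt(np.clip(1.0 - z * z, 0.0, None))
    return np.column_stack([r * np.cos(phi), r * np.sin(phi), z])


def generate_mk_grid(positions: np.ndarray, radii: np.ndarray,
                     shells=DEFAULT_SHELLS,
                     density: float = DEFAULT_DENSITY) -> np.ndarray:
    """Union of scaled-vdW sphere surfaces, exclusion-filtered.

    Points on atom a's sphere (radius shell*r_a) are dropped when they lie
    inside any *other* atom's sphere at the same shell scale.
    """
    positions = np.asarray(positions, dtype=float).reshape(-1, 3)
    radii = np.asarray(radii, dtype=float)
    if np.any(radii <= 0):
        raise GridError("all radii must be positive")
    shells = sorted(shells)
    if any(s <= 1.0 for s in shells):
        raise GridError("shell scale factors must exceed 1")
    points = []
    for s in shells:
        scaled = s * radii
        for a in range(len(positions)):
            n = max(1, int(round(4.0 * np.pi * scaled[a] ** 2 * density)))
            sphere = positions[a] + scaled[a] * fibonacci_sphere(n)
            d = np.linalg.norm(sphere[:, None, :] - positions[None, :, :], axis=2)
            d[:, a] = np.inf
            keep = np.all(d >= scaled[None, :] - 1e-12, axis=1)
            if keep.any():
                points.append(sphere[keep])
    if not points:
        raise GridError("MK grid construction produced no points")
    return np.vstack(points)


@dataclass
class FitSpec:
    """Inputs of one constrained ESP fit."""

    grid: np.ndarray                # (g, 3) angstrom
    esp: np.ndarray                 # (g,) atomic units
    positions: np.ndarray           # (n, 3) fitted charge sites
    total_charge: float
    #: quadratic equality restraints: (site index, target, weight in au/e^2)
    restraints: list[tuple[int, float, float]] = field(default_factory=list)
    #: hyperbolic RESP restraint strength toward 0 for heavy atoms (au); 0=off
    resp_strength: float = 0.0
    resp_heavy_mask: np.ndarray | None = None

    def __post_init__(self):
        self.grid = np.asarray(self.grid, dtype=float).reshape(-1, 3)
        self.esp = np.asarray(self.esp, dtype=float)
        self.positions = np.asarray(self.positions, dtype=float).reshape(-1, 3)
        if len(self.grid) != len(self.esp):
            raise FitError("grid/esp length mismatch")
        if len(self.grid) < len(self.positions):
            raise FitError("need at least as many grid points as charges")
        for _, _, w in self.restraints:
            if w < 0:
                raise FitError("restraint weights must be >= 0")


@dataclass
class FittedCharges:
    values: np.ndarray              # per fitted site, e
    rms_residual: float             # au
    condition: float

    def __len__(self):
        return len(self.values)


def _design_matrix(grid: np.ndarray, positions: np.ndarray) -> np.ndarray:
    d = np.linalg.norm(grid[:, None, :] - positions[None, :, :], axis=2)
    if np.any(d < 1e-6):
        raise FitError("grid point coincides with a charge site")
    return 1.0 / (d * BOHR_PER_ANGSTROM)


def fit_charges(spec: FitSpec, _resp_iters: int = 20) -> FittedCharges:
    """Solve the restrained, charge-constrained least-squares ESP fit."""
    n = len(spec.positions)
    a = _design_matrix(spec.grid, spec.positions)

    rows = [a]
    rhs = [spec.esp]
    for idx, target, w in spec.restraints:
        row = np.zeros((1, n))
        row[0, idx] = np.sqrt(w)
        rows.append(row)
        rhs.append(np.array([np.sqrt(w) * target]))

    resp_w = np.zeros(n)
    heavy = (np.zeros(n, dtype=bool) if spec.resp_heavy_mask is None
             else np.asarray(spec.resp_heavy_mask, dtype=bool))
    beta = 0.1
    last = None
    for _ in range(max(1, _resp_iters if spec.resp_strength > 0 else 1)):
        all_rows = list(rows)
        all_rhs = list(rhs)
        if spec.resp_strength > 0 and last is not None:
            w_eff = spec.resp_strength / np.sqrt(last ** 2 + beta ** 2)
            w_eff[~heavy] = 0.0
            all_rows.append(np.diag(np.sqrt(w_eff)))
            all_rhs.append(np.zeros(n))
        m = np.vstack(all_rows)
        b = np.concatenate(all_rhs)

        # eliminate the hard constraint 1^T q = Q
        q0 = np.full(n, spec.total_charge / n)
        z = scipy.linalg.null_space(np.ones((1, n)))
        mz = m @ z
        y, _, rank, sv = np.linalg.lstsq(mz, b - m @ q0, rcond=None)
        if rank < z.shape[1]:
            raise FitError(
                "singular fit system; add grid points or restraints")
        q = q0 + z @ y
        if spec.resp_strength <= 0:
            last = q
            break
        if last is not None and np.max(np.abs(q - last)) < 1e-10:
            last = q
            break
        last = q

    resid = a @ last - spec.esp
    rms = float(np.sqrt(np.mean(resid ** 2)))
    cond = float(sv[0] / sv[-1]) if len(sv) and sv[-1] > 0 else np.inf
    # enforce the constraint to the last ulp
    last = last + (spec.total_charge - last.sum()) / n
    return FittedCharges(values=last, rms_residual=rms, condition=cond)


@dataclass
class FitConfig:
    shells: tuple = DEFAULT_SHELLS
    density: float = DEFAULT_DENSITY
    w_link: float = DEFAULT_W_LINK
    resp_restraint: float = 0.0


def fit_subsystem(structure: Structure, subsystem: Subsystem,
                  backend: QMBackend, reference: ChargeSet,
                  config: FitConfig | None = None,
                  fragment_fits: dict[int, "SubsystemFitResult"] | None = None,
                  extra_background=None) -> "SubsystemFitResult":
    """ESP-fit one capped subsystem in its embedding background.

    Concap link atoms are restrained (weight ``config.w_link``) to the
    already-fitted value of the corresponding fragment link atom, so
    fragments must be fitted first.
    """
    config = config or FitConfig()
    positions, elements, is_link = subsystem.geometry(structure)
    radii = np.empty(len(positions))
    for k, i in enumerate(subsystem.member_atoms):
        radii[k] = structure.atoms[i].vdw_radius
    from .structure import load_radius_table
    h_radius = load_radius_table()["H"]
    radii[len(subsystem.member_atoms):] = h_radius

    grid = generate_mk_grid(positions, radii, config.shells, config.density)
    bg_pos, bg_q = background_charges(structure, subsystem, reference,
                                      extra=extra_background)
    parents = np.array(subsystem.member_atoms
                       + [-1] * len(subsystem.link_atoms))
    task = QMTask(positions=positions, elements=elements, is_link=is_link,
                  net_charge=subsystem.net_charge, grid=grid,
                  background_positions=bg_pos, background_charges=bg_q,
                  method=backend.name, parent_indices=parents)
    result = backend.compute_esp(task)

    restraints = []
    if isinstance(subsystem, Concap):
        if fragment_fits is None:
            raise FitError("concap fits require fragment fits first")
        n_members = len(subsystem.member_atoms)
        for li, frag_center, frag_li in subsystem.link_correspondence:
            try:
                frag_fit = fragment_fits[frag_center]
            except KeyError as exc:
                raise FitError(
                    f"no fitted fragment {frag_center} for concap link "
                    f"{subsystem.link_atoms[li].description}") from exc
            target = frag_fit.link_values[frag_li]
            restraints.append((n_members + li, float(target), config.w_link))

    heavy = np.array([el != "H" for el in elements])
    spec = FitSpec(grid=grid, esp=result.esp, positions=positions,
                   total_charge=float(subsystem.net_charge),
                   restraints=restraints,
                   resp_strength=config.resp_restraint,
                   resp_heavy_mask=heavy)
    fitted = fit_charges(spec)
    return SubsystemFitResult(subsystem=subsystem, fitted=fitted,
                              energy=result.total_energy,
                              n_grid=len(grid))


@dataclass
class SubsystemFitResult:
    subsystem: Subsystem
    fitted: FittedCharges
    energy: float | None = None
    n_grid: int = 0

    @property
    def parent_values(self) -> np.ndarray:
        return self.fitted.values[:len(self.subsystem.member_atoms)]

    @property
    def link_values(self) -> np.ndarray:
        return self.fitted.values[len(self.subsystem.member_atoms):]
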