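"""Finite-difference linearized Poisson-Boltzmann solver and the
self-consistent coupling between the charge pipeline and the continuum
solvent.

The dielectric boundary is the union of atom spheres inflated by the
solvent probe (vdW + probe union surface; re-entrant rolling correction is
deliberately off).  The PB equation div(eps grad phi) = -4 pi rho (+ Debye
screening) is discretised on a cubic grid with 7-point stencils; face
permittivities are harmonic means of samples along each edge, which is the
series-resistance-exact treatment of a 1D interface crossing.  Units:
charges in e, lengths in angstrom, so q*phi is e^2/angstrom and energies
convert to kcal/mol with the 332.0636 Coulomb constant.

The reaction-field potential is the difference between the solvated solve
and a uniform-dielectric vacuum solve on the *same* grid, which cancels
the grid self-energy of the spread charges exactly.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import scipy.sparse
import scipy.sparse.linalg

from .constants import COULOMB_KCAL
from .errors import PBError
from .structure import ChargeSet, Structure


@dataclass
class DielectricModel:
    eps_in: float = 1.0
    eps_out: float = 80.0
    probe_radius: float = 1.4   # angstrom
    kappa: float = 0.0          # inverse Debye length, 1/angstrom

    def __post_init__(self):
        if not (self.eps_out > self.eps_in >= 1.0):
            raise PBError("need eps_out > eps_in >= 1")
        if self.probe_radius < 0:
            raise PBError("probe radius must be >= 0")


@dataclass
class GridSpec:
    spacing: float = 0.4        # angstrom
    padding: float = 8.0        # angstrom beyond the solute extent
    edge_samples: int = 5       # permittivity samples per face edge
    cg_rtol: float = 1e-8
    max_iter: int = 20000


@dataclass
class SolvationState:
    reaction_field_energy: float                 # kcal/mol
    surface_positions: np.ndarray                # (m, 3) angstrom
    surface_charges: np.ndarray                  # (m,) e
    iteration: int = 0
    energy_history: list[float] = field(default_factory=list)


class PBGrid:
    """Grid geometry + dielectric maps, reusable across charge updates."""

    def __init__(self, positions: np.ndarray, radii: np.ndarray,
                 model: DielectricModel, spec: GridSpec):
        positions = np.asarray(positions, dtype=float).reshape(-1, 3)
        radii = np.asarray(radii, dtype=float)
        if np.any(radii <= 0):
            raise PBError("all atom radii must be positive")
        h = spec.spacing
        if h > radii.min():
            raise PBError(
                f"grid spacing {h} too coarse for smallest atom radius "
                f"{radii.min():.2f} (< 2 cells across)")
        self.model = model
        self.spec = spec
        self.h = h
        lo = positions.min(axis=0) - spec.padding
        hi = positions.max(axis=0) + spec.padding
        self.origin = lo
        self.shape = tuple(int(np.ceil((hi[d] - lo[d]) / h)) + 1
                           for d in range(3))
        self.inflated = radii + model.probe_radius
        self.atom_positions = positions
        self._build_eps()

    # -- geometry -------------------------------------------------------------

    def node_coords(self, axis: int) -> np.ndarray:
        return self.origin[axis] + self.h * np.arange(self.shape[axis])

    def _inside(self, pts: np.ndarray) -> np.ndarray:
        """True where a point is inside the inflated-sphere union."""
        inside = np.zeros(len(pts), dtype=bool)
        for p, r in zip(self.atom_positions, self.inflated):
            d2 = ((pts - p) ** 2).sum(axis=1)
            inside |= d2 < r * r
        return inside

    def _build_eps(self) -> None:
        nx, ny, nz = self.shape
        h, m = self.h, self.model
        xs, ys, zs = (self.node_coords(d) for d in range(3))
        k = self.spec.edge_samples
        offsets = (np.arange(k) + 0.5) / k  # fractions along the edge

        def face_eps(axis):
            shape = [nx, ny, nz]
            shape[axis] -= 1
            base = np.stack(np.meshgrid(xs[:shape[0]] if axis == 0 else xs,
                                        ys[:shape[1]] if axis == 1 else ys,
                                        zs[:shape[2]] if axis == 2 else zs,
                                        indexing="ij"), axis=-1)
            pts = base.reshape(-1, 3)
            inv_sum = np.zeros(len(pts))
            for f in offsets:
                sample = pts.copy()
                sample[:, axis] += f * h
                eps = np.where(self._inside(sample), m.eps_in, m.eps_out)
                inv_sum += 1.0 / eps
            return (k / inv_sum).reshape(shape)

        self.eps_x = face_eps(0)
        self.eps_y = face_eps(1)
        self.eps_z = face_eps(2)
        # node-centred inside mask (for Debye screening: solvent only)
        nodes = np.stack(np.meshgrid(xs, ys, zs, indexing="ij"),
                         axis=-1).reshape(-1, 3)
        self.inside_nodes = self._inside(nodes).reshape(self.shape)
        # nodes on the dielectric interface (an axis neighbour differs)
        interface = np.zeros(self.shape, dtype=bool)
        for axis in range(3):
            sl_p = [slice(None)] * 3
            sl_n = [slice(None)] * 3
            sl_p[axis] = slice(0, self.shape[axis] - 1)
            sl_n[axis] = slice(1, self.shape[axis])
            differs = self.inside_nodes[tuple(sl_p)] != self.inside_nodes[tuple(sl_n)]
            interface[tuple(sl_p)] |= differs
            interface[tuple(sl_n)] |= differs
        self.interface_nodes = interface

    # -- assembly -------------------------------------------------------------

    def _interior_index(self):
        nx, ny, nz = self.shape
        idx = -np.ones(self.shape, dtype=np.int64)
        interior = np.zeros(self.shape, dtype=bool)
        interior[1:-1, 1:-1, 1:-1] = True
        idx[interior] = np.arange(interior.sum())
        return idx, interior

    def _assemble(self, eps_x, eps_y, eps_z, screened: bool):
        """Sparse SPD system for the interior unknowns."""
        nx, ny, nz = self.shape
        idx, interior = self._interior_index()
        n_unknown = int(interior.sum())
        rows, cols, vals = [], [], []
        diag = np.zeros(n_unknown)

        def add_faces(eps_f, axis):
            # face between node p and its +axis neighbour
            sl_p = [slice(None)] * 3
            sl_n = [slice(None)] * 3
            sl_p[axis] = slice(0, self.shape[axis] - 1)
            sl_n[axis] = slice(1, self.shape[axis])
            p_idx = idx[tuple(sl_p)].ravel()
            n_idx = idx[tuple(sl_n)].ravel()
            e = eps_f.ravel()
            both = (p_idx >= 0) & (n_idx >= 0)
            rows.extend([p_idx[both], n_idx[both]])
            cols.extend([n_idx[both], p_idx[both]])
            vals.extend([-e[both], -e[both]])
            for a, b in ((p_idx, n_idx), (n_idx, p_idx)):
                inz = a >= 0
                np.add.at(diag, a[inz], e[inz])

        for eps_f, axis in ((eps_x, 0), (eps_y, 1), (eps_z, 2)):
            add_faces(eps_f, axis)

        if screened and self.model.kappa > 0:
            # linearized screening eps_out * kappa^2 phi in solvent nodes
            solvent = (~self.inside_nodes) & interior
            extra = (self.model.eps_out * self.model.kappa ** 2
                     * self.h ** 2)
            diag[idx[solvent]] += extra

        rows.append(np.arange(n_unknown))
        cols.append(np.arange(n_unknown))
        vals.append(diag)
        a = scipy.sparse.csr_matrix(
            (np.concatenate(vals),
             (np.concatenate(rows), np.concatenate(cols))),
            shape=(n_unknown, n_unknown))
        return a, idx, interior

    # -- charge spreading and boundary values ---------------------------------

    def spread_charges(self, positions: np.ndarray, charges: np.ndarray):
        """Trilinear (cloud-in-cell) charge assignment to grid nodes."""
        rho = np.zeros(self.shape)
        frac = (np.asarray(positions) - self.origin) / self.h
        base = np.floor(frac).astype(int)
        t = frac - base
        nx, ny, nz = self.shape
        if np.any(base < 1) or np.any(base + 1 > np.array(self.shape) - 2):
            raise PBError("charge too close to the grid boundary; "
                          "increase padding")
        for dx in (0, 1):
            for dy in (0, 1):
                for dz in (0, 1):
                    w = (np.where(dx, t[:, 0], 1 - t[:, 0])
                         * np.where(dy, t[:, 1], 1 - t[:, 1])
                         * np.where(dz, t[:, 2], 1 - t[:, 2]))
                    np.add.at(rho, (base[:, 0] + dx, base[:, 1] + dy,
                                    base[:, 2] + dz), w * charges)
        return rho

    def boundary_potential(self, positions, charges, eps: float,
                           screened: bool = True):
        """Analytic (optionally Debye-screened) Coulomb boundary values,
        e/angstrom units."""
        nx, ny, nz = self.shape
        phi = np.zeros(self.shape)
        xs, ys, zs = (self.node_coords(d) for d in range(3))
        nodes = np.stack(np.meshgrid(xs, ys, zs, indexing="ij"), axis=-1)
        boundary = np.zeros(self.shape, dtype=bool)
        boundary[0, :, :] = boundary[-1, :, :] = True
        boundary[:, 0, :] = boundary[:, -1, :] = True
        boundary[:, :, 0] = boundary[:, :, -1] = True
        pts = nodes[boundary]
        vals = np.zeros(len(pts))
        kappa = self.model.kappa if screened else 0.0
        for p, q in zip(np.asarray(positions), np.asarray(charges)):
            r = np.linalg.norm(pts - p, axis=1)
            damp = np.exp(-kappa * r) if kappa > 0 else 1.0
            vals += q * damp / (eps * r)
        phi[boundary] = vals
        return phi, boundary

    # -- solving --------------------------------------------------------------

    def _solve(self, eps_x, eps_y, eps_z, rho, phi_bc, screened):
        a, idx, interior = self._assemble(eps_x, eps_y, eps_z, screened)
        rhs = 4.0 * np.pi * rho[interior] / self.h

        # move known boundary values to the RHS
        full_phi = phi_bc.copy()
        for eps_f, axis in ((eps_x, 0), (eps_y, 1), (eps_z, 2)):
            sl_p = [slice(None)] * 3
            sl_n = [slice(None)] * 3
            sl_p[axis] = slice(0, self.shape[axis] - 1)
            sl_n[axis] = slice(1, self.shape[axis])
            p_idx = idx[tuple(sl_p)].ravel()
            n_idx = idx[tuple(sl_n)].ravel()
            e = eps_f.ravel()
            bvals_p = full_phi[tuple(sl_p)].ravel()
            bvals_n = full_phi[tuple(sl_n)].ravel()
            m = (p_idx >= 0) & (n_idx < 0)
            np.add.at(rhs, p_idx[m], e[m] * bvals_n[m])
            m = (n_idx >= 0) & (p_idx < 0)
            np.add.at(rhs, n_idx[m], e[m] * bvals_p[m])

        diag = a.diagonal()
        m_inv = scipy.sparse.diags(1.0 / diag)
        phi_int, info = scipy.sparse.linalg.cg(
            a, rhs, rtol=self.spec.cg_rtol, maxiter=self.spec.max_iter,
            M=m_inv)
        if info != 0:
            res = np.linalg.norm(a @ phi_int - rhs) / np.linalg.norm(rhs)
            raise PBError(f"PB solve did not converge (info={info}, "
                          f"relative residual {res:.2e})")
        phi = full_phi.copy()
        phi[interior] = phi_int
        return phi

    def interpolate(self, phi: np.ndarray, positions: np.ndarray) -> np.ndarray:
        frac = (np.asarray(positions) - self.origin) / self.h
        base = np.floor(frac).astype(int)
        t = frac - base
        out = np.zeros(len(frac))
        for dx in (0, 1):
            for dy in (0, 1):
                for dz in (0, 1):
                    w = (np.where(dx, t[:, 0], 1 - t[:, 0])
                         * np.where(dy, t[:, 1], 1 - t[:, 1])
                         * np.where(dz, t[:, 2], 1 - t[:, 2]))
                    out += w * phi[base[:, 0] + dx, base[:, 1] + dy,
                                   base[:, 2] + dz]
        return out

    def induced_charges(self, phi: np.ndarray):
        """Bound charge per node from the flux of (eps-1) E (Gauss law)."""
        qb = np.zeros(self.shape)
        for eps_f, axis in ((self.eps_x, 0), (self.eps_y, 1),
                            (self.eps_z, 2)):
            sl_p = [slice(None)] * 3
            sl_n = [slice(None)] * 3
            sl_p[axis] = slice(0, self.shape[axis] - 1)
            sl_n[axis] = slice(1, self.shape[axis])
            dphi = phi[tuple(sl_n)] - phi[tuple(sl_p)]
            flux = (eps_f - 1.0) * dphi * self.h / (4.0 * np.pi)
            qb[tuple(sl_p)] += flux
            qb[tuple(sl_n)] -= flux
        return qb


def solve_pb(positions: np.ndarray, charges: np.ndarray, radii: np.ndarray,
             model: DielectricModel | None = None,
             spec: GridSpec | None = None,
             grid: PBGrid | None = None) -> SolvationState:
    """One linearized PB solve: reaction-field energy + induced charges.

    ``grid`` may be passed to reuse a prebuilt dielectric map when only the
    charges change (the self-consistent loop does this).
    """
    model = model or DielectricModel()
    spec = spec or GridSpec()
    positions = np.asarray(positions, dtype=float).reshape(-1, 3)
    charges = np.asarray(charges, dtype=float)
    if grid is None:
        grid = PBGrid(positions, radii, model, spec)
    inside = grid._inside(positions)
    if not inside.all():
        bad = np.where(~inside)[0][:5].tolist()
        raise PBError(f"charges outside the cavity: atom indices {bad}")

    rho = grid.spread_charges(positions, charges)
    phi_bc_solv, _ = grid.boundary_potential(positions, charges, model.eps_out)
    phi_solv = grid._solve(grid.eps_x, grid.eps_y, grid.eps_z, rho,
                           phi_bc_solv, screened=True)

    phi_bc_vac, _ = grid.boundary_potential(positions, charges, model.eps_in,
                                            screened=False)
    eps_in = model.eps_in
    ones = [np.full_like(grid.eps_x, eps_in),
            np.full_like(grid.eps_y, eps_in),
            np.full_like(grid.eps_z, eps_in)]
    phi_vac = grid._solve(*ones, rho, phi_bc_vac, screened=False)

    phi_rf = phi_solv - phi_vac
    e_rf = 0.5 * float(np.dot(charges, grid.interpolate(phi_rf, positions)))
    e_rf *= COULOMB_KCAL

    qb = grid.induced_charges(phi_solv)
    mask = grid.interface_nodes & (np.abs(qb) > 1e-14)
    xs, ys, zs = (grid.node_coords(d) for d in range(3))
    nodes = np.stack(np.meshgrid(xs, ys, zs, indexing="ij"), axis=-1)
    return SolvationState(reaction_field_energy=e_rf,
                          surface_positions=nodes[mask],
                          surface_charges=qb[mask])


def solvation_state_for_structure(structure: Structure, charges: ChargeSet,
                                  model=None, spec=None, grid=None):
    return solve_pb(structure.positions(), charges.values, structure.radii(),
                    model=model, spec=spec, grid=grid)


# ---------------------------------------------------------------------------
# self-consistent reaction field
# ---------------------------------------------------------------------------

@dataclass
class SCRFResult:
    charges: ChargeSet
    state: SolvationState
    converged: bool
    iterations: int
    energy_history: list[float]


def scrf_iterate(structure: Structure, reference: ChargeSet, backend,
                 lam: float = 4.0, tolerance: float = 0.1,
                 max_iter: int = 10, damping: float = 1.0,
                 model: DielectricModel | None = None,
                 spec: GridSpec | None = None,
                 fit_config=None) -> SCRFResult:
    """Iterate charge fitting against the PB reaction field.

    Loop: (1) assemble charges with the current surface charges in every
    subsystem background, (2) solve PB for new surface charges and the
    reaction-field energy, (3) stop when |delta E_rf| < tolerance.
    """
    from .pipeline import compute_charges

    if tolerance <= 0:
        raise ValueError("tolerance must be > 0")
    model = model or DielectricModel()
    spec = spec or GridSpec()
    grid = PBGrid(structure.positions(), structure.radii(), model, spec)

    surface = (np.zeros((0, 3)), np.zeros(0))
    history: list[float] = []
    charges = None
    state = None
    for it in range(1, max_iter + 1):
        extra = surface if len(surface[1]) else None
        result = compute_charges(structure, reference, backend, lam,
                                 fit_config=fit_config, extra_background=extra)
        charges = result.charges
        state = solvation_state_for_structure(structure, charges,
                                              model=model, spec=spec,
                                              grid=grid)
        history.append(state.reaction_field_energy)
        state.iteration = it
        state.energy_history = list(history)
        if len(history) >= 2:
            delta = history[-1] - history[-2]
            if abs(delta) < tolerance:
                return SCRFResult(charges, state, True, it, history)
            if len(history) >= 4:
                d1 = history[-3] - history[-4]
                d2 = history[-2] - history[-3]
                d3 = delta
                if (d1 * d2 < 0 and d2 * d3 < 0
                        and abs(d3) > abs(d2) > abs(d1)):
                    raise PBError(
                        "SCRF oscillation detected (growing sign-alternating "
                        "energy changes); reduce the damping factor")
        new_q = state.surface_charges
        new_p = state.surface_positions
        if damping != 1.0 and len(surface[1]) and len(surface[1]) == len(new_q):
            new_q = damping * new_q + (1.0 - damping) * surface[1]
        surface = (new_p, new_q)
    return SCRFResult(charges, state, False, max_iter, history)


def relative_solvation_energies(conformers: list[Structure],
                                reference_for, backend_for,
                                lam: float = 4.0, tolerance: float = 0.1,
                                max_iter: int = 10,
                                model: DielectricModel | None = None,
                                spec: GridSpec | None = None,
                                fit_config=None):
    """Converged E_rf per conformer, relative to the first conformer.

    ``reference_for(structure)`` and ``backend_for(structure, reference)``
    supply per-conformer reference charges and backends (geometries
    differ, so backends are conformer-specific).
    """
    if len(conformers) < 2:
        raise ValueError("need at least 2 conformers")
    names0 = [(r.name, len(r.atom_indices)) for r in conformers[0].residues]
    for k, s in enumerate(conformers[1:], start=2):
        names = [(r.name, len(r.atom_indices)) for r in s.residues]
        if names != names0:
            raise ValueError(f"conformer {k} topology differs from conformer 1")
    rows = []
    absolute = []
    for s in conformers:
        ref = reference_for(s)
        backend = backend_for(s, ref)
        res = scrf_iterate(s, ref, backend, lam=lam, tolerance=tolerance,
                           max_iter=max_iter, model=model, spec=spec,
                           fit_config=fit_config)
        absolute.append(res.state.reaction_field_energy)
    for k, e in enumerate(absolute, start=1):
        rows.append({"conformer": k, "e_rf": e,
                     "relative_e_rf": e - absolute[0]})
    return rows
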