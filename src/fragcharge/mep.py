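"""Molecular electrostatic potential evaluation on shell grids.

The comparison grid is a regular cubic lattice filtered to the points
whose distance to the closest protein atom lies in [r_min, r_max]
(default 2.5-4.5 angstrom); potentials are point-charge Coulomb sums in
atomic units.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy.spatial import cKDTree

from .errors import GridError
from .qm import coulomb_potential
from .structure import ChargeSet, Structure

DEFAULT_SPACING = 0.8  # angstrom


@dataclass
class ShellGrid:
    points: np.ndarray         # (g, 3) angstrom
    min_distances: np.ndarray  # distance to the closest atom per point
    r_min: float
    r_max: float
    spacing: float

    def __len__(self):
        return len(self.points)


def generate_shell_grid(structure: Structure, r_min: float = 2.5,
                        r_max: float = 4.5,
                        spacing: float = DEFAULT_SPACING) -> ShellGrid:
    """Cubic-lattice points with closest-atom distance in [r_min, r_max]."""
    if not (0.0 < r_min < r_max):
        raise GridError("need 0 < r_min < r_max")
    pos = structure.positions()
    lo = pos.min(axis=0) - r_max
    hi = pos.max(axis=0) + r_max
    axes = [np.arange(lo[d], hi[d] + spacing / 2, spacing) for d in range(3)]
    grid = np.stack(np.meshgrid(*axes, indexing="ij"), axis=-1).reshape(-1, 3)
    d, _ = cKDTree(pos).query(grid)
    keep = (d >= r_min) & (d <= r_max)
    if not keep.any():
        raise GridError("shell grid is empty; refine spacing or bounds")
    return ShellGrid(points=grid[keep], min_distances=d[keep],
                     r_min=r_min, r_max=r_max, spacing=spacing)


def evaluate_potential(charges: ChargeSet, structure: Structure,
                       grid: ShellGrid | np.ndarray) -> np.ndarray:
    """V(g) = sum_k q_k / |g - r_k|, atomic units."""
    if len(charges) != structure.n_atoms:
        raise ValueError("charges not aligned to structure")
    points = grid.points if isinstance(grid, ShellGrid) else np.asarray(grid)
    pos = structure.positions()
    d = np.linalg.norm(points[:, None, :] - pos[None, :, :], axis=2)
    if np.any(d < 1e-6):
        raise GridError("grid point coincides with an atom")
    return coulomb_potential(points, pos, charges.values)


@dataclass
class MEPComparison:
    rmsd: float
    pearson_r: float
    n_points: int


def compare_mep(a: np.ndarray, b: np.ndarray) -> MEPComparison:
    """RMSD and Pearson correlation of two potentials on a shared grid."""
    a = np.asarray(a, dtype=float)
    b = np.asarray(b, dtype=float)
    if a.shape != b.shape:
        raise ValueError("potential arrays differ in length")
    rmsd = float(np.sqrt(np.mean((a - b) ** 2)))
    if np.allclose(a, a[0]) or np.allclose(b, b[0]):
        # constant vectors: correlation undefined; report 1 for equal-up-to-
        # constant inputs, 0 otherwise
        r = 1.0 if np.allclose(a - a.mean(), b - b.mean()) else 0.0
    else:
        r = float(np.corrcoef(a, b)[0, 1])
    return MEPComparison(rmsd=rmsd, pearson_r=r, n_points=len(a))


def lambda_sweep(structure: Structure, reference: ChargeSet, backend,
                 lambdas, grid: ShellGrid, reference_potential: np.ndarray,
                 fit_config=None):
    """Assembled-charge MEP RMSD against a reference potential per lambda.

    Returns a list of dicts (lambda, rmsd, pearson_r, n_pairs) plus a
    monotone-trend diagnostic flag on the last entry.
    """
    from .pipeline import compute_charges

    lambdas = list(lambdas)
    if any(b < a for a, b in zip(lambdas, lambdas[1:])):
        raise ValueError("lambda values must be ascending")
    rows = []
    for lam in lambdas:
        result = compute_charges(structure, reference, backend, lam,
                                 fit_config=fit_config)
        pot = evaluate_potential(result.charges, structure, grid)
        cmp_ = compare_mep(pot, reference_potential)
        rows.append({"lambda": lam, "rmsd": cmp_.rmsd,
                     "pearson_r": cmp_.pearson_r,
                     "n_pairs": len(result.pair_fits)})
    rmsds = [r["rmsd"] for r in rows]
    for row in rows:
        row["monotone_trend"] = all(
            y <= x + 1e-15 for x, y in zip(rmsds, rmsds[1:]))
    return rows
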