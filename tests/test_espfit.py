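import numpy as np
import pytest

from fragcharge.errors import FitError, GridError
from fragcharge.espfit import (FitConfig, FitSpec, fibonacci_sphere,
                               fit_charges, fit_subsystem, generate_mk_grid)
from fragcharge.fragmentation import build_concaps, build_fragments
from fragcharge.qm import MockESPBackend, coulomb_potential


def equality_constrained_oracle(grid, esp, positions, total, fixed):
    """Independent KKT solve with *hard* equality constraints.

    ``fixed``: list of (site index, value).  Used to validate the
    penalty-limit behaviour of the production fitter.
    """
    from fragcharge.constants import BOHR_PER_ANGSTROM

    n = len(positions)
    d = np.linalg.norm(grid[:, None, :] - positions[None, :, :], axis=2)
    a = 1.0 / (d * BOHR_PER_ANGSTROM)
    n_con = 1 + len(fixed)
    kkt = np.zeros((n + n_con, n + n_con))
    rhs = np.zeros(n + n_con)
    kkt[:n, :n] = 2.0 * a.T @ a
    rhs[:n] = 2.0 * a.T @ esp
    kkt[:n, n] = 1.0
    kkt[n, :n] = 1.0
    rhs[n] = total
    for c, (idx, val) in enumerate(fixed, start=1):
        kkt[idx, n + c] = 1.0
        kkt[n + c, idx] = 1.0
        rhs[n + c] = val
    sol = np.linalg.solve(kkt, rhs)
    return sol[:n]


class TestMkGrid:
    def test_single_atom_count_and_radius(self):
        g = generate_mk_grid(np.zeros((1, 3)), np.array([1.5]),
                             shells=[1.4], density=1.0)
        r = np.linalg.norm(g, axis=1)
        assert np.allclose(r, 2.1, atol=1e-12)
        assert len(g) == round(4 * np.pi * 2.1 ** 2 * 1.0)

    def test_exclusion_rule(self):
        pos = np.array([[0.0, 0, 0], [1.5, 0, 0]])
        radii = np.array([1.5, 1.5])
        for scale in (1.4, 2.0):
            g = generate_mk_grid(pos, radii, shells=[scale], density=2.0)
            for p in (pos[0], pos[1]):
                d = np.linalg.norm(g - p, axis=1)
                assert d.min() >= scale * 1.5 - 1e-9

    def test_rejection_sampling_oracle(self):
        """Deterministic lattice vs Monte-Carlo surface-area estimate."""
        pos = np.array([[0.0, 0, 0], [2.0, 0, 0]])
        radii = np.array([1.5, 1.2])
        scale, density = 1.6, 4.0
        g = generate_mk_grid(pos, radii, shells=[scale], density=density)
        rng = np.random.default_rng(0)
        kept = total = 0
        for a in range(2):
            rr = scale * radii[a]
            n_mc = 20000
            v = rng.normal(size=(n_mc, 3))
            v /= np.linalg.norm(v, axis=1)[:, None]
            pts = pos[a] + rr * v
            other = 1 - a
            keep = np.linalg.norm(pts - pos[other], axis=1) >= scale * radii[other]
            area = 4 * np.pi * rr ** 2
            kept += keep.mean() * area * density
            total += area * density
        assert len(g) == pytest.approx(kept, rel=0.02)

    def test_bad_inputs(self):
        with pytest.raises(GridError):
            generate_mk_grid(np.zeros((1, 3)), np.array([0.0]))
        with pytest.raises(GridError):
            generate_mk_grid(np.zeros((1, 3)), np.array([1.0]), shells=[0.9])

    def test_fibonacci_deterministic_unit(self):
        pts = fibonacci_sphere(200)
        assert np.allclose(np.linalg.norm(pts, axis=1), 1.0)
        assert np.array_equal(pts, fibonacci_sphere(200))


class TestFitCharges:
    def _well_separated(self):
        pos = np.array([[0.0, 0, 0], [4.0, 0, 0], [0, 4.0, 1.0]])
        q = np.array([0.4, -0.7, 0.3])
        grid = generate_mk_grid(pos, np.full(3, 1.5), density=1.5)
        esp = coulomb_potential(grid, pos, q)
        return pos, q, grid, esp

    def test_exact_recovery(self):
        pos, q, grid, esp = self._well_separated()
        fit = fit_charges(FitSpec(grid, esp, pos, q.sum()))
        assert np.abs(fit.values - q).max() < 1e-8
        assert fit.rms_residual < 1e-10

    def test_consistent_restraint_changes_nothing(self):
        pos, q, grid, esp = self._well_separated()
        base = fit_charges(FitSpec(grid, esp, pos, q.sum()))
        pinned = fit_charges(FitSpec(grid, esp, pos, q.sum(),
                                     restraints=[(0, q[0], 7.0)]))
        assert np.abs(base.values - pinned.values).max() < 1e-10

    def test_penalty_limit_matches_equality_oracle(self):
        pos, q, grid, esp = self._well_separated()
        # perturb the ESP so the restraint actually binds
        esp_noisy = esp + 1e-3 * np.sin(np.arange(len(esp)))
        target = 0.1234
        soft = fit_charges(FitSpec(grid, esp_noisy, pos, q.sum(),
                                   restraints=[(1, target, 1e6)]))
        hard = equality_constrained_oracle(grid, esp_noisy, pos, q.sum(),
                                           [(1, target)])
        assert np.abs(soft.values - hard).max() < 1e-5

    def test_hard_total_charge_constraint(self):
        pos, q, grid, esp = self._well_separated()
        esp_noisy = esp + 1e-2 * np.cos(np.arange(len(esp)))
        fit = fit_charges(FitSpec(grid, esp_noisy, pos, -2.0))
        assert abs(fit.values.sum() - (-2.0)) < 1e-10

    def test_grid_density_stability(self):
        pos = np.array([[0.0, 0, 0], [1.5, 0, 0], [3.0, 0.5, 0]])
        q = np.array([0.2, -0.5, 0.3])
        radii = np.full(3, 1.5)
        fits = []
        for density in (1.0, 2.0):
            grid = generate_mk_grid(pos, radii, density=density)
            esp = coulomb_potential(grid, pos, q)
            fits.append(fit_charges(FitSpec(grid, esp, pos, q.sum())).values)
        assert np.abs(fits[0] - fits[1]).max() < 1e-3

    def test_resp_zero_restraint_shrinks_heavy_charges(self):
        pos, q, grid, esp = self._well_separated()
        heavy = np.array([True, True, True])
        free = fit_charges(FitSpec(grid, esp, pos, 0.0))
        shrunk = fit_charges(FitSpec(grid, esp, pos, 0.0,
                                     resp_strength=0.5,
                                     resp_heavy_mask=heavy))
        assert np.abs(shrunk.values).sum() < np.abs(free.values).sum()

    def test_underdetermined_rejected(self):
        pos = np.zeros((3, 3))
        pos[1, 0] = 2.0
        pos[2, 1] = 2.0
        with pytest.raises(FitError):
            FitSpec(np.ones((2, 3)), np.ones(2), pos, 0.0)


class TestFitSubsystem:
    def test_fragment_gain0_recovers_reference(self, penta):
        s, q = penta
        backend = MockESPBackend(s, q, 0.0)
        frag = build_fragments(s, q)[0]
        fit = fit_subsystem(s, frag, backend, q)
        assert np.abs(fit.parent_values
                      - q.values[frag.member_atoms]).max() < 1e-9
        assert np.abs(fit.link_values).max() < 1e-9

    def test_concap_links_match_fragment_links(self, penta):
        s, q = penta
        backend = MockESPBackend(s, q, 0.0)
        frag_fits = {f.center_residue_index: fit_subsystem(s, f, backend, q)
                     for f in build_fragments(s, q)}
        for concap in build_concaps(s, q):
            fit = fit_subsystem(s, concap, backend, q,
                                fragment_fits=frag_fits)
            for li, center, fli in concap.link_correspondence:
                assert fit.link_values[li] == pytest.approx(
                    frag_fits[center].link_values[fli], abs=1e-9)

    def test_concap_requires_fragments(self, penta):
        s, q = penta
        backend = MockESPBackend(s, q, 0.0)
        concap = build_concaps(s, q)[0]
        with pytest.raises(FitError):
            fit_subsystem(s, concap, backend, q, fragment_fits=None)

    def test_perturbed_concap_link_deviation_bounded(self, contact):
        s, q = contact
        backend = MockESPBackend(s, q, 0.1)
        config = FitConfig(w_link=0.1)
        frag_fits = {f.center_residue_index:
                     fit_subsystem(s, f, backend, q, config)
                     for f in build_fragments(s, q)}
        for concap in build_concaps(s, q):
            fit = fit_subsystem(s, concap, backend, q, config,
                                fragment_fits=frag_fits)
            for li, center, fli in concap.link_correspondence:
                dev = abs(fit.link_values[li] - frag_fits[center].link_values[fli])
                # penalty algebra: w * dev^2 <= total objective ~ residual^2
                bound = np.sqrt(
                    max(fit.fitted.rms_residual ** 2 * fit.n_grid, 1e-20)
                    / config.w_link)
                assert dev <= bound + 1e-12
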