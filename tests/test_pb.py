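import numpy as np
import pytest

from fragcharge.constants import COULOMB_KCAL
from fragcharge.errors import PBError
from fragcharge.fixtures import PeptideSpec, build_peptide, make_conformers
from fragcharge.pb import (DielectricModel, GridSpec, PBGrid,
                           relative_solvation_energies, scrf_iterate,
                           solvation_state_for_structure, solve_pb)
from fragcharge.qm import MockESPBackend
from fragcharge.structure import load_reference_charges


def born_energy(q, radius, eps_in=1.0, eps_out=80.0):
    return -0.5 * (1.0 / eps_in - 1.0 / eps_out) * COULOMB_KCAL * q * q / radius


COARSE = GridSpec(spacing=0.55, padding=4.0)


class TestDielectricModel:
    def test_invariants(self):
        with pytest.raises(PBError):
            DielectricModel(eps_in=80.0, eps_out=1.0)
        with pytest.raises(PBError):
            DielectricModel(probe_radius=-1.0)


class TestBoundary:
    def test_single_sphere_probe_inflation(self):
        grid = PBGrid(np.zeros((1, 3)), np.array([2.0]),
                      DielectricModel(probe_radius=1.4),
                      GridSpec(spacing=0.5, padding=3.0))
        xs = grid.node_coords(0)
        mid = np.array([grid.node_coords(1).mean(),
                        grid.node_coords(2).mean()])
        # nodes on the x-axis: inside iff |x| < 3.4 (vdW + probe union)
        for i, x in enumerate(xs):
            node = np.array([[x, 0.0, 0.0]])
            assert grid._inside(node)[0] == (abs(x) < 3.4)

    def test_probe_zero_vdw_surface(self):
        grid = PBGrid(np.zeros((1, 3)), np.array([2.0]),
                      DielectricModel(probe_radius=0.0),
                      GridSpec(spacing=0.5, padding=3.0))
        assert grid._inside(np.array([[1.9, 0, 0]]))[0]
        assert not grid._inside(np.array([[2.1, 0, 0]]))[0]

    def test_two_sphere_union_matches_analytic(self):
        pos = np.array([[0.0, 0, 0], [2.5, 0, 0]])
        radii = np.array([2.0, 1.7])
        model = DielectricModel(probe_radius=1.0)
        grid = PBGrid(pos, radii, model, GridSpec(spacing=0.6, padding=3.0))
        rng = np.random.default_rng(0)
        pts = rng.uniform(-4, 7, size=(500, 3))
        inside = grid._inside(pts)
        analytic = ((np.linalg.norm(pts - pos[0], axis=1) < 3.0)
                    | (np.linalg.norm(pts - pos[1], axis=1) < 2.7))
        assert np.array_equal(inside, analytic)

    def test_too_coarse_grid_rejected(self):
        with pytest.raises(PBError, match="coarse"):
            PBGrid(np.zeros((1, 3)), np.array([1.0]), DielectricModel(),
                   GridSpec(spacing=1.5, padding=3.0))


class TestSolvePB:
    def test_born_ion_closed_form(self):
        state = solve_pb(np.zeros((1, 3)), np.array([1.0]), np.array([2.0]),
                         DielectricModel(probe_radius=0.0),
                         GridSpec(spacing=0.25, padding=5.0))
        exact = born_energy(1.0, 2.0)
        assert state.reaction_field_energy == pytest.approx(exact, rel=0.03)

    def test_refinement_decreases_error(self):
        exact = born_energy(1.0, 2.0)
        errors = []
        for h in (0.5, 0.25):
            state = solve_pb(np.zeros((1, 3)), np.array([1.0]),
                             np.array([2.0]),
                             DielectricModel(probe_radius=0.0),
                             GridSpec(spacing=h, padding=5.0))
            errors.append(abs(state.reaction_field_energy - exact))
        assert errors[1] < errors[0]

    def test_equal_dielectrics_give_zero(self):
        # eps_out == eps_in is forbidden by the model; approximate with a
        # minimally larger outside value
        state = solve_pb(np.zeros((1, 3)), np.array([1.0]), np.array([2.0]),
                         DielectricModel(eps_in=1.0, eps_out=1.0 + 1e-9,
                                         probe_radius=0.0),
                         GridSpec(spacing=0.5, padding=4.0))
        assert abs(state.reaction_field_energy) < 1e-5
        assert abs(state.surface_charges.sum()) < 1e-7

    def test_gauss_law_single_ion(self):
        state = solve_pb(np.zeros((1, 3)), np.array([1.0]), np.array([2.0]),
                         DielectricModel(probe_radius=0.0),
                         GridSpec(spacing=0.4, padding=5.0))
        expected = -1.0 * (1.0 - 1.0 / 80.0)
        assert state.surface_charges.sum() == pytest.approx(expected, rel=0.02)

    def test_gauss_law_peptide(self):
        s, q = build_peptide(PeptideSpec("AKA", -57, -47))
        state = solvation_state_for_structure(
            s, q, model=DielectricModel(), spec=COARSE)
        expected = -q.total * (1.0 - 1.0 / 80.0)
        assert state.surface_charges.sum() == pytest.approx(expected, rel=0.02)

    def test_charge_outside_cavity_rejected(self):
        with pytest.raises(PBError, match="outside"):
            solve_pb(np.array([[0.0, 0, 0], [8.0, 0, 0]]),
                     np.array([1.0, 1.0]), np.array([2.0, 2.0]),
                     DielectricModel(probe_radius=0.0),
                     GridSpec(spacing=0.5, padding=4.0),
                     grid=PBGrid(np.zeros((1, 3)), np.array([2.0]),
                                 DielectricModel(probe_radius=0.0),
                                 GridSpec(spacing=0.5, padding=4.0)))

    def test_translation_invariance(self):
        model = DielectricModel(probe_radius=0.0)
        spec = GridSpec(spacing=0.4, padding=4.0)
        e = []
        for shift in (np.zeros(3), np.array([0.13, -0.21, 0.07])):
            state = solve_pb(shift[None, :], np.array([1.0]), np.array([2.0]),
                             model, spec)
            e.append(state.reaction_field_energy)
        assert abs(e[1] - e[0]) / abs(e[0]) < 0.005

    def test_kappa_strengthens_screening(self):
        base = solve_pb(np.zeros((1, 3)), np.array([1.0]), np.array([2.0]),
                        DielectricModel(probe_radius=0.0),
                        GridSpec(spacing=0.4, padding=5.0))
        screened = solve_pb(np.zeros((1, 3)), np.array([1.0]), np.array([2.0]),
                            DielectricModel(probe_radius=0.0, kappa=0.3),
                            GridSpec(spacing=0.4, padding=5.0))
        assert screened.reaction_field_energy < base.reaction_field_energy


class TestSCRF:
    def test_gain0_fixed_point(self, ala3):
        s, ref = ala3
        backend = MockESPBackend(s, ref, 0.0)
        result = scrf_iterate(s, ref, backend, lam=4.0, tolerance=1e-9,
                              max_iter=10, spec=COARSE)
        assert result.converged
        assert result.iterations == 2
        assert result.energy_history[1] == result.energy_history[0]

    def test_small_gain_geometric_convergence(self, ala3):
        s, ref = ala3
        backend = MockESPBackend(s, ref, 0.02)
        result = scrf_iterate(s, ref, backend, lam=4.0, tolerance=1e-7,
                              max_iter=10, spec=COARSE)
        assert result.converged
        deltas = [abs(b - a) for a, b in
                  zip(result.energy_history, result.energy_history[1:])]
        assert all(d2 < d1 for d1, d2 in zip(deltas, deltas[1:]))

    def test_huge_tolerance_single_solve(self, ala3):
        s, ref = ala3
        backend = MockESPBackend(s, ref, 0.02)
        result = scrf_iterate(s, ref, backend, lam=4.0, tolerance=1e9,
                              max_iter=10, spec=COARSE)
        assert result.iterations == 2
        assert len(result.energy_history) == 2

    def test_bad_tolerance(self, ala3):
        s, ref = ala3
        with pytest.raises(ValueError):
            scrf_iterate(s, ref, MockESPBackend(s, ref, 0.0), tolerance=0.0)


class TestRelativeSolvation:
    def test_identical_conformers_zero(self, ala3):
        s, ref = ala3
        confs = [s, s]
        rows = relative_solvation_energies(
            confs, lambda c: load_reference_charges(c),
            lambda c, r: MockESPBackend(c, r, 0.0),
            lam=4.0, tolerance=1e-6, spec=COARSE)
        assert rows[0]["relative_e_rf"] == 0.0
        assert rows[1]["relative_e_rf"] == pytest.approx(0.0, abs=1e-9)

    def test_ordering_matches_single_shot_pb(self):
        spec = PeptideSpec("AGA", -135, 135)
        confs = make_conformers(spec, 3, 20.0, seed=4)
        rows = relative_solvation_energies(
            confs, lambda c: load_reference_charges(c),
            lambda c, r: MockESPBackend(c, r, 0.0),
            lam=4.0, tolerance=1e-6, spec=COARSE)
        # independent one-shot PB on fixed reference charges
        single = []
        for c in confs:
            ref = load_reference_charges(c)
            st = solvation_state_for_structure(c, ref, spec=COARSE)
            single.append(st.reaction_field_energy)
        got = [r["e_rf"] for r in rows]
        assert np.argsort(got).tolist() == np.argsort(single).tolist()
        # zero-gain SCRF equals one-shot PB exactly (fixed-point charges)
        assert np.allclose(got, single, atol=1e-9)

    def test_topology_mismatch_rejected(self, ala3, penta):
        with pytest.raises(ValueError, match="topology"):
            relative_solvation_energies(
                [ala3[0], penta[0]], lambda c: None, lambda c, r: None)
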