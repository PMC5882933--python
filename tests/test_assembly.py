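import numpy as np
import pytest

from fragcharge.assembly import (assemble_charges, assemble_total_energy,
                                 double_count_energy, total_charge_report)
from fragcharge.constants import BOHR_PER_ANGSTROM
from fragcharge.errors import FragchargeError
from fragcharge.fixtures import PeptideSpec, build_peptide
from fragcharge.pipeline import compute_charges
from fragcharge.qm import MockESPBackend
from fragcharge.structure import ChargeSet


class TestAssembleCharges:
    @pytest.mark.parametrize("seq", ["AGS", "AGSV", "AGSVA"])
    def test_gain0_exact_recovery(self, seq):
        s, ref = build_peptide(PeptideSpec(seq, -135.0, 135.0))
        backend = MockESPBackend(s, ref, 0.0)
        result = compute_charges(s, ref, backend, lam=4.0)
        assert np.abs(result.charges.values - ref.values).max() < 1e-10
        assert result.charges.provenance == "ee_gmfcc"

    def test_lambda_irrelevant_at_gain0(self, contact):
        s, ref = contact
        backend = MockESPBackend(s, ref, 0.0)
        r0 = compute_charges(s, ref, backend, lam=0.0)
        r4 = compute_charges(s, ref, backend, lam=4.0)
        assert len(r4.pair_fits) >= 1
        assert np.abs(r0.charges.values - r4.charges.values).max() < 1e-10

    def test_two_body_corrections_zero_at_gain0(self, contact):
        s, ref = contact
        backend = MockESPBackend(s, ref, 0.0)
        result = compute_charges(s, ref, backend, lam=4.0)
        for tb in result.pair_fits:
            correction = np.zeros(s.n_atoms)
            correction[tb.pair.subsystem.member_atoms] += tb.pair.parent_values
            correction[tb.mono_i.subsystem.member_atoms] -= tb.mono_i.parent_values
            correction[tb.mono_j.subsystem.member_atoms] -= tb.mono_j.parent_values
            assert np.abs(correction).max() < 1e-10

    def test_lambda_convergence_with_gain(self, contact):
        s, ref = contact
        backend = MockESPBackend(s, ref, 0.05)
        by_lam = {lam: compute_charges(s, ref, backend, lam=lam).charges.values
                  for lam in (1.7, 2.7, 4.0)}
        d_17_27 = np.abs(by_lam[1.7] - by_lam[2.7]).max()
        d_27_40 = np.abs(by_lam[2.7] - by_lam[4.0]).max()
        assert d_27_40 <= d_17_27

    def test_translation_invariance(self, contact):
        s, ref = contact
        result = compute_charges(s, ref, MockESPBackend(s, ref, 0.05), lam=4.0)
        s2 = s.translated([13.0, -7.0, 3.0])
        ref2 = ChargeSet(ref.values.copy(), ref.provenance)
        result2 = compute_charges(s2, ref2, MockESPBackend(s2, ref2, 0.05),
                                  lam=4.0)
        assert np.abs(result.charges.values
                      - result2.charges.values).max() < 1e-8

    def test_ledger_complete(self, penta):
        s, ref = penta
        result = compute_charges(s, ref, MockESPBackend(s, ref, 0.0), lam=4.0)
        ledger = result.ledger
        assert (ledger.multiplicity == 1).all()
        for k in range(s.n_atoms):
            total = sum(sign * val for _, sign, val in ledger.contributions[k])
            assert total == pytest.approx(ledger.assembled[k], abs=1e-12)

    def test_multiplicity_violation_raises(self, penta):
        s, ref = penta
        backend = MockESPBackend(s, ref, 0.0)
        result = compute_charges(s, ref, backend, lam=0.0)
        with pytest.raises(FragchargeError, match="multiplicity"):
            assemble_charges(s, result.fragment_fits[:-1], result.concap_fits)


class TestTotalChargeReport:
    def test_gain0_zero_deviation(self, penta):
        s, ref = penta
        result = compute_charges(s, ref, MockESPBackend(s, ref, 0.0), lam=0.0)
        dev, out = total_charge_report(result.charges, round(ref.total))
        assert abs(dev) < 1e-10
        assert out is result.charges

    def test_renormalization(self):
        charges = ChargeSet(np.array([0.3, 0.3, 0.3]), "ee_gmfcc")
        dev, out = total_charge_report(charges, 1.0, renormalize=True)
        assert dev == pytest.approx(-0.1)
        assert out.total == pytest.approx(1.0, abs=1e-14)
        assert np.allclose(out.values - charges.values, 0.1 / 3)

    def test_default_returns_unmodified(self):
        charges = ChargeSet(np.array([0.4, 0.4]), "ee_gmfcc")
        dev, out = total_charge_report(charges, 1.0)
        assert dev == pytest.approx(-0.2)
        assert np.array_equal(out.values, charges.values)


class TestEnergyAssembly:
    def test_single_fragment_no_background(self, ala3):
        s, ref = ala3
        consts = np.linspace(0.1, 0.2, s.n_atoms)
        backend = MockESPBackend(s, ref, 0.0, atom_constants=consts)
        result = compute_charges(s, ref, backend, lam=0.0)
        ledger = assemble_total_energy(s, result.charges,
                                       result.fragment_fits,
                                       result.concap_fits, [])
        assert ledger.e_dc == pytest.approx(0.0, abs=1e-12)
        assert ledger.total == pytest.approx(result.fragment_fits[0].energy)

    def test_single_double_counted_pair(self):
        """Two point charges counted twice -> E_DC = q1 q2 / r."""
        from fragcharge.structure import Atom, Residue, Structure

        atoms = [Atom(0, "CA", "C", 1, np.zeros(3), 1.7),
                 Atom(1, "CA", "C", 2, np.array([3.0, 0, 0]), 1.7)]
        s = Structure(atoms, [Residue("ALA", 1, [0]), Residue("ALA", 2, [1])],
                      chain_breaks=[1])
        q = ChargeSet(np.array([0.5, -0.4]), "mock_reference")
        # two subsystems, each containing one atom, each embedded in the
        # other's charge: the pair interaction is counted twice
        e_dc = double_count_energy(s, q, [[0], [1]], [+1, +1])
        expected = 0.5 * -0.4 / (3.0 * BOHR_PER_ANGSTROM)
        assert e_dc == pytest.approx(expected, rel=1e-12)

    def test_additive_oracle_n5(self):
        """Mock energies telescope to the exact whole-molecule value."""
        s, ref = build_peptide(PeptideSpec("AGSVA", -135.0, 135.0))
        consts = np.linspace(-0.3, 0.4, s.n_atoms)
        backend = MockESPBackend(s, ref, 0.0, atom_constants=consts)
        result = compute_charges(s, ref, backend, lam=4.0)
        ledger = assemble_total_energy(s, result.charges,
                                       result.fragment_fits,
                                       result.concap_fits, result.pair_fits)
        # independent whole-molecule evaluation
        pos = s.positions()
        d = np.linalg.norm(pos[:, None, :] - pos[None, :, :], axis=2)
        np.fill_diagonal(d, np.inf)
        coulomb = (np.outer(ref.values, ref.values)
                   / (d * BOHR_PER_ANGSTROM)).sum() / 2.0
        expected = consts.sum() + coulomb
        assert ledger.total == pytest.approx(expected, abs=1e-9)
        arithmetic = (sum(ledger.fragment_energies)
                      - sum(ledger.concap_energies)
                      + sum(ledger.two_body_terms) - ledger.e_dc)
        assert ledger.total == pytest.approx(arithmetic, abs=1e-12)

    def test_additive_oracle_with_contacts(self, contact):
        s, ref = contact
        consts = np.linspace(0.05, 0.15, s.n_atoms)
        backend = MockESPBackend(s, ref, 0.0, atom_constants=consts)
        result = compute_charges(s, ref, backend, lam=4.0)
        assert len(result.pair_fits) >= 1
        ledger = assemble_total_energy(s, result.charges,
                                       result.fragment_fits,
                                       result.concap_fits, result.pair_fits)
        pos = s.positions()
        d = np.linalg.norm(pos[:, None, :] - pos[None, :, :], axis=2)
        np.fill_diagonal(d, np.inf)
        coulomb = (np.outer(ref.values, ref.values)
                   / (d * BOHR_PER_ANGSTROM)).sum() / 2.0
        assert ledger.total == pytest.approx(consts.sum() + coulomb, abs=1e-9)

    def test_missing_energy_raises(self, penta):
        s, ref = penta
        result = compute_charges(s, ref, MockESPBackend(s, ref, 0.0), lam=0.0)
        result.fragment_fits[0].energy = None
        with pytest.raises(FragchargeError, match="energy"):
            assemble_total_energy(s, result.charges, result.fragment_fits,
                                  result.concap_fits, [])
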