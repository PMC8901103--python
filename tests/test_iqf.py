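"""Fragment-level assembly: zeroth-order interaction, four-term split, reports."""

import numpy as np
import pytest

import iqfcp as q
from iqfcp.coulomb import CoulombEngine
from iqfcp.errors import GeometryError, InconsistencyError
from iqfcp.iqf import cp_decomposition, multipolar_penetration, relaxed_iqf, zeroth_order_interaction
from iqfcp.qtaim import assign_basins
from iqfcp.scan import decompose_geometry
from iqfcp.toys import make_toy_dimer, toy_preset


class TestZerothOrderInteraction:
    def test_far_neutral_pair_is_screened(self):
        a = q.build_promolecule(["Ne"], np.zeros((1, 3)))
        b = q.build_promolecule(["Ne"], np.array([[0, 0, 50 * 0.529177]]))
        assert abs(zeroth_order_interaction(a, b)) < 1e-8

    def test_bare_nuclei_point_coulomb(self):
        a = q.GaussianDensity([q.Nucleus("H", 1.0, np.zeros(3))], [])
        b = q.GaussianDensity([q.Nucleus("H", 1.0, np.array([0, 0, 2.0]))], [])
        assert zeroth_order_interaction(a, b) == pytest.approx(0.5, abs=1e-14)

    def test_overlapping_nuclei_rejected(self):
        a = q.GaussianDensity([q.Nucleus("H", 1.0, np.zeros(3))], [])
        b = q.GaussianDensity([q.Nucleus("H", 1.0, np.zeros(3) + 1e-9)], [])
        with pytest.raises(GeometryError):
            zeroth_order_interaction(a, b)

    def test_machinery_total_agrees_with_analytic_oracle(self, hf_system):
        a, b, rho0, g, p, eng = hf_system
        cp = cp_decomposition(a, b, p, engine=eng)
        assert cp.E0_ele == pytest.approx(zeroth_order_interaction(a, b), abs=5e-4)


class TestCPDecomposition:
    def test_four_terms_close_exactly(self, hf_system):
        a, b, rho0, g, p, eng = hf_system
        cp = cp_decomposition(a, b, p, engine=eng)
        assert abs(cp.closure_residual) < 1e-12
        assert cp.E_pen_IQF == cp.E_intra_A + cp.E_intra_B + cp.E_tail_tail

    def test_tail_tail_is_pure_electronic_repulsion(self, hf_system):
        a, b, rho0, g, p, eng = hf_system
        cp = cp_decomposition(a, b, p, engine=eng)
        tt = cp.breakdowns["tail_tail"]
        assert tt.en == 0.0 and tt.nn == 0.0
        assert cp.E_tail_tail >= 0.0

    def test_far_limit_kills_penetration_terms(self, cheap_spec):
        spec = toy_preset("hf", separation=3.2 * 3.0)
        a, b, frag = make_toy_dimer(spec)
        cp, _ = decompose_geometry(a, b, frag, grid_spec=cheap_spec)
        assert abs(cp.E_pen_IQF) < 1e-5
        assert cp.E0_ele == pytest.approx(cp.E_inter_AB, abs=1e-5)

    def test_mirror_symmetric_homodimer_has_equal_intra_terms(self, disp_system):
        a, b, rho0, g, p, eng = disp_system
        cp = cp_decomposition(a, b, p, engine=eng)
        assert cp.E_intra_A == pytest.approx(cp.E_intra_B, abs=1e-6)

    def test_relabeling_swaps_intra_terms_and_keeps_penetration(self, hf_system):
        a, b, rho0, g, p, eng = hf_system
        cp_ab = cp_decomposition(a, b, p, engine=eng)
        cp_ba = cp_decomposition(b, a, p, engine=eng)
        assert cp_ba.E_intra_A == pytest.approx(cp_ab.E_intra_B, abs=1e-12)
        assert cp_ba.E_intra_B == pytest.approx(cp_ab.E_intra_A, abs=1e-12)
        assert cp_ba.E_pen_IQF == pytest.approx(cp_ab.E_pen_IQF, abs=1e-12)
        assert cp_ba.mutual_cp_A == pytest.approx(cp_ab.mutual_cp_B, abs=1e-12)

    def test_mutual_cp_counts_complete_the_monomer_charge(self, hf_system):
        a, b, rho0, g, p, eng = hf_system
        cp = cp_decomposition(a, b, p, engine=eng)
        assert cp.NB_grid == pytest.approx(cp.NB, abs=2e-3)
        assert cp.NA_grid == pytest.approx(cp.NA, abs=2e-3)
        assert cp.mutual_cp_A > 0

    def test_report_dict_carries_both_unit_systems(self, hf_system):
        a, b, rho0, g, p, eng = hf_system
        d = cp_decomposition(a, b, p, engine=eng).to_dict("hf", 1.0)
        assert d["kcalmol"]["E0_ele"] == pytest.approx(
            d["E0_ele"] * q.HARTREE_TO_KCALMOL
        )
        assert set(d) >= {"E0_ele", "E_inter_AB", "E_intra_A", "E_intra_B",
                          "E_tail_tail", "E_pen_IQF", "q_pen_A", "q_pen_B"}


class TestRelaxedIQF:
    def test_zeroth_order_complex_reduces_to_cp_totals(self, disp_system):
        a, b, rho0, g, p, eng = disp_system
        cp = cp_decomposition(a, b, p, engine=eng)
        rep = relaxed_iqf(rho0, a, b, p, engine=eng)
        assert rep.mode == "zeroth_order"
        assert abs(rep.closure_residual) < 1e-12
        assert rep.dE_ele == pytest.approx(cp.E0_ele, abs=5e-4)

    def test_polarization_of_one_fragment_changes_its_intra_term(self, cheap_spec):
        a, b, frag = make_toy_dimer(toy_preset("disp"))
        a_pol = q.polarize_atom(a, 0, 0.1, np.array([0, 0, 0.5]))
        rho = q.ComplexDensity([a_pol, b], mode="relaxed")
        g = q.build_grid(rho, cheap_spec)
        p = assign_basins(rho, g, frag)
        eng = CoulombEngine(p, g)
        rep = relaxed_iqf(rho, a, b, p, engine=eng)
        assert rep.mode == "relaxed"
        assert abs(rep.dE_A) > 10 * abs(rep.dE_B)

    def test_electron_count_mismatch_rejected(self, disp_system):
        a, b, rho0, g, p, eng = disp_system
        small = q.build_promolecule(["Ne"], np.zeros((1, 3)), populations=[9.0])
        with pytest.raises(InconsistencyError):
            relaxed_iqf(rho0, small, b, p, engine=eng)


class TestMultipolarPenetration:
    def test_definition_and_truncation_record(self):
        rec = multipolar_penetration(-0.010, -0.007, l_max=2)
        assert rec.E_pen == pytest.approx(-0.003)
        assert rec.l_max == 2

    def test_point_charge_system_has_zero_penetration(self):
        a = q.GaussianDensity([q.Nucleus("H", 1.0, np.zeros(3))], [])
        b = q.GaussianDensity([q.Nucleus("H", 1.0, np.array([0, 0, 4.0]))], [])
        E0 = zeroth_order_interaction(a, b)
        from iqfcp.multipole import MultipoleSet, mtp_interaction

        A = MultipoleSet(np.zeros((1, 3)), np.array([[1.0]]), 0)
        B = MultipoleSet(np.array([[0, 0, 4.0]]), np.array([[1.0]]), 0)
        E_mtp, _ = mtp_interaction(A, B)
        assert multipolar_penetration(E0, E_mtp).E_pen == pytest.approx(0.0, abs=1e-14)
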