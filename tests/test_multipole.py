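"""Point-charge / distributed-multipole comparators and ESP fitting."""

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

import iqfcp as q
from iqfcp.errors import InconsistencyError
from iqfcp.harmonics import regular_solid_harm
from iqfcp.multipole import MultipoleSet, atom_pair_compare, esp_grid, fit_charges, mtp_interaction


def _site(pos, Q, l_max):
    return MultipoleSet(np.atleast_2d(np.asarray(pos, float)),
                        np.atleast_2d(np.asarray(Q, float)), l_max)


class TestInteractionTensors:
    def test_point_charges(self):
        E, _ = mtp_interaction(_site([0, 0, 0], [1.0], 0), _site([0, 0, 2], [-1.0], 0))
        assert E == pytest.approx(-0.5, abs=1e-14)

    def test_collinear_coaligned_dipoles(self):
        # mu_z = Q10 at index 1
        A = _site([0, 0, 0], [0, 1, 0, 0], 1)
        B = _site([0, 0, 10], [0, 1, 0, 0], 1)
        assert mtp_interaction(A, B)[0] == pytest.approx(-2e-3, abs=1e-15)

    def test_charge_with_radially_outward_dipole(self):
        A = _site([0, 0, 0], [1, 0, 0, 0], 1)
        B = _site([0, 0, 5], [0, 1, 0, 0], 1)
        assert mtp_interaction(A, B)[0] == pytest.approx(-0.04, abs=1e-15)

    @settings(max_examples=20, deadline=None, derandomize=True)
    @given(st.integers(0, 10_000))
    def test_point_charge_cluster_oracle_and_symmetry(self, seed):
        """Moments of random neutral point-charge clusters reproduce the exact
        far-field interaction; the energy is symmetric under set exchange."""
        rng = np.random.default_rng(seed)
        qa = rng.uniform(-1, 1, 4)
        qa -= qa.mean()
        ra = rng.uniform(-0.4, 0.4, (4, 3))
        qb = rng.uniform(-1, 1, 4)
        qb -= qb.mean()
        off = np.array([0, 0, 14.0])
        rb = rng.uniform(-0.4, 0.4, (4, 3)) + off
        QA = (regular_solid_harm(2, ra) * qa[None, :]).sum(axis=1)
        QB = (regular_solid_harm(2, rb - off) * qb[None, :]).sum(axis=1)
        A, B = _site([0, 0, 0], QA, 2), _site(off, QB, 2)
        Eab = mtp_interaction(A, B)[0]
        Eba = mtp_interaction(B, A)[0]
        exact = sum(qa[i] * qb[j] / np.linalg.norm(ra[i] - rb[j])
                    for i in range(4) for j in range(4))
        assert Eab == pytest.approx(Eba, rel=1e-12, abs=1e-15)
        assert Eab == pytest.approx(exact, abs=5e-7)

    def test_coincident_sites_rejected(self):
        A = _site([0, 0, 0], [1.0], 0)
        with pytest.raises(InconsistencyError):
            mtp_interaction(A, A)


class TestEspGrid:
    def test_single_atom_single_shell_radius(self):
        d = q.build_promolecule(["O"], np.zeros((1, 3)))
        pts = esp_grid(d, shells=(1.4,))
        r = np.linalg.norm(pts, axis=1)
        expected = 1.4 * 1.52 * q.BOHR_PER_ANGSTROM
        np.testing.assert_allclose(r, expected, rtol=1e-12)

    def test_diatomic_excludes_interior_points(self):
        d = q.build_promolecule(["O", "H"], np.array([[0, 0, 0], [1.0, 0, 0]]))
        pts = esp_grid(d)
        radii = {"O": 1.52, "H": 1.20}
        for sym, pos in zip(["O", "H"], d.positions):
            for scale in (1.4, 1.6, 1.8, 2.0):
                r = np.linalg.norm(pts - pos, axis=1)
                assert np.all(r >= 1.4 * radii[sym] * q.BOHR_PER_ANGSTROM * (1 - 1e-9))

    def test_deterministic_across_runs(self):
        d = q.build_promolecule(["O", "H"], np.array([[0, 0, 0], [1.0, 0, 0]]))
        assert esp_grid(d).tobytes() == esp_grid(d).tobytes()


class TestFitCharges:
    def test_recovers_point_like_charges(self):
        d = q.build_promolecule(
            ["H", "H"], np.array([[0, 0, 0], [0, 0, 1.2]]),
            params={"H": 25.0}, populations=[0.5, 1.5],
        )
        ms = fit_charges(d, esp_grid(d))
        np.testing.assert_allclose(ms.Q[:, 0], [0.5, -0.5], atol=1e-3)

    def test_neutral_spherical_atom_fits_zero(self):
        d = q.build_promolecule(["O"], np.zeros((1, 3)))
        ms = fit_charges(d, esp_grid(d))
        assert abs(ms.Q[0, 0]) < 1e-3

    def test_total_charge_constraint_is_exact(self):
        d = q.build_promolecule(["O", "H"], np.array([[0, 0, 0], [0.96, 0, 0]]))
        ms = fit_charges(d, esp_grid(d), total_charge=0.0)
        assert ms.total_charge == pytest.approx(0.0, abs=1e-12)

    def test_rank_deficient_design_rejected(self):
        d = q.build_promolecule(["H", "H"], np.array([[0, 0, -0.6], [0, 0, 0.6]]))
        # points on the perpendicular bisector see both atoms identically
        t = np.linspace(0, 2 * np.pi, 12, endpoint=False)
        pts = np.column_stack([3 * np.cos(t), 3 * np.sin(t), np.zeros_like(t)])
        with pytest.raises(InconsistencyError, match="shells|rank"):
            fit_charges(d, pts)

    def test_too_few_points_rejected(self):
        d = q.build_promolecule(["O", "H"], np.array([[0, 0, 0], [0.96, 0, 0]]))
        with pytest.raises(InconsistencyError):
            fit_charges(d, np.array([[5.0, 0, 0]]))


class TestAtomPairCompare:
    def test_identical_matrices_are_perfectly_correlated(self):
        m = np.array([[1.0, -2.0], [0.5, 3.0]])
        _, stats = atom_pair_compare(m, m)
        assert stats["R2"] == pytest.approx(1.0)
        assert stats["spearman_rho"] == pytest.approx(1.0)
        assert stats["RMS"] == 0.0

    def test_single_perturbed_pair_tops_difference_table(self):
        m = np.array([[1.0, -2.0], [0.5, 3.0]])
        m2 = m.copy()
        m2[1, 0] += 0.7
        table, _ = atom_pair_compare(m, m2)
        assert (table.loc[0, "site_i"], table.loc[0, "site_j"]) == (1, 0)
        assert table.loc[0, "delta"] == pytest.approx(0.7)

    def test_shape_mismatch_rejected(self):
        with pytest.raises(InconsistencyError):
            atom_pair_compare(np.zeros((2, 2)), np.zeros((2, 3)))


def test_multipole_text_format_round_trip():
    sites = np.array([[0.0, 0, 0], [0, 0, 2.0]])
    Q = np.arange(18, dtype=float).reshape(2, 9) / 10
    ms = MultipoleSet(sites, Q, 2, labels=["O", "H"])
    ms2 = MultipoleSet.from_text(ms.to_text())
    np.testing.assert_allclose(ms2.sites, sites, atol=1e-9)
    np.testing.assert_allclose(ms2.Q, Q, atol=1e-12)
    assert ms2.l_max == 2
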