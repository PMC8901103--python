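"""Restricted-piece Coulomb machinery: expansions, potentials, pair energies."""

import numpy as np
import pytest
from scipy.special import erf

import iqfcp as q
from iqfcp.coulomb import CoulombEngine, ExpansionSettings, RestrictedPiece
from iqfcp.harmonics import degree_of_index
from iqfcp.qtaim import assign_basins
from iqfcp.toys import make_toy_dimer, toy_preset


def _cloud(pos, alpha=1.0, pop=1.0, Z=1.0, symbol="H"):
    c = np.asarray(pos, dtype=float)
    return q.GaussianDensity([q.Nucleus(symbol, Z, c)],
                             [q.GaussianPrimitive(c, alpha, pop)])


@pytest.fixture(scope="module")
def two_clouds(test_spec):
    c1 = _cloud((0, 0, 0))
    c2 = _cloud((0, 0, 2.0))
    rho0 = q.ComplexDensity([c1, c2])
    g = q.build_grid(rho0, test_spec)
    p = assign_basins(rho0, g)
    return c1, c2, rho0, g, p, CoulombEngine(p, g)


class TestExpansion:
    def test_spherical_whole_space_piece_is_pure_monopole(self, two_clouds):
        c1, *_, eng = two_clouds
        exp = eng.expansion(c1, None, center=np.zeros(3))
        ell = degree_of_index(exp.l_max)
        assert np.all(np.abs(exp.f_lm[ell > 0]) < 1e-10)

    def test_piece_electron_count_matches_masked_grid_integral(self, two_clouds):
        c1, c2, rho0, g, p, eng = two_clouds
        exp = eng.expansion(c1, 0)
        direct = float(g.weights[p.mask(0)] @ c1.evaluate(g.points[p.mask(0)]))
        assert exp.electron_count == pytest.approx(direct, abs=1e-3)

    def test_half_space_restriction_creates_dipole_toward_retained_half(self, two_clouds):
        c1, c2, rho0, g, p, eng = two_clouds
        # basin 0 is the half-space z < 1 for this symmetric pair
        exp = eng.expansion(c1, 0)
        from iqfcp.harmonics import lm_index

        f10 = exp.f_lm[lm_index(1, 0)]
        # the retained half points toward -z beyond the center: net negative z-moment
        mom = np.trapezoid(f10 * exp.r_mesh**3, exp.r_mesh)
        assert mom < -1e-4


class TestRestrictedPotential:
    def test_whole_space_far_point_is_q_over_r(self, two_clouds):
        *_, eng = two_clouds
        c = _cloud((0, 0, 0), alpha=1.3, pop=2.0)
        exp = eng.expansion(c, None, center=np.zeros(3))
        v = q.restricted_potential(exp, np.array([[12.0, 0, 0]]))[0]
        assert v == pytest.approx(2.0 / 12.0, abs=1e-6)

    def test_center_value_matches_erf_closed_form(self, two_clouds):
        *_, eng = two_clouds
        c = _cloud((0, 0, 0), alpha=1.3, pop=2.0)
        exp = eng.expansion(c, None, center=np.zeros(3))
        v = q.restricted_potential(exp, np.zeros((1, 3)))[0]
        assert v == pytest.approx(2.0 * 2.0 * np.sqrt(1.3 / np.pi), abs=1e-4)

    def test_zero_density_piece_has_zero_potential(self, two_clouds):
        c1, c2, rho0, g, p, eng = two_clouds
        empty = q.GaussianDensity([], [])
        exp = eng.expansion(empty, None, center=np.zeros(3))
        pts = np.array([[0.0, 0, 0], [1.0, 2.0, 3.0]])
        np.testing.assert_allclose(exp.potential(pts), 0.0, atol=1e-15)


class TestPiecePieceEnergy:
    def test_whole_space_gaussian_pair_matches_erf_formula(self, two_clouds):
        c1, c2, rho0, g, p, eng = two_clouds
        e = eng.piece_piece_energy(
            RestrictedPiece(c1, None, include_nuclei=False),
            RestrictedPiece(c2, None, include_nuclei=False),
        )
        exact = erf(np.sqrt(0.5) * 2.0) / 2.0
        assert e.ee == pytest.approx(exact, abs=1e-6)
        assert e.en == 0.0 and e.nn == 0.0

    def test_bare_nuclei_interaction_is_point_coulomb(self, two_clouds):
        c1, c2, rho0, g, p, eng = two_clouds
        bare1 = q.GaussianDensity([q.Nucleus("H", 1.0, np.zeros(3))], [])
        bare2 = q.GaussianDensity([q.Nucleus("H", 1.0, np.array([0, 0, 2.0]))], [])
        e = eng.piece_piece_energy(
            RestrictedPiece(bare1, None, True), RestrictedPiece(bare2, None, True)
        )
        assert e.nn == pytest.approx(0.5, abs=1e-12)
        assert e.ee == 0.0

    def test_far_disjoint_neutral_pieces_interact_negligibly(self, test_spec):
        a = q.build_promolecule(["Ne"], np.zeros((1, 3)), label="A")
        b = q.build_promolecule(["Ne"], np.array([[0, 0, 40 * 0.529177]]), label="B")
        rho0 = q.ComplexDensity([a, b])
        g = q.build_grid(rho0, test_spec)
        p = assign_basins(rho0, g)
        eng = CoulombEngine(p, g)
        e = eng.piece_piece_energy(
            RestrictedPiece(a, (0,), True), RestrictedPiece(b, (1,), True)
        )
        assert abs(e.total) < 1e-6

    def test_bilinearity_in_the_density_argument(self, two_clouds):
        c1, c2, rho0, g, p, eng = two_clouds
        # split c1's cloud into two half-population clouds
        h1 = _cloud((0, 0, 0), pop=0.4)
        h2 = _cloud((0, 0, 0), pop=0.6)
        p2 = RestrictedPiece(c2, None, include_nuclei=False)
        whole = eng.piece_piece_energy(RestrictedPiece(c1, None, False), p2)
        parts = (
            eng.piece_piece_energy(RestrictedPiece(h1, None, False), p2).ee
            + eng.piece_piece_energy(RestrictedPiece(h2, None, False), p2).ee
        )
        assert whole.ee == pytest.approx(parts, abs=1e-10)


class TestTotalElectrostaticEnergy:
    def test_matrix_sums_to_scalar_total(self, hf_system):
        a, b, rho0, g, p, eng = hf_system
        E, M = q.total_electrostatic_energy(rho0, p, engine=eng)
        assert M.sum() == pytest.approx(E, abs=1e-10)

    def test_homodimer_matrix_is_symmetric(self, disp_system):
        a, b, rho0, g, p, eng = disp_system
        E, M = eng.total_matrix(rho0)
        assert M[0, 0] == pytest.approx(M[1, 1], abs=1e-9)
        assert M[0, 1] == pytest.approx(M[1, 0], abs=1e-12)

    def test_pair_energy_matches_double_grid_brute_force(self, cheap_spec):
        """O(N^2) double-sum oracle over masked grid points for E^IJ."""
        a, b, frag = make_toy_dimer(toy_preset("hf"))
        rho0 = q.ComplexDensity([a, b])
        g = q.build_grid(rho0, cheap_spec)
        p = assign_basins(rho0, g, frag)
        eng = CoulombEngine(p, g)
        _, M = eng.total_matrix(rho0)
        e_machinery = M[0, 1] + M[1, 0]

        rho = rho0.evaluate(g.points)
        mA, mB = p.mask(0), p.mask(1)
        qa = g.weights[mA] * rho[mA]
        qb = g.weights[mB] * rho[mB]
        pa, pb = g.points[mA], g.points[mB]
        from scipy.spatial.distance import cdist

        ee = 0.0
        for i in range(0, pa.shape[0], 2000):
            ee += float(qa[i:i + 2000] @ (1.0 / cdist(pa[i:i + 2000], pb)) @ qb)
        za, ra = rho0.charges[0], rho0.positions[0]
        zb, rb = rho0.charges[1], rho0.positions[1]
        en = -za * float(qb @ (1.0 / np.linalg.norm(pb - ra, axis=1)))
        en += -zb * float(qa @ (1.0 / np.linalg.norm(pa - rb, axis=1)))
        nn = za * zb / np.linalg.norm(ra - rb)
        assert e_machinery == pytest.approx(ee + en + nn, abs=1e-3)

    def test_region_completeness_recovers_total_coulomb_energy(self, disp_system):
        """Sum over all basin-pair pieces vs the analytic self-Coulomb energy."""
        a, b, rho0, g, p, eng = disp_system
        E, _ = eng.total_matrix(rho0)
        c, al, qq = np.vstack([a._prim_arrays()[0], b._prim_arrays()[0]]), None, None
        prims = a.primitives + b.primitives
        cs = np.array([pr.center for pr in prims])
        als = np.array([pr.exponent for pr in prims])
        qs = np.array([pr.population for pr in prims])
        r = np.linalg.norm(cs[:, None] - cs[None, :], axis=2)
        mu = np.sqrt(als[:, None] * als[None, :] / (als[:, None] + als[None, :]))
        v = np.where(r < 1e-12, 2 * mu / np.sqrt(np.pi),
                     erf(mu * np.maximum(r, 1e-12)) / np.maximum(r, 1e-12))
        ee = 0.5 * float((qs[:, None] * qs[None, :] * v).sum())
        pos, z = rho0.positions, rho0.charges
        rn = np.linalg.norm(cs[:, None] - pos[None, :], axis=2)
        vn = np.where(rn < 1e-12, 2 * np.sqrt(als)[:, None] / np.sqrt(np.pi),
                      erf(np.sqrt(als)[:, None] * np.maximum(rn, 1e-12))
                      / np.maximum(rn, 1e-12))
        en = -float((qs[:, None] * z[None, :] * vn).sum())
        nn = sum(z[i] * z[j] / np.linalg.norm(pos[i] - pos[j])
                 for i in range(len(z)) for j in range(i + 1, len(z)))
        assert E == pytest.approx(ee + en + nn, abs=1e-3)

    def test_lmax_10_and_14_agree_on_contact_dimer(self, hf_system):
        a, b, rho0, g, p, _ = hf_system
        e10 = CoulombEngine(p, g, ExpansionSettings(l_max=10)).total_matrix(rho0)[0]
        e14 = CoulombEngine(p, g, ExpansionSettings(l_max=14)).total_matrix(rho0)[0]
        assert abs(e10 - e14) < 1e-4
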