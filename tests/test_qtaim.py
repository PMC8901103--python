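"""QTAIM basin assignment, populations, multipoles and fragment maps."""

import warnings

import numpy as np
import pytest

import iqfcp as q
from iqfcp.errors import InconsistencyError, NonNuclearAttractorError
from iqfcp.harmonics import lm_index
from iqfcp.qtaim import Fragmentation, assign_basins


class TestFragmentation:
    def test_range_spec_parses(self):
        fr = Fragmentation.from_spec("A=1-2,B=3-4", 4)
        assert fr.labels == ("A", "A", "B", "B")
        assert fr.atoms_of("B") == [2, 3]

    @pytest.mark.parametrize("bad", ["A=1-2", "A=1-3,B=3-4", "A=1-2,B=3-9", "junk"])
    def test_bad_specs_rejected(self, bad):
        with pytest.raises(InconsistencyError):
            Fragmentation.from_spec(bad, 4)

    def test_exactly_two_fragments_required(self):
        with pytest.raises(InconsistencyError):
            Fragmentation(("A", "A"))
        with pytest.raises(InconsistencyError):
            Fragmentation(("A", "B", "C"))


class TestAssignBasins:
    def test_symmetric_homodimer_splits_half_half(self, disp_system):
        a, b, rho0, grid, part, _ = disp_system
        pops = q.basin_population(part, rho0, grid)
        assert pops[0] == pytest.approx(pops[1], abs=1e-3)
        assert pops.sum() == pytest.approx(20.0, abs=2e-3)
        # perpendicular-bisector partition: ownership follows the closer atom
        z = grid.points[:, 2]
        mid = 0.5 * (grid.nuclei_positions[0, 2] + grid.nuclei_positions[1, 2])
        interior = np.abs(z - mid) > 0.2
        assert np.all((part.owner[interior] == 0) == (z[interior] < mid))

    def test_isolated_atom_single_basin(self, cheap_spec):
        d = q.build_promolecule(["O"], np.zeros((1, 3)))
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            g = q.build_grid(d, cheap_spec)
            part = assign_basins(d, g)
        assert part.n_basins == 1
        assert np.all(part.owner == 0)

    def test_heteronuclear_populations_match_fine_trajectory_oracle(self, hf_system):
        """Independent oracle: per-point steepest ascent with a 5x smaller
        step and capture radius, following the gradient field directly."""
        a, b, rho0, grid, part, _ = hf_system
        rho = rho0.evaluate(grid.points)
        sel = rho * grid.weights > 1e-9  # points carrying measurable charge
        pts = grid.points[sel].copy()
        attr = part.attractors
        owner = np.full(pts.shape[0], -1)
        x = pts.copy()
        step = np.full(x.shape[0], 0.02)
        for _ in range(2000):
            live = owner < 0
            if not live.any():
                break
            rr, gg = rho0.density_and_gradient(x[live])
            gn = np.linalg.norm(gg, axis=1)
            xn = x[live] + step[live, None] * gg / np.maximum(gn, 1e-300)[:, None]
            better = rho0.evaluate(xn) > rr
            xl = x[live]
            xl[better] = xn[better]
            x[live] = xl
            sl = step[live]
            sl[~better] *= 0.5
            step[live] = sl
            d = np.linalg.norm(x[live][:, None, :] - attr[None, :, :], axis=2)
            cap = (d <= 0.06).any(axis=1) | (step[live] < 1e-5)
            idx = np.flatnonzero(live)[cap]
            owner[idx] = np.argmin(d[cap], axis=1)
        owner[owner < 0] = np.argmin(
            np.linalg.norm(x[owner < 0][:, None, :] - attr[None, :, :], axis=2), axis=1
        )
        for bas in range(part.n_basins):
            pop_main = q.basin_population(part, rho0, grid, bas)
            m = owner == bas
            pop_oracle = float(grid.weights[sel][m] @ rho[sel][m])
            # oracle omits the negligible-density tail; compensate via totals
            assert pop_main == pytest.approx(pop_oracle, abs=5e-3)

    def test_relabeling_fragments_leaves_ownership_unchanged(self, cheap_spec):
        a = q.build_promolecule(["F"], np.zeros((1, 3)), label="A")
        b = q.build_promolecule(["H"], np.array([[0, 0, 1.7]]), label="B")
        rho0 = q.ComplexDensity([a, b])
        g = q.build_grid(rho0, cheap_spec)
        p1 = assign_basins(rho0, g, Fragmentation(("A", "B")))
        p2 = assign_basins(rho0, g, Fragmentation(("B", "A")))
        np.testing.assert_array_equal(p1.owner, p2.owner)

    def test_non_nuclear_attractor_rejected(self, cheap_spec):
        # density maximum displaced 1 bohr away from the only nucleus
        d = q.GaussianDensity(
            [q.Nucleus("H", 1.0, np.zeros(3))],
            [q.GaussianPrimitive(np.array([0.0, 0.0, 1.0]), 2.0, 1.0)],
        )
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            g = q.build_grid(d, cheap_spec)
            with pytest.raises(NonNuclearAttractorError):
                assign_basins(d, g)


class TestBasinPopulation:
    def test_partition_completeness_is_exact(self, hf_system):
        a, b, rho0, grid, part, _ = hf_system
        rho = rho0.evaluate(grid.points)
        total = q.integrate(grid, rho)
        by_basin = q.basin_population(part, rho0, grid)
        assert by_basin.sum() == pytest.approx(total, abs=1e-12)

    def test_cross_density_population_partitions_monomer_count(self, hf_system):
        a, b, rho0, grid, part, _ = hf_system
        in_a = q.basin_population(part, b, grid, 0)
        in_b = q.basin_population(part, b, grid, 1)
        assert in_a + in_b == pytest.approx(
            q.integrate(grid, b.evaluate(grid.points)), abs=1e-12
        )

    def test_far_separation_keeps_monomer_charge_in_own_basin(self, cheap_spec):
        a = q.build_promolecule(["Ne"], np.zeros((1, 3)), label="A")
        b = q.build_promolecule(["Ne"], np.array([[0, 0, 50 * 0.529177]]), label="B")
        rho0 = q.ComplexDensity([a, b])
        g = q.build_grid(rho0, cheap_spec)
        part = assign_basins(rho0, g)
        assert q.basin_population(part, b, g, 0) < 1e-6  # no B charge in Omega_A

    def test_unknown_basin_id_rejected(self, hf_system):
        *_, part, _ = hf_system
        with pytest.raises(KeyError):
            part.mask(5)


class TestBasinMultipoles:
    def test_spherical_atom_monopole_and_vanishing_higher_moments(self, cheap_spec):
        d = q.build_promolecule(["O"], np.zeros((1, 3)))
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            g = q.build_grid(d, cheap_spec)
            part = assign_basins(d, g)
        ms = q.basin_multipoles(part, d, g, l_max=2)
        assert ms.Q[0, 0] == pytest.approx(0.0, abs=2e-3)  # Z - N for neutral
        assert np.all(np.abs(ms.Q[0, 1:]) < 1e-4)

    def test_monopoles_sum_to_system_charge(self, hf_system):
        a, b, rho0, grid, part, _ = hf_system
        ms = q.basin_multipoles(part, rho0, grid, l_max=2)
        total = sum(n.Z for n in rho0.nuclei) - rho0.electron_count
        assert ms.Q[:, 0].sum() == pytest.approx(total, abs=2e-3)

    def test_dipole_matches_direct_moment_integral(self, cheap_spec):
        d = q.polarize_atom(
            q.build_promolecule(["N"], np.zeros((1, 3))), 0, 0.15, np.array([0, 0, 0.6])
        )
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            g = q.build_grid(d, cheap_spec)
            part = assign_basins(d, g)
        ms = q.basin_multipoles(part, d, g, l_max=1)
        rho = d.evaluate(g.points)
        mu_z_direct = -float(g.weights @ (rho * g.points[:, 2]))
        assert ms.Q[0, lm_index(1, 0)] == pytest.approx(mu_z_direct, abs=1e-4)
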