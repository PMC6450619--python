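"""Boltzmann inversion, IBI/IMC updates, convergence metric, orchestrator."""

import numpy as np
import pytest

from cginverse.distributions import CorrelationMatrix, Distribution, DistributionSet
from cginverse.fixtures import ToyFluidSpec, make_toy_fluid, toy_fluid_system
from cginverse.inversion import (
    InversionError,
    Schedule,
    ThermoState,
    convergence_delta,
    direct_boltzmann_inversion,
    ibi_update,
    imc_update,
    run_inversion,
)
from cginverse.sampler import SamplerConfig
from cginverse.units import KB_KCAL

T303 = ThermoState(303.0)


def bond_dist(edges, density):
    density = np.asarray(density, float)
    w = edges[1] - edges[0]
    density = density / (density.sum() * w)
    return Distribution("bond", "A-A", edges, density,
                        counts_mean=density * 1000, n_frames=10)


class TestDirectBoltzmannInversion:
    def test_gaussian_bond_density_gives_harmonic_curvature(self):
        r0, sigma = 0.5, 0.02
        edges = np.arange(0.35, 0.65, 0.002)
        x = 0.5 * (edges[:-1] + edges[1:])
        dist = bond_dist(edges, np.exp(-((x - r0) ** 2) / (2 * sigma ** 2)))
        table = direct_boltzmann_inversion(dist, T303)
        # quadratic fit around the minimum; expect curvature kB T / sigma^2
        sel = np.abs(table.x - r0) < sigma
        coef = np.polyfit(table.x[sel], table.u[sel], 2)
        k_fit = 2 * coef[0]
        k_expected = T303.kT / sigma ** 2
        assert k_fit == pytest.approx(k_expected, rel=0.02)

    def test_uniform_torsion_density_gives_flat_potential(self):
        edges = np.arange(-180.0, 180.0 + 1e-9, 4.0)
        d = Distribution("torsion", "t", edges,
                         np.full(len(edges) - 1, 1.0 / 360.0))
        table = direct_boltzmann_inversion(d, T303)
        assert np.abs(table.u - table.u[0]).max() < 1e-12

    def test_sine_angle_density_cancels_jacobian(self):
        edges = np.arange(0.0, 180.0 + 1e-9, 2.0)
        x = 0.5 * (edges[:-1] + edges[1:])
        p = np.sin(np.radians(x))
        d = Distribution("angle", "a", edges, p / (p.sum() * 2.0))
        table = direct_boltzmann_inversion(d, T303)
        assert np.abs(table.u - table.u[0]).max() < 1e-10

    def test_rdf_inversion_zeroed_at_largest_distance(self):
        edges = np.arange(0.0, 1.2 + 1e-9, 0.01)
        x = 0.5 * (edges[:-1] + edges[1:])
        g = np.where(x > 0.3, 1.0 + 0.5 * np.exp(-((x - 0.5) ** 2) / 0.01), 0.0)
        d = Distribution("rdf", "A-A", edges, g)
        table = direct_boltzmann_inversion(d, T303, cutoff=1.2)
        assert table.kind == "pair"
        assert table.u[table.defined][-1] == pytest.approx(0.0, abs=1e-12)
        assert not table.defined[x <= 0.3].any()

    def test_all_empty_distribution_is_an_error(self):
        edges = np.arange(0.0, 1.0, 0.01)
        d = Distribution("bond", "A-A", edges, np.zeros(len(edges) - 1))
        with pytest.raises(InversionError, match="empty"):
            direct_boltzmann_inversion(d, T303)


class TestIBIUpdate:
    edges = np.arange(0.4, 0.62, 0.02)

    def table_and_dists(self):
        x = 0.5 * (self.edges[:-1] + self.edges[1:])
        from cginverse.potential_tables import PotentialTable
        table = PotentialTable("bond", "A-A", x, 10 * (x - 0.5) ** 2)
        ref = bond_dist(self.edges, np.exp(-((x - 0.5) ** 2) / 0.001))
        return table, ref

    def test_matched_distributions_are_a_fixed_point(self):
        table, ref = self.table_and_dists()
        out = ibi_update(table, ref, ref, a=1.0, thermo=T303)
        assert np.array_equal(out.u, table.u)

    def test_single_bin_ratio_e_with_half_step(self):
        # S_n/S_ref = e in one bin, a = 0.5, kB T = 0.6 -> dU = +0.3 kcal/mol
        thermo = ThermoState(0.6 / KB_KCAL)
        assert thermo.kT == pytest.approx(0.6)
        table, ref = self.table_and_dists()
        sn_vals = ref.values.copy()
        sn_vals[4] *= np.e
        sn = Distribution("bond", "A-A", self.edges, sn_vals)
        out = ibi_update(table, sn, ref, a=0.5, thermo=thermo)
        delta = out.u - table.u
        assert delta[4] == pytest.approx(0.3, rel=1e-9)
        np.testing.assert_allclose(np.delete(delta, 4), 0.0, atol=1e-12)

    def test_update_linear_in_a(self):
        table, ref = self.table_and_dists()
        sn = Distribution("bond", "A-A", self.edges, ref.values *
                          np.linspace(0.5, 1.5, ref.n_bins))
        d1 = ibi_update(table, sn, ref, 0.4, T303).u - table.u
        d2 = ibi_update(table, sn, ref, 0.8, T303).u - table.u
        assert d2 == pytest.approx(2 * d1)

    def test_grid_mismatch_rejected(self):
        table, ref = self.table_and_dists()
        other = bond_dist(self.edges + 0.01, np.ones(ref.n_bins))
        with pytest.raises(InversionError, match="mismatch"):
            ibi_update(table, other, ref, 1.0, T303)


class TestIMCUpdate:
    def setup_objects(self, rng, nbins=5):
        from cginverse.potential_tables import PotentialTable
        edges = np.arange(0.0, nbins * 0.01 + 1e-12, 0.01)
        x = 0.5 * (edges[:-1] + edges[1:])
        table = PotentialTable("pair", "A-A", x, np.zeros(nbins), cutoff=2.0)
        ref_counts = 50 + 10 * rng.random(nbins)
        mk = lambda c: Distribution("rdf", "A-A", edges, np.maximum(c, 0) / 100,
                                    counts_mean=c, n_frames=100)
        return table, edges, mk, ref_counts

    def test_zero_rhs_gives_zero_update(self, rng):
        table, edges, mk, c = self.setup_objects(rng)
        A = CorrelationMatrix(-np.eye(5), [("A-A", b) for b in range(5)])
        ref = DistributionSet([mk(c)])
        cur = DistributionSet([mk(c.copy())])
        out, du = imc_update([table], cur, ref, A, a=0.5)
        assert np.all(du["A-A"] == 0.0)
        assert np.array_equal(out[0].u, table.u)

    def test_diagonal_matrix_decouples_to_scalar_solves(self, rng):
        table, edges, mk, c = self.setup_objects(rng)
        diag = -(1.0 + rng.random(5))
        A = CorrelationMatrix(np.diag(diag), [("A-A", b) for b in range(5)])
        cn = c + rng.normal(size=5)
        out, du = imc_update([table], DistributionSet([mk(cn)]),
                             DistributionSet([mk(c)]), A, a=0.7)
        expected = 0.7 * (c - cn) / diag
        assert du["A-A"] == pytest.approx(expected, abs=1e-10)

    def test_dimension_mismatch_rejected(self, rng):
        table, edges, mk, c = self.setup_objects(rng)
        A = CorrelationMatrix(-np.eye(4), [("A-A", b) for b in range(4)])
        with pytest.raises(InversionError, match="dim"):
            imc_update([table], DistributionSet([mk(c)]),
                       DistributionSet([mk(c)]), A, a=0.5)


class TestConvergenceDelta:
    def mk(self, name, values, width=0.5):
        edges = width * np.arange(len(values) + 1)
        return Distribution("bond", name, edges, np.maximum(values, 0))

    def test_identical_sets_give_zero(self):
        a = DistributionSet([self.mk("x", [0.3, 0.7])])
        assert convergence_delta(a, a) == 0.0

    def test_hand_evaluated_two_bin_case(self):
        # one interaction, 2 bins, l = 0.5, diffs (0.1, -0.1):
        # delta = (1/(0.5*2)) * (0.01 + 0.01) = 0.02
        ref = DistributionSet([self.mk("x", [0.5, 0.5])])
        cur = DistributionSet([self.mk("x", [0.6, 0.4])])
        assert convergence_delta(cur, ref) == pytest.approx(0.02)

    def test_additive_over_interactions_and_order_invariant(self):
        r1, c1 = self.mk("x", [0.5, 0.5]), self.mk("x", [0.6, 0.4])
        r2, c2 = self.mk("y", [1.0, 0.0]), self.mk("y", [0.8, 0.2])
        d_joint = convergence_delta(DistributionSet([c1, c2]),
                                    DistributionSet([r1, r2]))
        d_sep = (convergence_delta(DistributionSet([c1]), DistributionSet([r1]))
                 + convergence_delta(DistributionSet([c2]), DistributionSet([r2])))
        d_swap = convergence_delta(DistributionSet([c2, c1]),
                                   DistributionSet([r2, r1]))
        assert d_joint == pytest.approx(d_sep)
        assert d_joint == pytest.approx(d_swap)

    def test_missing_interaction_rejected(self):
        with pytest.raises(InversionError, match="missing"):
            convergence_delta(DistributionSet([self.mk("x", [1.0])]),
                              DistributionSet([self.mk("y", [1.0])]))


class TestRunInversion:
    def small_reference(self):
        spec = ToyFluidSpec(n_particles=40, box=(2.5, 2.5, 2.5), cutoff=1.0,
                            seed=5)
        traj, table, system = make_toy_fluid(spec, n_steps=1500,
                                             equil_steps=500, stride=10)
        from cginverse.distributions import compute_rdf
        edges = np.arange(0.0, 1.0 + 1e-9, 0.02)
        ref = compute_rdf(traj.frames, traj.box, system.topology.bead_types,
                          ("A", "A"), set(), edges, keep_frames=True)
        return spec, DistributionSet([ref])

    def test_zero_schedule_returns_dbi_tables_untouched(self):
        spec, refset = self.small_reference()
        schedule = Schedule(n_ibi=0, n_imc=0)
        res = run_inversion(refset, toy_fluid_system(spec), schedule,
                            SamplerConfig(seed=0), seed=9)
        dbi = direct_boltzmann_inversion(refset.members[0],
                                         ThermoState(spec.temperature),
                                         cutoff=spec.cutoff)
        assert np.array_equal(res.raw_tables["pair:A-A"].u, dbi.u)
        assert len(res.delta_trace) == 0

    def test_identical_seeds_give_identical_delta_traces(self):
        spec, refset = self.small_reference()
        schedule = Schedule(n_ibi=1, n_imc=1, sample_steps=600,
                            equil_steps=200, stride=5, imc_steps_factor=1)
        runs = []
        for _ in range(2):
            res = run_inversion(refset, toy_fluid_system(spec), schedule,
                                SamplerConfig(seed=0), seed=77)
            runs.append(res.delta_trace)
        assert np.array_equal(runs[0], runs[1])
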