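"""Energy model and canonical samplers: exactness, consistency, statistics."""

import numpy as np
import pytest
from scipy import stats

from cginverse.mapping import BondedTerms, CGTopology, build_exclusions
from cginverse.potential_tables import PotentialTable
from cginverse.sampler import (
    CGSystem,
    SamplerConfig,
    SamplerError,
    ThermoState,
    evaluate_energy_forces,
    kinetic_temperature,
    sample_canonical,
)
from cginverse.units import COULOMB_K, KB_KCAL

BOX = np.array([5.0, 5.0, 5.0])


def chain_system(charges=None, n=4, tables=None, cutoff=2.0):
    terms = BondedTerms(bonds=[((i, i + 1), "A-A") for i in range(n - 1)])
    if n >= 3:
        terms.angles = [((i, i + 1, i + 2), "A-A-A") for i in range(n - 2)]
    if n >= 4:
        terms.torsions = [((i, i + 1, i + 2, i + 3), "A-A-A-A")
                          for i in range(n - 3)]
    top = CGTopology(["A"] * n, np.full(n, 60.0),
                     np.zeros(n) if charges is None else np.asarray(charges),
                     terms, build_exclusions(terms), np.zeros(n, int))
    system = CGSystem(top, BOX, ThermoState(303.0), cutoff=cutoff)
    system.set_tables(tables or standard_tables())
    return system


def standard_tables():
    xb = np.linspace(0.1, 1.2, 111)
    xa = np.linspace(0.0, 180.0, 91)
    xt = np.arange(-178.0, 182.0, 4.0)
    xp = np.linspace(0.05, 2.0, 196)
    return {
        "bond:A-A": PotentialTable("bond", "A-A", xb, 40 * (xb - 0.5) ** 2),
        "angle:A-A-A": PotentialTable("angle", "A-A-A", xa,
                                      0.005 * (xa - 120) ** 2),
        "torsion:A-A-A-A": PotentialTable(
            "torsion", "A-A-A-A", xt,
            1.5 * np.cos(np.radians(xt)) + 0.8 * np.sin(np.radians(2 * xt))),
        "pair:A-A": PotentialTable("pair", "A-A", xp,
                                   0.3 * np.exp(-((xp - 0.7) ** 2) / 0.05),
                                   cutoff=2.0),
    }


def free_system(n, charges=None, box=BOX):
    top = CGTopology(["A"] * n, np.full(n, 60.0),
                     np.zeros(n) if charges is None else np.asarray(charges),
                     BondedTerms(), set(), np.zeros(n, int))
    system = CGSystem(top, box, ThermoState(303.0), cutoff=min(box) / 2 - 0.1)
    system.set_tables({})
    return system


class TestEnergyModel:
    def test_pair_energy_exact_at_table_node(self):
        xp = np.linspace(0.05, 2.0, 196)
        u = 0.3 * np.exp(-((xp - 0.7) ** 2) / 0.05)
        system = free_system(2)
        system.set_tables({"pair:A-A": PotentialTable("pair", "A-A", xp, u,
                                                      cutoff=2.0)})
        node = xp[60]
        pos = np.array([[1.0, 1, 1], [1.0 + node, 1, 1]])
        e, _ = evaluate_energy_forces(pos, system)
        assert e == pytest.approx(u[60], abs=1e-12)

    def test_coulomb_unit_charges_at_one_nm(self):
        # two +1e charges, eps = 78, r = 1 nm: 33.206/78 ~ 0.4257 kcal/mol
        system = free_system(2, charges=[1.0, 1.0])
        pos = np.array([[1.0, 1, 1], [2.0, 1, 1]])
        e, _ = evaluate_energy_forces(pos, system)
        assert e == pytest.approx(COULOMB_K / 78.0, rel=1e-12)
        assert e == pytest.approx(0.4257, abs=2e-4)

    def test_excluded_pair_contributes_no_shortrange_or_coulomb(self):
        terms = BondedTerms(bonds=[((0, 1), "A-A")])
        xb = np.linspace(0.1, 1.2, 111)
        top = CGTopology(["A", "A"], np.full(2, 60.0), np.array([1.0, -1.0]),
                         terms, build_exclusions(terms), np.zeros(2, int))
        system = CGSystem(top, BOX, ThermoState(303.0), cutoff=2.0)
        system.set_tables({
            "bond:A-A": PotentialTable("bond", "A-A", xb, np.zeros_like(xb)),
            "pair:A-A": PotentialTable("pair", "A-A", xb, np.ones_like(xb),
                                       cutoff=2.0),
        })
        e, f = evaluate_energy_forces(np.array([[1.0, 1, 1], [1.5, 1, 1]]),
                                      system)
        assert e == pytest.approx(0.0, abs=1e-14)
        assert np.abs(f).max() == pytest.approx(0.0, abs=1e-12)

    def test_forces_match_finite_differences(self, rng):
        system = chain_system(charges=[0.3, 0.0, 0.0, -0.3])
        worst = 0.0
        for _ in range(3):
            pos = np.cumsum(rng.normal(scale=0.35, size=(4, 3)), axis=0) + 1.5
            _, F = evaluate_energy_forces(pos, system)
            h = 1e-6
            for i in range(4):
                for d in range(3):
                    pp = pos.copy()
                    pp[i, d] += h
                    pm = pos.copy()
                    pm[i, d] -= h
                    ep, _ = evaluate_energy_forces(pp, system)
                    em, _ = evaluate_energy_forces(pm, system)
                    worst = max(worst, abs(F[i, d] + (ep - em) / (2 * h)))
        assert worst < 1e-5

    def test_energy_invariant_under_translation_and_image_shift(self, rng):
        system = chain_system(charges=[0.3, 0.0, 0.0, -0.3])
        pos = np.cumsum(rng.normal(scale=0.3, size=(4, 3)), axis=0) + 1.5
        e0, _ = evaluate_energy_forces(pos, system)
        e1, _ = evaluate_energy_forces(pos + np.array([1.3, -2.1, 0.7]), system)
        shifted = pos.copy()
        shifted[2] += BOX  # full periodic image displacement of one bead
        e2, _ = evaluate_energy_forces(shifted, system)
        assert e1 == pytest.approx(e0, abs=1e-9)
        assert e2 == pytest.approx(e0, abs=1e-9)

    def test_bond_outside_table_range_reports_term(self):
        system = chain_system(n=2)
        pos = np.array([[1.0, 1, 1], [2.9, 1, 1]])
        with pytest.raises(SamplerError, match="bond:A-A"):
            evaluate_energy_forces(pos, system)

    def test_missing_bonded_table_reported(self):
        system = chain_system(n=2)
        with pytest.raises(SamplerError, match="missing table"):
            system.set_tables({})
            system.model()


class TestLangevin:
    def test_same_seed_bitwise_identical_trajectories(self):
        system = chain_system()
        cfg = SamplerConfig(n_steps=300, stride=10, seed=123)
        init = np.array([[1, 1, 1], [1.5, 1.1, 1], [1.9, 1.5, 1.2],
                         [2.3, 1.8, 1.6]], dtype=float)
        t1 = sample_canonical(system, cfg, initial=init, minimize_first=False)
        t2 = sample_canonical(system, cfg, initial=init, minimize_first=False)
        assert np.array_equal(t1.frames, t2.frames)

    def test_kinetic_temperature_near_target(self):
        system = free_system(60)
        cfg = SamplerConfig(n_steps=12000, equil_steps=2000, stride=10, seed=4)
        traj = sample_canonical(system, cfg, minimize_first=False)
        assert np.mean(traj.temperatures) == pytest.approx(303.0, rel=0.02)

    def test_blowup_detected_with_diagnostics(self):
        xb = np.linspace(0.1, 1.2, 111)
        tables = standard_tables()
        tables["bond:A-A"] = PotentialTable("bond", "A-A", xb,
                                            1e9 * (xb - 0.5) ** 2)
        system = chain_system(n=2, tables=tables)
        cfg = SamplerConfig(n_steps=1000, stride=10, seed=7, timestep_fs=50.0)
        with pytest.raises(SamplerError, match="blow-up|beyond table"):
            sample_canonical(system, cfg,
                             initial=np.array([[1.0, 1, 1], [1.9, 1, 1]]),
                             minimize_first=False)

    def test_kinetic_temperature_estimator_definition(self, rng):
        from cginverse.units import KB_KJ
        vel = rng.normal(size=(500, 3))
        m = np.full(500, 42.0)
        ke = 0.5 * np.sum(m[:, None] * vel ** 2)
        assert kinetic_temperature(vel, m) == pytest.approx(
            2 * ke / (3 * 500 * KB_KJ))


class TestMetropolis:
    def test_free_particle_position_marginal_uniform(self):
        system = free_system(1, box=np.array([4.0, 4.0, 4.0]))
        cfg = SamplerConfig(method="metropolis", n_steps=30000, stride=10,
                            seed=11, max_displacement=2.0)
        traj = sample_canonical(system, cfg, minimize_first=False)
        for axis in range(3):
            h, _ = np.histogram(traj.frames[:, 0, axis], bins=8, range=(0, 4))
            n = h.sum()
            chi2 = np.sum((h - n / 8) ** 2 / (n / 8))
            assert chi2 < stats.chi2.ppf(0.999, 7)

    def test_two_state_boltzmann_ratio(self):
        # smooth double-well dimer: occupancy of the two wells must match
        # the enumerated Boltzmann ratio over the table's exact support
        # (outside the table the move is rejected — a hard wall the oracle
        # integral reproduces by truncating its domain)
        from scipy.special import expit

        T = 303.0
        kT = KB_KCAL * T

        def u_fn(r):
            return 0.8 * expit((r - 0.7) / 0.02) + 20.0 * (r - 0.7) ** 4

        xb = np.arange(0.1, 1.4 + 1e-9, 0.01)
        terms = BondedTerms(bonds=[((0, 1), "A-A")])
        top = CGTopology(["A", "A"], np.full(2, 60.0), np.zeros(2), terms,
                         build_exclusions(terms), np.zeros(2, int))
        system = CGSystem(top, BOX, ThermoState(T), cutoff=2.0)
        system.set_tables({"bond:A-A": PotentialTable("bond", "A-A", xb,
                                                      u_fn(xb))})
        cfg = SamplerConfig(method="metropolis", n_steps=120_000, stride=4,
                            seed=21, max_displacement=0.25)
        init = np.array([[2.0, 2, 2], [2.5, 2, 2]])
        traj = sample_canonical(system, cfg, initial=init, minimize_first=False)
        disp = traj.frames[:, 1] - traj.frames[:, 0]
        disp -= np.round(disp / BOX) * BOX
        d = np.linalg.norm(disp, axis=1)
        p_low = np.mean(d < 0.7)
        r = np.linspace(xb[0], xb[-1], 4001)
        w = r ** 2 * np.exp(-u_fn(r) / kT)
        p_expected = np.trapezoid(w[r < 0.7], r[r < 0.7]) / np.trapezoid(w, r)
        assert p_low == pytest.approx(p_expected, abs=0.03)
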