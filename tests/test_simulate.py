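import numpy as np
import pytest
from scipy.special import expit

from turflag import vital_rates as vr
from turflag.climate import constant_scenario, gradual_scenario
from turflag.grid import KernelSpec, make_grid
from turflag.simulate import (
    CommunityState,
    EquilibrationError,
    EquilibriumCriterion,
    equilibrate,
    run_no_lag,
    run_scenario,
    run_stepwise,
    step_year,
)

GRID = make_grid(1.0, 0.05, 0.10)
KERNEL = KernelSpec()


def taxon(name="x", **over):
    """A healthy, mildly competing taxon near equilibrium at ~12 C."""
    surv = dict(lam_max=4.0, T_infl0=16.0, m_moist=0.0, k_sig=1.0, b_S=0.05,
                a_ii0=0.01, a_ii1=0.0, a_ij0=0.01, a_ij1=0.0)
    grow = dict(g_max=2.5, T_opt=12.3, sigma_T=4.0, b_G=0.78,
                c_ii=-4.5, d_ii=0.0, c_ij=-4.5, d_ij=0.0, sigma_eps=0.6)
    rec = dict(r_ii0=np.log(0.2), r_ii1=0.0, r_ij0=-5.0, r_ij1=0.0,
               theta_r=-5.0, u_init=0.25)
    surv.update(over.get("survival", {}))
    grow.update(over.get("growth", {}))
    rec.update(over.get("recruitment", {}))
    return vr.TaxonParams(name, vr.SurvivalParams(**surv),
                          vr.GrowthParams(**grow), vr.RecruitmentParams(**rec))


def seeded_state(taxa, occupancy=0.2, seed=0, size_range=(3.0, 9.0)):
    rng = np.random.default_rng(seed)
    n = GRID.n_side
    sizes = np.zeros((len(taxa), n, n))
    inner = GRID.inner_mask()
    for k in range(len(taxa)):
        occ = (rng.random((n, n)) < occupancy) & inner
        sizes[k][occ] = rng.uniform(*size_range, int(occ.sum()))
    return CommunityState("t", 2020, GRID, tuple(taxa), sizes)


class TestStepYear:
    def test_forced_death_empties_community(self):
        # enormous negative size effect drives survival probability to 0
        p = {"x": taxon(survival={"b_S": -1e6},
                        recruitment={"r_ii0": -50.0, "theta_r": -50.0})}
        state = seeded_state(["x"])
        nxt = step_year(state, 12.3, 0.5, p, KERNEL, np.random.default_rng(0))
        assert nxt.total_cover() == 0.0

    def test_background_recruitment_expectation(self):
        # empty community, immigration allowed: recruits ~ Binomial(n_inner, p)
        p = {"x": taxon()}
        n = GRID.n_side
        empty = CommunityState("t", 2020, GRID, ("x",), np.zeros((1, n, n)))
        rng = np.random.default_rng(1)
        total = 0
        n_steps = 400
        for _ in range(n_steps):
            nxt = step_year(empty, 12.3, 0.5, p, KERNEL, rng, allow_immigration=True)
            total += int((nxt.sizes > 0).sum())
        expected = n_steps * GRID.n_inner * expit(-5.0)
        sd = np.sqrt(n_steps * GRID.n_inner * expit(-5.0) * (1 - expit(-5.0)))
        assert abs(total - expected) < 4 * sd

    def test_seed_determinism(self):
        p = {"x": taxon(), "y": taxon("y")}
        state = seeded_state(["x", "y"])
        a = step_year(state, 13.0, 0.5, p, KERNEL, np.random.default_rng(42))
        b = step_year(state, 13.0, 0.5, p, KERNEL, np.random.default_rng(42))
        assert np.array_equal(a.sizes, b.sizes)

    def test_sizes_bounded_after_step(self):
        p = {"x": taxon(growth={"g_max": 30.0, "sigma_eps": 5.0})}
        state = seeded_state(["x"], occupancy=0.5)
        nxt = step_year(state, 12.3, 0.5, p, KERNEL, np.random.default_rng(0))
        alive = nxt.sizes[nxt.sizes > 0]
        assert np.all(alive >= vr.U_MIN)
        assert np.all(alive <= GRID.quadrant_area_cm2)

    def test_missing_params_named(self):
        state = seeded_state(["x", "y"])
        with pytest.raises(ValueError, match="y"):
            step_year(state, 12.3, 0.5, {"x": taxon()}, KERNEL, np.random.default_rng(0))

    def test_absorbing_extinction(self):
        p = {"x": taxon(), "y": taxon("y")}
        n = GRID.n_side
        sizes = np.zeros((2, n, n))
        sizes[0, 10, 10] = 5.0  # only taxon x present
        state = CommunityState("t", 2020, GRID, ("x", "y"), sizes)
        rng = np.random.default_rng(0)
        for _ in range(25):
            state = step_year(state, 12.3, 0.5, p, KERNEL, rng)
            assert state.per_taxon_cover()[1] == 0.0

    def test_buffer_cover_frozen_but_crowds(self):
        p = {"x": taxon(recruitment={"r_ii0": -50.0, "theta_r": -50.0})}
        n = GRID.n_side
        sizes = np.zeros((1, n, n))
        sizes[0, 0, 0] = 12.0  # buffer quadrant
        state = CommunityState("t", 2020, GRID, ("x",), sizes)
        nxt = step_year(state, 12.3, 0.5, p, KERNEL, np.random.default_rng(0))
        assert nxt.sizes[0, 0, 0] == 12.0


class TestEquilibrate:
    def test_already_stable_returns_after_one_step(self):
        p = {"x": taxon(survival={"b_S": 100.0},  # ~immortal
                        growth={"sigma_eps": 0.001, "b_G": 0.0, "g_max": 5.0, "sigma_T": 50.0},
                        recruitment={"r_ii0": -50.0, "theta_r": -50.0})}
        state = seeded_state(["x"], occupancy=0.3, size_range=(5.0, 5.01))
        crit = EquilibriumCriterion()
        out = equilibrate(state, 12.3, 0.5, p, crit, KERNEL, np.random.default_rng(0))
        assert out.year == state.year + 1

    def test_halting_year_decreases_with_looser_thresholds(self):
        p = {"x": taxon()}
        state = seeded_state(["x"], occupancy=0.02, size_range=(0.5, 1.0))
        years = []
        for rate in (0.01, 0.05, 0.25):
            crit = EquilibriumCriterion(growth_rate_threshold=rate,
                                        cover_change_frac=1e-9, max_years=400)
            out = equilibrate(state, 12.3, 0.5, p, crit, KERNEL, np.random.default_rng(7))
            years.append(out.year - state.year)
        assert years[0] >= years[1] >= years[2]

    def test_default_thresholds_match_stated_rule(self):
        crit = EquilibriumCriterion()
        assert crit.growth_rate_threshold == 0.05
        assert crit.cover_change_frac == 0.005
        # boundary behaviour on constructed cover pairs (10000 cm2 turf)
        assert crit.satisfied(1000.0, 1000.0 + 49.9, 10000.0)       # change < 0.5%
        assert not crit.satisfied(1000.0, 1000.0 + 51.0, 10000.0)   # both criteria fail

    def test_nonconvergence_raises_with_trajectory(self):
        p = {"x": taxon(growth={"g_max": 0.1, "b_G": 0.3},
                        survival={"lam_max": 0.2, "b_S": 0.3})}
        state = seeded_state(["x"], occupancy=0.5, size_range=(15.0, 20.0))
        crit = EquilibriumCriterion(growth_rate_threshold=1e-9,
                                    cover_change_frac=1e-12, max_years=5)
        with pytest.raises(EquilibrationError) as err:
            equilibrate(state, 12.3, 0.5, p, crit, KERNEL, np.random.default_rng(0))
        assert len(err.value.trajectory) == 6


class TestScenarioRuns:
    def test_default_run_has_20_replicates(self):
        p = {"x": taxon()}
        state = seeded_state(["x"])
        climate = constant_scenario(12.3, 3, year0=2021)
        traj = run_scenario(state, climate, p, KERNEL, seed=0)
        assert traj.n_reps == 20
        assert traj.cover.shape == (20, 3, 1)

    def test_single_rep_summary_is_the_trajectory(self):
        p = {"x": taxon()}
        state = seeded_state(["x"])
        climate = constant_scenario(12.3, 4, year0=2021)
        traj = run_scenario(state, climate, p, KERNEL, n_reps=1, seed=3)
        s = traj.summary()
        assert np.array_equal(s["cover_median"], traj.cover[0])
        assert np.array_equal(s["cover_q05"], traj.cover[0])

    def test_bit_identical_for_same_seed(self):
        p = {"x": taxon(), "y": taxon("y")}
        state = seeded_state(["x", "y"])
        climate = gradual_scenario(12.3, 2.0, 2021, 2030, "linear", 0.2, seed=5)
        a = run_scenario(state, climate, p, KERNEL, n_reps=5, seed=11)
        b = run_scenario(state, climate, p, KERNEL, n_reps=5, seed=11)
        assert np.array_equal(a.cover, b.cover)
        assert np.array_equal(a.shannon, b.shannon, equal_nan=True)

    def test_quantile_ordering(self):
        p = {"x": taxon(), "y": taxon("y")}
        state = seeded_state(["x", "y"])
        climate = constant_scenario(13.0, 6, year0=2021)
        s = run_scenario(state, climate, p, KERNEL, n_reps=10, seed=2).summary()
        assert np.all(s["cover_q05"] <= s["cover_median"] + 1e-12)
        assert np.all(s["cover_median"] <= s["cover_q95"] + 1e-12)

    def test_stepwise_of_constant_window_equals_constant_control(self):
        p = {"x": taxon()}
        state = seeded_state(["x"])
        src = constant_scenario(12.3, 30, year0=2021)
        a = run_stepwise(state, src, (2021, 2050), 10, p, KERNEL, n_reps=3, seed=9)
        b = run_scenario(state, src.slice(2021, 2030), p, KERNEL, n_reps=3, seed=9)
        assert np.array_equal(a.cover, b.cover)

    def test_stepwise_seed_determinism(self):
        p = {"x": taxon()}
        state = seeded_state(["x"])
        src = gradual_scenario(12.3, 2.0, 2021, 2098, "linear", 0.3, seed=1)
        a = run_stepwise(state, src, (2088, 2098), 15, p, KERNEL, n_reps=3, seed=4)
        b = run_stepwise(state, src, (2088, 2098), 15, p, KERNEL, n_reps=3, seed=4)
        assert np.array_equal(a.cover, b.cover)

    def test_no_lag_matches_lagged_at_equilibrium(self):
        p = {"x": taxon(), "y": taxon("y")}
        state = seeded_state(["x", "y"], occupancy=0.15)
        crit = EquilibriumCriterion()
        rng = np.random.default_rng(0)
        # drive the community to a genuine equilibrium first, so the lagged
        # run has no transient left for the no-lag run to fast-forward
        tight = EquilibriumCriterion(growth_rate_threshold=0.01,
                                     cover_change_frac=5e-4, max_years=500)
        eq = equilibrate(state, 12.3, 0.5, p, tight, KERNEL, rng)
        climate = constant_scenario(12.3, 8, year0=2021)
        lagged = run_scenario(eq, climate, p, KERNEL, n_reps=10, seed=21)
        nolag = run_no_lag(eq, climate, p, crit, KERNEL, n_reps=10, seed=22)
        ls, ns = lagged.summary(), nolag.summary()
        # medians of each run sit inside the other's 5-95% band
        assert np.all(ns["cover_median"] >= ls["cover_q05"] - 1e-9)
        assert np.all(ns["cover_median"] <= ls["cover_q95"] + 1e-9)
        assert np.all(ls["cover_median"] >= ns["cover_q05"] - 1e-9)
        assert np.all(ls["cover_median"] <= ns["cover_q95"] + 1e-9)

    def test_neutral_control_taxa_exchangeable(self):
        # identical parameters, no interactions, flat temperature response:
        # per-taxon outcomes should be statistically indistinguishable
        kwargs = dict(
            survival={"a_ii0": 0.0, "a_ij0": 0.0, "T_infl0": 1000.0, "lam_max": 2.0},
            growth={"c_ii": -30.0, "c_ij": -30.0, "sigma_T": 1e6},
            recruitment={"r_ij0": -30.0},
        )
        p = {"x": taxon("x", **kwargs), "y": taxon("y", **kwargs)}
        state = seeded_state(["x", "y"], occupancy=0.2, seed=5)
        climate = constant_scenario(12.3, 5, year0=2021)
        traj = run_scenario(state, climate, p, KERNEL, n_reps=20, seed=13)
        final = traj.cover[:, -1, :]
        mx, my = final[:, 0].mean(), final[:, 1].mean()
        pooled_sd = final.std()
        assert abs(mx - my) < pooled_sd  # means within one SD of each other
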