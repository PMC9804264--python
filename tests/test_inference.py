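import numpy as np
import pandas as pd
import pytest
from scipy.special import expit

from turflag import vital_rates as vr
from turflag.inference import (
    ValidationResult,
    fit_growth,
    fit_recruitment,
    fit_survival,
    growth_params_to_internal,
    recruitment_params_to_internal,
    select_taxa,
    survival_params_to_internal,
    validate_taxon,
)
from turflag.synthetic import (
    RECOVERY_GROWTH,
    RECOVERY_RECRUITMENT,
    RECOVERY_SURVIVAL,
    RECOVERY_TEMPS,
    simulate_growth_data,
    simulate_recruitment_data,
    simulate_survival_data,
)


class TestFitSurvival:
    def test_recovery_within_3_se(self):
        df = simulate_survival_data(5000, np.random.default_rng(7))
        res = fit_survival(df, seed=0)
        assert res.converged
        assert res.n_obs == 5000
        assert res.within(survival_params_to_internal(RECOVERY_SURVIVAL))

    def test_all_survive_flags_separation(self):
        df = simulate_survival_data(500, np.random.default_rng(0))
        df["event"] = "survival"
        res = fit_survival(df, seed=0)
        assert res.diagnostics["separation"]
        assert not res.converged
        assert np.isfinite(res.x).all()  # estimates still returned

    def test_zero_crowding_leaves_interaction_terms_at_prior(self):
        df = simulate_survival_data(4000, np.random.default_rng(3))
        df["w_con"] = 0.0
        df["w_het"] = 0.0
        res = fit_survival(df, seed=0)
        for name in ("a_ii0", "a_ii1", "a_ij0", "a_ij1"):
            i = res.x_names.index(name)
            assert abs(res.x[i]) < 0.05  # prior mean is 0


class TestFitGrowth:
    def test_recovery_within_3_se(self):
        df = simulate_growth_data(5000, np.random.default_rng(7))
        res = fit_growth(df, seed=0)
        assert res.converged
        assert res.within(growth_params_to_internal(RECOVERY_GROWTH))

    def test_noise_free_data_recovers_mean_structure_exactly(self):
        df = simulate_growth_data(3000, np.random.default_rng(1))
        mu = vr.growth_mean(
            RECOVERY_GROWTH,
            df["T_prev"].to_numpy(), df["size_from_cm2"].to_numpy(),
            df["w_con"].to_numpy(), df["w_het"].to_numpy(),
        )
        df["size_to_cm2"] = mu
        res = fit_growth(df, seed=0)
        truth = growth_params_to_internal(RECOVERY_GROWTH)
        for name in ("g_max", "T_opt", "log_sigma_T", "b_G", "c_ii", "d_ii", "c_ij", "d_ij"):
            i = res.x_names.index(name)
            assert res.x[i] == pytest.approx(truth[name], abs=1e-2)

    def test_single_temperature_flags_ridge(self):
        df = simulate_growth_data(2000, np.random.default_rng(2))
        df["T_prev"] = 14.5
        res = fit_growth(df, seed=0)
        assert res.diagnostics.get("temperature_ridge")


class TestFitRecruitment:
    def test_recovery_within_3_se(self):
        df = simulate_recruitment_data(20000, np.random.default_rng(7))
        res = fit_recruitment(df, seed=0)
        assert res.converged
        assert res.within(recruitment_params_to_internal(RECOVERY_RECRUITMENT))

    def test_zero_conspecific_data(self):
        rng = np.random.default_rng(5)
        n = 20000
        wh = rng.uniform(0, 5, n)
        p = expit(-5.0 - np.exp(-4.0) * wh)
        df = pd.DataFrame({
            "recruited": rng.random(n) < p,
            "T_prev": rng.choice(RECOVERY_TEMPS, n),
            "w_con": 0.0, "w_het": wh,
        })
        res = fit_recruitment(df, seed=0)
        # no conspecific signal: the facilitative coefficients stay at the prior
        assert abs(res.x[res.x_names.index("r_ii0")]) < 0.5
        # realised recruitment frequency within binomial noise of the
        # analytic background expectation (inverse-logit(-5), damped by w_het)
        expected = p.mean()
        sd = np.sqrt(expected * (1 - expected) / n)
        assert abs(df["recruited"].mean() - expected) < 5 * sd
        # and the fitted model reproduces the crowding-free background rate
        assert expit(res.estimates["theta_r"]) == pytest.approx(expit(-5.0))

    def test_theta_held_fixed(self):
        df = simulate_recruitment_data(5000, np.random.default_rng(1))
        res = fit_recruitment(df, seed=0, theta_r=-5.0)
        assert res.estimates["theta_r"] == -5.0
        assert "theta_r" not in res.x_names

    def test_theta_override_degrades_fit_on_theta5_data(self):
        # theta enters as a fixed offset with no free intercept to absorb it,
        # so refitting with the wrong theta must fit the same data worse
        df = simulate_recruitment_data(8000, np.random.default_rng(4))
        good = fit_recruitment(df, seed=0, theta_r=-5.0)
        bad = fit_recruitment(df, seed=0, theta_r=0.0)
        assert good.log_posterior > bad.log_posterior

    def test_map_agrees_with_grid_search_oracle(self):
        # 2-parameter toy: slopes pinned to zero by near-delta priors; compare
        # the optimiser's (r_ii0, r_ij0) against a dense grid maximiser
        rng = np.random.default_rng(9)
        n = 1500
        wc = np.where(rng.random(n) < 0.4, 0.0, rng.exponential(10.0, n))
        wh = rng.uniform(0, 40, n)
        p = expit(np.exp(-3.0) * wc - np.exp(-4.0) * wh - 5.0)
        df = pd.DataFrame({
            "recruited": rng.random(n) < p, "T_prev": 0.0, "w_con": wc, "w_het": wh,
        })
        prior_mean = np.array([-3.5, 0.0, -3.5, 0.0])
        prior_sd = np.array([2.0, 1e-6, 2.0, 1e-6])
        res = fit_recruitment(df, priors=(prior_mean, prior_sd), seed=0)

        y = df["recruited"].to_numpy()
        step = 0.02
        g0 = np.arange(-5.0, -1.0, step)
        g1 = np.arange(-6.0, -2.0, step)
        best, arg = -np.inf, None
        for a in g0:
            z = np.exp(a) * wc[None, :] - np.exp(g1)[:, None] * wh[None, :] - 5.0
            ll = -(np.logaddexp(0.0, np.where(y[None, :], -z, z))).sum(axis=1)
            ll -= 0.5 * ((a + 3.5) / 2.0) ** 2 + 0.5 * ((g1 + 3.5) / 2.0) ** 2
            j = int(np.argmax(ll))
            if ll[j] > best:
                best, arg = ll[j], (a, g1[j])
        assert res.x[0] == pytest.approx(arg[0], abs=step)
        assert res.x[2] == pytest.approx(arg[1], abs=step)


class TestSelectTaxa:
    def test_boundary(self):
        df = pd.DataFrame({"taxon": ["a"] * 999 + ["b"] * 1000})
        assert select_taxa(df, 1000) == ["b"]

    def test_empty_table(self):
        assert select_taxa(pd.DataFrame({"taxon": []})) == []

    def test_default_threshold_is_1000(self):
        df = pd.DataFrame({"taxon": ["a"] * 1000})
        assert select_taxa(df) == ["a"]


class TestValidationRule:
    def test_perfect_prediction_included(self):
        res = ValidationResult.from_ratios("x", ["t1", "t2"], [0.5, -0.2], [0.5, -0.2])
        assert res.ssr_ratio == 0.0
        assert res.included

    def test_null_prediction_excluded(self):
        res = ValidationResult.from_ratios("x", ["t1", "t2"], [0.0, 0.0], [0.5, -0.2])
        assert res.ssr_ratio == pytest.approx(1.0)
        assert not res.included

    def test_boundary_inclusion_at_80_percent(self):
        obs = np.array([1.0, -1.0, 0.5])
        ssr_null = float((obs**2).sum())
        scale = 1.0 - np.sqrt(0.8)  # pred = c*obs gives ssr_model = (1-c)^2 * ssr_null
        pred = (1.0 - np.sqrt(0.8)) * 0 + obs * (1 - np.sqrt(0.8))
        pred = obs * (1.0 - np.sqrt(0.8))
        res = ValidationResult.from_ratios("x", ["a", "b", "c"], pred, obs)
        assert res.ssr_ratio == pytest.approx(0.8)
        assert res.included

    def test_order_invariance(self):
        pred = [0.3, -0.1, 0.8]
        obs = [0.2, 0.0, 0.5]
        a = ValidationResult.from_ratios("x", list("abc"), pred, obs)
        b = ValidationResult.from_ratios("x", list("cba"), pred[::-1], obs[::-1])
        assert a.ssr_ratio == pytest.approx(b.ssr_ratio)

    def test_adding_perfect_turf_never_increases_ratio(self):
        pred = [0.3, -0.1]
        obs = [0.2, 0.3]
        base = ValidationResult.from_ratios("x", list("ab"), pred, obs)
        ext = ValidationResult.from_ratios("x", list("abc"), pred + [0.7], obs + [0.7])
        assert ext.ssr_ratio <= base.ssr_ratio


class TestValidateTaxon:
    def test_absent_taxon_raises(self, clean_dataset, kernel):
        initial = [m[0] for m in clean_dataset.maps_true.values()]
        final = [m[-1] for m in clean_dataset.maps_true.values()]
        with pytest.raises(ValueError, match="absent"):
            validate_taxon("nonexistent", clean_dataset.params, initial, final,
                           clean_dataset.climate, kernel, n_reps=2, seed=0)

    def test_self_consistency_on_generating_model(self, clean_dataset, kernel):
        """The generating parameters must pass their own inclusion rule for
        the community's dominant taxa."""
        initial = [m[0] for m in clean_dataset.maps_true.values()]
        final = [m[-1] for m in clean_dataset.maps_true.values()]
        totals = {
            t: sum(m.total_cover(t, inner_only=True) for m in initial)
            for t in clean_dataset.params
        }
        dominant = sorted(totals, key=totals.get, reverse=True)[:3]
        for taxon in dominant:
            res = validate_taxon(taxon, clean_dataset.params, initial, final,
                                 clean_dataset.climate, kernel, n_reps=20, seed=1)
            assert res.included, f"{taxon}: ssr_ratio={res.ssr_ratio:.3f}"
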