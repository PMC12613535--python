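"""Posterior computation: HDI, superiority rule, conjugate oracles, samplers."""

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, strategies as st
from scipy import stats

from epidex.config import McmcSettings, PriorSpec
from epidex.inference import (InferenceError, decide_superiority, fit_cost_model,
                              fit_pe_hazard, fit_rr_model, hdi, prob_superiority,
                              summarise_effect, summarise_hazard)
from epidex.inference import PosteriorDraws

from conftest import two_arm_frame


class TestHdi:
    def test_symmetric_normal_matches_equal_tailed(self):
        x = np.random.default_rng(0).standard_normal(100_000)
        lo, hi = hdi(x, 0.95)
        assert lo == pytest.approx(-1.96, abs=0.05)
        assert hi == pytest.approx(1.96, abs=0.05)

    def test_beta_matches_brute_force_grid(self):
        x = np.random.default_rng(1).beta(2, 8, 50_000)
        lo, hi = hdi(x, 0.95)
        # independent oracle: grid search over candidate lower bounds using the
        # exact Beta quantile function
        grid = np.linspace(0, stats.beta.ppf(0.0499, 2, 8), 4000)
        uppers = stats.beta.ppf(stats.beta.cdf(grid, 2, 8) + 0.95, 2, 8)
        j = np.argmin(uppers - grid)
        assert lo == pytest.approx(grid[j], abs=0.01)
        assert hi == pytest.approx(uppers[j], abs=0.01)

    def test_constant_draws_zero_width(self):
        lo, hi = hdi(np.full(500, 3.14), 0.95)
        assert lo == hi == pytest.approx(3.14)

    def test_preconditions(self):
        with pytest.raises(InferenceError):
            hdi(np.arange(50), 0.95)
        with pytest.raises(InferenceError):
            hdi(np.arange(500), 1.5)

    def test_multimodal_note_still_returns_interval(self):
        x = np.r_[np.random.default_rng(2).normal(-5, 0.1, 5000),
                  np.random.default_rng(3).normal(5, 0.1, 5000)]
        with pytest.warns(UserWarning, match="multimodal"):
            lo, hi = hdi(x, 0.95)
        assert lo < hi


class TestSuperiority:
    def test_extreme_and_symmetric_draws(self):
        assert prob_superiority(-np.abs(np.random.default_rng(0).standard_normal(1000))) == 1.0
        sym = np.random.default_rng(1).standard_normal(200_000)
        assert prob_superiority(sym) == pytest.approx(0.5, abs=0.01)

    def test_normal_draws_match_cdf(self):
        x = np.random.default_rng(2).normal(-0.2, 0.1, 100_000)
        expected = stats.norm.cdf(0, -0.2, 0.1)
        mc_se = np.sqrt(expected * (1 - expected) / 100_000)
        assert abs(prob_superiority(x) - expected) < 3 * mc_se

    def test_decision_strict_at_threshold(self):
        assert decide_superiority(0.995) == "superior"
        assert decide_superiority(0.99) == "not_superior"  # strictly above 99%
        assert decide_superiority(0.5) == "not_superior"

    @given(p=st.floats(0, 1), q=st.floats(0, 1))
    def test_decision_monotone_in_probability(self, p, q):
        lo, hi = sorted([p, q])
        if decide_superiority(lo) == "superior":
            assert decide_superiority(hi) == "superior"


class TestRRModel:
    def test_flat_prior_two_arm_matches_beta_binomial_oracle(self, fast_settings):
        df = two_arm_frame(410, 140, 410, 111)
        fit = fit_rr_model(df, PriorSpec(kind="flat"), fast_settings, "two_arm")
        p0 = np.exp(fit.flat("beta0"))
        p1 = np.exp(fit.flat("beta0") + fit.theta)
        for p, (a, b) in ((p0, (141, 271)), (p1, (112, 300))):
            mean = a / (a + b)
            sd = np.sqrt(a * b / ((a + b) ** 2 * (a + b + 1)))
            ess = min(d["ess"] for d in fit.diagnostics.values())
            mc_se = sd / np.sqrt(ess)
            assert abs(p.mean() - mean) < 3 * mc_se

    def test_conjugate_path_is_exact_product_beta(self):
        df = two_arm_frame(100, 30, 100, 20)
        fit = fit_rr_model(df, PriorSpec(kind="flat"), McmcSettings(seed=3, n_draws=20_000),
                          "two_arm", method="conjugate")
        p0 = np.exp(fit.flat("beta0"))
        assert p0.mean() == pytest.approx(31 / 102, abs=3 * np.sqrt(0.3 * 0.7 / 102 / 80_000) * 10)
        assert stats.kstest(p0, stats.beta(31, 71).cdf).pvalue > 0.001

    def test_site_prior_scale_to_zero_recovers_two_arm(self, fast_settings):
        rng = np.random.default_rng(5)
        n = 1200
        df = pd.DataFrame({
            "arm": rng.integers(0, 2, n).astype(float),
            "site": rng.integers(0, 6, n),
        })
        df["y"] = (rng.random(n) < np.where(df["arm"] > 0, 0.25, 0.35)).astype(int)
        tight = PriorSpec(kind="normal_logrr", site_sd_scale=1e-4)
        hier = fit_rr_model(df, tight, fast_settings, "site_hierarchical")
        flat2 = fit_rr_model(df, PriorSpec(kind="flat"), fast_settings, "two_arm")
        sites = [k for k in hier.draws if k.startswith("site[")]
        assert all(np.abs(hier.flat(k)).max() < 0.01 for k in sites)
        se = np.sqrt(hier.theta.var() / 200 + flat2.theta.var() / 200)
        assert abs(hier.theta.mean() - flat2.theta.mean()) < 4 * se

    def test_constraint_no_draw_implies_probability_above_one(self, fast_settings):
        df = two_arm_frame(40, 35, 40, 30)  # high risks push against p <= 1
        fit = fit_rr_model(df, PriorSpec(kind="flat"), fast_settings, "two_arm")
        assert (fit.flat("beta0") < 0).all()
        assert (fit.flat("beta0") + fit.theta < 0).all()

    def test_reproducible_for_identical_seeds(self, loop_settings):
        df = two_arm_frame(200, 60, 200, 45)
        a = fit_rr_model(df, settings=loop_settings, diagnostics=False)
        b = fit_rr_model(df, settings=loop_settings, diagnostics=False)
        assert np.array_equal(a.theta, b.theta)

    def test_separation_and_empty_warnings(self, loop_settings):
        none = two_arm_frame(50, 0, 50, 0)
        fit = fit_rr_model(none, settings=loop_settings, diagnostics=False)
        assert any("flat" in w for w in fit.warnings)
        one_sided = two_arm_frame(50, 8, 50, 0)
        fit2 = fit_rr_model(one_sided, settings=loop_settings, diagnostics=False)
        assert any("separation" in w for w in fit2.warnings)
        with pytest.raises(InferenceError):
            fit_rr_model(two_arm_frame(50, 5, 0, 0), settings=loop_settings)


class TestEffectSummary:
    def test_fixed_arm_risks(self):
        p0, p1 = 0.35, 0.27
        draws = {"beta0": np.full((1, 500), np.log(p0)),
                 "theta": np.full((1, 500), np.log(p1 / p0))}
        post = PosteriorDraws(draws, "two_arm", "conjugate")
        s = summarise_effect(post)
        assert s.mean_rd == pytest.approx(0.08)
        assert s.mean_rr == pytest.approx(p1 / p0, abs=1e-9)
        assert s.decision == "superior"  # all draws below zero

    def test_null_draws(self):
        draws = {"beta0": np.full((1, 500), np.log(0.3)),
                 "theta": np.zeros((1, 500))}
        s = summarise_effect(PosteriorDraws(draws, "two_arm", "conjugate"))
        assert s.mean_rr == pytest.approx(1.0)
        assert s.mean_rd == pytest.approx(0.0)
        assert s.decision == "not_superior"


class TestHazardModel:
    def test_single_interval_matches_gamma_exponential_oracle(self, fast_settings):
        rng = np.random.default_rng(7)
        n = 600
        arm = rng.integers(0, 2, n)
        t = rng.exponential(1 / np.where(arm == 1, 0.07, 0.1))
        df = pd.DataFrame({"duration": t, "event": 1, "arm": arm.astype(float)})
        fit = fit_pe_hazard(df, settings=fast_settings, n_intervals=1)
        hr = np.exp(fit.theta)
        d0, T0 = float((arm == 0).sum()), t[arm == 0].sum()
        d1, T1 = float((arm == 1).sum()), t[arm == 1].sum()
        oracle = rng.gamma(d1, 1 / T1, 40_000) / rng.gamma(d0, 1 / T0, 40_000)
        se = np.sqrt(hr.var() / 300 + oracle.var() / 40_000)
        assert abs(np.median(hr) - np.median(oracle)) < 4 * se + 0.01

    def test_permuted_arms_give_null_hazard_ratio(self, fast_settings):
        rng = np.random.default_rng(8)
        n = 1000
        t = rng.exponential(10.0, n)
        df = pd.DataFrame({"duration": t, "event": 1,
                           "arm": rng.permutation(np.repeat([0.0, 1.0], n // 2))})
        s = summarise_hazard(fit_pe_hazard(df, settings=fast_settings, n_intervals=4))
        assert s["hdi_hr"][0] < 1 < s["hdi_hr"][1]
        assert s["median_hr"] == pytest.approx(1.0, abs=0.2)

    def test_identical_durations_rejected(self):
        df = pd.DataFrame({"duration": [5.0] * 20, "event": 1,
                           "arm": [0.0, 1.0] * 10})
        with pytest.raises(InferenceError, match="degenerate"):
            fit_pe_hazard(df)


class TestCostModel:
    def test_normal_family_matches_closed_form(self, fast_settings):
        rng = np.random.default_rng(9)
        y = np.r_[rng.normal(100, 5, 500), rng.normal(110, 5, 500)]
        df = pd.DataFrame({"expenses": y, "arm": np.repeat([0.0, 1.0], 500)})
        post, report = fit_cost_model(df, "normal", settings=fast_settings)
        delta = post.flat("delta")
        closed = y[500:].mean() - y[:500].mean()
        se_closed = 5 * np.sqrt(2 / 500)
        mc_se = delta.std() / np.sqrt(200)
        assert abs(delta.mean() - closed) < 3 * (mc_se + se_closed / 50)
        assert not report["non_normal"]

    def test_skewed_data_flagged(self, loop_settings):
        rng = np.random.default_rng(10)
        y = rng.gamma(1.0, 60, 800)
        df = pd.DataFrame({"expenses": y, "arm": rng.integers(0, 2, 800).astype(float)})
        _, report = fit_cost_model(df, "normal", settings=loop_settings)
        assert report["non_normal"] and report["skewness"] > 1

    def test_identical_distributions_cover_zero(self, fast_settings):
        rng = np.random.default_rng(11)
        y = rng.normal(80, 10, 600)
        df = pd.DataFrame({"expenses": y, "arm": np.repeat([0.0, 1.0], 300)})
        post, _ = fit_cost_model(df, "normal", settings=fast_settings)
        from epidex.inference import hdi as _hdi
        lo, hi = _hdi(post.flat("delta"))
        assert lo < 0 < hi

    def test_lognormal_rejects_zeros(self):
        df = pd.DataFrame({"expenses": [0.0, 5.0, 2.0, 3.0],
                           "arm": [0.0, 0.0, 1.0, 1.0]})
        with pytest.raises(InferenceError, match="gamma"):
            fit_cost_model(df, "lognormal")


class TestRepeatedMeasures:
    def test_patient_random_effects_recover_effect(self, loop_settings):
        """Two binary symptom measurements per infant, analysed with patient
        random intercepts, recover the treatment log RR."""
        rng = np.random.default_rng(12)
        n = 600
        arm = rng.integers(0, 2, n)
        u = rng.normal(0, 0.3, n)
        theta = -0.3
        rows = []
        for visit in range(2):
            p = np.minimum(np.exp(np.log(0.4) + theta * arm + u), 0.99)
            y = (rng.random(n) < p).astype(int)
            rows.append(pd.DataFrame({"y": y, "arm": arm.astype(float),
                                      "patient": np.arange(n)}))
        df = pd.concat(rows, ignore_index=True)
        fit = fit_rr_model(df, settings=loop_settings, structure="repeated_measures",
                           diagnostics=False)
        lo, hi = hdi(fit.theta)
        assert lo < theta < hi
        assert fit.theta.mean() == pytest.approx(theta, abs=0.15)


class TestGammaCostFamily:
    def test_ratio_effect_recovered(self, fast_settings):
        rng = np.random.default_rng(13)
        shape = 2.0
        mean = np.repeat([50.0, 75.0], 400)  # ratio 1.5
        y = rng.gamma(shape, mean / shape)
        df = pd.DataFrame({"expenses": y, "arm": np.repeat([0.0, 1.0], 400)})
        post, report = fit_cost_model(df, "gamma", settings=fast_settings)
        ratio = np.exp(post.flat("delta"))
        assert np.median(ratio) == pytest.approx(1.5, abs=0.15)
        lo, hi = hdi(ratio)
        assert lo < 1.5 < hi
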