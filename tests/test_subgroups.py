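"""Subgroup classification, interaction declarations, risk model, strata."""

import numpy as np
import pandas as pd
import pytest

from epidex import CohortConfig, generate_cohort
from epidex.config import McmcSettings, PriorSpec
from epidex.outcomes import derive_outcomes, resolve_confirmation
from epidex.subgroups import (SubgroupError, classify_subgroups, fit_risk_model,
                              hte_analysis, make_risk_strata,
                              stratum_treatment_effects,
                              subgroup_interaction_analysis)


class TestClassification:
    def test_membership_rules(self, cohort):
        m = classify_subgroups(cohort.participants).set_index("participant_id")
        p = cohort.participants.set_index("participant_id")
        pid = p.index[p["age_days"] < 183][0]
        assert m.loc[pid, "age_lt6m"] == 1.0
        pid2 = p.index[p["age_days"] >= 183][0]
        assert m.loc[pid2, "age_lt6m"] == 0.0
        south = p["site_hemisphere"] == "southern"
        assert (m.loc[south[south].index, "hemisphere"] == 1.0).all()

    def test_onset_boundary_inclusive(self):
        p = pd.DataFrame({
            "participant_id": ["a", "b", "c"],
            "age_days": [100, 200, 300],
            "symptom_onset_hours_before_enrolment": [48.0, 48.1, np.nan],
            "eczema": [True, False, True], "family_atopy": [False, True, False],
            "site_hemisphere": ["northern"] * 3, "delivery_mdi": [True, False, True],
        })
        m = classify_subgroups(p)
        assert m["onset_48h"].tolist()[:2] == [1.0, 0.0]
        assert np.isnan(m["onset_48h"].iloc[2])

    def test_missing_covariate_propagates(self):
        p = pd.DataFrame({
            "participant_id": ["a"], "age_days": [100],
            "symptom_onset_hours_before_enrolment": [10.0],
            "eczema": [np.nan], "family_atopy": [True],
            "site_hemisphere": ["southern"], "delivery_mdi": [False],
        })
        m = classify_subgroups(p)
        assert np.isnan(m["eczema"].iloc[0])
        assert m["family_atopy"].iloc[0] == 1.0


def _interaction_data(rng, n, delta, base=0.3, theta=-0.25):
    arm = rng.integers(0, 2, n).astype(float)
    g = rng.integers(0, 2, n).astype(float)
    p = np.exp(np.log(base) + theta * arm + 0.0 * g + delta * arm * g)
    y = (rng.random(n) < p).astype(int)
    return pd.DataFrame({"y": y, "arm": arm, "group": g})


class TestInteraction:
    def test_strong_interaction_declared_and_symmetric(self, loop_settings):
        rng = np.random.default_rng(1)
        df = _interaction_data(rng, 6000, delta=0.8)
        res = subgroup_interaction_analysis(df, "eczema", settings=loop_settings)
        assert res.declaration == "positive"
        flipped = df.assign(group=1 - df["group"])
        res2 = subgroup_interaction_analysis(flipped, "eczema", settings=loop_settings)
        assert res2.declaration == "negative"
        assert res.prob_positive + res2.prob_positive == pytest.approx(1.0, abs=0.05)

    def test_no_declaration_below_threshold(self, loop_settings):
        rng = np.random.default_rng(2)
        df = _interaction_data(rng, 800, delta=0.0)
        res = subgroup_interaction_analysis(df, "eczema", settings=loop_settings)
        assert res.declaration == "none"

    def test_empty_cell_refused_with_counts(self, loop_settings):
        df = pd.DataFrame({"y": [0, 1, 0, 1], "arm": [0.0, 0.0, 1.0, 1.0],
                           "group": [0.0, 0.0, 0.0, 0.0]})
        with pytest.raises(SubgroupError, match="cell"):
            subgroup_interaction_analysis(df, "eczema", settings=loop_settings)


class TestRiskModel:
    def test_arm_permutation_invariance(self, clean_cohort, clean_outcomes):
        df = clean_cohort.participants.merge(
            clean_outcomes[["participant_id", "primary_hosp_7d"]], on="participant_id")
        rm = fit_risk_model(df, outcome="primary_hosp_7d")
        permuted = df.copy()
        permuted["arm"] = np.random.default_rng(0).permutation(permuted["arm"].to_numpy())
        rm2 = fit_risk_model(permuted, outcome="primary_hosp_7d")
        assert np.allclose(rm.predict_risk(df), rm2.predict_risk(df))

    def test_arm_in_covariates_rejected(self, clean_cohort, clean_outcomes):
        df = clean_cohort.participants.merge(
            clean_outcomes[["participant_id", "primary_hosp_7d"]], on="participant_id")
        with pytest.raises(ValueError, match="treatment"):
            fit_risk_model(df, covariates=("age_days", "arm"), outcome="primary_hosp_7d")

    def test_null_generator_gives_flat_predictions(self):
        c = generate_cohort(CohortConfig(n_participants=3000, seed=51,
                                         covariate_effects={}, site_sd=0.0))
        ev = resolve_confirmation(c.events, c.participants)
        oc = derive_outcomes(c.participants, ev)
        df = c.participants.merge(oc[["participant_id", "primary_hosp_7d"]],
                                  on="participant_id")
        rm = fit_risk_model(df, outcome="primary_hosp_7d")
        assert rm.predict_risk(df).std() < 0.05

    def test_recovers_true_risk_ordering(self):
        strong = {"prematurity": 0.7, "previous_wheeze": 0.6, "household_smoke": 0.5,
                  "rdai": 0.08, "age_days": -0.002, "breastfeeding": -0.3}
        c = generate_cohort(CohortConfig(n_participants=5000, seed=52,
                                         covariate_effects=strong))
        ev = resolve_confirmation(c.events, c.participants)
        oc = derive_outcomes(c.participants, ev)
        df = c.participants.merge(oc[["participant_id", "primary_hosp_7d"]],
                                  on="participant_id")
        rm = fit_risk_model(df, outcome="primary_hosp_7d")
        pred = rm.predict_risk(df)
        true_p = c.truth.set_index("participant_id").loc[df["participant_id"], "p_true"]
        rho = pd.Series(pred).corr(pd.Series(true_p.to_numpy()), method="spearman")
        assert rho > 0.8


class TestStrata:
    def test_exact_deciles(self):
        r = np.random.default_rng(3).random(1000)
        assign, bounds = make_risk_strata(r, 10)
        counts = np.bincount(assign)
        assert (counts == 100).all()
        assert len(bounds) == 11 and (np.diff(bounds) >= 0).all()

    def test_partition_is_exact(self):
        r = np.random.default_rng(4).random(537)
        assign, _ = make_risk_strata(r, 10)
        assert assign.size == 537 and set(np.unique(assign)) == set(range(10))

    def test_small_n_sizes(self):
        assign, _ = make_risk_strata(np.random.default_rng(5).random(23), 10)
        counts = np.bincount(assign)
        assert counts.min() == 23 // 10 and counts.max() == -(-23 // 10)

    def test_identical_risks_warn(self):
        with pytest.warns(UserWarning, match="distinct"):
            make_risk_strata(np.full(100, 0.3), 10)

    def test_too_few_participants(self):
        with pytest.raises(ValueError):
            make_risk_strata(np.arange(5) / 5, 10)


class TestStratumEffects:
    def test_minimal_cells_finite(self, loop_settings):
        df = pd.DataFrame({"y": [1, 0] * 10, "arm": ["placebo", "epidex"] * 10})
        strata = np.repeat(np.arange(10), 2)
        res = stratum_treatment_effects(df, strata, settings=loop_settings,
                                        method="conjugate")
        assert res.table["estimable"].all()
        assert np.isfinite(res.table[["median_rr", "rr_lo", "rr_hi"]]).all().all()

    def test_single_arm_stratum_reported_inestimable(self, loop_settings):
        df = pd.DataFrame({"y": [1, 0, 0, 1], "arm": ["placebo"] * 2 + ["epidex"] * 2})
        strata = np.array([0, 0, 1, 1])
        res = stratum_treatment_effects(df, strata, settings=loop_settings,
                                        method="conjugate")
        assert len(res.table) == 2
        assert not res.table["estimable"].any()
        assert res.table["n_placebo"].tolist() == [2, 0]

    def test_full_hte_partitions_cohort(self, clean_cohort, clean_outcomes, loop_settings):
        rm, res = hte_analysis(clean_cohort.participants, clean_outcomes,
                               settings=loop_settings, method="conjugate")
        assert res.table["stratum"].tolist() == list(range(10))
        n_total = (res.table["n_placebo"] + res.table["n_epidex"]).sum()
        assert n_total == len(clean_outcomes)
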