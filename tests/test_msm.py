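"""Outcome models: weighted pooled logistic, sandwich variance, sensitivity."""

import numpy as np
import pandas as pd
import pytest
import statsmodels.api as sm

from occmsm import cohort
from occmsm.msm import (
    ModelSpec,
    MsmError,
    compare_weighted_unweighted,
    fit_msm_with_iptw,
    fit_pooled_logistic,
    render_comparison_markdown,
    threshold_sensitivity,
)
from occmsm.weights import (
    WeightSet,
    compute_stabilized_weights,
    fit_exposure_models,
    truncate_weights,
)


def _unit_weights(persondays):
    return WeightSet(table=pd.DataFrame({
        "patient_id": persondays["patient_id"].to_numpy(),
        "t": persondays["t"].to_numpy(),
        "sw": np.ones(len(persondays)),
    }, index=persondays.index))


class TestPooledLogistic:
    def test_unit_weights_equal_unweighted_fit(self, small_cohort):
        pdt = small_cohort["persondays"]
        a = fit_pooled_logistic(pdt, ModelSpec())
        b = fit_pooled_logistic(pdt, ModelSpec(), weights=_unit_weights(pdt))
        np.testing.assert_allclose(a.terms["estimate"], b.terms["estimate"], atol=1e-8)

    def test_singleton_clusters_match_heteroskedastic_robust(self, small_cohort):
        pdt = small_cohort["persondays"].copy()
        pdt["patient_id"] = np.arange(len(pdt))  # one row per cluster
        res = fit_pooled_logistic(pdt, ModelSpec(cluster_level="patient"))
        from occmsm.design import baseline_design
        X = sm.add_constant(
            pd.concat([pdt[["cum_exposed"]].astype(float), baseline_design(pdt)], axis=1),
            has_constant="add",
        )
        glm = sm.GLM(pdt["death"].to_numpy(float), X,
                     family=sm.families.Binomial()).fit(cov_type="HC0")
        np.testing.assert_allclose(res.terms["se"], glm.bse, atol=1e-6)

    def test_recovers_effect_on_unconfounded_cohort(self, unconfounded_cohort):
        """With every confounding channel off, the naive pooled logistic
        recovers the true per-day log-odds effect within 2 robust SE."""
        res = fit_pooled_logistic(unconfounded_cohort["persondays"], ModelSpec())
        row = res.exposure_row
        truth = unconfounded_cohort["config"].beta_cum_exposure
        assert abs(row["estimate"] - truth) < 2 * row["se"]

    def test_ci_is_exp_of_estimate_pm_1p96_se(self, small_cohort):
        res = fit_pooled_logistic(small_cohort["persondays"], ModelSpec())
        t = res.terms
        np.testing.assert_allclose(t["ci_low"], np.exp(t["estimate"] - 1.96 * t["se"]))
        np.testing.assert_allclose(t["ci_high"], np.exp(t["estimate"] + 1.96 * t["se"]))
        assert (t["odds_ratio"] > 0).all()

    def test_deterministic_refit(self, small_cohort):
        pdt = small_cohort["persondays"]
        a = fit_pooled_logistic(pdt, ModelSpec())
        b = fit_pooled_logistic(pdt, ModelSpec())
        pd.testing.assert_frame_equal(a.terms, b.terms)

    def test_single_level_outcome_raises(self, small_cohort):
        pdt = small_cohort["persondays"].copy()
        pdt["death"] = 0
        with pytest.raises(MsmError):
            fit_pooled_logistic(pdt, ModelSpec())

    def test_short_term_spec_runs_on_same_table(self, small_cohort):
        res = fit_pooled_logistic(small_cohort["persondays"],
                                  ModelSpec(exposure_term="short_term"))
        assert "exposed" in res.terms.index

    def test_unknown_cluster_level_raises(self, small_cohort):
        with pytest.raises(MsmError):
            fit_pooled_logistic(small_cohort["persondays"],
                                ModelSpec(cluster_level="ward"))


class TestComparison:
    def test_table_schema_and_markdown(self, small_cohort):
        pdt = small_cohort["persondays"]
        models = fit_exposure_models(pdt)
        ws = compute_stabilized_weights(models, pdt)
        comp = compare_weighted_unweighted(pdt, ws)
        assert {"or_unweighted", "or_weighted", "estimate_unweighted",
                "estimate_weighted"} <= set(comp.columns)
        assert "cum_exposed" in comp.index
        md = render_comparison_markdown(comp)
        assert md.startswith("|") and "cum_exposed" in md

    def test_no_confounding_estimates_agree(self, unconfounded_cohort):
        """With confounding off, weighted and unweighted estimates differ by
        less than twice their combined SE."""
        pdt = unconfounded_cohort["persondays"]
        models = fit_exposure_models(pdt)
        ws = compute_stabilized_weights(models, pdt)
        comp = compare_weighted_unweighted(pdt, ws)
        unw = fit_pooled_logistic(pdt, ModelSpec())
        w = fit_pooled_logistic(pdt, ModelSpec(), weights=ws)
        se = np.hypot(unw.exposure_row["se"], w.exposure_row["se"])
        diff = abs(comp.loc["cum_exposed", "estimate_weighted"]
                   - comp.loc["cum_exposed", "estimate_unweighted"])
        assert diff < 2 * se

    def test_truncation_tightens_robust_se(self, unconfounded_cohort):
        """Clipping the weight tails buys precision on a year-scale cohort."""
        pdt = unconfounded_cohort["persondays"]
        models = fit_exposure_models(pdt)
        ws = compute_stabilized_weights(models, pdt)
        full = fit_pooled_logistic(pdt, ModelSpec(), weights=ws)
        trunc = fit_pooled_logistic(pdt, ModelSpec(),
                                    weights=truncate_weights(ws, 1, 99))
        assert trunc.exposure_row["se"] <= full.exposure_row["se"]


class TestThresholdSensitivity:
    def test_sweep_rows_and_monotone_exposure(self, small_cohort):
        sens = threshold_sensitivity(
            small_cohort["records"], small_cohort["hospital_days"],
            percentiles=(75, 80, 85, 90, 95), use_weights=False,
        )
        assert len(sens) == 5
        counts = sens["n_exposed_person_days"].to_numpy()
        assert (np.diff(counts) <= 0).all()

    def test_extreme_percentile_flags_sparse_exposure(self, small_cohort):
        sens = threshold_sensitivity(
            small_cohort["records"], small_cohort["hospital_days"],
            percentiles=(99.9,), use_weights=False,
        )
        assert bool(sens["sparse_exposure"].iloc[0])

    def test_near_maximum_percentile_exposes_single_day(self):
        rng = np.random.default_rng(0)
        hd = pd.DataFrame({
            "hospital_id": "H", "day": np.arange(1, 101),
            "capacity_utilization": np.sort(rng.uniform(0, 100, 100)),
        })
        thr = cohort.derive_threshold(hd, 99.99)
        flagged = cohort.flag_exposure(hd, thr)
        assert flagged["exposed"].sum() == 1

    def test_invalid_percentile_raises(self, small_cohort):
        with pytest.raises(MsmError):
            threshold_sensitivity(small_cohort["records"],
                                  small_cohort["hospital_days"],
                                  percentiles=(-5,))


def test_fit_msm_with_iptw_returns_weights(small_cohort):
    res, ws = fit_msm_with_iptw(small_cohort["persondays"])
    assert res.weighted
    assert len(ws.table) == len(small_cohort["persondays"])
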