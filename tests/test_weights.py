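"""Stabilized IPTW: models, product formula, truncation, diagnostics."""

import numpy as np
import pandas as pd
import pytest
import statsmodels.api as sm

from occmsm.weights import (
    EstimationError,
    WeightSet,
    compute_stabilized_weights,
    fit_exposure_models,
    stabilized_weights_from_probs,
    truncate_weights,
    weight_diagnostics,
)

from oracles import sequence_weight_tabulation


def _persondays_from_arrays(pid, t, a, l):
    n = len(pid)
    df = pd.DataFrame({
        "patient_id": pid, "hospital_id": "H", "t": t,
        "exposed": np.asarray(a, int),
        "turnover": np.asarray(l, float), "mean_pccl": 1.0,
        "hospital_type": 1, "sex": "f", "age_group": 8,
        "pccl": 1, "elixhauser_weight": 0.0, "weekend_admission": False,
        "admission_day": 1,
    })
    df["cum_exposed"] = df.groupby("patient_id")["exposed"].cumsum()
    df["death"] = 0
    return df


class TestStabilizedProduct:
    def test_identical_models_give_unit_weights(self):
        rng = np.random.default_rng(0)
        df = _persondays_from_arrays(
            np.repeat(np.arange(50), 2), np.tile([1, 2], 50),
            rng.integers(0, 2, 100), rng.integers(0, 2, 100),
        )
        p = rng.uniform(0.2, 0.8, len(df))
        ws = stabilized_weights_from_probs(df, p, p)
        np.testing.assert_allclose(ws.sw, 1.0)

    def test_hand_arithmetic_two_day_patient(self):
        df = _persondays_from_arrays(["p", "p"], [1, 2], [1, 0], [0, 0])
        ws = stabilized_weights_from_probs(
            df, np.array([0.5, 0.5]), np.array([0.8, 0.4])
        )
        assert ws.sw.iloc[0] == pytest.approx(0.625)
        assert ws.sw.iloc[1] == pytest.approx(0.625 * (0.5 / 0.6), abs=5e-5)

    def test_product_formula_matches_sequence_tabulation(self):
        """On a 2-day discrete system, cumulative-product weights from
        tabulated conditional frequencies equal the ratio of empirical
        sequence probabilities computed independently."""
        rng = np.random.default_rng(11)
        n = 400
        l1 = rng.integers(0, 2, n)
        a1 = rng.binomial(1, 0.3 + 0.4 * l1)
        l2 = rng.binomial(1, 0.3 + 0.3 * a1)
        a2 = rng.binomial(1, 0.2 + 0.3 * l2 + 0.2 * a1)
        df = pd.DataFrame({
            "patient_id": np.repeat(np.arange(n), 2),
            "t": np.tile([1, 2], n),
            "a": np.column_stack([a1, a2]).ravel(),
            "l": np.column_stack([l1, l2]).ravel(),
        })
        # conditional frequencies by direct tabulation feed the product formula
        pdt = _persondays_from_arrays(df["patient_id"], df["t"], df["a"], df["l"])
        wide_a1 = np.repeat(a1, 2)
        p_num = np.empty(2 * n)
        p_den = np.empty(2 * n)
        is_t1 = np.tile([True, False], n)
        p1 = a1.mean()
        for lv in (0, 1):
            m = l1 == lv
            p_den[np.repeat(m, 2) & is_t1] = a1[m].mean()
        p_num[is_t1] = p1
        for av in (0, 1):
            m = a1 == av
            p_num[np.repeat(m, 2) & ~is_t1] = a2[m].mean()
            for l1v in (0, 1):
                for l2v in (0, 1):
                    mm = m & (l1 == l1v) & (l2 == l2v)
                    if mm.any():
                        p_den[np.repeat(mm, 2) & ~is_t1] = a2[mm].mean()
        ws = stabilized_weights_from_probs(pdt, p_num, p_den)
        oracle = sequence_weight_tabulation(df)
        mine = pd.Series(
            ws.sw.to_numpy(),
            index=pd.MultiIndex.from_arrays([df["patient_id"], df["t"]]),
        )
        np.testing.assert_allclose(mine.to_numpy(), oracle[mine.index].to_numpy(), atol=1e-6)


class TestExposureModels:
    def test_saturated_model_equals_empirical_frequencies(self):
        """With one binary confounder and single-day records the denominator
        logistic is saturated, so fitted probabilities are the nonparametric
        conditional frequencies."""
        rng = np.random.default_rng(4)
        n = 2000
        l = rng.integers(0, 2, n)
        a = rng.binomial(1, 0.25 + 0.5 * l)
        df = _persondays_from_arrays(np.arange(n), np.ones(n, int), a, l)
        models = fit_exposure_models(df, history="prev")
        ws = compute_stabilized_weights(models, df)
        for lv in (0, 1):
            emp = a[l == lv].mean()
            fitted = ws.table.loc[(df["turnover"] == lv) & (df["exposed"] == 1), "p_den"]
            np.testing.assert_allclose(fitted, emp, atol=1e-6)
        # numerator ignores the confounder: marginal frequency
        np.testing.assert_allclose(
            ws.table.loc[df["exposed"] == 1, "p_num"], a.mean(), atol=1e-6
        )

    def test_independent_confounder_aligns_models(self):
        """When the exposure is independent of the confounder, the denominator's
        confounder terms vanish and numerator and denominator probabilities
        nearly coincide.  (Uses a randomized-exposure table: in the hospital
        simulator turnover and utilization are mechanically coupled through
        the flow accounting, so the independence null never holds there.)"""
        rng = np.random.default_rng(8)
        n, days = 4000, 3
        pid = np.repeat(np.arange(n), days)
        t = np.tile(np.arange(1, days + 1), n)
        a = rng.binomial(1, 0.25, n * days)
        l = rng.normal(10, 3, n * days)
        pdt = _persondays_from_arrays(pid, t, a, l)
        models = fit_exposure_models(pdt)
        res = models.denominator_result
        for term in ("turnover", "mean_pccl"):
            if term in res.params:
                assert abs(res.params[term]) < 2 * res.bse[term]
        ws = compute_stabilized_weights(models, pdt)
        assert np.max(np.abs(ws.table["p_num"] - ws.table["p_den"])) < 0.02

    def test_constant_exposure_raises(self):
        df = _persondays_from_arrays(np.arange(30), np.ones(30, int),
                                     np.zeros(30, int), np.zeros(30))
        with pytest.raises(EstimationError):
            fit_exposure_models(df)

    def test_weighting_removes_confounder_exposure_association(self):
        """In the weighted pseudo-population the time-varying confounder no
        longer predicts the exposure, on a system where the weight model is
        correctly specified (L drives A through a logistic law)."""
        rng = np.random.default_rng(9)
        n, days = 6000, 2
        pid = np.repeat(np.arange(n), days)
        t = np.tile([1, 2], n)
        l = rng.binomial(1, 0.5, n * days).astype(float)
        from scipy.special import expit
        a = np.zeros(n * days, int)
        a[t == 1] = rng.binomial(1, expit(-1.2 + 1.5 * l[t == 1]))
        a[t == 2] = rng.binomial(1, expit(-1.4 + 1.5 * l[t == 2] + 0.8 * a[t == 1]))
        pdt = _persondays_from_arrays(pid, t, a, l)
        # unweighted association is strong by construction
        models = fit_exposure_models(pdt, history="prev")
        ws = compute_stabilized_weights(models, pdt)
        X = sm.add_constant(pd.DataFrame({
            "turnover": pdt["turnover"].to_numpy(float),
            "exposed_prev": pdt.groupby("patient_id")["exposed"].shift(1).fillna(0.0).to_numpy(),
        }))
        kw = dict(groups=pdt["patient_id"].to_numpy(), family=sm.families.Binomial(),
                  cov_struct=sm.cov_struct.Independence())
        unw = sm.GEE(pdt["exposed"].to_numpy(float), X, **kw).fit()
        w = sm.GEE(pdt["exposed"].to_numpy(float), X, weights=ws.sw.to_numpy(), **kw).fit()
        assert abs(unw.params["turnover"]) > 10 * unw.bse["turnover"]
        assert abs(w.params["turnover"]) < 2 * w.bse["turnover"]


class TestTruncation:
    def test_all_equal_unchanged(self):
        ws = WeightSet(table=pd.DataFrame({"patient_id": range(5), "t": 1, "sw": 2.0}))
        out = truncate_weights(ws)
        assert out.n_modified == 0
        assert (out.sw == 2.0).all()

    def test_distinct_values_clip_to_percentiles(self):
        sw = np.arange(1.0, 101.0)
        ws = WeightSet(table=pd.DataFrame({"patient_id": range(100), "t": 1, "sw": sw}))
        out = truncate_weights(ws, 1, 99)
        lo, hi = np.percentile(sw, [1, 99])
        assert out.truncation_bounds == (pytest.approx(lo), pytest.approx(hi))
        assert out.sw.min() == pytest.approx(lo)
        assert out.sw.max() == pytest.approx(hi)
        assert out.n_modified == 2

    def test_full_range_is_identity(self):
        rng = np.random.default_rng(1)
        sw = rng.lognormal(0, 0.5, 50)
        ws = WeightSet(table=pd.DataFrame({"patient_id": range(50), "t": 1, "sw": sw}))
        out = truncate_weights(ws, 0, 100)
        np.testing.assert_allclose(out.sw, sw)

    def test_variance_never_increases_hypothesis(self):
        from hypothesis import given, settings, strategies as st

        @settings(derandomize=True, max_examples=40, deadline=None)
        @given(
            sw=st.lists(st.floats(0.01, 50.0), min_size=5, max_size=60),
            lo=st.floats(0.0, 40.0),
            span=st.floats(1.0, 60.0),
        )
        def check(sw, lo, span):
            ws = WeightSet(table=pd.DataFrame(
                {"patient_id": range(len(sw)), "t": 1, "sw": sw}))
            out = truncate_weights(ws, lo, min(lo + span, 100.0))
            assert out.sw.var() <= ws.sw.var() + 1e-12
            # clipping preserves order statistics at the bounds
            assert out.sw.min() >= ws.sw.min() - 1e-12
            assert out.sw.max() <= ws.sw.max() + 1e-12

        check()

    def test_variance_never_increases(self):
        rng = np.random.default_rng(2)
        for _ in range(20):
            sw = rng.lognormal(0, rng.uniform(0.1, 1.5), 200)
            ws = WeightSet(table=pd.DataFrame({"patient_id": range(200), "t": 1, "sw": sw}))
            lo = rng.uniform(0, 20)
            hi = rng.uniform(80, 100)
            out = truncate_weights(ws, lo, hi)
            assert out.sw.var() <= ws.sw.var() + 1e-12

    def test_bad_bounds_raise(self):
        ws = WeightSet(table=pd.DataFrame({"patient_id": [0], "t": [1], "sw": [1.0]}))
        with pytest.raises(ValueError):
            truncate_weights(ws, 99, 1)


class TestDiagnostics:
    def test_degenerate_unit_weights(self):
        ws = WeightSet(table=pd.DataFrame({"patient_id": range(4), "t": 1, "sw": 1.0}))
        d = weight_diagnostics(ws)
        assert d["mean"] == 1 and d["median"] == 1
        assert d["iqr"] == (1, 1) and d["min"] == 1 and d["max"] == 1
        assert not d["misspecification_warning"]

    def test_simple_arithmetic(self):
        ws = WeightSet(table=pd.DataFrame({"patient_id": range(4), "t": 1,
                                           "sw": [0.5, 1.0, 1.5, 2.0]}))
        d = weight_diagnostics(ws)
        assert d["mean"] == pytest.approx(1.25)
        assert d["median"] == pytest.approx(1.25)
        assert d["min"] == 0.5 and d["max"] == 2.0
        assert d["misspecification_warning"]

    def test_summary_schema(self):
        ws = WeightSet(table=pd.DataFrame({"patient_id": range(4), "t": 1, "sw": 1.0}))
        d = weight_diagnostics(ws)
        assert {"mean", "median", "iqr", "min", "max"} <= set(d)

    def test_density_plot_written(self, tmp_path):
        rng = np.random.default_rng(0)
        ws = WeightSet(table=pd.DataFrame({"patient_id": range(200), "t": 1,
                                           "sw": rng.lognormal(0, 0.3, 200)}))
        path = tmp_path / "density.png"
        weight_diagnostics(ws, plot_path=path)
        assert path.exists() and path.stat().st_size > 0
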