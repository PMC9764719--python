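"""Stabilized inverse-probability-of-treatment weights for the daily exposure.

For a binary time-varying exposure :math:`A_t` (high capacity utilization on
stay-day :math:`t`) the stabilized weight of a person-day is

.. math::

    sw_t = \\prod_{s \\le t}
        \\frac{P(A_s = a_s \\mid \\bar A_{s-1}, V, s)}
              {P(A_s = a_s \\mid \\bar A_{s-1}, V, s, L_s)}

where :math:`V` are baseline covariates (sex, age, hospital type, comorbidity
class, weekend admission), :math:`L_s` the time-varying confounders of the
hospital-day (patient turnover, mean clinical complexity) and
:math:`\\bar A_{s-1}` the exposure history, summarised by the previous day's
exposure and the running count.  Both conditional probabilities come from
pooled logistic regressions over all person-days; weighting by ``sw`` creates
a pseudo-population in which :math:`L_t` no longer predicts :math:`A_t`, so a
marginal structural model can be fitted by weighted regression.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
import statsmodels.api as sm

from .design import baseline_design, comorbidity_class

__all__ = [
    "ExposureModels",
    "WeightSet",
    "fit_exposure_models",
    "compute_stabilized_weights",
    "truncate_weights",
    "weight_diagnostics",
]

POSITIVITY_EPS = 1e-9


class EstimationError(RuntimeError):
    """Raised when an exposure model cannot be estimated (degenerate exposure,
    perfect separation, or non-convergence)."""


@dataclass
class ExposureModels:
    """Fitted numerator and denominator pooled logistic exposure models."""

    numerator: sm.GLM
    denominator: sm.GLM
    numerator_result: object
    denominator_result: object
    numerator_columns: list[str]
    denominator_columns: list[str]
    spec: dict = field(default_factory=dict)

    @property
    def converged(self) -> bool:
        return bool(
            getattr(self.numerator_result, "converged", True)
            and getattr(self.denominator_result, "converged", True)
        )


@dataclass
class WeightSet:
    """Per person-day numerator/denominator probabilities and stabilized weights.

    ``table`` is aligned 1:1 with the person-day table it was computed from and
    carries ``p_num``, ``p_den`` (probability of the *observed* exposure) and
    the within-patient cumulative-product weight ``sw``.
    """

    table: pd.DataFrame
    truncation: tuple[float, float] | None = None
    truncation_bounds: tuple[float, float] | None = None
    n_modified: int = 0

    @property
    def sw(self) -> pd.Series:
        return self.table["sw"]


def _history_design(persondays: pd.DataFrame, history: str) -> pd.DataFrame:
    """Exposure-history terms: previous-day exposure and/or lagged cumulative count."""
    g = persondays.groupby("patient_id", sort=False)
    prev = g["exposed"].shift(1).fillna(0.0)
    cum_prev = persondays["cum_exposed"] - persondays["exposed"]
    cols = {}
    if history in ("prev", "both"):
        cols["exposed_prev"] = prev.to_numpy(float)
    if history in ("cum", "both"):
        cols["cum_exposed_prev"] = cum_prev.to_numpy(float)
    return pd.DataFrame(cols, index=persondays.index)


def _day_dummies(persondays: pd.DataFrame) -> pd.DataFrame:
    """Stay-day index as a categorical baseline (reference: day 1)."""
    d = pd.get_dummies(persondays["t"].astype(int), prefix="day", dtype=float)
    return d.drop(columns=d.columns[0])


def _fit_logit(y: np.ndarray, X: pd.DataFrame, label: str):
    if len(np.unique(y)) < 2:
        raise EstimationError(f"{label}: exposure takes a single level")
    # constant columns carry no information and would alias the intercept
    X = X.loc[:, X.nunique() > 1]
    model = sm.GLM(y, sm.add_constant(X, has_constant="add"), family=sm.families.Binomial())
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        res = model.fit(maxiter=200)
    if not res.converged:
        raise EstimationError(f"{label}: IRLS did not converge")
    bad = res.params.index[~np.isfinite(res.params) | (res.params.abs() > 30)]
    if len(bad):
        raise EstimationError(f"{label}: separation suspected for covariate(s) {list(bad)}")
    return model, res


def fit_exposure_models(
    persondays: pd.DataFrame,
    history: str = "both",
    confounders: tuple[str, ...] = ("turnover", "mean_pccl"),
    extra_numerator: pd.DataFrame | None = None,
) -> ExposureModels:
    """Fit the numerator and denominator pooled logistic exposure models.

    The numerator conditions on exposure history, baseline covariates and the
    stay-day index; the denominator adds the time-varying hospital-day
    confounders, so its covariate set strictly contains the numerator's.
    """
    y = persondays["exposed"].to_numpy(float)
    base = baseline_design(persondays)
    hist = _history_design(persondays, history)
    days = _day_dummies(persondays)
    num_X = pd.concat([hist, base, days], axis=1)
    if extra_numerator is not None:
        num_X = pd.concat([num_X, extra_numerator], axis=1)
    den_X = pd.concat([num_X, persondays[list(confounders)].astype(float)], axis=1)
    num_model, num_res = _fit_logit(y, num_X, "numerator")
    den_model, den_res = _fit_logit(y, den_X, "denominator")
    return ExposureModels(
        numerator=num_model,
        denominator=den_model,
        numerator_result=num_res,
        denominator_result=den_res,
        numerator_columns=list(num_X.columns),
        denominator_columns=list(den_X.columns),
        spec={"history": history, "confounders": list(confounders)},
    )


def compute_stabilized_weights(models: ExposureModels, persondays: pd.DataFrame) -> WeightSet:
    """Per-row probability ratios cumulated within patient in stay-day order.

    The contribution of a row with observed exposure :math:`a_t` is
    :math:`P_{num}(a_t)/P_{den}(a_t)`, using :math:`1-P` when :math:`a_t = 0`;
    ``sw`` is the running product over the patient's rows.
    """
    if not models.converged:
        raise EstimationError("exposure models did not converge")
    a = persondays["exposed"].to_numpy(float)
    p1_num = np.asarray(models.numerator_result.predict())
    p1_den = np.asarray(models.denominator_result.predict())
    p_num = np.where(a == 1, p1_num, 1.0 - p1_num)
    p_den = np.where(a == 1, p1_den, 1.0 - p1_den)
    n_extreme = int(((p_den < POSITIVITY_EPS) | (p_den > 1 - POSITIVITY_EPS)).sum())
    if n_extreme:
        warnings.warn(
            f"positivity: {n_extreme} person-day(s) with denominator probability "
            f"outside ({POSITIVITY_EPS}, 1-{POSITIVITY_EPS})",
            RuntimeWarning,
            stacklevel=2,
        )
    table = pd.DataFrame(
        {
            "patient_id": persondays["patient_id"].to_numpy(),
            "t": persondays["t"].to_numpy(),
            "p_num": p_num,
            "p_den": p_den,
            "ratio": p_num / p_den,
        },
        index=persondays.index,
    )
    table["sw"] = table.groupby("patient_id", sort=False)["ratio"].cumprod()
    return WeightSet(table=table)


def stabilized_weights_from_probs(
    persondays: pd.DataFrame, p_num_1: np.ndarray, p_den_1: np.ndarray
) -> WeightSet:
    """Weights from externally supplied P(A_t = 1) arrays (e.g. known truth)."""
    a = persondays["exposed"].to_numpy(float)
    p_num = np.where(a == 1, p_num_1, 1.0 - p_num_1)
    p_den = np.where(a == 1, p_den_1, 1.0 - p_den_1)
    table = pd.DataFrame(
        {
            "patient_id": persondays["patient_id"].to_numpy(),
            "t": persondays["t"].to_numpy(),
            "p_num": p_num,
            "p_den": p_den,
            "ratio": p_num / p_den,
        },
        index=persondays.index,
    )
    table["sw"] = table.groupby("patient_id", sort=False)["ratio"].cumprod()
    return WeightSet(table=table)


def truncate_weights(weights: WeightSet, lower_pct: float = 1.0, upper_pct: float = 99.0) -> WeightSet:
    """Clip stabilized weights at their own sample percentiles (default 1st/99th)."""
    if lower_pct >= upper_pct:
        raise ValueError("lower_pct must be below upper_pct")
    sw = weights.table["sw"].to_numpy(float)
    if sw.size == 0:
        raise ValueError("empty weight set")
    lo, hi = np.percentile(sw, [lower_pct, upper_pct])
    clipped = np.clip(sw, lo, hi)
    table = weights.table.copy()
    table["sw"] = clipped
    return WeightSet(
        table=table,
        truncation=(lower_pct, upper_pct),
        truncation_bounds=(float(lo), float(hi)),
        n_modified=int((clipped != sw).sum()),
    )


def weight_diagnostics(weights: WeightSet, plot_path=None) -> dict:
    """Summaries mirroring the usual reporting of stabilized weights
    (mean, median, IQR, min, max) plus a misspecification flag.

    A mean drifting from 1 by more than 0.05 suggests the exposure models are
    misspecified.  When ``plot_path`` is given, a density plot is written.
    """
    sw = weights.table["sw"].to_numpy(float)
    if sw.size == 0:
        raise ValueError("empty weight set")
    q25, q75 = np.percentile(sw, [25, 75])
    out = {
        "mean": float(np.mean(sw)),
        "median": float(np.median(sw)),
        "iqr": (float(q25), float(q75)),
        "min": float(np.min(sw)),
        "max": float(np.max(sw)),
        "misspecification_warning": bool(abs(np.mean(sw) - 1.0) > 0.05),
    }
    if plot_path is not None:
        import matplotlib
        matplotlib.use("Agg")
        import matplotlib.pyplot as plt
        from scipy import stats

        fig, ax = plt.subplots(figsize=(6, 4))
        grid = np.linspace(max(sw.min(), 1e-6), np.percentile(sw, 99.5), 400)
        kde = stats.gaussian_kde(sw)
        ax.plot(grid, kde(grid))
        ax.axvline(1.0, color="grey", ls="--", lw=0.8)
        ax.set_xlabel("stabilized weight")
        ax.set_ylabel("density")
        ax.set_title("Stabilized IPTW density")
        fig.tight_layout()
        fig.savefig(plot_path, dpi=120)
        plt.close(fig)
        out["plot"] = str(plot_path)
    return out
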