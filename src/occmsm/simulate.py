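"""Synthetic multi-hospital cohort generator with a known causal truth.

The generator emulates one study year of inpatient episodes across a small
set of general hospitals of different types and sizes:

* admissions are Poisson with a weekday/weekend rhythm;
* length of stay is geometric with configurable mean (days present);
* an unmeasured care-pressure process :math:`U_{h,d}` (AR(1), hospital
  level) — demand surges on short-staffed days — boosts admissions and slows
  discharges (both visible only through the day's patient turnover) and
  raises the daily death hazard: the unmeasured common cause of turnover and
  mortality;
* occupancy feedback: a day with utilization above the hospital's running
  high-occupancy quantile throttles next-day admissions and speeds next-day
  discharges by a factor :math:`e^{\\mp\\delta}`, so that past exposure feeds
  the future turnover — the treatment-confounder feedback arrow;
* each patient's daily death hazard over the first 14 stay-days is
  :math:`\\operatorname{expit}(\\alpha_0 + \\beta_A \\cdot cumA_t + \\beta'X_i
  + \\gamma U_{h,d})`, where :math:`cumA_t` counts high-utilization days using
  the same hospital-specific percentile-threshold machinery the analysis
  applies, so the generative exposure and the analysed exposure coincide.

A death closes the episode on the death day (death takes precedence over
discharge).  The module also provides a randomized-exposure oracle that
computes the true marginal per-day effect targeted by the MSM.
"""

from __future__ import annotations

import json
from dataclasses import asdict, dataclass, field, replace

import numpy as np
import pandas as pd
import statsmodels.api as sm
import yaml
from scipy.special import expit

from . import cohort as cohort_mod
from .design import baseline_design

__all__ = [
    "SimConfig",
    "SimTruth",
    "generate_cohort",
    "true_marginal_effect_oracle",
    "default_config",
]


class ConfigError(ValueError):
    pass


class PrecisionError(RuntimeError):
    """Oracle Monte-Carlo error larger than the requested precision."""


# age bands: index b covers ages [5b, 5b+4]; 18 = 90+
DEFAULT_AGE_PROBS = {
    # decade-level mix of a general acute-care population, split evenly
    # across the two 5-year bands of each decade
    0: 0.0663, 1: 0.0663, 2: 0.0371, 3: 0.0371, 4: 0.0543, 5: 0.0543,
    6: 0.0431, 7: 0.0431, 8: 0.0606, 9: 0.0606, 10: 0.0708, 11: 0.0708,
    12: 0.0836, 13: 0.0836, 14: 0.0677, 15: 0.0677, 16: 0.0500, 17: 0.0500,
    18: 0.0330,
}

DEFAULT_COVARIATE_MIX = {
    "female": 0.534,
    "age_probs": DEFAULT_AGE_PROBS,
    "pccl_probs": [0.612, 0.0147, 0.1135, 0.1515, 0.1083],
    # comorbidity-weight classes: <0, =0, >0 to <5, >=5
    "comorbidity_class_probs": [0.171, 0.462, 0.066, 0.301],
}

DEFAULT_BETA_COVARIATES = {
    "female": -0.27,
    "age_band": 0.028,
    "weekend": 0.09,
    "htype": {1: 0.0, 2: 0.0, 3: -0.15, 4: -0.11, 5: 0.23},
    "comorb": {"neg": 0.0, "zero": 1.09, "low_pos": 0.85, "high_pos": 2.06},
}


@dataclass(frozen=True)
class SimConfig:
    """Full parameterisation of the synthetic study year."""

    n_hospitals: int = 5
    hospital_sizes: tuple[float, ...] = (320.0, 220.0, 150.0, 100.0, 60.0)
    hospital_types: tuple[int, ...] = (1, 2, 3, 4, 5)
    year_length: int = 365
    weekday_of_day1: int = 1
    admission_rate_base: float = 13.5
    weekend_admission_factor: float = 0.5
    los_mean: float = 6.2
    covariate_mix: dict = field(default_factory=lambda: dict(DEFAULT_COVARIATE_MIX))
    feedback_strength: float = 0.3           # delta
    staffing_ar_coef: float = 0.7
    staffing_sd: float = 0.4
    staffing_turnover_coef: float = 0.4      # U -> discharge intensity (slows discharges)
    staffing_admission_coef: float = 0.0     # U -> admission intensity (demand surges)
    mortality_intercept: float = -7.5        # alpha0
    beta_cum_exposure: float = float(np.log(1.02))
    beta_covariates: dict = field(default_factory=lambda: dict(DEFAULT_BETA_COVARIATES))
    gamma_staffing: float = 0.5
    exposure_percentile: float = 85.0
    exposure_includes_current_day: bool = True
    seed: int = 0

    def validate(self) -> "SimConfig":
        if self.n_hospitals < 1:
            raise ConfigError("n_hospitals must be >= 1")
        if len(self.hospital_sizes) != self.n_hospitals or len(self.hospital_types) != self.n_hospitals:
            raise ConfigError("hospital_sizes/types must have n_hospitals entries")
        if self.year_length < 28:
            raise ConfigError("year_length must be >= 28 days")
        if not (0 < self.weekend_admission_factor <= 1):
            raise ConfigError("weekend_admission_factor must lie in (0, 1]")
        if self.los_mean <= 0:
            raise ConfigError("los_mean must be positive")
        if not 1 <= self.weekday_of_day1 <= 7:
            raise ConfigError("weekday_of_day1 must be 1..7")
        if not 0 < self.exposure_percentile < 100:
            raise ConfigError("exposure_percentile must lie in (0, 100)")
        mix = self.covariate_mix
        probs = [mix["female"], *mix["pccl_probs"], *mix["comorbidity_class_probs"],
                 *mix["age_probs"].values()]
        arr = np.asarray(probs, float)
        if not np.all(np.isfinite(arr)) or arr.min() < 0 or arr.max() > 1:
            raise ConfigError("covariate_mix probabilities must lie in [0, 1]")
        for name in ("admission_rate_base", "feedback_strength", "staffing_ar_coef",
                     "staffing_sd", "staffing_turnover_coef", "staffing_admission_coef",
                     "mortality_intercept",
                     "beta_cum_exposure", "gamma_staffing"):
            if not np.isfinite(getattr(self, name)):
                raise ConfigError(f"{name} must be finite")
        return self

    @classmethod
    def from_yaml(cls, path) -> "SimConfig":
        with open(path) as fh:
            raw = yaml.safe_load(fh) or {}
        if "hospital_sizes" in raw:
            raw["hospital_sizes"] = tuple(raw["hospital_sizes"])
        if "hospital_types" in raw:
            raw["hospital_types"] = tuple(raw["hospital_types"])
        if "covariate_mix" in raw and "age_probs" in raw["covariate_mix"]:
            raw["covariate_mix"]["age_probs"] = {
                int(k): v for k, v in raw["covariate_mix"]["age_probs"].items()
            }
        if "beta_covariates" in raw and "htype" in raw["beta_covariates"]:
            raw["beta_covariates"]["htype"] = {
                int(k): v for k, v in raw["beta_covariates"]["htype"].items()
            }
        return cls(**raw).validate()

    def to_yaml(self, path) -> None:
        with open(path, "w") as fh:
            yaml.safe_dump(json.loads(json.dumps(asdict(self))), fh, sort_keys=False)


def default_config(**overrides) -> SimConfig:
    return replace(SimConfig(), **overrides).validate()


@dataclass
class SimTruth:
    """Ground truth of a generated cohort, for validation."""

    staffing: pd.DataFrame          # hospital_id, day, u
    thresholds: pd.DataFrame        # hospital-specific exposure thresholds
    hospital_days: pd.DataFrame     # flagged daily series used by the hazard
    beta_cum_exposure: float
    exposure_prevalence_person_day: float
    oracle_marginal_log_or: float | None = None
    oracle_mc_se: float | None = None

    def to_json(self, path) -> None:
        payload = {
            "beta_cum_exposure": self.beta_cum_exposure,
            "exposure_prevalence_person_day": self.exposure_prevalence_person_day,
            "oracle_marginal_log_or": self.oracle_marginal_log_or,
            "oracle_mc_se": self.oracle_mc_se,
            "thresholds": self.thresholds.to_dict(orient="records"),
        }
        with open(path, "w") as fh:
            json.dump(payload, fh, indent=2)


def _draw_covariates(rng: np.random.Generator, n: int, mix: dict) -> pd.DataFrame:
    female = rng.random(n) < mix["female"]
    age_bands = np.fromiter(mix["age_probs"].keys(), dtype=int)
    age_p = np.fromiter(mix["age_probs"].values(), dtype=float)
    age_p = age_p / age_p.sum()
    age = rng.choice(age_bands, size=n, p=age_p)
    pccl_p = np.asarray(mix["pccl_probs"], float)
    pccl = rng.choice(np.arange(5), size=n, p=pccl_p / pccl_p.sum())
    cls_p = np.asarray(mix["comorbidity_class_probs"], float)
    cls = rng.choice(np.arange(4), size=n, p=cls_p / cls_p.sum())
    # a numeric weight consistent with the class bins
    weight = np.empty(n)
    weight[cls == 0] = -rng.uniform(0.1, 3.0, size=int((cls == 0).sum()))
    weight[cls == 1] = 0.0
    weight[cls == 2] = rng.uniform(0.1, 4.9, size=int((cls == 2).sum()))
    weight[cls == 3] = 5.0 + rng.exponential(2.0, size=int((cls == 3).sum()))
    return pd.DataFrame({
        "sex": np.where(female, "f", "m"),
        "age_group": age,
        "pccl": pccl,
        "elixhauser_weight": np.round(weight, 3),
    })


def _simulate_hospital_dynamics(
    cfg: SimConfig, h: int, rng: np.random.Generator
) -> tuple[pd.DataFrame, np.ndarray]:
    """One hospital's year of admissions/stays (no deaths yet) plus its U series.

    The feedback flag for day ``d`` compares the census with the running
    ``exposure_percentile`` quantile of the census history (active once four
    weeks of history exist), mirroring the annual-quantile exposure the
    analysis derives.
    """
    Y = cfg.year_length
    sizes = np.asarray(cfg.hospital_sizes, float)
    rate_h = cfg.admission_rate_base * sizes[h] / sizes.mean()
    p0 = 1.0 / cfg.los_mean
    days = np.arange(1, Y + 1)
    weekday = ((cfg.weekday_of_day1 - 1) + (days - 1)) % 7 + 1
    is_weekend = weekday >= 6

    ar, sd = cfg.staffing_ar_coef, cfg.staffing_sd
    stat_sd = sd / np.sqrt(max(1.0 - ar**2, 1e-12)) if abs(ar) < 1 else sd
    u = np.empty(Y)
    u_prev = rng.normal(0.0, stat_sd)
    for i in range(Y):
        u_prev = ar * u_prev + rng.normal(0.0, sd)
        u[i] = u_prev

    # warm start: begin the year with a steady-state complement of patients
    init_n = rng.poisson(rate_h * cfg.los_mean)
    adm_days: list[int] = [1] * init_n
    dep_days: list[int] = []
    in_house: list[int] = list(range(init_n))  # indices into adm_days
    dep_record: dict[int, int] = {}
    census_hist: list[int] = []
    high_prev = 0
    for i, d in enumerate(days):
        lam = rate_h * (cfg.weekend_admission_factor if is_weekend[i] else 1.0)
        lam *= np.exp(-cfg.feedback_strength * high_prev + cfg.staffing_admission_coef * u[i])
        n_new = rng.poisson(lam)
        for _ in range(n_new):
            adm_days.append(int(d))
            in_house.append(len(adm_days) - 1)
        census = len(in_house)
        census_hist.append(census)
        if i >= 28:
            thr = np.percentile(census_hist, cfg.exposure_percentile)
            high = int(census >= thr)
        else:
            high = 0
        # end-of-day discharge decisions
        p_dis = p0 * np.exp(cfg.feedback_strength * high_prev - cfg.staffing_turnover_coef * u[i])
        p_dis = min(p_dis, 0.95)
        stay = np.array(in_house, dtype=int)
        leave = rng.random(len(stay)) < p_dis
        for idx in stay[leave]:
            dep_record[idx] = int(d)  # last day present; discharge_day = d + 1
        in_house = [idx for idx, lv in zip(in_house, leave) if not lv]
        high_prev = high
    for idx in in_house:
        dep_record[idx] = Y  # censored at year end; present through the last day
    episodes = pd.DataFrame({
        "admission_day": np.asarray(adm_days, int),
        "last_day_present": np.asarray([dep_record[i] for i in range(len(adm_days))], int),
    })
    episodes["discharge_day"] = episodes["last_day_present"] + 1
    return episodes, u


def generate_cohort(config: SimConfig) -> tuple[pd.DataFrame, SimTruth]:
    """Generate one study year of episodes across all hospitals.

    Returns the episode table (one row per stay, deaths already resolved) and
    the :class:`SimTruth` holding the latent staffing series, the exposure
    thresholds/flags that entered the hazard, and the conditional effect used.
    """
    cfg = config.validate()
    root = np.random.SeedSequence(cfg.seed)
    hosp_seeds = root.spawn(cfg.n_hospitals)
    cov_seed, death_seed = root.spawn(2)

    all_eps = []
    u_frames = []
    for h in range(cfg.n_hospitals):
        rng = np.random.default_rng(hosp_seeds[h])
        eps, u = _simulate_hospital_dynamics(cfg, h, rng)
        eps["hospital_id"] = f"H{h + 1:02d}"
        eps["hospital_type"] = cfg.hospital_types[h]
        all_eps.append(eps)
        u_frames.append(pd.DataFrame({
            "hospital_id": f"H{h + 1:02d}",
            "day": np.arange(1, cfg.year_length + 1),
            "u": u,
        }))
    episodes = pd.concat(all_eps, ignore_index=True)
    staffing = pd.concat(u_frames, ignore_index=True)

    cov_rng = np.random.default_rng(cov_seed)
    covs = _draw_covariates(cov_rng, len(episodes), cfg.covariate_mix)
    episodes = pd.concat([episodes.reset_index(drop=True), covs], axis=1)
    episodes["patient_id"] = [f"P{i + 1:07d}" for i in range(len(episodes))]
    episodes["died"] = False
    episodes["death_day"] = np.nan
    episodes = cohort_mod.attach_weekend_admission(episodes, cfg.weekday_of_day1)

    # exposure through the analysis machinery on the pre-death stays
    hospital_days = cohort_mod.build_daily_series(
        episodes, year_length=cfg.year_length, weekday_of_day1=cfg.weekday_of_day1
    )
    thresholds = cohort_mod.derive_threshold(hospital_days, cfg.exposure_percentile)
    flagged = cohort_mod.flag_exposure(hospital_days, thresholds)
    exp_flag = flagged.set_index(["hospital_id", "day"])["exposed"]
    u_series = staffing.set_index(["hospital_id", "day"])["u"]

    # daily death hazard over the first 14 stay-days
    b = cfg.beta_covariates
    base = baseline_design(episodes)
    lin_base = (
        cfg.mortality_intercept
        + b["female"] * base["female"].to_numpy()
        + b["age_band"] * base["age_band"].to_numpy()
        + b["weekend"] * base["weekend"].to_numpy()
    )
    htype_beta = np.array([b["htype"][t] for t in episodes["hospital_type"]])
    from .design import comorbidity_class
    comorb_beta = np.array([b["comorb"][c] for c in comorbidity_class(episodes["elixhauser_weight"])])
    lin_base = lin_base + htype_beta + comorb_beta

    death_rng = np.random.default_rng(death_seed)
    adm = episodes["admission_day"].to_numpy(int)
    dis = episodes["discharge_day"].to_numpy(int)
    hosp = episodes["hospital_id"].to_numpy()
    days_present = np.maximum(dis - adm, 1)
    max_t = np.minimum(days_present, cohort_mod.MAX_FOLLOWUP_DAYS)
    died = np.zeros(len(episodes), bool)
    death_day = np.full(len(episodes), np.nan)
    # vectorised over stay-days: day t cohort = patients with max_t >= t and alive
    alive = np.ones(len(episodes), bool)
    cum_a = np.zeros(len(episodes))
    for t in range(1, cohort_mod.MAX_FOLLOWUP_DAYS + 1):
        at_risk = alive & (max_t >= t)
        if not at_risk.any():
            break
        cal = adm[at_risk] + t - 1
        in_year = cal <= cfg.year_length
        key = pd.MultiIndex.from_arrays([hosp[at_risk], cal])
        a_t = exp_flag.reindex(key).to_numpy(float)
        a_t = np.where(np.isnan(a_t), 0.0, a_t)
        idx = np.flatnonzero(at_risk)
        if cfg.exposure_includes_current_day:
            cum_a[idx] += a_t
            cum_now = cum_a[idx]
        else:
            cum_now = cum_a[idx].copy()
            cum_a[idx] += a_t
        u_t = u_series.reindex(key).to_numpy(float)
        u_t = np.where(np.isnan(u_t), 0.0, u_t)
        haz = expit(lin_base[idx] + cfg.beta_cum_exposure * cum_now + cfg.gamma_staffing * u_t)
        dies = death_rng.random(len(idx)) < haz
        dies &= in_year  # the study year bounds the observable window
        died[idx[dies]] = True
        death_day[idx[dies]] = cal[dies]
        alive[idx[dies]] = False

    episodes.loc[died, "died"] = True
    episodes.loc[died, "death_day"] = death_day[died]
    episodes.loc[died, "discharge_day"] = death_day[died].astype(int)

    # person-day exposure prevalence in the generated world
    pdt = cohort_mod.expand_person_days(episodes, hospital_days, thresholds)
    prevalence = float(pdt["exposed"].mean()) if len(pdt) else float("nan")

    cols = [
        "patient_id", "hospital_id", "hospital_type", "admission_day",
        "discharge_day", "died", "death_day", "sex", "age_group", "pccl",
        "elixhauser_weight", "admission_weekday", "weekend_admission",
    ]
    truth = SimTruth(
        staffing=staffing,
        thresholds=thresholds,
        hospital_days=flagged,
        beta_cum_exposure=cfg.beta_cum_exposure,
        exposure_prevalence_person_day=prevalence,
    )
    return episodes[cols], truth


def true_marginal_effect_oracle(
    config: SimConfig,
    n_rep: int = 200_000,
    seed: int | None = None,
    exposure_prevalence: float | None = None,
    precision: float | None = None,
) -> tuple[float, float]:
    """True marginal per-day effect of cumulative exposure, by randomization.

    Simulates ``n_rep`` patients under the *same outcome mechanism* as the
    observational generator, but with daily exposure drawn independently
    (Bernoulli at the observational person-day prevalence), which severs every
    path into the exposure.  The unweighted pooled logistic of daily death on
    cumulative exposure plus baseline covariates then recovers the marginal
    structural coefficient the MSM targets; its standard error is the
    Monte-Carlo SE.

    When ``exposure_prevalence`` is not supplied, one observational cohort is
    generated from ``config`` to measure it.
    """
    cfg = config.validate()
    if seed is None:
        seed = cfg.seed + 1
    if exposure_prevalence is None:
        _, truth = generate_cohort(cfg)
        exposure_prevalence = truth.exposure_prevalence_person_day
    rng = np.random.default_rng(np.random.SeedSequence(seed))

    covs = _draw_covariates(rng, n_rep, cfg.covariate_mix)
    # hospital type assigned with probability proportional to admission volume
    sizes = np.asarray(cfg.hospital_sizes, float)
    type_p = sizes / sizes.sum()
    htype = rng.choice(np.asarray(cfg.hospital_types), size=n_rep, p=type_p)
    weekend = rng.random(n_rep) < (2 * cfg.weekend_admission_factor) / (5 + 2 * cfg.weekend_admission_factor)
    covs["hospital_type"] = htype
    covs["weekend_admission"] = weekend
    covs["patient_id"] = np.arange(n_rep)

    los = rng.geometric(1.0 / cfg.los_mean, size=n_rep)
    max_t = np.minimum(los, cohort_mod.MAX_FOLLOWUP_DAYS)

    b = cfg.beta_covariates
    base = baseline_design(covs)
    from .design import comorbidity_class
    lin_base = (
        cfg.mortality_intercept
        + b["female"] * base["female"].to_numpy()
        + b["age_band"] * base["age_band"].to_numpy()
        + b["weekend"] * base["weekend"].to_numpy()
        + np.array([b["htype"][t] for t in covs["hospital_type"]])
        + np.array([b["comorb"][c] for c in comorbidity_class(covs["elixhauser_weight"])])
    )

    ar, sd = cfg.staffing_ar_coef, cfg.staffing_sd
    stat_sd = sd / np.sqrt(max(1.0 - ar**2, 1e-12)) if abs(ar) < 1 else sd

    alive = np.ones(n_rep, bool)
    cum_a = np.zeros(n_rep)
    u_t = rng.normal(0.0, stat_sd, size=n_rep)
    rows_y, rows_cum, rows_idx = [], [], []
    for t in range(1, cohort_mod.MAX_FOLLOWUP_DAYS + 1):
        at_risk = alive & (max_t >= t)
        if not at_risk.any():
            break
        idx = np.flatnonzero(at_risk)
        a_t = (rng.random(len(idx)) < exposure_prevalence).astype(float)
        if cfg.exposure_includes_current_day:
            cum_a[idx] += a_t
            cum_now = cum_a[idx]
        else:
            cum_now = cum_a[idx].copy()
            cum_a[idx] += a_t
        u_t = ar * u_t + rng.normal(0.0, sd, size=n_rep)
        haz = expit(lin_base[idx] + cfg.beta_cum_exposure * cum_now + cfg.gamma_staffing * u_t[idx])
        dies = rng.random(len(idx)) < haz
        rows_idx.append(idx)
        rows_cum.append(cum_now.copy())
        rows_y.append(dies.astype(float))
        alive[idx[dies]] = False

    idx_all = np.concatenate(rows_idx)
    pdays = covs.iloc[idx_all].reset_index(drop=True)
    pdays["cum_exposed"] = np.concatenate(rows_cum)
    y = np.concatenate(rows_y)

    X = sm.add_constant(
        pd.concat(
            [pdays[["cum_exposed"]].astype(float), baseline_design(pdays)], axis=1
        ),
        has_constant="add",
    )
    res = sm.GLM(y, X, family=sm.families.Binomial()).fit()
    est = float(res.params["cum_exposed"])
    se = float(res.bse["cum_exposed"])
    floor = 0.002
    target = max(0.1 * abs(cfg.beta_cum_exposure), floor)
    if precision is not None:
        target = precision
    if precision is not None and se > target:
        raise PrecisionError(
            f"oracle Monte-Carlo SE {se:.4g} exceeds requested precision {target:.4g}; "
            f"increase n_rep"
        )
    return est, se
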