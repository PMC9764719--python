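"""From episode records to hospital-day series, exposure thresholds and person-days.

The episode table has one row per hospital stay with integer study-day dates
(day 1 is the first day of the study year).  Derivations:

* daily census under the half-open convention ``[admission, discharge)``,
  with same-day stays counted as present on the admission day;
* capacity utilization ``CU_d = 100 * census_d / peak census`` and patient
  turnover ``PT_d = 100 * (admissions_d + discharges_d) / peak census``,
  both normalised by the hospital's busiest day of the year;
* a hospital-specific exposure threshold at a percentile (default 85) of the
  year's daily utilization, with ties (``CU_d == threshold``) exposed;
* a person-day table following each patient for at most 14 stay-days, with
  daily binary exposure, its running cumulative count, the hospital-day
  confounders (turnover, mean complexity) and the daily death indicator.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd

logger = logging.getLogger(__name__)

MAX_FOLLOWUP_DAYS = 14

EPISODE_COLUMNS = [
    "patient_id", "hospital_id", "hospital_type", "admission_day",
    "discharge_day", "died", "death_day", "sex", "age_group", "pccl",
    "elixhauser_weight",
]


class CohortError(ValueError):
    """Raised for invalid episode tables or degenerate series."""


def validate_episodes(records: pd.DataFrame) -> pd.DataFrame:
    """Validate the episode-table contract; returns the frame unchanged."""
    missing = [c for c in EPISODE_COLUMNS if c not in records.columns]
    if missing:
        raise CohortError(f"episode table missing columns: {missing}")
    if len(records) == 0:
        return records
    bad = records["discharge_day"] < records["admission_day"]
    if bad.any():
        raise CohortError(
            f"discharge before admission for patient_id(s) "
            f"{records.loc[bad, 'patient_id'].tolist()[:5]}"
        )
    died = records["died"].astype(bool)
    dd = records.loc[died, "death_day"]
    ok = (dd >= records.loc[died, "admission_day"]) & (dd <= records.loc[died, "discharge_day"])
    if not ok.all():
        raise CohortError("death_day outside [admission_day, discharge_day]")
    if not records["pccl"].isin([0, 1, 2, 3, 4]).all():
        raise CohortError("pccl outside 0..4")
    return records


def apply_inclusion_filters(records: pd.DataFrame, year_length: int = 365) -> pd.DataFrame:
    """Drop episodes admitted before the study year or in its final two weeks.

    Patients admitted before day 1 cannot be linked to their full exposure
    history; patients admitted after day ``year_length - 14`` cannot accrue
    the full 14-day follow-up window.  Dropped counts are logged per rule.
    """
    validate_episodes(records)
    if len(records) == 0:
        return records.copy()
    before = records["admission_day"] < 1
    late = records["admission_day"] > year_length - MAX_FOLLOWUP_DAYS
    logger.info(
        "inclusion filters: dropped %d admitted before study year, %d in final 14 days (of %d)",
        int(before.sum()), int(late.sum()), len(records),
    )
    return records.loc[~(before | late)].reset_index(drop=True)


def _presence_interval(adm: np.ndarray, dis: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    """First and last day present under [admission, discharge); same-day
    stays count on the admission day."""
    last = np.maximum(dis - 1, adm)
    return adm, last


def build_daily_series(
    records: pd.DataFrame,
    year_length: int = 365,
    weekday_of_day1: int = 1,
    closed_interval: bool = False,
) -> pd.DataFrame:
    """Derive the per-hospital daily series (census, flows, CU, PT, mean PCCL).

    ``closed_interval=True`` switches to counting patients as present on the
    discharge day as well.  Peak census (the hospital's busiest day) is the
    normalising denominator for both utilization and turnover; a hospital
    with zero peak census yields ``CU == 0`` throughout.
    """
    validate_episodes(records)
    hospitals = sorted(records["hospital_id"].unique()) if len(records) else []
    days = np.arange(1, year_length + 1)
    weekday = ((weekday_of_day1 - 1) + (days - 1)) % 7 + 1  # 1=Mon .. 7=Sun
    frames = []
    for hid in hospitals:
        sub = records[records["hospital_id"] == hid]
        adm = sub["admission_day"].to_numpy(int)
        dis = sub["discharge_day"].to_numpy(int)
        first, last = _presence_interval(adm, dis)
        if closed_interval:
            last = dis
        # census via difference array over 1..year_length (clipped)
        delta = np.zeros(year_length + 2, dtype=int)
        f = np.clip(first, 1, year_length + 1)
        l = np.clip(last, 0, year_length)
        valid = f <= l
        np.add.at(delta, f[valid], 1)
        np.add.at(delta, l[valid] + 1, -1)
        census = np.cumsum(delta)[1:year_length + 1]
        admissions = np.bincount(np.clip(adm, 0, year_length + 1), minlength=year_length + 2)[1:year_length + 1]
        discharges = np.bincount(np.clip(dis, 0, year_length + 1), minlength=year_length + 2)[1:year_length + 1]
        # mean PCCL of in-house patients
        pccl_sum = np.zeros(year_length + 2)
        np.add.at(pccl_sum, f[valid], sub["pccl"].to_numpy(float)[valid])
        np.add.at(pccl_sum, l[valid] + 1, -sub["pccl"].to_numpy(float)[valid])
        pccl_cum = np.cumsum(pccl_sum)[1:year_length + 1]
        with np.errstate(invalid="ignore", divide="ignore"):
            mean_pccl = np.where(census > 0, pccl_cum / np.maximum(census, 1), np.nan)
        peak = census.max() if census.size else 0
        denom = peak if peak > 0 else 1
        cu = 100.0 * census / denom
        pt = 100.0 * (admissions + discharges) / denom
        frames.append(pd.DataFrame({
            "hospital_id": hid,
            "day": days,
            "census": census,
            "admissions": admissions,
            "discharges": discharges,
            "capacity_utilization": cu,
            "turnover": pt,
            "mean_pccl": mean_pccl,
            "is_weekend": weekday >= 6,
            "peak_census": peak,
        }))
    if not frames:
        return pd.DataFrame(columns=[
            "hospital_id", "day", "census", "admissions", "discharges",
            "capacity_utilization", "turnover", "mean_pccl", "is_weekend",
            "peak_census",
        ])
    return pd.concat(frames, ignore_index=True)


def derive_threshold(hospital_days: pd.DataFrame, percentile: float = 85.0) -> pd.DataFrame:
    """Hospital-specific exposure threshold: a linear-interpolation sample
    quantile of the year's daily capacity utilization."""
    if len(hospital_days) == 0:
        raise CohortError("empty hospital-day table")
    rows = []
    for hid, sub in hospital_days.groupby("hospital_id"):
        cu = sub["capacity_utilization"].to_numpy(float)
        if cu.size == 0:
            raise CohortError(f"hospital {hid!r} has an empty utilization series")
        rows.append({
            "hospital_id": hid,
            "percentile": percentile,
            "threshold": float(np.percentile(cu, percentile)),
        })
    return pd.DataFrame(rows)


def flag_exposure(hospital_days: pd.DataFrame, thresholds: pd.DataFrame) -> pd.DataFrame:
    """Attach the daily binary exposure flag (CU >= hospital threshold; ties exposed)."""
    out = hospital_days.merge(
        thresholds[["hospital_id", "threshold"]], on="hospital_id", how="left", validate="many_to_one"
    )
    out["exposed"] = (out["capacity_utilization"] >= out["threshold"]).astype(int)
    return out


@dataclass(frozen=True)
class ExposureLag:
    """How the running exposure count treats the current day.

    ``include_current=True`` (default): the count through stay-day ``t``
    includes day ``t`` itself, so the death day's exposure contributes.
    """
    include_current: bool = True


def expand_person_days(
    records: pd.DataFrame,
    hospital_days: pd.DataFrame,
    thresholds: pd.DataFrame,
    max_days: int = MAX_FOLLOWUP_DAYS,
    exposure_lag: ExposureLag = ExposureLag(),
) -> pd.DataFrame:
    """Expand episodes into one row per at-risk stay-day (discrete-time format).

    A patient contributes rows for stay-days ``t = 1..min(days present,
    death day index, max_days)``; the exposure on stay-day ``t`` is the
    hospital's flag on calendar day ``admission_day + t - 1``; the outcome
    indicator is 1 only on the death day's row.
    """
    validate_episodes(records)
    flagged = flag_exposure(hospital_days, thresholds)
    if len(records) == 0:
        return pd.DataFrame(columns=[
            "patient_id", "hospital_id", "t", "day", "exposed", "cum_exposed",
            "turnover", "mean_pccl", "death",
        ])
    year_max = int(flagged["day"].max())
    lookup = flagged.set_index(["hospital_id", "day"])

    adm = records["admission_day"].to_numpy(int)
    dis = records["discharge_day"].to_numpy(int)
    died = records["died"].to_numpy(bool)
    death_day = records["death_day"].to_numpy(float)
    days_present = np.maximum(dis - adm, 1)
    death_stay_day = np.where(died, death_day - adm + 1, np.inf)
    # a death closes the record on the death day itself (discharge_day ==
    # death_day), so the death day is an at-risk day even though the
    # half-open census convention does not count it
    followed = np.where(died, death_stay_day, days_present)
    n_rows = np.minimum(followed, max_days).astype(int)

    idx = np.repeat(np.arange(len(records)), n_rows)
    t = np.concatenate([np.arange(1, k + 1) for k in n_rows]) if len(records) else np.array([], int)
    cal_day = adm[idx] + t - 1
    if cal_day.size and cal_day.max() > year_max:
        raise CohortError("person-day maps outside the hospital-day table; apply inclusion filters first")

    hosp = records["hospital_id"].to_numpy()[idx]
    key = pd.MultiIndex.from_arrays([hosp, cal_day])
    hd = lookup.reindex(key)
    if hd["exposed"].isna().any():
        raise CohortError("missing hospital-day rows for some person-days")

    pd_table = pd.DataFrame({
        "patient_id": records["patient_id"].to_numpy()[idx],
        "hospital_id": hosp,
        "t": t,
        "day": cal_day,
        "exposed": hd["exposed"].to_numpy(int),
        "turnover": hd["turnover"].to_numpy(float),
        "mean_pccl": hd["mean_pccl"].to_numpy(float),
    })
    cum = pd_table.groupby("patient_id", sort=False)["exposed"].cumsum()
    if exposure_lag.include_current:
        pd_table["cum_exposed"] = cum
    else:
        pd_table["cum_exposed"] = cum - pd_table["exposed"]
    is_last = np.concatenate([np.zeros(k - 1, bool).tolist() + [True] for k in n_rows]) if len(records) else np.array([], bool)
    death_on_row = died[idx] & is_last & (t == death_stay_day[idx])
    pd_table["death"] = death_on_row.astype(int)

    # carry baseline covariates for downstream models
    baseline_cols = [
        "patient_id", "hospital_type", "sex", "age_group", "pccl",
        "elixhauser_weight", "admission_day",
    ] + [c for c in ("admission_weekday", "weekend_admission") if c in records.columns]
    baseline = records[baseline_cols].copy()
    pd_table = pd_table.merge(baseline, on="patient_id", how="left", validate="many_to_one")
    return pd_table


def attach_weekend_admission(
    records: pd.DataFrame, weekday_of_day1: int = 1
) -> pd.DataFrame:
    """Add admission weekday (1=Mon..7=Sun) and the weekend-admission dummy."""
    out = records.copy()
    wd = ((weekday_of_day1 - 1) + (out["admission_day"].to_numpy(int) - 1)) % 7 + 1
    out["admission_weekday"] = wd
    out["weekend_admission"] = wd >= 6
    return out


# ---------------------------------------------------------------------------
# CSV interfaces (ISO dates accepted on input; integer study-days internal)

def read_episodes(path, year_start: str | None = None) -> pd.DataFrame:
    """Read an episode CSV.  If the file carries ISO-8601 ``admission_date``
    / ``discharge_date`` / ``death_date`` columns, ``year_start`` (an ISO
    date, day 1 of the study year) converts them to integer study-days."""
    df = pd.read_csv(path)
    if "admission_date" in df.columns:
        if year_start is None:
            raise CohortError("year_start required to convert ISO dates to study days")
        origin = pd.Timestamp(year_start)
        for src, dst in [("admission_date", "admission_day"),
                         ("discharge_date", "discharge_day"),
                         ("death_date", "death_day")]:
            if src in df.columns:
                parsed = pd.to_datetime(df[src], format="%Y-%m-%d", errors="coerce")
                bad = parsed.isna() & df[src].notna()
                if bad.any():
                    raise CohortError(
                        f"unparseable {src} at row(s) {df.index[bad].tolist()[:5]}"
                    )
                df[dst] = (parsed - origin).dt.days + 1
        df = df.drop(columns=[c for c in ("admission_date", "discharge_date", "death_date") if c in df.columns])
    if "death_day" not in df.columns:
        df["death_day"] = np.nan
    return validate_episodes(df)


def write_episodes(records: pd.DataFrame, path) -> None:
    records.to_csv(path, index=False)
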