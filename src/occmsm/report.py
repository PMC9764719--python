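"""Descriptive reporting: cohort characteristics, rates and daily-covariate summaries.

Produces a characteristics table in the usual clinical-research layout
(counts and 14-day death rates overall and by sex, age group, hospital type,
comorbidity class, complexity level and admission weekday), plus per-hospital
distribution summaries of the time-varying covariates with a violin-style
plot of the annual utilization densities.
"""

from __future__ import annotations

from decimal import ROUND_HALF_UP, Decimal

import numpy as np
import pandas as pd

from .cohort import MAX_FOLLOWUP_DAYS
from .design import comorbidity_class

__all__ = ["rate_from_counts", "table_one", "covariate_distribution_summary"]

AGE_DECADES = [
    (0, 3, "0-19 years"), (4, 5, "20-29 years"), (6, 7, "30-39 years"),
    (8, 9, "40-49 years"), (10, 11, "50-59 years"), (12, 13, "60-69 years"),
    (14, 15, "70-79 years"), (16, 17, "80-89 years"), (18, 18, "90+ years"),
]

PCCL_LABELS = {
    0: "No clinical complexity (0)", 1: "Mild clinical complexity (1)",
    2: "Moderate clinical complexity (2)", 3: "Severe clinical complexity (3)",
    4: "Very severe clinical complexity (4)",
}

HOSPITAL_TYPE_NAMES = {
    1: "University (level 1)", 2: "Tertiary care (level 2)",
    3: "Large basic (level 3)", 4: "Medium basic (level 4)",
    5: "Small basic (level 5)",
}

COMORB_LABELS = {"neg": "< 0", "zero": "= 0", "low_pos": "> 0 to < 5", "high_pos": ">= 5"}

WEEKDAY_NAMES = {1: "Mondays", 2: "Tuesdays", 3: "Wednesdays", 4: "Thursdays",
                 5: "Fridays", 6: "Saturdays", 7: "Sundays"}


def rate_from_counts(events: int, total: int) -> float:
    """Percentage ``100*events/total`` rounded half-up to one decimal."""
    if total <= 0:
        raise ZeroDivisionError("total must be positive")
    if not 0 <= events <= total:
        raise ValueError("events must lie in [0, total]")
    pct = Decimal(100 * events) / Decimal(total)
    return float(pct.quantize(Decimal("0.1"), rounding=ROUND_HALF_UP))


def _stratum_rows(records: pd.DataFrame, death14: pd.Series, partition: str,
                  groups: list[tuple[str, pd.Series]]) -> list[dict]:
    rows = []
    for label, mask in groups:
        n = int(mask.sum())
        d = int((mask & death14).sum())
        rows.append({
            "partition": partition,
            "stratum": label,
            "count": n,
            "deaths_14d": d,
            "death_rate_pct": rate_from_counts(d, n) if n > 0 else 0.0,
        })
    return rows


def table_one(records: pd.DataFrame) -> pd.DataFrame:
    """Characteristics table: counts and 14-day death rates per stratum.

    Deaths are counted only when they fall within the first 14 days of the
    stay.  Every partition's strata sum to the overall count.
    """
    if len(records) == 0:
        raise ValueError("empty cohort")
    death14 = records["died"].astype(bool) & (
        (records["death_day"] - records["admission_day"]) < MAX_FOLLOWUP_DAYS
    )
    rows = [{
        "partition": "overall", "stratum": "Total population",
        "count": len(records), "deaths_14d": int(death14.sum()),
        "death_rate_pct": rate_from_counts(int(death14.sum()), len(records)),
    }]
    sex = records["sex"]
    rows += _stratum_rows(records, death14, "sex",
                          [("Male", sex == "m"), ("Female", sex == "f")])
    age = records["age_group"].astype(int)
    rows += _stratum_rows(records, death14, "age_group",
                          [(label, (age >= lo) & (age <= hi)) for lo, hi, label in AGE_DECADES])
    ht = records["hospital_type"].astype(int)
    rows += _stratum_rows(records, death14, "hospital_type",
                          [(name, ht == k) for k, name in HOSPITAL_TYPE_NAMES.items()])
    cc = comorbidity_class(records["elixhauser_weight"]).astype(str)
    rows += _stratum_rows(records, death14, "comorbidity_class",
                          [(lbl, cc == key) for key, lbl in COMORB_LABELS.items()])
    pccl = records["pccl"].astype(int)
    rows += _stratum_rows(records, death14, "pccl",
                          [(lbl, pccl == k) for k, lbl in PCCL_LABELS.items()])
    if "admission_weekday" in records.columns:
        wd = records["admission_weekday"].astype(int)
        rows += _stratum_rows(records, death14, "admission_weekday",
                              [(name, wd == k) for k, name in WEEKDAY_NAMES.items()])
        rows += _stratum_rows(records, death14, "weekend_admission",
                              [("Weekdays", wd <= 5), ("Weekends", wd >= 6)])
    return pd.DataFrame(rows)


def render_table_one_markdown(table: pd.DataFrame) -> str:
    lines = ["| Stratum | Total | 14-day deaths (%) |", "|---|---|---|"]
    for _, r in table.iterrows():
        lines.append(f"| {r['stratum']} | {r['count']:,} | {r['deaths_14d']:,} ({r['death_rate_pct']}) |")
    return "\n".join(lines) + "\n"


def covariate_distribution_summary(
    hospital_days: pd.DataFrame,
    thresholds: pd.DataFrame | None = None,
    plot_path=None,
) -> pd.DataFrame:
    """Per-hospital median, IQR and min-max of the daily time-varying covariates.

    Covers capacity utilization, turnover and mean complexity; optionally
    attaches the hospital's exposure threshold and writes a violin plot of the
    utilization densities with threshold markers.
    """
    if len(hospital_days) == 0:
        raise ValueError("empty hospital-day table")
    rows = []
    for hid, sub in hospital_days.groupby("hospital_id"):
        row = {"hospital_id": hid}
        if "hospital_type" in sub.columns:
            row["hospital_type"] = sub["hospital_type"].iloc[0]
        for var, short in [("capacity_utilization", "cu"), ("turnover", "pt"),
                           ("mean_pccl", "pccl")]:
            vals = sub[var].dropna().to_numpy(float)
            q25, q50, q75 = np.percentile(vals, [25, 50, 75])
            row.update({
                f"{short}_median": q50, f"{short}_q25": q25, f"{short}_q75": q75,
                f"{short}_min": float(vals.min()), f"{short}_max": float(vals.max()),
            })
        rows.append(row)
    out = pd.DataFrame(rows)
    if thresholds is not None:
        out = out.merge(thresholds[["hospital_id", "threshold"]], on="hospital_id", how="left")
    if plot_path is not None:
        import matplotlib
        matplotlib.use("Agg")
        import matplotlib.pyplot as plt

        hospitals = sorted(hospital_days["hospital_id"].unique())
        data = [hospital_days.loc[hospital_days["hospital_id"] == h,
                                  "capacity_utilization"].to_numpy(float)
                for h in hospitals]
        fig, ax = plt.subplots(figsize=(1.2 * len(hospitals) + 2, 4.5))
        ax.violinplot(data, showmedians=True)
        if thresholds is not None:
            tmap = thresholds.set_index("hospital_id")["threshold"]
            for i, h in enumerate(hospitals, start=1):
                if h in tmap.index:
                    ax.hlines(tmap[h], i - 0.3, i + 0.3, color="crimson", lw=1.2)
        ax.set_xticks(range(1, len(hospitals) + 1), hospitals)
        ax.set_ylabel("daily capacity utilization (%)")
        ax.set_title("Annual utilization distribution per hospital (red: exposure threshold)")
        fig.tight_layout()
        fig.savefig(plot_path, dpi=120)
        plt.close(fig)
    return out
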