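#!/usr/bin/env python
"""Derive the analysis tables from the episode records.

Applies the inclusion filters (episodes admitted before the study year or in
its last two weeks are dropped), builds the per-hospital daily series
(census, admissions, discharges, capacity utilization, turnover, mean
complexity), derives each hospital's 85th-percentile exposure threshold, and
expands the cohort into the 14-day person-day table used by all models.
Reads results/cohort/, writes results/derived/.
"""

import json
from pathlib import Path

import pandas as pd

from occmsm import cohort

IN = Path("results/cohort")
OUT = Path("results/derived")


def main() -> None:
    OUT.mkdir(parents=True, exist_ok=True)
    episodes = pd.read_csv(IN / "episodes.csv")
    kept = cohort.apply_inclusion_filters(episodes, year_length=365)
    hospital_days = cohort.build_daily_series(kept, year_length=365)
    thresholds = cohort.derive_threshold(hospital_days, 85)
    persondays = cohort.expand_person_days(kept, hospital_days, thresholds)

    hospital_days.to_csv(OUT / "hospital_days.csv", index=False)
    thresholds.to_csv(OUT / "thresholds.csv", index=False)
    persondays.to_csv(OUT / "persondays.csv", index=False)

    flagged = cohort.flag_exposure(hospital_days, thresholds)
    exposed_share = flagged.groupby("hospital_id")["exposed"].mean()
    summary = {
        "n_episodes_analysed": int(len(kept)),
        "n_person_days": int(len(persondays)),
        "person_day_exposure_prevalence_pct": round(100 * float(persondays["exposed"].mean()), 1),
        "thresholds_pct_of_peak": {r.hospital_id: round(r.threshold, 1)
                                   for r in thresholds.itertuples()},
        "exposed_hospital_day_share": {k: round(v, 3) for k, v in exposed_share.items()},
    }
    with open(OUT / "derivation_summary.json", "w") as fh:
        json.dump(summary, fh, indent=2)
    print("Derived tables written to", OUT)
    print(json.dumps(summary, indent=2))


if __name__ == "__main__":
    main()
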