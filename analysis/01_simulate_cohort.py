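#!/usr/bin/env python
"""Generate the synthetic study year.

Simulates the default five-hospital year (~21,000 inpatient episodes) with
occupancy feedback and the unmeasured care-pressure process, and writes the
episode table plus the generator's ground truth (thresholds, staffing series
metadata, true per-day effect) under results/cohort/.
"""

import json
from pathlib import Path

from occmsm.cohort import apply_inclusion_filters
from occmsm.simulate import generate_cohort, default_config

OUT = Path("results/cohort")


def main() -> None:
    OUT.mkdir(parents=True, exist_ok=True)
    cfg = default_config(seed=1)
    cfg.to_yaml(OUT / "sim_config.yaml")
    episodes, truth = generate_cohort(cfg)
    episodes.to_csv(OUT / "episodes.csv", index=False)
    truth.to_json(OUT / "sim_truth.json")

    kept = apply_inclusion_filters(episodes, cfg.year_length)
    died14 = kept["died"] & ((kept["death_day"] - kept["admission_day"]) < 14)
    summary = {
        "n_episodes": int(len(episodes)),
        "n_after_inclusion_filters": int(len(kept)),
        "mortality_14d_pct": round(100 * float(died14.mean()), 2),
        "female_pct": round(100 * float((kept["sex"] == "f").mean()), 1),
        "weekend_admission_pct": round(100 * float(kept["weekend_admission"].mean()), 1),
        "mean_los_days": round(float(
            (kept["discharge_day"] - kept["admission_day"]).clip(lower=1).mean()), 2),
        "true_per_day_log_or": truth.beta_cum_exposure,
    }
    with open(OUT / "cohort_summary.json", "w") as fh:
        json.dump(summary, fh, indent=2)
    print("Synthetic study year written to", OUT)
    for k, v in summary.items():
        print(f"  {k}: {v}")


if __name__ == "__main__":
    main()
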