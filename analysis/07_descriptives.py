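#!/usr/bin/env python
"""Descriptive tables and plots for the analysed cohort.

Produces the characteristics table (counts and 14-day death rates by sex,
age decade, hospital type, comorbidity class, complexity level and admission
weekday), the per-hospital distribution summary of the daily time-varying
covariates, and the violin plot of annual utilization densities with each
hospital's exposure threshold marked.  Writes results/descriptives/.
"""

from pathlib import Path

import pandas as pd

from occmsm import cohort
from occmsm.report import (
    covariate_distribution_summary, render_table_one_markdown, table_one,
)

OUT = Path("results/descriptives")


def main() -> None:
    OUT.mkdir(parents=True, exist_ok=True)
    episodes = pd.read_csv("results/cohort/episodes.csv")
    kept = cohort.apply_inclusion_filters(episodes, year_length=365)
    t1 = table_one(kept)
    t1.to_csv(OUT / "table_one.csv", index=False)
    (OUT / "table_one.md").write_text(render_table_one_markdown(t1))

    hospital_days = pd.read_csv("results/derived/hospital_days.csv")
    # attach hospital type for the by-type summary
    types = kept.drop_duplicates("hospital_id")[["hospital_id", "hospital_type"]]
    hospital_days = hospital_days.merge(types, on="hospital_id", how="left")
    thresholds = pd.read_csv("results/derived/thresholds.csv")
    summary = covariate_distribution_summary(hospital_days, thresholds,
                                             plot_path=OUT / "cu_violin.png")
    summary.to_csv(OUT / "covariate_summary.csv", index=False)

    overall = t1[t1["partition"] == "overall"].iloc[0]
    print("Descriptives written to", OUT)
    print(f"  cohort {overall['count']:,} episodes, "
          f"{overall['deaths_14d']:,} deaths within 14 days "
          f"({overall['death_rate_pct']}%)")
    print("  per-hospital utilization medians:",
          {r.hospital_id: round(r.cu_median, 1) for r in summary.itertuples()})


if __name__ == "__main__":
    main()
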