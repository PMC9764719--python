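#!/usr/bin/env python
"""Estimate the stabilized inverse-probability-of-treatment weights.

Fits the numerator (exposure history + baseline covariates + stay-day) and
denominator (plus same-day turnover and mean complexity) pooled logistic
models, forms the within-patient cumulative-product stabilized weights, and
writes the weight table, the summary diagnostics (the mean should sit at 1)
and a density plot.  Reads results/derived/, writes results/weights/.
"""

import json
from pathlib import Path

import pandas as pd

from occmsm.weights import (
    compute_stabilized_weights, fit_exposure_models, weight_diagnostics,
)

IN = Path("results/derived")
OUT = Path("results/weights")


def main() -> None:
    OUT.mkdir(parents=True, exist_ok=True)
    persondays = pd.read_csv(IN / "persondays.csv")
    models = fit_exposure_models(persondays)
    weights = compute_stabilized_weights(models, persondays)
    weights.table.to_csv(OUT / "weights.csv", index=False)
    diag = weight_diagnostics(weights, plot_path=OUT / "weight_density.png")
    with open(OUT / "weight_diagnostics.json", "w") as fh:
        json.dump(diag, fh, indent=2)
    print("Stabilized weights written to", OUT)
    print(f"  mean {diag['mean']:.3f}  median {diag['median']:.3f}  "
          f"IQR ({diag['iqr'][0]:.3f}, {diag['iqr'][1]:.3f})  "
          f"min-max {diag['min']:.2f}-{diag['max']:.1f}")
    if diag["misspecification_warning"]:
        print("  WARNING: mean deviates from 1 by more than 0.05 — "
              "check the exposure-model specification")
    else:
        print("  mean within 1 +/- 0.05: no misspecification flag")


if __name__ == "__main__":
    main()
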