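"""Shared covariate coding for exposure and outcome models.

Baseline covariates and their reference levels follow the main-analysis
convention: hospital type dummies with university hospitals (type 1) as the
reference; comorbidity weight binned into four classes with the negative
class as the reference; the 5-year age band treated as numeric; a female
dummy; a weekend-admission dummy.
"""

from __future__ import annotations

import numpy as np
import pandas as pd

HOSPITAL_TYPE_LABELS = {
    1: "university",
    2: "tertiary",
    3: "large_basic",
    4: "medium_basic",
    5: "small_basic",
}

COMORBIDITY_CLASSES = ["neg", "zero", "low_pos", "high_pos"]  # <0 | =0 | >0 to <5 | >=5


def comorbidity_class(weight) -> pd.Series:
    """Bin the numeric comorbidity weight into the four reporting classes."""
    w = np.asarray(weight, dtype=float)
    out = np.where(w < 0, "neg", np.where(w == 0, "zero", np.where(w < 5, "low_pos", "high_pos")))
    return pd.Series(pd.Categorical(out, categories=COMORBIDITY_CLASSES), index=getattr(weight, "index", None))


def baseline_design(table: pd.DataFrame) -> pd.DataFrame:
    """Design columns for the baseline covariate vector V.

    Requires columns ``sex`` ('f'/'m' or 0/1 female flag), ``age_group``,
    ``hospital_type``, ``elixhauser_weight`` and either ``weekend_admission``
    or ``admission_weekday``.
    """
    cols = {}
    sex = table["sex"]
    if sex.dtype == object:
        cols["female"] = (sex == "f").astype(float).to_numpy()
    else:
        cols["female"] = sex.astype(float).to_numpy()
    cols["age_band"] = table["age_group"].astype(float).to_numpy()
    if "weekend_admission" in table.columns:
        cols["weekend"] = table["weekend_admission"].astype(float).to_numpy()
    elif "admission_weekday" in table.columns:
        cols["weekend"] = (table["admission_weekday"] >= 6).astype(float).to_numpy()
    else:
        raise KeyError("need weekend_admission or admission_weekday column")
    out = pd.DataFrame(cols, index=table.index)
    # dummies over levels present in the data; the reference is the lowest
    # present level (university hospitals / negative comorbidity weight when
    # they occur, as in the main-analysis coding)
    ht = pd.Categorical(table["hospital_type"], categories=sorted(HOSPITAL_TYPE_LABELS))
    ht_d = pd.get_dummies(ht, prefix="htype", dtype=float)
    ht_d.index = table.index
    present = [c for c in ht_d.columns if ht_d[c].abs().sum() > 0]
    if len(present) > 1:
        out = pd.concat([out, ht_d[present[1:]]], axis=1)
    cc = comorbidity_class(table["elixhauser_weight"])
    cc_d = pd.get_dummies(cc, prefix="comorb", dtype=float)
    cc_d.index = table.index
    present = [c for c in cc_d.columns if cc_d[c].abs().sum() > 0]
    if len(present) > 1:
        out = pd.concat([out, cc_d[present[1:]]], axis=1)
    return out
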