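import sys
from pathlib import Path

import numpy as np
import pandas as pd
import pytest

sys.path.insert(0, str(Path(__file__).parent))  # for the oracles helper module

from occmsm import cohort as cohort_mod
from occmsm.experiments import derive_analysis_tables, unconfounded_config
from occmsm.simulate import default_config, generate_cohort


def make_episodes(rows) -> pd.DataFrame:
    """Episode frame from (pid, hid, htype, adm, dis, died, death_day) tuples."""
    recs = []
    for pid, hid, htype, adm, dis, died, dday in rows:
        recs.append(dict(
            patient_id=pid, hospital_id=hid, hospital_type=htype,
            admission_day=adm, discharge_day=dis, died=died,
            death_day=float(dday) if died else np.nan,
            sex="f", age_group=8, pccl=1, elixhauser_weight=0.0,
        ))
    return pd.DataFrame(recs)


@pytest.fixture(scope="session")
def small_cohort():
    """A small confounded cohort with its derived tables (3 hospitals, 120 days)."""
    cfg = default_config(
        seed=42, n_hospitals=3, hospital_sizes=(150.0, 100.0, 60.0),
        hospital_types=(2, 3, 5), year_length=120, admission_rate_base=6.0,
    )
    kept, hospital_days, thresholds, persondays = derive_analysis_tables(cfg)
    return dict(config=cfg, records=kept, hospital_days=hospital_days,
                thresholds=thresholds, persondays=persondays)


@pytest.fixture(scope="session")
def unconfounded_cohort():
    """A year-long unconfounded cohort: the hazard model is exactly specified."""
    cfg = unconfounded_config(seed=7, year_length=365, admission_rate_base=6.0)
    kept, hospital_days, thresholds, persondays = derive_analysis_tables(cfg)
    return dict(config=cfg, records=kept, hospital_days=hospital_days,
                thresholds=thresholds, persondays=persondays)


@pytest.fixture(scope="session")
def random_episode_fixtures():
    """Batches of random small episode tables for brute-force cross-checks."""
    rng = np.random.default_rng(2024)
    batches = []
    for _ in range(8):
        n = int(rng.integers(20, 80))
        adm = rng.integers(1, 80, size=n)
        los = rng.geometric(0.25, size=n)
        dis = adm + los
        died = rng.random(n) < 0.15
        death_day = np.where(died, adm + rng.integers(0, np.maximum(los, 1)), np.nan)
        death_day = np.minimum(death_day, dis)
        df = pd.DataFrame(dict(
            patient_id=[f"p{i}" for i in range(n)],
            hospital_id=rng.choice(["A", "B"], size=n),
            hospital_type=rng.choice([1, 3], size=n),
            admission_day=adm, discharge_day=dis,
            died=died, death_day=death_day,
            sex=rng.choice(["f", "m"], size=n),
            age_group=rng.integers(0, 19, size=n),
            pccl=rng.integers(0, 5, size=n),
            elixhauser_weight=rng.normal(1.0, 2.0, size=n).round(2),
        ))
        batches.append(df)
    return batches
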