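import numpy as np
import pandas as pd
import pytest

from glycovar import CgmSeries, CohortConfig

MIDNIGHT = pd.Timestamp("2024-01-01 00:00:00")


def make_series(values, start=MIDNIGHT, interval=5, pid="P0000", trimmed=False):
    return CgmSeries(
        participant_id=pid,
        start=start,
        interval=interval,
        values=np.asarray(values, dtype=float),
        trimmed=trimmed,
    )


def random_series(rng, n_days=3, interval=5, missing=0.0, pid="P0000"):
    """Random physiologic series on a full-day grid, optionally with gaps."""
    n = n_days * 1440 // interval
    vals = np.clip(rng.normal(5.5, 1.0, n), 2.5, 12.0)
    if missing > 0:
        vals[rng.random(n) < missing] = np.nan
    return make_series(vals, interval=interval, pid=pid, trimmed=True)


@pytest.fixture
def rng():
    return np.random.default_rng(20240101)


@pytest.fixture
def quick_cohort_config():
    """Small, fast cohort for pipeline-level tests."""
    return CohortConfig(n_participants=40, seed=11, missing_rate=0.02)
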