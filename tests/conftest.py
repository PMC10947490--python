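import numpy as np
import pytest
from hypothesis import HealthCheck, settings

from actiprofile import EpochSeries

settings.register_profile(
    "ci",
    derandomize=True,
    deadline=None,
    suppress_health_check=[HealthCheck.too_slow],
)
settings.load_profile("ci")

MONDAY = "2021-05-03 00:00:00"


def build_series(counts, hr=None, met=None, start=MONDAY, subject_id="S1"):
    """EpochSeries from a counts vector; HR defaults to physiological
    (120 bpm) and METs to resting (1.0)."""
    counts = np.asarray(counts, dtype=int)
    n = len(counts)
    if hr is None:
        hr = np.full(n, 120.0)
    if met is None:
        met = np.ones(n)
    return EpochSeries.from_counts(subject_id, start, counts, hr, met)


@pytest.fixture
def full_week_series():
    """Seven full days of constant light activity, Monday through Sunday."""
    return build_series(np.full(7 * 1440, 70))
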