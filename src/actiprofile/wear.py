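"""Wear filtering and diurnal balancing of epoch records.

Non-wear is detected as a maximal run of zero-acceleration epochs with a
non-physiological heart-rate reading lasting strictly more than 90 minutes.
A record is considered valid for analysis when it provides at least 48 h of
wear overall, 32 h on weekdays, 16 h on the weekend, and 12 h in each of
four day segments (morning, noon, afternoon, evening).  Because remaining
non-wear is rarely uniform over the day, summary metrics are computed with
per-epoch weights that give every hour of the day equal total weight.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .epochs import EpochSeries

#: Heart-rate readings outside this open interval (or missing) are
#: non-physiological.  The bounds are configurable in :func:`detect_nonwear`.
HR_MIN_BPM = 30.0
HR_MAX_BPM = 240.0

#: Minimum duration (minutes, strict) of a zero-acceleration + invalid-HR
#: run for it to count as non-wear.
NONWEAR_MIN_MINUTES = 90

#: Day-segment boundaries for the validity check, as half-open hour
#: intervals [start, end).  The segment names are fixed by convention; the
#: clock bounds are a package default and can be overridden.
DEFAULT_SEGMENTS = {
    "morning": (6, 12),
    "noon": (12, 15),
    "afternoon": (15, 19),
    "evening": (19, 24),
}

#: Wear-hour thresholds: total, weekday, weekend, and per day segment.
VALIDITY_THRESHOLDS = {
    "total": 48.0,
    "weekday": 32.0,
    "weekend": 16.0,
    "segment": 12.0,
}


@dataclass
class WearMask:
    """Per-epoch wear flags plus the detected non-wear intervals."""

    wear: np.ndarray  # boolean, True = worn
    nonwear_intervals: list  # list of (start_timestamp, end_timestamp)

    def __post_init__(self):
        self.wear = np.asarray(self.wear, dtype=bool)

    @property
    def n_wear(self) -> int:
        return int(self.wear.sum())

    @property
    def wear_hours(self) -> float:
        return self.n_wear / 60.0


@dataclass
class ValidityReport:
    """Wear-time accounting against the validity thresholds."""

    total_hours: float
    weekday_hours: float
    weekend_hours: float
    segment_hours: dict
    valid: bool
    failed_rules: list = field(default_factory=list)

    def to_dict(self):
        return {
            "total_hours": self.total_hours,
            "weekday_hours": self.weekday_hours,
            "weekend_hours": self.weekend_hours,
            "segment_hours": dict(self.segment_hours),
            "valid": self.valid,
            "failed_rules": list(self.failed_rules),
        }


@dataclass
class DiurnalWeights:
    """Per-epoch weights that equalize the influence of each time-of-day slot.

    Weight of a wear epoch in slot ``s`` is ``1 / (n_slots * n_wear_in_s)``;
    non-wear epochs carry zero weight.  Weights sum to one, so a weighted
    mean over epochs weights each slot of the day equally.
    """

    weights: np.ndarray
    slot_of_epoch: np.ndarray
    slot_wear_counts: dict

    def __post_init__(self):
        self.weights = np.asarray(self.weights, dtype=float)


def _is_nonphysiological(hr, hr_min=HR_MIN_BPM, hr_max=HR_MAX_BPM):
    hr = np.asarray(hr, dtype=float)
    return np.isnan(hr) | (hr < hr_min) | (hr > hr_max)


def _runs(flag):
    """Start/end (exclusive) index pairs of maximal True runs."""
    flag = np.asarray(flag, dtype=bool)
    if not flag.any():
        return []
    padded = np.concatenate(([False], flag, [False])).astype(int)
    edges = np.diff(padded)
    starts = np.flatnonzero(edges == 1)
    ends = np.flatnonzero(edges == -1)
    return list(zip(starts, ends))


def detect_nonwear(
    series: EpochSeries,
    min_minutes: int = NONWEAR_MIN_MINUTES,
    hr_min: float = HR_MIN_BPM,
    hr_max: float = HR_MAX_BPM,
) -> WearMask:
    """Flag non-wear intervals in a calibrated epoch series.

    An interval is non-wear iff every epoch in it has zero acceleration AND
    a non-physiological heart rate, and its duration strictly exceeds
    ``min_minutes``.  Maximal such runs are reported.  The decision for an
    epoch depends only on the run containing it, so prepending or appending
    wear epochs never changes existing flags.
    """
    candidate = (series.acceleration == 0) & _is_nonphysiological(
        series.heart_rate, hr_min, hr_max
    )
    wear = np.ones(len(series), dtype=bool)
    intervals = []
    ts = series.timestamps
    for start, end in _runs(candidate):
        if end - start > min_minutes:  # 60-s epochs: count == minutes
            wear[start:end] = False
            intervals.append((ts.iloc[start], ts.iloc[end - 1] + pd.Timedelta(seconds=60)))
    return WearMask(wear=wear, nonwear_intervals=intervals)


def assess_validity(
    series: EpochSeries,
    mask: WearMask,
    segments: dict = None,
    thresholds: dict = None,
) -> ValidityReport:
    """Evaluate the wear-time validity rules, each independently.

    The record is valid iff total wear >= 48 h, weekday wear >= 32 h,
    weekend wear >= 16 h and each of the four day segments has >= 12 h of
    wear.  Hours outside the segment map (midnight to 06:00 by default)
    count toward the totals but no segment.
    """
    segments = DEFAULT_SEGMENTS if segments is None else segments
    thr = dict(VALIDITY_THRESHOLDS)
    if thresholds:
        thr.update(thresholds)

    wear = mask.wear
    ts = series.timestamps
    hours = ts.dt.hour.to_numpy()
    weekend = ts.dt.dayofweek.to_numpy() >= 5  # Sat=5, Sun=6

    total_h = wear.sum() / 60.0
    weekend_h = (wear & weekend).sum() / 60.0
    weekday_h = (wear & ~weekend).sum() / 60.0

    segment_h = {}
    for name, (lo, hi) in segments.items():
        in_seg = (hours >= lo) & (hours < hi)
        segment_h[name] = float((wear & in_seg).sum() / 60.0)

    failed = []
    if total_h < thr["total"]:
        failed.append(f"total≥{thr['total']:g}h")
    if weekday_h < thr["weekday"]:
        failed.append(f"weekday≥{thr['weekday']:g}h")
    if weekend_h < thr["weekend"]:
        failed.append(f"weekend≥{thr['weekend']:g}h")
    for name in segments:
        if segment_h[name] < thr["segment"]:
            failed.append(f"{name}≥{thr['segment']:g}h")

    return ValidityReport(
        total_hours=float(total_h),
        weekday_hours=float(weekday_h),
        weekend_hours=float(weekend_h),
        segment_hours=segment_h,
        valid=not failed,
        failed_rules=failed,
    )


def diurnal_weights(
    series: EpochSeries, mask: WearMask, slot_edges=None
) -> DiurnalWeights:
    """Equal-weight-per-time-of-day-slot reweighting of wear epochs.

    Parameters
    ----------
    slot_edges : sequence of int, optional
        Hour-of-day boundaries defining the slots; default
        ``0, 1, ..., 24`` (24 hourly slots).  A custom coarser map, e.g.
        ``[0, 12, 24]``, yields two half-day slots.

    Raises
    ------
    ValueError
        If any slot contains no wear epoch ("cannot balance: empty slot").
        This cannot occur for a series passing :func:`assess_validity`
        with the default hourly slots, since every hour of a >=48 h valid
        record spanning full days is visited.
    """
    if slot_edges is None:
        slot_edges = np.arange(25)
    slot_edges = np.asarray(slot_edges)
    n_slots = len(slot_edges) - 1
    hours = series.hour_of_day
    slot = np.searchsorted(slot_edges, hours, side="right") - 1

    weights = np.zeros(len(series), dtype=float)
    slot_counts = {}
    for s in range(n_slots):
        in_slot = (slot == s) & mask.wear
        n = int(in_slot.sum())
        slot_counts[s] = n
        if n == 0:
            raise ValueError(f"cannot balance: empty slot {s}")
        weights[in_slot] = 1.0 / (n_slots * n)

    return DiurnalWeights(weights=weights, slot_of_epoch=slot, slot_wear_counts=slot_counts)
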