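"""Epoch-level activity records.

A combined heart-rate/movement sensor summarises its signal in fixed
60-second epochs.  Each epoch carries an integer activity count, the
acceleration implied by that count (counts x 0.003 m/s^2), a heart-rate
reading and a MET estimate.  :class:`EpochSeries` wraps one subject's
contiguous record and is the unit every downstream stage operates on.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

#: Conversion factor from device counts per 60-s epoch to m/s^2.
COUNTS_TO_MS2 = 0.003

#: Epoch length in seconds.
EPOCH_SECONDS = 60

EPOCH_COLUMNS = ["timestamp", "counts", "acceleration", "heart_rate", "met_estimate"]


def counts_to_acceleration(counts):
    """Convert integer activity counts to acceleration in m/s^2.

    Parameters
    ----------
    counts : array-like of int
        Non-negative activity counts per 60-s epoch.

    Returns
    -------
    numpy.ndarray
        ``counts * 0.003`` in m/s^2.
    """
    counts = np.asarray(counts)
    if np.any(counts < 0):
        raise ValueError("activity counts must be non-negative")
    return counts * COUNTS_TO_MS2


@dataclass
class EpochSeries:
    """One subject's 60-s epoch record.

    Attributes
    ----------
    subject_id : str
    data : pandas.DataFrame
        Columns ``timestamp`` (tz-naive local clock), ``counts`` (int),
        ``acceleration`` (m/s^2, exactly counts x 0.003), ``heart_rate``
        (bpm, NaN if missing) and ``met_estimate`` (METs).
    """

    subject_id: str
    data: pd.DataFrame = field(repr=False)

    def __post_init__(self):
        df = self.data
        missing = [c for c in EPOCH_COLUMNS if c not in df.columns]
        if missing:
            raise ValueError(f"epoch data missing columns: {missing}")
        if len(df) == 0:
            raise ValueError("epoch series must contain at least one epoch")
        ts = pd.to_datetime(df["timestamp"])
        deltas = ts.diff().dropna()
        if len(deltas) and not (deltas == pd.Timedelta(seconds=EPOCH_SECONDS)).all():
            raise ValueError("timestamps must be strictly increasing at 60-s spacing")
        acc = df["acceleration"].to_numpy(dtype=float)
        expected = df["counts"].to_numpy() * COUNTS_TO_MS2
        if not np.allclose(acc, expected, rtol=0, atol=1e-12):
            raise ValueError("acceleration must equal counts x 0.003 exactly")
        if np.any(acc < 0):
            raise ValueError("acceleration must be non-negative")
        self.data = df.reset_index(drop=True)
        self.data["timestamp"] = ts.reset_index(drop=True)

    @classmethod
    def from_counts(cls, subject_id, start, counts, heart_rate, met_estimate):
        """Build a series from raw channels, deriving acceleration from counts."""
        counts = np.asarray(counts, dtype=int)
        n = len(counts)
        timestamps = pd.date_range(start=start, periods=n, freq=f"{EPOCH_SECONDS}s")
        df = pd.DataFrame(
            {
                "timestamp": timestamps,
                "counts": counts,
                "acceleration": counts_to_acceleration(counts),
                "heart_rate": np.asarray(heart_rate, dtype=float),
                "met_estimate": np.asarray(met_estimate, dtype=float),
            }
        )
        return cls(subject_id=subject_id, data=df)

    def __len__(self):
        return len(self.data)

    @property
    def timestamps(self) -> pd.Series:
        return self.data["timestamp"]

    @property
    def acceleration(self) -> np.ndarray:
        return self.data["acceleration"].to_numpy(dtype=float)

    @property
    def heart_rate(self) -> np.ndarray:
        return self.data["heart_rate"].to_numpy(dtype=float)

    @property
    def met_estimate(self) -> np.ndarray:
        return self.data["met_estimate"].to_numpy(dtype=float)

    @property
    def hour_of_day(self) -> np.ndarray:
        return self.data["timestamp"].dt.hour.to_numpy()

    def to_csv(self, path):
        """Write the epoch CSV dialect (header, UTF-8, missing HR empty)."""
        out = self.data.copy()
        out.insert(0, "subject_id", self.subject_id)
        out["timestamp"] = out["timestamp"].dt.strftime("%Y-%m-%dT%H:%M:%S")
        out = out.rename(columns={"heart_rate": "heart_rate_bpm"})
        out[
            ["subject_id", "timestamp", "counts", "heart_rate_bpm", "met_estimate"]
        ].to_csv(path, index=False, encoding="utf-8")

    @classmethod
    def read_csv(cls, path):
        """Read a per-subject epoch CSV written by :meth:`to_csv`."""
        df = pd.read_csv(path, encoding="utf-8")
        sid = str(df["subject_id"].iloc[0])
        return cls.from_counts(
            subject_id=sid,
            start=pd.to_datetime(df["timestamp"].iloc[0]),
            counts=df["counts"].to_numpy(),
            heart_rate=df["heart_rate_bpm"].to_numpy(dtype=float),
            met_estimate=df["met_estimate"].to_numpy(dtype=float),
        )
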