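"""Per-subject movement-profile metrics.

Four summaries describe a subject's physical-activity profile:

* **average-acceleration** — diurnally weighted mean acceleration over
  wear time, a proxy for total activity volume;
* **intensity-gradient** — the slope of a natural log-log regression of
  fraction-of-wear-time on intensity across 25 incremental acceleration
  bands, describing how steeply time drops off with intensity (more
  negative = less of the day spent at high intensity);
* **MX metrics** — the acceleration above which the most active X minutes
  were accumulated (upper order statistics of the epoch intensities);
* **MVPA** — minutes/day spent at >= 4 METs.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import statsmodels.api as sm

from .epochs import EpochSeries
from .wear import DiurnalWeights, WearMask

#: Default band edges: 24 bands of 0.25 m/s^2 from 0 to 6.0 plus an open
#: top band, 25 bands in total, spanning the observed MX range in children.
DEFAULT_BAND_EDGES = np.concatenate([np.arange(0, 6.25, 0.25), [np.inf]])

#: The X values (minutes) reported for MX metrics; M1/3 is M480.
DEFAULT_MX_MINUTES = (2, 5, 10, 15, 30, 60, 120, 240, 480)

MVPA_MET_THRESHOLD = 4.0


@dataclass
class IntensityDistribution:
    """Fraction of (diurnally weighted) wear time per acceleration band."""

    band_edges: np.ndarray
    fractions: np.ndarray

    def __post_init__(self):
        self.band_edges = np.asarray(self.band_edges, dtype=float)
        self.fractions = np.asarray(self.fractions, dtype=float)
        if len(self.fractions) != len(self.band_edges) - 1:
            raise ValueError("need one fraction per band")
        if np.any(self.fractions < 0):
            raise ValueError("band fractions must be non-negative")
        if abs(self.fractions.sum() - 1.0) > 1e-9:
            raise ValueError("band fractions must sum to 1")

    @property
    def midpoints(self) -> np.ndarray:
        """Band midpoints; the open top band uses top edge + half the
        width of the last finite band (a finite abscissa is required and
        the tail fraction there is tiny)."""
        edges = self.band_edges
        mids = (edges[:-1] + edges[1:]) / 2.0
        if np.isinf(edges[-1]):
            width = edges[-2] - edges[-3]
            mids[-1] = edges[-2] + width / 2.0
        return mids


@dataclass
class IntensityGradientFit:
    """OLS fit of ln(fraction) on ln(band midpoint)."""

    gradient: float  # slope b1
    intercept: float  # b0
    ci_low: float
    ci_high: float
    r_squared: float
    n_bands: int


@dataclass
class ProfileMetrics:
    """One subject's movement-profile summary."""

    subject_id: str
    average_acceleration: float
    ig: IntensityGradientFit
    mx: dict
    mvpa_min_day: float
    wear_hours: float

    def to_row(self) -> dict:
        row = {
            "subject_id": self.subject_id,
            "average_acceleration": self.average_acceleration,
            "ig_b1": self.ig.gradient,
            "ig_b0": self.ig.intercept,
            "ig_ci_lo": self.ig.ci_low,
            "ig_ci_hi": self.ig.ci_high,
            "ig_r2": self.ig.r_squared,
            "ig_n_bands": self.ig.n_bands,
        }
        for x, v in sorted(self.mx.items()):
            row[f"m{x}"] = v
        row["mvpa_min_day"] = self.mvpa_min_day
        row["wear_h"] = self.wear_hours
        return row


def intensity_distribution(
    series: EpochSeries,
    mask: WearMask,
    weights: DiurnalWeights,
    band_edges=None,
) -> IntensityDistribution:
    """Diurnally weighted fraction of wear time per acceleration band.

    Bands are left-open/right-closed, except the first which is closed at
    zero so resting epochs are counted.
    """
    edges = DEFAULT_BAND_EDGES if band_edges is None else np.asarray(band_edges, float)
    if mask.n_wear == 0:
        raise ValueError("no wear epochs")
    acc = series.acceleration[mask.wear]
    w = weights.weights[mask.wear]
    # (a, b] binning with the first band including 0
    idx = np.searchsorted(edges, acc, side="left") - 1
    idx[acc == edges[0]] = 0
    fractions = np.bincount(idx, weights=w, minlength=len(edges) - 1)
    fractions = fractions / fractions.sum()
    return IntensityDistribution(band_edges=edges, fractions=fractions)


def fit_intensity_gradient(dist: IntensityDistribution, alpha: float = 0.05) -> IntensityGradientFit:
    """Fit the intensity-gradient by OLS on the ln-ln band data.

    Zero-fraction bands are excluded (ln 0 undefined); at least three
    positive bands are required.  The slope's two-sided CI comes from the
    t distribution with n-2 degrees of freedom.
    """
    keep = dist.fractions > 0
    n = int(keep.sum())
    if n < 3:
        raise ValueError("unfittable distribution: fewer than 3 non-empty bands")
    x = np.log(dist.midpoints[keep])
    y = np.log(dist.fractions[keep])
    model = sm.OLS(y, sm.add_constant(x)).fit()
    ci = model.conf_int(alpha=alpha)
    return IntensityGradientFit(
        gradient=float(model.params[1]),
        intercept=float(model.params[0]),
        ci_low=float(ci[1, 0]),
        ci_high=float(ci[1, 1]),
        r_squared=float(model.rsquared),
        n_bands=n,
    )


def average_acceleration(
    series: EpochSeries, mask: WearMask, weights: DiurnalWeights
) -> float:
    """Diurnally weighted mean wear-epoch acceleration (m/s^2)."""
    if mask.n_wear == 0:
        raise ValueError("no wear epochs")
    w = weights.weights[mask.wear]
    acc = series.acceleration[mask.wear]
    return float(np.sum(w * acc) / np.sum(w))


def mx_metrics(series: EpochSeries, mask: WearMask, minutes=DEFAULT_MX_MINUTES) -> dict:
    """MX metrics: acceleration above which the most active X min accumulate.

    With 60-s epochs, M_X is the X-th largest wear-epoch acceleration.
    Epochs are pooled over all wear days, unweighted.
    """
    acc = np.sort(series.acceleration[mask.wear])[::-1]
    out = {}
    for x in minutes:
        if x > len(acc):
            raise ValueError(f"insufficient wear epochs ({len(acc)}) for M{x}")
        out[int(x)] = float(acc[x - 1])
    return out


def mvpa_minutes(
    series: EpochSeries,
    mask: WearMask,
    weights: DiurnalWeights,
    met_threshold: float = MVPA_MET_THRESHOLD,
) -> float:
    """Moderate-to-vigorous activity in min/day.

    The diurnally weighted fraction of wear epochs at or above the MET
    threshold, scaled to a 1440-min day.
    """
    mets = series.met_estimate[mask.wear]
    if np.all(np.isnan(mets)):
        raise ValueError("missing MET channel")
    w = weights.weights[mask.wear]
    frac = float(np.sum(w * (mets >= met_threshold)) / np.sum(w))
    return frac * 1440.0


def standardize_mx(profile: dict, sex_means: dict) -> dict:
    """Divide each M_X by the corresponding sex-specific mean M_X."""
    out = {}
    for x, v in profile.items():
        mean = sex_means[x]
        if mean == 0:
            raise ValueError(f"zero sex-specific mean for M{x}")
        out[x] = v / mean
    return out


def compute_profile(
    series: EpochSeries,
    mask: WearMask,
    weights: DiurnalWeights,
    band_edges=None,
    mx_mins=DEFAULT_MX_MINUTES,
) -> ProfileMetrics:
    """Convenience: all profile metrics for one wear-filtered subject."""
    dist = intensity_distribution(series, mask, weights, band_edges)
    return ProfileMetrics(
        subject_id=series.subject_id,
        average_acceleration=average_acceleration(series, mask, weights),
        ig=fit_intensity_gradient(dist),
        mx=mx_metrics(series, mask, mx_mins),
        mvpa_min_day=mvpa_minutes(series, mask, weights),
        wear_hours=mask.wear_hours,
    )
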