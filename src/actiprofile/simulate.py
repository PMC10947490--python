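"""Synthetic epoch records and cohorts with known ground truth.

No suitable raw cohort is openly available, so every downstream stage is
exercised against generated data whose true parameters are stored.  The
per-epoch intensity process is a two-component mixture:

* with probability ``1 - p_active(h)`` a sedentary draw, uniform on a
  narrow floor interval near zero;
* with probability ``p_active(h)`` an active draw: one of the finite
  non-floor acceleration bands is selected with probability proportional
  to ``midpoint ** tail_exponent`` and the value is uniform within the
  band.

``p_active(h)`` follows a smooth 24-h rhythm peaking mid-afternoon.  The
diurnal rhythm modulates the *probability* of an active draw, not the
magnitude, so the marginal time-in-band fractions remain exactly
proportional to ``midpoint ** tail_exponent`` above the floor band —
:func:`expected_band_fractions` returns that closed form and serves as an
analytic oracle for the whole chain.  Outcomes (bone mineral content,
lean and fat mass) are produced by a linear model on the subject's true
centred activity metrics plus Gaussian noise, so regression stages can be
tested for exact and statistical parameter recovery.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field, asdict

import numpy as np
import pandas as pd

from .epochs import COUNTS_TO_MS2, EpochSeries
from .metrics import DEFAULT_BAND_EDGES

#: Sedentary component: uniform on [0, SEDENTARY_MAX] m/s^2 (within the
#: floor band of the default 0.25-wide banding).
SEDENTARY_MAX = 0.10
SEDENTARY_MEAN = SEDENTARY_MAX / 2.0

#: Hour of peak activity and relative amplitude of the diurnal rhythm.
DIURNAL_PEAK_HOUR = 14.0
DEFAULT_DIURNAL_AMPLITUDE = 0.9

#: METs = 1 + MET_SLOPE * acceleration; 4 METs at 1.5 m/s^2 (brisk-walk
#: scale), placing the moderate-intensity threshold where it belongs.
MET_SLOPE = 2.0

EPOCHS_PER_DAY = 1440
_ANCHOR_MONDAY = pd.Timestamp("2021-05-03")  # arbitrary fixed Monday


@dataclass
class SubjectParams:
    """Ground-truth parameters of one simulated subject.

    ``base_level`` is the mean of the subject's acceleration process
    (m/s^2) and plays the role of true activity volume;
    ``tail_exponent`` (< 0) is the power-law exponent of the intensity
    distribution's tail and plays the role of true intensity gradient.
    ``nonwear_blocks`` are (day_index, start_hour, duration_min) triples;
    each is inserted once.
    """

    subject_id: str
    sex: str
    age: float
    stature: float
    pubertal: int
    base_level: float
    tail_exponent: float
    wear_days: int
    nonwear_blocks: list = field(default_factory=list)
    diurnal_amplitude: float = DEFAULT_DIURNAL_AMPLITUDE

    def __post_init__(self):
        if self.sex not in ("female", "male"):
            raise ValueError("sex must be 'female' or 'male'")
        if self.base_level <= 0:
            raise ValueError("base_level must be positive")
        if self.tail_exponent >= 0:
            raise ValueError("tail_exponent must be negative")
        if self.wear_days < 4:
            raise ValueError("wear_days must be at least 4")
        self._validate_blocks()

    def _validate_blocks(self):
        spans = []
        for day, start_hour, dur in self.nonwear_blocks:
            a = day * EPOCHS_PER_DAY + int(round(start_hour * 60))
            b = a + int(dur)
            if dur <= 0:
                raise ValueError("non-positive non-wear duration")
            if a < 0 or b > self.wear_days * EPOCHS_PER_DAY:
                raise ValueError("non-wear block outside the wear record")
            spans.append((a, b))
        spans.sort()
        for (a1, b1), (a2, b2) in zip(spans, spans[1:]):
            if a2 < b1:
                raise ValueError("overlapping nonwear_blocks")

    @property
    def wear_hours(self) -> float:
        lost = sum(dur for _, _, dur in self.nonwear_blocks)
        return self.wear_days * 24.0 - lost / 60.0


@dataclass
class OutcomeCoefficients:
    """True generating coefficients for one outcome (units: kg)."""

    name: str
    intercept: float
    volume: float  # per m/s^2 of centred average-acceleration
    intensity: float  # per unit of centred intensity-gradient
    interaction: float  # per product of centred exposures
    age: float  # per year
    stature: float  # per cm
    pubertal: float  # per status step
    wear_time: float  # per hour
    noise_sd: float

    def __post_init__(self):
        if self.noise_sd < 0:
            raise ValueError("noise SD must be non-negative")


def default_outcome_coefficients():
    """Plausible generating models for a 9-11-y cohort (kg-scale outcomes)."""
    return [
        OutcomeCoefficients("tblh_bmc_kg", -0.60, 0.60, -0.15, 0.20,
                            0.040, 0.0080, 0.05, 0.0004, 0.10),
        OutcomeCoefficients("lean_kg", -8.0, 6.0, -0.80, 1.0,
                            0.80, 0.150, 0.80, 0.0020, 1.80),
        OutcomeCoefficients("fat_kg", -9.0, -8.0, -1.50, 2.0,
                            0.50, 0.100, 0.50, 0.0020, 3.00),
    ]


def _diurnal_shape(hours, amplitude):
    """24-h multiplier with exact mean 1 over the hourly grid."""
    return 1.0 + amplitude * np.cos(2 * np.pi * (np.asarray(hours) - DIURNAL_PEAK_HOUR) / 24.0)


def _tail_band_probs(tail_exponent, band_edges):
    """Selection probabilities over the finite non-floor bands."""
    edges = np.asarray(band_edges, dtype=float)
    finite = edges[np.isfinite(edges)]
    lefts, rights = finite[1:-1], finite[2:]
    mids = (lefts + rights) / 2.0
    w = mids ** tail_exponent
    return lefts, rights, mids, w / w.sum()


def _activity_probability(params, band_edges=DEFAULT_BAND_EDGES):
    """Mean per-epoch probability of an active (tail) draw implied by
    base_level, before diurnal modulation."""
    _, _, mids, q = _tail_band_probs(params.tail_exponent, band_edges)
    mu_tail = float(np.dot(q, mids))
    p = (params.base_level - SEDENTARY_MEAN) / (mu_tail - SEDENTARY_MEAN)
    if not 0.0 <= p <= 1.0:
        raise ValueError(
            f"base_level {params.base_level} incompatible with "
            f"tail_exponent {params.tail_exponent} (implied activity "
            f"probability {p:.3f} outside [0, 1])"
        )
    return p


def _hourly_activity_probs(params, band_edges=DEFAULT_BAND_EDGES):
    p = _activity_probability(params, band_edges)
    shape = _diurnal_shape(np.arange(24), params.diurnal_amplitude)
    return np.clip(p * shape, 0.0, 1.0)


def _start_timestamp(wear_days):
    """Start so the record ends on a Sunday: any 4-9-day span then
    contains one full weekend."""
    start_weekday = (5 - (wear_days - 2)) % 7
    return _ANCHOR_MONDAY + pd.Timedelta(days=start_weekday)


def generate_subject_series(params: SubjectParams, seed: int) -> EpochSeries:
    """Simulate one subject's contiguous 60-s epoch record.

    Deterministic in ``(params, seed)``.  Counts are the quantized
    acceleration (acc / 0.003, rounded); heart rate is physiological
    during wear and zero inside inserted non-wear blocks, whose epochs
    also carry zero counts and a resting MET value.
    """
    rng = np.random.default_rng(seed)
    n = params.wear_days * EPOCHS_PER_DAY
    hours = (np.arange(n) // 60) % 24

    p_h = _hourly_activity_probs(params)[hours]
    active = rng.random(n) < p_h

    acc = rng.uniform(0.0, SEDENTARY_MAX, size=n)
    n_active = int(active.sum())
    if n_active:
        lefts, rights, _, q = _tail_band_probs(params.tail_exponent, DEFAULT_BAND_EDGES)
        band = rng.choice(len(q), size=n_active, p=q)
        acc[active] = lefts[band] + rng.random(n_active) * (rights[band] - lefts[band])

    heart_rate = np.clip(rng.normal(120.0, 15.0, size=n), 40.0, 220.0)
    counts = np.rint(acc / COUNTS_TO_MS2).astype(int)
    mets = 1.0 + MET_SLOPE * counts * COUNTS_TO_MS2

    for day, start_hour, dur in params.nonwear_blocks:
        a = day * EPOCHS_PER_DAY + int(round(start_hour * 60))
        b = a + int(dur)
        counts[a:b] = 0
        heart_rate[a:b] = 0.0
        mets[a:b] = 1.0

    return EpochSeries.from_counts(
        subject_id=params.subject_id,
        start=_start_timestamp(params.wear_days),
        counts=counts,
        heart_rate=heart_rate,
        met_estimate=mets,
    )


def expected_band_fractions(params: SubjectParams, band_edges=None):
    """Closed-form marginal time-in-band fractions of the generator.

    The marginal density is piecewise uniform (sedentary floor component
    plus per-band uniform tail components), so the expected fraction in
    any band of any requested edge set is exact.  Fractions sum to 1.
    Returns an :class:`~actiprofile.metrics.IntensityDistribution`.
    """
    from .metrics import IntensityDistribution

    edges = DEFAULT_BAND_EDGES if band_edges is None else np.asarray(band_edges, float)
    if edges[0] != 0 or not np.isinf(edges[-1]):
        raise ValueError("bands must cover [0, inf)")

    p_bar = float(_hourly_activity_probs(params).mean())
    lefts, rights, _, q = _tail_band_probs(params.tail_exponent, DEFAULT_BAND_EDGES)

    # piecewise-uniform components: (lo, hi, mass)
    pieces = [(0.0, SEDENTARY_MAX, 1.0 - p_bar)]
    pieces += [(l, r, p_bar * qi) for l, r, qi in zip(lefts, rights, q)]

    fractions = np.zeros(len(edges) - 1)
    for lo, hi, mass in pieces:
        if mass == 0:
            continue
        overlap_lo = np.maximum(edges[:-1], lo)
        overlap_hi = np.minimum(edges[1:], hi)
        overlap = np.clip(overlap_hi - overlap_lo, 0.0, None)
        fractions += mass * overlap / (hi - lo)
    fractions /= fractions.sum()
    return IntensityDistribution(band_edges=edges, fractions=fractions)


def true_mvpa_minutes(params: SubjectParams) -> float:
    """Expected MVPA min/day of the generating process (METs >= 4)."""
    acc_threshold = (4.0 - 1.0) / MET_SLOPE
    p_bar = float(_hourly_activity_probs(params).mean())
    lefts, rights, _, q = _tail_band_probs(params.tail_exponent, DEFAULT_BAND_EDGES)
    above = np.clip(rights - np.maximum(lefts, acc_threshold), 0.0, None) / (rights - lefts)
    return float(p_bar * np.dot(q, above) * 1440.0)


@dataclass
class Cohort:
    """Simulated subjects, their true metrics and linked outcomes.

    ``table`` has one row per subject with covariates, true activity
    metrics (``true_volume``, ``true_intensity``, ``true_mvpa``) and the
    generated outcomes.  Epoch series are produced lazily through
    :meth:`series` from stored per-subject seeds.
    """

    subjects: list
    table: pd.DataFrame
    series_seeds: dict
    coefficients: list

    def series(self, subject_id: str) -> EpochSeries:
        params = next(s for s in self.subjects if s.subject_id == subject_id)
        return generate_subject_series(params, self.series_seeds[subject_id])

    def to_manifest(self) -> dict:
        return {
            "series_seeds": {k: int(v) for k, v in self.series_seeds.items()},
            "subjects": [asdict(s) for s in self.subjects],
            "outcome_coefficients": [asdict(c) for c in self.coefficients],
        }

    def write(self, directory):
        """Write the covariate/outcome CSV and a manifest JSON."""
        import pathlib

        d = pathlib.Path(directory)
        d.mkdir(parents=True, exist_ok=True)
        self.table.to_csv(d / "cohort.csv", index=False)
        with open(d / "manifest.json", "w") as fh:
            json.dump(self.to_manifest(), fh, indent=1)


# sex-specific sampling ranges for covariates and activity parameters,
# matching a 9-11-y mixed-sex cohort
_COHORT_DEFAULTS = {
    "female": {"base_mean": 0.19, "base_sd": 0.058, "tail_mean": -1.69,
               "tail_sd": 0.14, "pubertal_p": 0.35},
    "male": {"base_mean": 0.22, "base_sd": 0.070, "tail_mean": -1.65,
             "tail_sd": 0.18, "pubertal_p": 0.13},
}
_BASE_LEVEL_RANGE = (0.09, 0.50)
_TAIL_RANGE = (-2.6, -0.8)


def _truncated_normal(rng, mean, sd, lo, hi, size):
    out = rng.normal(mean, sd, size=size)
    bad = (out < lo) | (out > hi)
    while bad.any():
        out[bad] = rng.normal(mean, sd, size=int(bad.sum()))
        bad = (out < lo) | (out > hi)
    return out


def generate_cohort(
    n_female: int,
    n_male: int,
    coeffs=None,
    seed: int = 0,
    nonwear_rate: float = 0.5,
) -> Cohort:
    """Simulate a mixed-sex cohort with outcomes tied to true metrics.

    Outcomes are built from the *true* activity metrics, centred on the
    realized sex-stratum means, so a regression on the true metrics with
    sample centring recovers the generating coefficients exactly when
    ``noise_sd`` is zero.  ``nonwear_rate`` is the expected number of
    ~2-4 h non-wear blocks per subject.
    """
    if n_female < 0 or n_male < 0:
        raise ValueError("counts must be non-negative")
    if coeffs is None:
        coeffs = default_outcome_coefficients()
    rng = np.random.default_rng(seed)

    subjects, rows, series_seeds = [], [], {}
    for sex, n in (("female", n_female), ("male", n_male)):
        if n == 0:
            continue
        cfg = _COHORT_DEFAULTS[sex]
        base = _truncated_normal(rng, cfg["base_mean"], cfg["base_sd"], *_BASE_LEVEL_RANGE, n)
        tail = _truncated_normal(rng, cfg["tail_mean"], cfg["tail_sd"], *_TAIL_RANGE, n)
        age = rng.uniform(9.0, 11.2, size=n)
        stature = rng.normal(141.0, 6.5, size=n)
        pubertal = (rng.random(n) < cfg["pubertal_p"]).astype(int)
        wear_days = rng.integers(4, 10, size=n)

        for i in range(n):
            sid = f"{sex[0].upper()}{i:04d}"
            n_blocks = rng.poisson(nonwear_rate)
            days = rng.permutation(wear_days[i])[: min(n_blocks, wear_days[i])]
            blocks = [
                (int(day), float(rng.uniform(8, 17)), int(rng.integers(120, 241)))
                for day in days
            ]
            params = SubjectParams(
                subject_id=sid, sex=sex, age=float(age[i]),
                stature=float(stature[i]), pubertal=int(pubertal[i]),
                base_level=float(base[i]), tail_exponent=float(tail[i]),
                wear_days=int(wear_days[i]), nonwear_blocks=blocks,
            )
            subjects.append(params)
            series_seeds[sid] = int(rng.integers(0, 2**31 - 1))
            rows.append(
                {
                    "subject_id": sid, "sex": sex, "age": params.age,
                    "stature": params.stature, "pubertal": params.pubertal,
                    "wear_time_h": params.wear_hours,
                    "true_volume": params.base_level,
                    "true_intensity": params.tail_exponent,
                    "true_mvpa": true_mvpa_minutes(params),
                }
            )

    table = pd.DataFrame(rows)
    for sex in table["sex"].unique():
        sel = table["sex"] == sex
        vc = table.loc[sel, "true_volume"] - table.loc[sel, "true_volume"].mean()
        ic = table.loc[sel, "true_intensity"] - table.loc[sel, "true_intensity"].mean()
        for c in coeffs:
            linpred = (
                c.intercept
                + c.volume * vc
                + c.intensity * ic
                + c.interaction * vc * ic
                + c.age * table.loc[sel, "age"]
                + c.stature * table.loc[sel, "stature"]
                + c.pubertal * table.loc[sel, "pubertal"]
                + c.wear_time * table.loc[sel, "wear_time_h"]
            )
            noise = rng.normal(0.0, c.noise_sd, size=int(sel.sum())) if c.noise_sd else 0.0
            table.loc[sel, c.name] = linpred + noise

    return Cohort(subjects=subjects, table=table, series_seeds=series_seeds,
                  coefficients=list(coeffs))
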