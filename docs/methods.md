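# Methods

`actiprofile` implements an epoch-level accelerometry pipeline for
pediatric cohorts: wear filtering, diurnally balanced movement-profile
metrics, a sex-stratified regression sequence against body-composition
outcomes, and a translational time-reallocation calculator.  This note
records the model choices, defaults, and their rationale.

## Epoch model and calibration

The unit of analysis is the 60-s epoch of a combined heart-rate/movement
sensor.  Integer activity counts are converted to acceleration by the
fixed device calibration 1 count = 0.003 m/s²; the package treats this
as exact and validates that the acceleration channel is the converted
counts channel.  A MET-estimate channel is taken as given (energy-
expenditure modelling from combined sensing is outside the package's
scope); only the ≥ 4 MET threshold is used, defining moderate-to-
vigorous physical activity (MVPA).

## Non-wear and validity

An interval is non-wear iff every epoch has zero acceleration **and** a
non-physiological heart-rate reading, and the interval lasts strictly
more than 90 min.  "Non-physiological" is HR < 30 bpm, HR > 240 bpm, or
missing; the bounds are configurable because no standard definition
exists.  The strict inequality matters at the boundary: a 90-min block
is sedentary wear, a 91-min block is non-wear.  Detection operates on
maximal runs, so flags are local: padding a record with wear epochs
never changes existing decisions.

A record is valid when it has ≥ 48 h of wear in total, ≥ 32 h on
weekdays (Mon–Fri by local date), ≥ 16 h on the weekend, and ≥ 12 h in
each of four day segments.  The segment boundaries are a package
default — morning 06:00–12:00, noon 12:00–15:00, afternoon 15:00–19:00,
evening 19:00–24:00 — and configurable, since the segment names do not
pin down clock bounds.  Night hours (00:00–06:00) count toward the
totals but no segment.  Note the total rule can never fail alone: four
passing segments already imply ≥ 48 h.

## Diurnal balancing

Residual non-wear is rarely uniform over the day, which biases plain
means toward over-represented hours.  The package reweights wear epochs
so that each of 24 hour-of-day slots carries equal total weight
(weight `1/(24 · n_wear_epochs_in_slot)` per epoch).  Any weighted mean
then weights every hour of the day equally.  The slot map is
configurable (e.g. two half-day slots).  A slot with no wear epochs is
an error; it cannot occur for records passing the validity rules with
the default hourly map.

## Profile metrics

* **Average-acceleration** — the diurnally weighted mean of wear-epoch
  accelerations; a volume proxy.
* **Intensity distribution and gradient** — wear time is summarized as
  the weighted fraction of time in 25 contiguous acceleration bands:
  24 bands of 0.25 m/s² width from 0 to 6.0 plus an open top band.
  The edges are configurable; the defaults span the MX range observed
  in children (~0.08–5 m/s²).  The intensity-gradient is the OLS slope
  of ln(fraction) on ln(band midpoint).  Numerical choices: bands are
  left-open/right-closed with the first band closed at zero;
  zero-fraction bands are excluded from the fit (ln 0 undefined) and
  the band count used is reported; the open top band needs a finite
  abscissa and uses the midpoint of a phantom band of the same width
  as the finite bands (6.125 m/s² by default) — results are insensitive
  because the tail fraction there is tiny; fewer than three positive
  bands is reported as unfittable.  The slope's 95% CI comes from the
  t distribution with n−2 df; R² and the intercept are recorded.
  Renormalizing the fractions only shifts the intercept, never the
  slope.
* **MX metrics** — the acceleration above which the most active X
  minutes accumulate, for X ∈ {2, 5, 10, 15, 30, 60, 120, 240, 480};
  with 60-s epochs this is the X-th largest wear-epoch acceleration.
  Epochs are pooled across all wear days and unweighted (an upper order
  statistic is not a mean, so slot reweighting does not apply cleanly);
  a per-day-average variant would be a straightforward alternative and
  the pooling choice is documented here precisely because either is
  defensible.  M1/3 (most active third of the day) is M480.
* **MVPA** — the diurnally weighted fraction of wear epochs at ≥ 4 METs
  (inclusive threshold), scaled to 1440 min.

## Regression sequence

Associations are estimated separately in females and males by an
incremental OLS sequence.  Activity exposures are mean-centred within
the sex stratum; the interaction term is the product of centred scores
(centring leaves slopes invariant — only the intercept moves — but
makes the interaction model's main effects interpretable at the
stratum means).  Model 1 enters one activity metric at a time with age,
stature, pubertal status (0/1) and wear time; Model 2 adds the
alternate metric; Model 3 the interaction.  For bone outcomes Models
4, 5, 6 add lean mass, fat mass, and both, each building on Model 3 —
so Models 4 and 5 are siblings, not nested in each other.  For lean
mass the final model adjusts for fat mass (labelled Model 5); for fat
mass, for lean mass (Model 4).  With MVPA as exposure the same
sequence runs with a single activity term and no alternate-metric or
interaction steps, keeping the same model labels (1, then 4/5/6).
Unstandardised coefficients, t-based 95% CIs and two-sided p-values are
reported; α = 0.05 with no multiplicity correction; complete-case
analysis within each stratum; rank-deficient designs raise an error
naming the collinear terms.

For descriptive profiles, each sex stratum is split at its means into
four volume × intensity groups (≥ mean is "high"), and group MX means
and standard errors are tabulated raw and standardized by the
sex-specific mean (radar-plot-ready output).

## Time-reallocation translation

Minutes/day of a named activity with acceleration anchor `a` that raise
average-acceleration by one SD, assuming the activity replaces time at
the current average level:

    minutes = 1440 × SD / (a − mean average-acceleration)

Anchors for children: high-intensity play (running, jumping, skipping)
4 m/s², brisk walking (5.2 km/h) ≈ 1.5 m/s², slow walking (3.2 km/h)
≈ 0.75 m/s².  An anchor at or below the mean is rejected (the activity
would not raise volume).  Presentation rounding: nearest minute below
120 min, otherwise hours to the nearest half hour — matching how such
equivalences are conventionally quoted.  Minutes are strictly
decreasing in the anchor and scale linearly in the SD.

## Synthetic cohort generator

No raw cohort travels with the package, so a generator with known
ground truth stands in.  Per subject it emulates a 4–9-day record of
60-s epochs, scheduled so the record always contains one full weekend.

The per-epoch intensity process is a two-component mixture: a sedentary
draw, uniform on [0, 0.1] m/s²; or an active draw in which one of the
finite non-floor bands (0.25–6.0 m/s²) is selected with probability
proportional to `midpoint^tail_exponent` and the value is uniform
within the band.  The subject's `base_level` (mean acceleration, the
true volume) fixes the mean probability of an active draw;
`tail_exponent` (< 0, the true intensity parameter) fixes the tail
shape.  A smooth 24-h rhythm peaking at 14:00 (relative amplitude 0.9
by default, exact mean 1 over the hourly grid) modulates the
*probability* of an active draw rather than the magnitude.  This is
deliberate: magnitude modulation would destroy the closed-form marginal
— with probability modulation the expected time-in-band fractions
remain exactly proportional to `midpoint^tail_exponent` above the floor
band, so `expected_band_fractions` is an analytic oracle for the whole
processing chain (empirical weighted fractions converge to it; total
variation < 0.02 at 60 simulated days).  Counts are the quantized
acceleration; METs are `1 + 2 × acceleration`, placing 4 METs at
1.5 m/s² (brisk-walk scale); heart rate is physiological
(Normal(120, 15), clipped) during wear.  Requested non-wear blocks are
inserted once each as zero counts with zero heart rate, so the
detector's recovery can be checked against the construction.

Cohort-level defaults mirror a 9–11-year mixed-sex sample: female/male
`base_level` centred at 0.19/0.22 m/s² (SD 0.058/0.070),
`tail_exponent` at −1.69/−1.65 (SD 0.14/0.18), age uniform on 9–11.2 y,
stature Normal(141, 6.5) cm, pubertal prevalence 35%/13%, and on
average half a non-wear block of 2–4 h per subject.  Outcomes (bone
mineral content, lean and fat mass, kg) come from a linear model on the
subject's **true** centred metrics plus covariates and Gaussian noise,
centred on the realized stratum means — so a noise-free fit of the
interaction model on the true metrics recovers the generating
coefficients to numerical precision, and noisy fits can be checked for
nominal CI coverage and type-I error (Monte Carlo: 200 replicates of
500 subjects per sex).

What the generator does **not** emulate: bouts and autocorrelation
(epochs are conditionally independent given the hour), weekday/weekend
differences (one rhythm for all days), sensor noise and drift, growth,
or the physiology linking heart rate to movement.  Passing tests
therefore demonstrate correctness of the *pipeline arithmetic and
statistical calibration* under a clean data-generating process, not
robustness to the messiness of real recordings.

A consequence of the mixture design worth stating plainly: the fitted
25-band gradient is not a function of `tail_exponent` alone — the floor
band carries the sedentary share, so the slope also moves with
`base_level`, just as the gradient of real profiles partly tracks
volume.  Metric-recovery experiments therefore vary one generating
parameter at a time (n = 200 subjects at 7 wear days each), where the
recovered metric correlates with its parameter above 0.95; varying both
jointly measures that confounding rather than recovery fidelity.

## Problem sizes and determinism

Simulation-based checks use 7-day records (10 080 epochs) for recovery
experiments, one 60-day record for distributional convergence, and
200-replicate Monte Carlo runs at 500 subjects per sex for coverage and
type-I calibration — sizes at which the binomial error of a coverage
proportion is ~1.5 percentage points.  All randomness flows through
seeded `numpy` generators; identical seeds reproduce cohorts and series
bit for bit.

## Known limitations

* The diurnal balancing method (equal weight per hour-of-day slot) is
  one reasonable choice among several; it is isolated behind
  `diurnal_weights` and swappable.
* Band edges for the intensity distribution are a package default, not
  a standard; gradients are comparable only across identical bandings.
* MX pooling across days (vs per-day averaging) is a documented choice;
  values differ slightly between the two conventions.
* The MET channel is taken at face value; errors in upstream energy-
  expenditure modelling propagate directly into MVPA.
* The translational calculator assumes the added activity replaces time
  at exactly the mean acceleration and that anchors are accurate for
  the population at hand.
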