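# Methods

## Problem and estimand

The package estimates the *point mean* bodyweight of a companion-animal
population on a target date (31 December of a reporting year) from clinical
records collected on arbitrary earlier dates.  Each animal contributes one
value: its latest recorded weight in the year, projected forward through the
juvenile growth model if the animal was still growing when weighed.  The
point mean is the arithmetic mean of these per-animal estimates with a normal
approximation 95% CI (`mean ± 1.96·sd/√n`; adequate at the intended sample
sizes, and the method is recorded in the report).  Two comparison statistics
are always reported: the period mean of the raw latest weights, and the
adults-only period mean (animals strictly over 24 months at their last
measurement).

Units: weights in kg, ages and intervals in months, with 1 month = 30.4375
days everywhere (the mean Gregorian month; the source records carry only
dates, so some day–month convention is unavoidable and this one is exact on
average).

## Record cleaning

Records pass four filters, in order: invoice linkage (uninvoiced weights may
be owner-reported guesses), presence of a date of birth (animal-level:
without it no age is computable), species plausibility ranges for weight and
age (closed intervals at day precision; packaged in a versioned YAML), and a
growth-jump rule: for consecutive measurements `w₁`, `w₂` of one animal
`I` months apart, the later record is dropped when the monthly-equivalent
ratio `(w₂/w₁)^(1/max(I,1))` exceeds 10 (dogs, cats) or 3 (rabbits, guinea
pigs).  The `max(I, 1)` floor applies the factor directly to sub-month gaps
rather than extrapolating them.  Jump comparisons always use the previous
*retained* record, so an isolated unit-error spike does not shadow later
valid records.  Plausibility and jump violations drop the offending record
only; an animal disappears only when it has no date of birth or no valid
record left — dropping a whole animal for one typo would discard good data.
Every removal is logged with its rule, and `retained + logged = input` is an
invariant under test.

Same-day duplicate measurements keep the last-entered record (entry order is
the only signal available).

## Growth pairs

For each animal, consecutive retained measurements yield observations
`(A, I, g)`: age at the earlier measurement (months), interval (months), and
proportional gain `g = (w₂ − w₁)/w₁`.  A proportional outcome makes animals
of very different absolute size comparable.  The earlier-age convention
matches the deployment direction: forecasts run forward from a recorded
weight.

## Stage 1 — growth cessation

The end of juvenile growth is the earliest age, on a 0.05-month grid, at
which the predicted interval change in bodyweight reaches zero.  "Zero" is an
increment at or below 1e-4 kg per 0.05-month step: exact zeros never occur in
floating-point smoother output, and the threshold is far below measurement
noise.

The curve being smoothed is the *within-animal monthly weight change*
(kg/month) against age, not the raw weight-vs-age trend.  Between-animal size
variation (log-sd ≈ 0.84 for dogs) dwarfs the late-juvenile growth signal in
the raw trend at realistic desk-scale sample sizes, whereas differencing
within animals removes it entirely.  Each consecutive pair with interval
≤ 2 months contributes `(w₂ − w₁)/I` at the age of the earlier measurement,
with precision weight `I²` (under multiplicative measurement error the noise
of a difference quotient scales as `1/I`); longer intervals are excluded
because they smear the growth rate across the plateau onset, and start-age
attribution keeps the expected curve exactly zero beyond it.

Pairs are aggregated to 0.05-month age bins (precision-weighted means), and a
tricube local-linear smoother is fitted to the bin means with weights equal
to each bin's effective (Kish) pair count.  The fit runs on the pair-count
CDF scale, so nearest-neighbour windows carry constant pair mass: narrow
bandwidths in the densely sampled juvenile region, wide ones on the sparse
plateau.  The smoothing span is selected by minimising the bias-corrected
AICc for nonparametric smoothers (Hurvich–Simonoff–Tsai form; GCV available
by flag) over [0.05, 0.95], via a coarse scan plus golden-section refinement;
the smoother's trace is accumulated exactly from per-point leverages, never
as an n×n matrix.  Local regression is implemented in `vetweight.loess`
(vectorised numpy; degree 1 default, degree 2 available) and is cross-checked
against `statsmodels`' lowess in the test suite.

The raw weight-vs-age mode of `detect_cessation` (first grid age where the
smoothed weight curve's per-step increment hits the tolerance) is retained
and unit-tested; it is the right tool when a single smooth series is already
in hand.  Note that any smoother rounds a sharp plateau onset over roughly
half a window width, so kink locations detected from noiseless piecewise
curves trail the true kink by up to that much.

## Stage 2 — juvenile growth model

Proportional gain is modelled as a cubic polynomial in age and interval with
an age×interval interaction and a random intercept per animal.  Fitting uses
an exact profiled solver written for this one structure: for a single random
intercept, GLS reduces to partial group demeaning with
`θ_g = 1 − 1/√(1 + λ n_g)`, and the (restricted) likelihood is a smooth 1-d
function of λ = σ²_u/σ²_e, maximised by bounded scalar optimisation.  This is
exact ML/REML (verified against `statsmodels` `MixedLM` and a dense
multivariate-normal likelihood to 1e-8 in the tests) and runs in milliseconds
at 10⁵ pairs, which the calibration loop's repeated refits require.
Predictors are internally scaled by 12 to keep the cubic design
well-conditioned; coefficients are reported on the months scale.

Backward selection drops, at each step, the term whose removal most reduces
the ML AIC (`−2·llf + 2k`, counting fixed effects and both variance
components), never removing a term while a higher-order or interaction
partner remains (marginality), and stops when no removal reduces AIC.  ML is
used during selection for AIC comparability across fixed-effect sets; the
final term set is refit by REML.  Note the statistical behaviour of
AIC selection: a truly null term survives a step with probability
P(χ²₁ > 2) ≈ 0.16, so on pure-noise data occasional small spurious terms are
expected (and have negligible predicted effects); the tests assert exactly
that behaviour.

New-animal prediction uses fixed effects only: the variance partition
coefficient `σ²_u/(σ²_u + σ²_e)` is negligible on well-specified synthetic
data (its estimate sits on the zero boundary in most samples), so per-animal
effects carry no useful information for unseen animals.

The model's solved cessation is the smallest positive age at which the
fixed-effect polynomial at a one-month interval crosses zero, found by a
0.001-month grid scan for the first sign change plus bisection to 1e-4
months — numeric root finding is reproducible where symbolic services are
not.

### Development-window calibration

The solved cessation rises as older animals enter the development data, so
the maximum admitted age `M` is calibrated: a binary search over integer `M`
(default bounds `[⌈loess target⌉ + 1, 72]` months) refits the model on pairs
with `A ≤ M` and picks the `M` whose solved cessation is closest to the loess
estimate (ties to the smaller `M`).  The fixed-effect term mask is frozen to
the backward-selection result at the upper bound so the solved-cessation
sequence is comparable across probes; a detected non-monotone probe sequence
(common in small cohorts, where the premise is noisy) triggers an exhaustive
scan with a warning.  An `M` whose polynomial never crosses zero counts as
"solved above target".

### Validation

Calibration-in-the-large is `mean(observed) − mean(predicted)` gain;
calibration slope is the OLS coefficient of observed on predicted gain (with
intercept), with decile plot data emitted for visual checks.  Bootstrap
optimism resamples *animals* with replacement (each draw gets a fresh group
identity), refits with the frozen term set, and averages apparent-minus-
original performance; desk defaults are 500 repetitions at 1% of animals,
both configurable.  Note that optimism estimates are only meaningful when the
resample is large enough to support the polynomial (at 1% of a few thousand
animals they are dominated by refit noise; the tests therefore exercise the
optimism property at larger resample fractions).

## Stage 3–4 — adjustment and reporting

An animal is juvenile when its age at the last measurement is below the
species juvenile bound (14 months dogs, 13 otherwise — the growth model's
validity range).  For juveniles the adjustment interval runs from the last
measurement to the target date or to `dob + cessation age`, whichever is
earlier (clamped at zero), and the estimate is `w·(1 + g(A, I))` in one shot:
the interval predictor was trained on variable-length gaps, so no monthly
compounding is applied.  Negative predicted gains are retained (weight loss
is possible); estimates are floored at 0.01 kg with a warning.  Adults enter
unadjusted.

Annual inclusion follows the "measured in the specified year" rule; an
`in_year_only=False` flag exposes the alternative cumulative
("any record on or before 31 December") reading.  Group consistency uses
Kruskal–Wallis tests of the estimated weights across practices and across
veterinary groups; the degenerate all-identical-values case (where the rank
statistic is undefined) is reported as H = 0, p = 1.

`dddvet_per_animal` converts a drug mass to average treatment-days per
animal: `total_mg / (dddvet_mg_per_kg_day × mean_weight_kg × n_animals)`.

## Synthetic EHR generator

The generator defines the study conditions for every test:

- **Adult weights**: log-normal per species, location = log median, tuned to
  reported primary-care medians and IQRs (dog 12.0 (7.1–22.1) kg, cat 3.9
  (3.0–4.8), rabbit 2.0 (1.5–2.5), guinea pig 1.0 (0.8–1.1)); the dog's large
  log-scale spread mimics breed diversity.  The law is truncated (rejection
  sampling) at the species plausibility maxima: an untruncated tail would
  plant animals that the cleaning stage removes but the truth oracle keeps,
  a generator/filter inconsistency rather than a feature of real data.
- **Growth curve**: `w(a) = W·exp(−c/2·(T − a)²)` for `a < T`, constant `W`
  after — monotone, exactly flat beyond the cessation age `T`, and C¹-smooth
  at the onset.  Its log-growth rate declines linearly to zero, matching the
  near-linear decline of monthly proportional gain that fitted models report
  for these populations; an exponentially decaying (Gompertz-type) gain was
  tried first and rejected because its long soft tail is qualitatively unlike
  the reference populations and leaves the stage-2 calibration without a
  reachable target.  The single shape parameter `c` is set by the monthly
  gain at first presentation (defaults 0.385/0.376/0.183/0.109 for
  dog/cat/rabbit/guinea pig, the magnitudes reported by fitted juvenile-gain
  models for the same populations).  True cessation ages default to
  13.8/12.8/13.0/12.8 months.
- **Visits**: two-rate Poisson process per animal — 0.8/month while juvenile,
  0.15/month adult (0.6/0.12 for rabbits and guinea pigs) — beginning at the
  first-presentation age (1.5 months; clinics never weigh neonates), with one
  visit forced inside the observation window so every generated animal is
  observable.  Ages at the window end are uniform up to a configurable
  maximum (default 180 months).
- **Noise**: multiplicative log-normal with CV 2% and mean exactly 1.  The
  within-animal noise magnitude is a free parameter of the generator, not an
  empirical value.
- **Planted defects**: unit-error weights (×1000 or ÷1000), blanked dates of
  birth (animal-level), dates of birth shifted to implausible ages, stripped
  invoice ids — each at a configurable record fraction, with an alteration
  log returned for recount tests.

All randomness flows from one integer seed through a named
`numpy.random.Generator`; identical configuration and seed give byte-identical
output.

Ground-truth oracles: `true_point_mean` (mean noiseless weight of all
generated animals alive on a date) and `true_cessation_oracle` (first
0.05-grid age at which the noiseless population curve's increment falls to
the detection tolerance — for light species this precedes `T`, because the
tolerance is absolute in kg).

**What passing tests do and do not show.**  The generator emulates growth,
visit-density, skew and defect structure, but not pregnancy, disease-related
weight loss, seasonal effects, breed- or litter-structure, practice-level
heterogeneity in measurement quality, or real age pyramids (ages are uniform,
so juvenile fractions run below those of real populations).  Recovery of the
truth here shows the pipeline is consistent under its own assumptions; it
does not certify accuracy on real EHR extracts.

## Problem sizes and test design

The suite exercises the pipeline at the sizes a workstation handles
comfortably: end-to-end recovery at 20,000 animals (point mean within 2% of
truth), plateau-age recovery at 10,000 animals per seed across ten seeds
(median error within 0.5 months of the truth-increment oracle, checked on the
13.0-month species), development/validation calibration at 5,000 + 5,000
animals, and brute-force oracle equivalences (per-rule filtering, exhaustive
term-mask enumeration, 0.001-month grid root scans, exhaustive window scans,
permutation tests) on small fixtures.  Two-year observation windows mirror
the multi-year development periods typical of such studies and give each
juvenile a full trajectory.

## Known limitations

- The calibration loop's monotonicity premise is an empirical property of
  large cohorts; small cohorts fall back to an exhaustive scan.
- Cessation detection needs a juvenile-dense cohort; on small or old-skewed
  record sets the smoothed gain curve may never reach the zero tolerance and
  the stage reports "no plateau" rather than guessing.
- The absolute zero-tolerance (kg) makes the detected cessation age of very
  light species precede the true plateau slightly; the truth oracle shares
  the convention.
- CIs on the point mean ignore practice-level clustering by design (the
  estimand is the population mean over animals).
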