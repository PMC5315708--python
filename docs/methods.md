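# Methods

## Metrics

A *camera episode* is one contiguous endoscope movement `[start, end]`
in seconds. Per trial:

- **CFrq** = (number of episodes) / CompTime, in movements/s.
- **CDur** = mean episode duration (s); undefined (missing) when a
  trial has no episodes. Reporting 0 instead would fake instantaneous
  movements and drag group means toward zero — novice trials with no
  camera movement at all do occur, so the distinction matters.
- **CInt** = mean end-to-start gap between consecutive episodes (s);
  undefined with fewer than two episodes. The end-to-start convention
  measures idle viewpoint-hold time; the start-to-start period would
  double-count durations already captured by CDur. A `period` mode is
  available for sensitivity analysis.
- **CompTime** = last minus first sample timestamp (s).
- **EOM** = total Euclidean polyline length of every instrument tip's
  sampled trajectory (m), summed over instruments (all instrument
  streams present are counted). Samples during clutch engagement are
  included; instruments are essentially stationary while clutched, so
  the contribution is negligible.
- **MWR**: per hand, distances from the mean hand position to every
  sample; default `scaled_max` mode returns 0.85 × the larger of the
  two maximum distances (the literal reading of the definition);
  `percentile` mode returns the larger 85th-percentile distance (the
  reading in which "85 %" denotes sample coverage). The mode is
  recorded in run metadata. MWR uses the hand controllers, not the
  instrument tips.

Missing values propagate as NaN and are excluded pairwise from all
downstream statistics; every reported statistic carries its effective n.

## Segmentation

When the platform records camera events, episodes come from pairing
`camera_start` with the next `camera_stop` (orphan stops skipped, never-
closed starts clamped to trial end, both logged). For position-only
data an opt-in detector thresholds the smoothed endoscope speed:
centered finite differences (edge samples replicate their neighbor,
avoiding the half-sample bias of one-sided differences), moving-average
smoothing over `smoothing_window` samples (default 5, odd), speed
threshold 2 mm/s, merge gap 0.2 s, minimum episode 0.1 s. The defaults
are plausible console dynamics and deliberately configurable, since no
canonical values exist; merging precedes the minimum-duration filter so
a briefly interrupted movement survives as one episode. Recovery tests
show exact episode counts and boundary errors within one smoothing
window on piecewise-constant-velocity traces.

## Statistical analysis

- Group comparisons use the pooled-variance Student's *t* test
  (two-sided) as the classical default; Welch's variant is available by
  flag. Sample SDs use the n−1 denominator. Degenerate inputs (a group
  with fewer than two values, zero variance in both samples) are
  flagged not-computable rather than silently dropped.
- Discrimination: per metric, the per-exercise means of the two extreme
  groups are pooled and min–max normalized with **shared** bounds.
  Normalizing each group separately would force both onto [0, 1] and
  destroy exactly the between-group difference being measured. The
  index d is the absolute difference of the across-exercise means of
  the normalized group means; per-exercise |differences| are retained
  for the dispersion estimate (their SD) and for metric-vs-metric
  comparisons, which are paired *t* tests (paired by exercise, since
  the same exercises underlie every metric; an unpaired mode exists).
  Two metrics with identical per-exercise values compare at p = 1.
- Correlations pool all surgeons within an exercise. Note the expected
  signs against raw CompTime: metrics that increase with skill (CFrq)
  correlate negatively with time, and CDur/CInt positively. Published
  tables of this analysis sometimes print the opposite sign convention
  for the time column (suggesting a time-derived score rather than raw
  seconds); this implementation correlates against raw seconds and
  makes no attempt to force sign agreement.
- No multiple-testing correction is applied, matching common practice
  for these validity tables; `run_info.json` records the comparison
  count so users can apply their own.
- The headline construct-validity declaration per metric is
  "significant in a majority of computable exercises" for a group pair
  — the whole-battery analogue of reporting "significant in k of N
  exercises". Single-exercise significance is a noisy event even at
  realistic effect sizes, so the battery-level majority is what the
  calibrated-simulation checks assert.

## Synthetic cohort generator

The generator emulates the *statistics* of a simulator study cohort,
not task content:

- **Cohort structure**: 18 new / 8 intermediate / 13 experienced
  surgeons, one trial per surgeon per exercise, group membership (and a
  latent skill multiplier) fixed across exercises.
- **Camera process**: alternating renewal — gap ~ Gamma(shape 2, mean
  `target_cint`), duration ~ Gamma(shape 2, mean `target_cdur`) —
  truncated at the trial end. Shape 2 gives the mild right skew seen in
  published dispersion (SDs approaching means). The long-run episode
  rate is 1/(CInt + CDur).
- **Completion time**: lognormal with mean `mean_comp_time` and CV 0.15
  (within-surgeon residual; strictly positive and right-skewed).
- **Between-surgeon heterogeneity**: a per-surgeon standard-normal z
  maps to mean-one lognormal multipliers `exp(s·z − s²/2)` applied
  jointly to gap, duration and completion targets (log-SD
  `between_sd` = 0.25 by default), with weaker couplings to instrument
  speed (0.4·s) and hand spread (0.2·s). This produces the printed-scale
  group SDs — renewal noise alone is far too small — and induces the
  within-group metric correlations implied by a shared underlying
  skill. Real inter-metric correlation structure is unreported for such
  cohorts; only this shared-skill correlation is modeled.
- **Kinematics**: instrument tips move at constant `path_speed` along
  smoothly wandering unit directions, so EOM = n_instruments ×
  path_speed × duration exactly; hands are i.i.d. Gaussian about fixed
  per-hand centroids (SD `hand_sigma` per axis); the endoscope
  integrates `endo_speed` along a random constant heading inside each
  episode and is stationary outside. Events are emitted at episode
  boundaries, so the event path and the kinematic detector can be
  cross-checked on the same trial.
- **Default profiles** cover five exemplar exercises whose CDur/CInt
  targets (e.g. new 1.42 s / 34.9 s vs experienced 0.80 s / 8.2 s on
  the first exemplar) and effect directions follow the published
  group-ordered pattern: experienced surgeons show higher CFrq, shorter
  CDur, shorter CInt, shorter CompTime, slightly lower EOM rate and a
  slightly narrower hand workspace. Completion-time means (120–420 s)
  are plausible simulator values. Hand-workspace scale varies per
  exercise (0.035–0.06 m) with only a 7 % group effect, so MWR is by
  construction the weakest discriminator, as observed in practice.
- **Surrogate overall score**: the average of `100·(1 − minmax)` of
  CompTime and EOM over the per-exercise cohort range. It is a
  documented, transparent stand-in for proprietary simulator composite
  scores — NOT a reimplementation of any vendor formula — and
  correlates positively with skill by construction.

What passing the simulation-based checks does **not** show: anything
about exercise content, learning across consecutive exercises, error/
penalty events, endoscope orientation (only gross position is modeled),
or the true inter-metric covariance of human cohorts.

## Numerical and reproducibility choices

- All randomness flows from one integer seed through
  `numpy.random.SeedSequence.spawn`; trials, manifests and report CSVs
  are byte-identical across runs with the same seed.
- Trial files store floats with `%.17g` and are read with round-trip
  parsing, so write → read restores bit-identical values.
- Min–max normalization of a constant vector returns all zeros with a
  degenerate flag instead of dividing by zero; surrogate scoring of a
  degenerate cohort range contributes a neutral 50 with a warning.
- Time is seconds from trial start (all metrics are relative
  durations); positions are meters and readers reject any other unit.

## Test-suite study conditions

The Monte-Carlo checks scale their problem sizes to what the statistics
need rather than to the full study:

- *p-value oracles*: analytic Student-t and Pearson p-values are
  compared against 10⁵-replicate brute-force simulations of the exact
  null distribution (both statistics are pivotal under their normal
  nulls), at n = 10 per sample, within 3 Monte-Carlo SEs. A
  label-permutation cross-check runs at n = 50, where the permutation
  null and the t null agree to ~10⁻²; at n = 10 the two exact nulls
  differ by O(1/n), which is larger than Monte-Carlo resolution — a
  real statistical gap, not an implementation artifact.
- *Null calibration*: 100 seeded cohorts of 39 surgeons × 5 exercises
  with identical, homogeneous group profiles (`between_sd` = 0, so
  exercise-level tests are independent and the binomial reference is
  valid); each (metric, pair) family's rejection count must lie in the
  exact binomial 99% region around 5 %.
- *Parameter recovery*: 50 seeded homogeneous cohorts with 1-hour
  trials, where O(1/T) truncation edge effects on the renewal-rate
  identity CFrq = 1/(CInt + CDur) fall below Monte-Carlo resolution.
  The identity itself only holds without between-surgeon heterogeneity
  (Jensen's inequality biases E[1/cycle] upward otherwise), which is
  why the recovery condition is homogeneous.
- *Pattern reproduction*: 100 seeded cohorts under the shipped default
  profiles at a reduced 2 Hz sampling rate (the sampling rate is not a
  modeled quantity and none of the tested statistics depend on it).
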