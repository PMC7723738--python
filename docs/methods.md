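# Methods

## The CO estimate

A breath test records exhaled air through an electrochemical CO sensor
for 20 s at 5 Hz (100 samples, 1 ppm resolution, accurate to within
10%). The first `pre_exhalation_count` samples precede exhalation
onset and carry only the sensor's baseline offset, which drifts upward
after recent charging and with ambient pollution. The estimator:

1. **Baseline** `b`: median of the pre-exhalation samples. The median
   resists single-sample spikes. When a trace carries no
   pre-exhalation segment, the fallback is the minimum over the first
   2 s — a conservative offset proxy.
2. **Window**: in the default `corrected` mode the half-maximum
   threshold is applied to the baseline-corrected signal
   `c = x − b`: `W = {i : c_i ≥ 0.5 · max(c)}`. The inclusive `≥`
   guarantees the maximum is always in its own window. A `literal`
   mode thresholds the raw samples instead and subtracts `b` from the
   window median afterwards; with a large offset the raw threshold can
   select essentially the whole trace, which is why `corrected` is the
   default. Both modes agree exactly on clean step traces (flat
   baseline, flat plateau), where each returns plateau − baseline.
3. **Value**: median over the window (even-sized windows average the
   two central order statistics, so an enumeration oracle can match
   bit for bit), clipped at 0 ppm. A negative pre-clip value sets a QC
   flag rather than erroring, as does a maximum rise below 1 ppm
   (`no_exhalation_detected`: below one resolution step there is no
   evidence of exhalation; threshold configurable).

The estimator accepts real-valued inputs and never re-quantizes;
quantization is a property of the sensor, simulated where appropriate.

Useful invariances, all property-tested: adding a constant offset to
every sample leaves the corrected-mode value unchanged; scaling a
zero-baseline trace scales the value; restricting a trace to its
window plus baseline segment reproduces the value.

## Physiology model

Both analytes follow first-order elimination with additive
superposition across cigarettes — the simplest model consistent with a
stated half-life:

    level(t) = Σ_events n_k · boost · 2^(−(t − t_k)/t_half)   (+ endogenous CO)

Defaults: breath CO half-life 4.5 h (mid-range of the 3–6 h
literature), endogenous CO 1 ppm, boost 3 ppm per cigarette; cotinine
half-life 9 h in pregnancy and 17 h otherwise, boost 100 ng/mL per
cigarette, assay quantitation floor 10 ng/mL with sub-floor values
reported as 5 ng/mL. The CO and cotinine boosts per cigarette are free
parameters of the simulator (no published per-cigarette value is
assumed); 3 ppm puts a 6–10 cigarette/day smoker's afternoon breath CO
in the 8–20 ppm range typical of daily smokers, and 100 ng/mL puts
steady-state cotinine well above the 50 ng/mL cutoff.

## The synthetic study

`simulate_study` emulates the design of a 12-week perinatal pilot:

- **Cohort**: 90% of participants smoke 6–10 cigarettes/day, 10%
  smoke 11–20; ~40% deliver mid-study, switching their cotinine
  half-life; per-participant Gaussian random intercepts on CO
  (sd 0.5 ppm) and cotinine (sd 20 ng/mL) induce the within-person
  correlation the clustered statistics must absorb.
- **Smoking histories**: whole days are abstinent or smoking under a
  two-state Markov chain whose stationary abstinent fraction is
  `quit_propensity` (default 0.2) and whose abstinent→abstinent
  transition is 0.85, so abstinence arrives in multi-day quit attempts
  (mean spell ≈ 1 week). Spell structure matters: cotinine clears over
  days, so independently scattered abstinent days would make the
  cotinine reference unattainably discordant with same-day breath CO.
  On smoking days cigarettes fall uniformly over 07:00–23:00.
- **Schedule**: in-office visits follow the 18-visit pattern (5 in
  week 1, 2 in weeks 2–3, then weekly) on spread weekdays at 14:00
  local — an afternoon visit hour, which reproduces the observed
  pattern that roughly 70% of tests occur within 5 h of the last
  cigarette. One remote notification per non-office day per week is
  drawn uniformly in the 08:30–15:00 window; it fails delivery with
  probability 0.07, else is completed with probability 0.5 at a
  uniform time before the 5-hour expiry, else expires.
- **Measurements**: the app trace comes from the sensor model below
  and is reduced by the package's own estimator; the reference monitor
  reads true CO plus N(0, 0.75) error rounded to integer ppm; cotinine
  is collected in office only; the reported time of last cigarette is
  missing with probability 0.056; completed remote tests are
  challenged with probability 0.08.

**Sensor model** (`synthesize_trace`): baseline offset drawn once per
test (default Exponential(1 ppm), standing in for charging/pollution
drift), multiplicative gain uniform in 1 ± 0.10 (the "accurate to
within 10%" spec, drawn per test), logistic rise over 1 s rescaled to
reach the plateau exactly at the end of the rise window, additive
per-sample N(0, 0.3 ppm) noise, optional rounding to the 1 ppm
resolution. `SensorParams.noiseless()` switches every error source off
for recovery tests. Any smooth monotone rise satisfies the estimator's
assumptions; the logistic is a convenience, not a claim about breath
dynamics.

What the generator does **not** emulate: nicotine-replacement therapy,
secondhand smoke, THC and air-pollution confounding of breath CO,
inter-day sensor drift, behavioural reactivity to incentives
(quit propensity is exogenous), and time zones (all clock times are
naive local). Passing tests therefore demonstrate correctness of the
algorithms under the stated physiological model, not field performance
of a device.

## Classification conventions

CO: abstinent iff value ≤ cutoff (6 ppm default; the printed
comparator is inclusive). Cotinine: abstinent iff value < 50 ng/mL
(strict, per "less than"). Recency: elapsed ≤ 5 h is "within", > 5 h
"beyond", absent report "missing" — the two phrases partition the line
at exactly 5 h, and the boundary is assigned to "within". Every cutoff
is overridable; whether one CO cutoff should serve both pregnancy and
postpartum is deliberately left as a single configurable value.

## Contingency management

The k-th consecutive negative test earns
`min(base + (k−1)·increment, cap)` tokens; positives earn nothing and
reset the escalation (`reset_policy="reset_to_base"`, configurable to
`"none"`). Missed/expired tests reset like positives by default
(standard CM practice). In-office and remote tests share one streak.
Token magnitudes are configuration, not science: defaults base = 1,
increment = 1, no cap preserve the escalation-with-reset structure
while leaving dollar values to the study protocol. A challenged test
that staff rule a false positive is excised from the history and the
streak recomputed; removing a positive can only merge neighbouring
negative runs, so the recomputed total never decreases (tested as an
invariant).

## Clustered statistics

- **Sensitivity/specificity**: point estimates are the pooled ratios
  TP/(TP+FN), TN/(TN+FP). The default CI Taylor-linearizes the ratio
  of per-participant totals: with cluster numerators x_i and
  denominators y_i, `var(R) = m/(m−1) · Σ(x_i − R·y_i)² / (Σy_i)²`,
  Wald interval clipped to [0, 1]. The alternative is a seeded
  participant-level bootstrap (resample clusters with replacement,
  percentile CI). A single-cluster ledger degenerates to the point
  estimate with a warning. An all-one-class reference raises an
  explicit error instead of returning NaN.
- **Repeated-measures correlation**: the ANCOVA formulation — common
  slope with participant-specific intercepts — computed from
  within-participant-centered sums of squares; r is the signed square
  root of the within-participant variance share explained, p from
  F(1, N − k − 1). Cross-checked in tests against an explicit-loop
  oracle and against `pingouin.rm_corr`.
- **ROC/AUC**: AUC is the Mann–Whitney pair-counting probability (ties
  ½), CI by DeLong's method (midrank implementation, verified to 10
  decimals against `pROC::ci.auc` on a frozen dataset), curve points
  at every distinct threshold.
- **GEE**: Gaussian family, identity link, working correlation AR(1)
  (within-participant rows treated as an evenly spaced series),
  exchangeable or independence. With the handful of clusters typical
  of pilot studies the asymptotic sandwich is anticonservative, so the
  default covariance is the bias-reduced (Mancl–DeRouen) estimator and
  p-values use a t reference with (clusters − parameters) degrees of
  freedom; in the packaged null simulation (10 participants × 14
  tests, within-participant binary group, AR(1) errors ρ = 0.3) this
  holds the type-I error at ≈ 0.05 where the plain sandwich sits near
  0.12. `cov_type="robust"` restores the asymptotic sandwich.
- **Summaries**: percentages round half away from zero, one decimal
  for the recency split / remote completion / per-participant mean and
  integers for the remote-outcome breakdowns, matching how such tables
  are printed; the decimals are a parameter. The delivery-failure and
  preceded-by-positive percentages use the *missed* notifications as
  denominator, the challenge percentage the *completed* ones.
- Two-sided tests at α = .05 throughout; no multiplicity correction.

## Simulation sizes used in the checks

The packaged calibration checks use 500 replicates each: the GEE null
at 10 participants × 14 observations (the pilot-scale design), and the
bootstrap-coverage check at 20 participants × 14 tests with
per-participant sensitivity Beta-distributed around 0.9
(concentration 50). Twenty clusters were chosen for the coverage check
because the percentile bootstrap is only expected to approach nominal
coverage once clusters are no longer very few; at pilot scale the
known small-m undercoverage of percentile intervals would be
indistinguishable from an implementation defect. Estimator and reward
oracle sweeps use 1,000 random instances.

## Known limitations

- The pre-exhalation sample count is metadata; no exhalation-onset
  detection is performed on the waveform.
- Identity/exhalation verification are boolean flags set upstream
  (staff or simulator), never computed from media.
- The DeLong AUC interval ignores clustering (a cluster-bootstrap AUC
  can be obtained by resampling the ledger); the rm-correlation p
  assumes homoscedastic within-participant errors.
- The fixture ledger reproduces marginal counts only; its cell values
  are arbitrary, so only count-derived summaries are meaningful on it.
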