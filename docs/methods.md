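# Methods

## Analysis model

The package treats a balance study as a two-way repeated-measures layout:
every subject performs every condition (no tape NT, strapping tape ST,
kinesiology tape KT), five trials per condition, and each trial yields
one value per channel per complexity measure. The modelling chain is

1. **Signal conditioning** per channel family:
   joint angles → zero-phase 4th-order Butterworth low-pass, 18 Hz;
   CoP → same, 50 Hz; surface EMG → 4th-order Butterworth band-pass
   20–450 Hz, full-wave rectification, Chebyshev type-II low-pass (order
   4, 10 Hz, 40 dB stopband) to form the linear envelope.
2. **Time normalization** of every conditioned series to 1001 equally
   spaced frames (cubic spline; linear by flag) so trials of different
   durations are comparable.
3. **Complexity estimation** per 1001-frame series: Higuchi fractal
   dimension (k_max = 8, natural-log least-squares fit of ln L(k) on
   ln(1/k) over all k = 1..k_max) and SVD entropy (delay embedding with
   m = 2, τ = 1; base-2 entropy of sum-normalized singular values).
4. **Aggregation**: arithmetic mean of the per-trial values within each
   (subject, condition, channel, measure) cell.
5. **Inference** per channel/measure: per-condition mean ± SE
   (sd/√n), one-within-factor repeated-measures ANOVA, and Tukey
   pairwise comparisons from the studentized-range distribution using
   the ANOVA's MS_error and error df (family size = number of
   conditions).

The ANOVA decomposition is SS_total = SS_subject + SS_condition +
SS_error with F = MS_condition/MS_error on (c−1, (c−1)(n−1)) df. A
second mode treats cells as independent groups on (c−1, cn−c) df:
published balance-taping comparisons sometimes print that df pattern
(e.g. df2 near 114–117 at n = 41, where a within-subject decomposition
gives 80), so both are shipped; `within_subject` is the default and the
correct model for this design. No sphericity correction is applied by
default; a Greenhouse–Geisser flag exists. Missing cells drop the
subject listwise for that channel with a warning — the classical
decomposition needs complete cases.

## Estimator conventions

* **Higuchi normalization.** L(m,k) uses the standard correction
  (N−1)/(⌊(N−m)/k⌋·k) so that offsets with fewer summed differences are
  comparable; the per-offset sums are exact (every difference used once)
  and verified against a loop-based direct transcription to 1e−12.
* **Uncentered embedding by default.** SvdEn is computed on the raw
  embedding matrix, so the signal's DC level participates: an
  offset-dominated channel (a joint angle fluctuating a few degrees
  around a large working posture) has one dominant singular value and an
  entropy of order 0.001–0.05 bits, which matches the magnitudes such
  analyses report for joint-angle channels. `center=True` removes the
  mean first and is the right choice when only fluctuation structure
  matters (an i.i.d. series then gives ≈ 1 bit at m = 2).
* **Degenerate inputs.** Constant or affine series have zero curve
  length at some scale; they return HDf = 1.0 with a warning. All-zero
  or constant series have a rank-0/1 embedding; SvdEn returns 0.0.
  Singular values below the numerical-rank cutoff
  (σ_max · max(N,m) · ε) are treated as exact zeros, so rank-1 cases
  are exactly 0 rather than 1e−16. Batch runs therefore never abort on
  flat channels.
* **Zero-phase filtering.** All offline filters run forward–backward:
  no phase lag, but attenuation at the cutoff is −6 dB rather than the
  single-pass −3 dB. Single-pass (causal) filtering is available via
  `zero_phase=False` / `--no-zero-phase`; the analytic-response tests
  are run on a single pass against the bilinear-prewarped Butterworth
  magnitude.
* **EMG complexity input.** The default complexity input for EMG is the
  linear envelope. Reported muscle HDf values near 2 in comparable
  studies suggest the rectified band-passed signal (which is noise-like)
  may have been used instead of the smooth envelope; both are supported
  (`emg_use_envelope=False` selects the rectified band-passed signal).
* **CoP derivation.** For force-plate ingest, cop_ap = −My/Fz and
  cop_ml = Mx/Fz with the plate origin at its surface; samples with
  |Fz| < 10 N are flagged invalid, and a trial with no contact at all is
  an error.

## Synthetic studies

No public recordings exist for this design, so the generator produces
datasets with the statistical structure the analysis assumes, with known
ground truth:

* **Kinematic and CoP channels** are fractional Brownian motion paths
  (exact circulant-embedding synthesis; Cholesky fallback when the
  circulant eigenvalues go negative), scaled to a channel-typical
  fluctuation amplitude and shifted by a channel-typical DC offset
  (joint angles sit at a flexed working posture; CoP sits off the plate
  origin). The Hurst exponent fixes the path's theoretical fractal
  dimension at 2 − H. Baseline H per channel was set so that 2 − H
  matches the fractal-dimension magnitudes reported for such channels
  (e.g. ankle ML ≈ 1.49 untaped).
* **EMG channels** are band-limited (20–450 Hz) Gaussian noise under a
  trapezoidal activation envelope (ramp up over the first 20% of the
  trial, hold, ramp down over the last 20%), mimicking eccentric loading
  during a reach.
* **Condition effects** are injected through two distinct mechanisms,
  mirroring how the two measures respond to different physiology:
  a Hurst shift (ankle ML: −0.20 under ST and KT, i.e. FD 1.49 → 1.69)
  moves HDf; a reduced latent-source count (ankle AP/SI: 3 sources
  untaped → 1 under tape, sources fanned out in roughness) together with
  a doubled DC offset moves SvdEn downward under tape. Effect magnitudes
  were anchored to the directions and relative sizes reported for ankle
  taping and then left fixed.
* **Within-subject correlation** comes from per-subject random effects
  drawn once per subject and shared across all that subject's trials and
  conditions: a Gaussian intercept on H (sd 0.04), a log-normal
  amplitude factor (sd 0.10), and a log-normal DC factor (sd 0.05).
  Observation noise (sd = 2% of channel amplitude) is added per sample.
* **Trial duration** is not fixed by the design being emulated (only the
  1001-frame normalization is); the default is 10 s, which makes a
  100 Hz angle trial exactly 1001 samples. It is configurable and all
  results at other durations pass through the same normalization.

What the generator does **not** emulate: actual reach biomechanics
(no segment model, no task-phase structure in the kinematics),
marker-tracking noise, EMG cross-talk or amplitude non-stationarity
beyond the envelope, heavy-tailed or asymmetric subject effects, and any
correlation *between* channels. Passing tests therefore show that the
pipeline recovers known signal structure and keeps its error rates under
the stated stochastic model — not that real recordings would show any
particular effect.

## Validation experiments and problem sizes

The study-level checks run on reduced designs chosen to keep the full
suite fast while leaving Monte-Carlo error well inside the asserted
margins:

* fractal-dimension recovery: 200 fBm paths of 1001 samples per Hurst
  value in {0.2, 0.35, 0.5, 0.65, 0.8};
* null calibration: 1000 synthetic studies at 20 subjects × 5 trials on
  one angle channel with all effects zeroed (the test suite) and 400 in
  the reproduction script; rejection at α = 0.05 is asserted in
  [0.03, 0.07] and the p-value distribution is checked uniform;
* effect-direction recovery: 500 replicates (test suite; 200–250 in the
  script) at the full 41-subject design, ankle AP/SI for the SvdEn
  effect and ankle ML for the HDf effect, asserting ≥ 80% detection at
  p < 0.05 with the correct direction of the condition means.

## Known limitations

* Higuchi's estimator at N = 1001, k_max = 8 carries a small downward
  bias at low fractal dimensions; the recovery-slope test bounds it
  (slope of mean HDf on 2 − H within [0.7, 1.2]) rather than assuming
  it away. Longer series and larger k_max reduce the bias; k_max is a
  parameter.
* At m = 2 the SVD entropy has only two singular values, so it
  compresses all source structure into one ratio; condition effects on
  source count are detectable mainly through the roughness mixture and
  the DC ratio. Larger m is supported but changes the scale
  ([0, log2 m]).
* The 18 Hz kinematic low-pass removes part of the sub-80 ms structure
  the Higuchi scales probe at 100 Hz, compressing (but preserving the
  ordering of) fractal-dimension contrasts; the filtered and unfiltered
  analyses are both available (`preprocess=False`).
* The Tukey p-values rely on the homoscedastic studentized-range model
  with the ANOVA's pooled MS_error; with strong sphericity violations
  they inherit the ANOVA's liberality (no correction is applied to the
  post-hoc tests).
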