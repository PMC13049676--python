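# Methods

This note documents the models behind `vmrlearn`: what the simulators
generate, how the extractors are defined, the numerical choices that were
genuinely open, and what the test suite does and does not establish.

## Task and behavioral model

The session is the standard four-block visuomotor rotation design:
baseline (trials 1–100), adaptation (101–300) under a 30° counterclockwise
cursor rotation, no-vision (301–500), washout (501–550). Reach direction
θ(n) is coded positive in the clockwise (compensatory) direction, so full
compensation is θ = +30°.

Behavior is simulated by a single-state learner with state u (degrees):

* adaptation: u ← r_a·u + η·(30 − u)
* no-vision: u ← r_nv·u
* washout: u ← r_a·u + η·(0 − u)

with executed θ(n) = u(n) + ε(n), ε ~ N(0, σ_motor²), σ_motor = 3° by
default. This is the simplest model that reproduces the canonical
rise-and-decay shape: exponential approach to the rotation during
adaptation and geometric decay without feedback. The asymptote is
30·η/(η + 1 − r_a); learning rates are drawn per participant
(η ~ U(0.1, 0.3), r_a ~ U(0.97, 1)), giving late-adaptation compensation
of roughly 77–100%.

Scoring: points are awarded only during adaptation, per the graded error
bins (hit / <10° / <20° / <30° / ≥30°), with invalid-speed trials
("Slow" < 312 mm/s, "Fast" > 469 mm/s) forced to the worst bin. Reward
participants accumulate from 0, punishment participants count down from
800; the running total is clipped to [0, 800] after every trial. "Hit" is
operationalized angularly as endpoint error ≤ 1.8° (a 0.25 cm target
half-width at 8 cm, ≈ atan(0.25/8)); the threshold is configurable since
target geometry admits other readings. Valid movement speeds are drawn
from a normal distribution truncated between the two thresholds;
slow/fast events occur only when explicitly injected, treating them as
rare nuisance trials.

## Cohort generator and planted effect

`simulate_cohort` plants recoverable ground truth:

* EEG features per participant and phase: alpha ERD ~ N(50, 15²) %
  (late-phase mean +5), beta ERD ~ N(40, 12²) % (+4), FRN ~ N(−3, 2²) µV
  (late +1, i.e. shrinking toward zero), all ERD values clipped to
  [5, 95] %. Early and late values of each feature are built from a
  shared/independent component mix with test–retest correlation ρ = 0.5 —
  band-power and ERP features are only moderately stable across task
  phases within a session, and this is what makes the early- and
  late-phase regressors statistically distinguishable.
* Retention target (%): 35.7 + 0.34·(condition × late alpha ERD) +
  N(0, 14²), condition coded 1 = reward / 0 = punishment, clipped to
  [1, 99] and capped by the participant's own learning asymptote. The
  intercept and slope are the package's reference effect; the residual SD
  is set so the planted model explains roughly a third of retention
  variance (realized adjusted R² ≈ 0.34–0.38 at n = 64).
* The no-vision decay rate r_nv is then obtained by inverting the
  geometric-mean identity mean_{j≤200}(r^j) = target/asymptote (Brent's
  method), so the measured retention amount reproduces the planted target
  up to motor noise (SE ≈ 0.2 points over 200 trials).
* "Measured" features (used when the EEG path is skipped) are truth +
  N(0, 2²) ERD points or N(0, 0.5²) µV — matched to the extraction error
  the EEG round trip actually produces on noisy fixtures.

Punishment-group retention carries no ERD dependence, so the interaction
is reward-specific by construction.

A structural property worth knowing: because ERD is an all-positive scale
(mean ≈ 50–55, SD ≈ 15), the interaction column condition×ERD correlates
≈ 0.96 with the condition code itself. At 1SE sparsity the Lasso therefore
sometimes substitutes the condition main effect (or a sibling interaction)
for the true term when the planted slope is small; identification of the
exact term across ≥ 90% of replicates requires slopes in the upper part of
the 0.3–0.5 range. This mirrors the real difficulty of separating a
group-mean difference from a group-specific slope on a ratio scale.

## Synthetic EEG

Go-cue epochs span −3 to +4 s at 1 kHz (configurable). Each sensorimotor
rhythm is an equal-amplitude comb of integer-hertz tones spanning its
analysis band (alpha 8–13 Hz, total amplitude 10 µV; beta 15–30 Hz, 5 µV),
shared coherently across the seven C3-cluster channels. Tone phases follow
an equispaced per-trial schedule (tone j in trial i has phase 2πji/n),
which makes every cross-tone interference term cancel exactly in the
trial-averaged power: the average spectrum is deterministic rather than a
sampling estimate, so planted ERD values round-trip through the extractor
to within half a percentage point. A pure-tone design was rejected
(no spectral support at most analysis bins, and envelope-transition
sidebands bias the peak neighborhood), as was band-limited noise (correct
in expectation but with several points of per-seed spread at realistic
trial counts).

The ERD envelope multiplies each band's comb by
√(1 − ERD/100) inside the preparatory window, with a 0.2-s raised-cosine
onset placed just inside −1 s (so the reference period keeps full
amplitude) and release at +1 s — desynchronization persists through
movement execution rather than rebounding at the go cue, which is both
physiological and keeps the analysis plateau wide. 1/f background noise
(spectrally shaped white noise, exponent 1) is added everywhere;
non-cluster channels (including mastoids M1/M2) carry background only.

Feedback epochs span −0.2 to +0.6 s. The outcome-dependent component is a
Gaussian bump (center 275 ms, SD 40 ms) scaled so the noiseless
success-minus-failure difference wave has mean amplitude exactly equal to
the planted FRN within the 200–350 ms window, split ±half between the two
outcome classes over the eight FCz-cluster channels; an outcome-independent
evoked component (4 µV, center 300 ms) is added for realism and cancels in
the difference. The bump is ≈ 0 throughout the baseline interval.

What the generator does *not* emulate: volume conduction/head geometry,
artifacts (blinks, EMG), autocorrelated rhythm dynamics, channel-specific
noise topographies. Passing round-trip tests therefore validates the
estimators' windowing, referencing, ratio and averaging logic — not their
robustness to real-world artifacts, which the upstream preprocessing the
package deliberately omits (ICA, channel repair) would handle.

## ERD estimation

Single Hanning taper, 1-s window, 0.1-s hops; window centers are reported
at the window midpoint, so the grid lands on −2.5, −2.4, … s. Windows
whose support would leave the epoch are dropped, not padded. Frequency
resolution is 1/win = 1 Hz. Power is averaged across trials *before* the
ERD ratio (the classic convention; the suite asserts this order
reproduces planted fixtures and differs from ratio-then-average).

Reference spectrum R(f): mean of A(f, t) over window centers in
[−2, −1) s. The half-open edge excludes the window centered exactly at
−1 s, whose 1-s support reaches 0.5 s into the preparatory window; with a
closed interval, planted desynchronization leaks into the baseline and
biases every ERD value downward by several points.

Reliability floor: ERD is a ratio, and at frequencies where the reference
spectrum carries essentially no energy the ratio is meaningless. Rows with
R(f) below `rel_floor` (default 10⁻²) of the spectrum's maximum are set to
NaN and skipped by the NaN-aware peak search. On real EEG, where rhythms
sit on a 1/f floor within one or two orders of magnitude of the peaks,
the guard is inert; on synthetic fixtures it masks bins outside the
planted combs' support. A reference spectrum that is zero (or degenerate)
everywhere is rejected.

Peak extraction: first-occurring maximum in (frequency, time) scan order
within band × search window (−1 to 0 s), then the mean over ±0.2 s ×
±2 Hz around it, inclusive of endpoints and truncated at the map edges.

## FRN estimation

Feedback-locked epochs are mastoid re-referenced, baseline corrected per
trial over [−200, 0) ms, cluster-averaged over FCz + 7 neighbors, averaged
within outcome class, and differenced (success − failure). Outcome classes
come from the point system: reward 4 = success, 0–3 = failure; punishment
0 = success, −1…−4 = failure. The amplitude is the arithmetic mean of the
difference wave over 200–350 ms, endpoints inclusive. Outlier exclusion is
a single pass at mean ± 2 sample SDs (n − 1), computed separately for the
early and late phase and pooled across feedback conditions (pooling is
configurable; the phrase "group mean" is ambiguous between the two
readings). Note that a sample of fewer than six values can never contain
a ±2-SD outlier under the sample-SD convention (the maximum standardized
deviation is (n−1)/√n).

## Statistics

* Mixed ANOVA: sums of squares and F statistics via `pingouin.mixed_anova`
  behind the module surface; the suite verifies them against a direct
  sums-of-squares oracle to 10⁻⁶. Participants missing any within level
  are dropped listwise and counted in the log.
* Sphericity: Mauchly's W from the pooled within-group covariance of the
  level scores under an orthonormal (Helmert) contrast, chi-square via the
  Box correction with n − G in place of n − 1; Greenhouse–Geisser ε =
  (tr D)²/((k−1)·tr D²) with a floor of 1/(k−1) and ε ≡ 1 for two levels.
  The GG correction is applied to the within and interaction effects when
  k > 2 and Mauchly's p < .05, rescaling both dfs by ε and recomputing p.
  (This grouped variant is implemented directly because the library
  routine pools across groups; the two agree exactly on single-group
  data, which the suite asserts.)
* Holm, pooled t-test, OLS: statsmodels/scipy, with longhand oracles in
  the tests.
* Lasso: objective (2n)⁻¹‖y − Xβ‖² + λ‖β‖₁ solved by coordinate descent
  (scikit-learn, tol 10⁻¹⁰). Grid: 100 log-spaced values from
  λ_max = max|X̃ᵀỹ|/n down to 10⁻³λ_max. Cross-validation: 5 shuffled
  folds (seeded; a fold with zero outcome variance triggers a logged
  reseed), predictors z-scored and outcome centered on training-fold
  statistics, per-fold MSE curves; SE = SD of fold MSEs/√k; λ_1SE =
  largest λ with CV(λ) ≤ CV(λ_min) + SE(λ_min). The selected support is
  refit by OLS on the *original-scale* columns so the coefficients are in
  retention-% per raw regressor unit (the scale on which the reference
  slope 0.34 lives). An empty selection yields an intercept-only model
  with adjusted R² reported as 0. The regression design has 13 columns
  (condition + 6 EEG features + 6 interactions), while the power analysis
  convention uses 7 regressors (condition + 6 EEG variables); both facts
  are kept as-is.
* Power: the overall F test of a fixed-model multiple regression, with
  noncentrality λ = f²·N and df (p, N − p − 1); the minimal N is found by
  upward scan of the noncentral-F survival function. With p = 7,
  f² = 0.33, α = .05, 1−β = .80 this gives N = 51.

## Problem sizes and determinism

The default test suite and the acceptance script run in well under a
minute of CPU each at the sizes the package ships with: round-trip
fixtures use 20-trial epoch sets (1 kHz for the headline recovery checks,
250–500 Hz in unit tests), the parameter-recovery study uses 20 seeded
replicates of 64-participant cohorts in behavior-only mode, and the
EEG-path integration test uses a 4-participant cohort at 250 Hz. All
randomness flows from explicit integer seeds; identical config + seed
gives byte-identical outputs (epoch container seeds are derived
arithmetically from the run seed, never from process state).

## Known limitations

* The behavioral model has a single state; it cannot express fast/slow
  two-state phenomena (spontaneous recovery, savings).
* ERD recovery tolerances assume the planted envelope's plateau covers
  the peak neighborhood; rhythms whose suppression is much shorter than
  the 1-s analysis window would be underestimated, an inherent property
  of the windowed method rather than of this implementation.
* The FRN model is amplitude-only: no latency variability, no
  peak-to-peak variants.
* The Lasso→OLS chain inherits the usual caveat of post-selection
  inference: the OLS p-values do not account for the selection step.
* No artifact handling: inputs are assumed cleaned.
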