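# vmrlearn

Simulation and inference pipeline for studying **individual differences in
motor learning under reward and punishment feedback**, combining a
visuomotor rotation (VMR) reaching task with EEG-derived neural features.

Human motor adaptation studies of this kind ask: when people learn to
compensate a rotated cursor while earning (or protecting) points, which
neural signatures predict who *learns* more and who *retains* more?
`vmrlearn` provides the full analysis chain as a tested, reusable package:

* a **task simulator** for the 550-trial session — baseline (trials 1–100),
  adaptation with a 30° counterclockwise cursor rotation (101–300),
  no-vision (301–500) and washout (501–550) — including the graded point
  system (reward: 4/3/2/1/0 points for hit/<10°/<20°/<30°/≥30° error;
  punishment: 0/−1/−2/−3/−4; "Slow"/"Fast" movements score the worst bin),
  with totals clipped to [0, 800];
* a **synthetic EEG generator** producing go-cue-locked epochs (−3 to +4 s)
  with planted sensorimotor event-related desynchronization (ERD) and
  feedback-locked epochs (−0.2 to +0.6 s) with a planted feedback-related
  negativity (FRN), both recoverable by the extractors;
* **behavior metrics** — learning amount = θ̄(trials 201–300)/30 × 100 % and
  retention amount = θ̄(trials 301–500)/30 × 100 %, where θ is the
  compensatory reach direction;
* **ERD extraction** — 1-s Hanning sliding-window PSD in 0.1-s steps,
  ERD(f,t) = (R(f) − A(f,t))/R(f) × 100 with reference period −2 to −1 s,
  C3-cluster averaging, per-band (alpha 8–13 Hz, beta 15–30 Hz) peak search
  in the preparatory window (−1 to 0 s) and a ±0.2 s × ±2 Hz window mean;
* **FRN extraction** — mastoid re-referencing, −200–0 ms baseline
  correction, success-minus-failure difference waves at an FCz cluster,
  mean amplitude in 200–350 ms, and ±2 SD group-level outlier exclusion;
* a **statistics layer** — two-way mixed ANOVA with Mauchly's test and
  Greenhouse–Geisser correction, Holm post hocs, pooled t-test, Lasso with
  5-fold cross-validation and the 1SE rule followed by an OLS refit of the
  selected regressors on their original scale, and a noncentral-F
  fixed-model regression power analysis.

The regression design couples them: retention (%) is regressed on the
feedback condition (reward = 1, punishment = 0), six EEG features (FRN,
alpha/beta ERD in early/late adaptation) and the six condition × feature
interactions; the Lasso-1SE step selects sparse predictors and the final
model

```
Y = β₀ + β₁ · (condition × late-adaptation alpha ERD)
```

is the planted ground truth of the synthetic cohort (β₀ = 35.7, β₁ = 0.34
by default).

## Worked example

```bash
vmrlearn all --seed 7 --n-per-group 8 --outdir demo --no-eeg
```

simulates 16 participants (behavior-only mode: EEG features come from the
planted ground truth plus extraction-level measurement noise), assembles
the cohort feature table and runs the inference layer. The report it
printed:

```
total score t-test: t(14) = -0.02, p = 0.988

learning_pct: lasso-1SE selected nothing
  beta[const] = 94.366 (p = 0.0000)
  adjusted R^2 = 0.000 (n = 15)

retention_pct: lasso-1SE selected ['cond_x_alpha_erd_late']
  beta[const] = 32.441 (p = 0.0000)
  beta[cond_x_alpha_erd_late] = 0.384 (p = 0.0080)
  adjusted R^2 = 0.386 (n = 15)

power analysis: 7 regressors, f2 = 0.33, alpha = 0.05, power = 0.8 -> N = 51
```

Reading this: the two feedback groups earned indistinguishable total scores
(t-test); no EEG feature predicts *learning* (the Lasso shrinks everything
to zero); *retention* is predicted by the reward × late-alpha-ERD
interaction, whose fitted slope 0.384 recovers the planted 0.34 — stronger
preparatory alpha desynchronization late in adaptation goes with better
retention, but only when feedback is framed as reward. The power line is
the a-priori design computation: detecting f² = 0.33 with 7 regressors at
80% power needs 51 participants.

Dropping `--no-eeg` runs the full path instead: per-participant epoched
EEG is generated from each participant's planted ERD/FRN values, written
as binary+JSON containers, and the features are re-derived by the spectral
and ERP extractors.

## Layout

```
src/vmrlearn/
  task.py       # schedule, point system, single-state learner, cohort generator
  synth.py      # planted-ground-truth EEG epochs (go-cue and feedback locked)
  eeg.py        # EpochedEEG container + binary/JSON persistence
  behavior.py   # reach direction, phase means, learning/retention amounts
  erd.py        # filtering, re-referencing, sliding-window PSD, ERD features
  frn.py        # baseline correction, difference waves, FRN amplitude, outliers
  stats.py      # mixed ANOVA, Mauchly/GG, Holm, t-test, Lasso-1SE, OLS, power
  pipeline.py   # simulate -> features -> stats orchestration
  cli.py        # vmrlearn simulate | features | stats | all
```

See `docs/methods.md` for the modeling assumptions, parameter choices and
known limitations.
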