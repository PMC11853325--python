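# Methods

This note documents the models, parameter choices and numerical
conventions behind `liftrisk`, and what the synthetic experiments do
and do not demonstrate.

## Lifting equation

The revised NIOSH lifting equation is implemented in its single-task
form.  RWL = LC·HM·VM·DM·AM·FM·CM with the standard load constant
(51 lb / 23 kg) as the default; the demographic variant (men: 25 kg
under 45, 20 kg from 45 on; women: 20 kg / 15 kg) is available as an
explicit mode.  Age exactly 45 falls in the older (lower-constant)
band — the conservative choice.  Only the standard constant reproduces
the experimental tasks' lifting indices of 0.85 and 1.54 exactly.

Multiplier conventions:

* HM = 10/H (in) or 25/H (cm), clamped to 1 below the optimum reach and
  0 beyond 25 in / 63 cm.
* VM = 1 − 0.0075·|V − 30| (in) or 1 − 0.003·|V − 75| (cm), clamped to
  [0, 1], 0 above 70 in / 175 cm.  VM is evaluated at both ends of the
  lift; every other multiplier is shared; the smaller RWL governs.
* DM = 0.82 + 1.8/D (in) or 0.82 + 4.5/D (cm); 1 for travel ≤ 10 in /
  25 cm, 0 beyond 70 in / 175 cm.
* AM = 1 − 0.0032·A, 0 beyond 135°.
* FM is a lookup in the Applications-Manual table (shipped as versioned
  YAML data), keyed by lifting rate, work-duration category (≤ 1 h,
  ≤ 2 h, ≤ 8 h) and vertical band (below/above knuckle height).  Rates
  between table rows round *up* to the next row — the conservative
  direction (smaller multiplier).  Rates below 0.2/min use the 0.2 row;
  above 15/min FM = 0.
* CM: good 1.00; fair 0.95 below knuckle height, else 1.00; poor 0.90.
  The factor is exposed as `coupling_multiplier` with a
  `grab_multiplier` alias, since both names circulate.

A zero multiplier gives RWL = 0; the lifting index is then reported as
`inf` with risk category `high`.  Multipliers are kept at full
precision; RWL and LI are rounded to 2 decimals only for presentation.

Note that the official metric-form constants are rounded relative to
the inch/pound forms (25 cm is not 10 in, 0.003/cm is not 0.0075/2.54,
23 kg is not 51 lb), so the same physical task evaluated in the two
unit systems agrees on LI only to within a few percent (~3% for the
experimental task).  Both systems are implemented exactly as published
rather than forcing consistency.

## Synthetic EMG generator

The generator emulates the acquisition conditions of the experiment:
8 channels at 1259.26 Hz, 20–450 Hz signal band, ~11 mV peak amplitude,
240 s tasks with 20 lifts at 5/min, and two recordings per participant
(low-risk 4.5 kg task, high-risk 8.2 kg task).

Each channel is a sum of three independent band-limited Gaussian noise
processes (surface EMG at this level of analysis is well approximated
by amplitude-modulated interference-pattern noise):

* a **sensor noise floor** (0.02 mV), unscaled by physiology;
* a **tonic (postural) component** — the sustained co-contraction of
  gripping and handling the box between lifts, identical across the
  two tasks (amplitude = `tonic_fraction` × the low-load burst gain,
  default 0.45);
* **lift bursts** — Hann envelopes of 1.5 s at the scheduled lift
  onsets (period 12 s, Gaussian onset jitter sd 0.2 s), with amplitude
  scaled by the load-dependent burst gain (1.0 for the 4.5 kg task,
  1.6 for the 8.2 kg task).

The tonic component matters: without it, windows between lifts (~85%
of stride-50 windows) would carry no label information at all and no
classifier could exceed ~60% window accuracy, contrary to what the
analysis demonstrates on real recordings.  With it, the *relative*
burst-to-tone energy differs between the classes, a contrast that
survives per-recording z-normalization the same way real load-dependent
EMG structure does.  Tying the tonic amplitude to the low-load burst
gain keeps it common to both classes and makes a zero-gain
configuration produce exact silence.

Band-limiting uses a 4th-order Butterworth band-pass applied
forward-backward (zero phase, so burst envelopes are not lagged); each
noise field is rescaled to unit variance after filtering.  The global
amplitude scale is chosen analytically so that the 99.9th-percentile
absolute amplitude of a high-risk recording lands near the configured
11 mV peak (Gaussian tail quantile of the near-peak envelope region;
accurate to ~10–20%, which is all the "≈ peak amplitude" statement
requires).

Per-participant gains (log-normal, sd 0.15) and per-channel gains
(log-normal, sd 0.10) are drawn once per participant and shared by both
of that participant's recordings.  Effect size and gain spreads are
exposed as configuration, not claimed as measured values; the 1.6 gain
ratio is the default study condition and produces high but non-trivial
class separation.

What the generator does **not** model: motor-unit physiology, fatigue
drift within a session, electrode lift-off artifacts, power-line
interference, inter-muscle correlation structure, or any systematic
spectral difference between loads.  Passing tests on this surrogate
show the pipeline's statistical machinery is correct and that
load-scaled amplitude structure is recoverable; they do not certify
classifier performance on real recordings.

## Preprocessing and features

Recordings are stored in an 11-column CSV (`Participant, EMG_Time,
Sensor 1…8, Risk`), one row per sample; a leading sampling-frequency
line is tolerated and skipped on read.  Reading uses round-trip float
parsing, so write→read is lossless (timestamps preserved to < 1e-9 s).

Normalization is per-recording-per-channel z-scoring by default,
x ← (x − μ)/σ with the population σ.  Per-window scoping is available
but degenerate: it forces every window's mean to 0 and σ/RMS to 1,
nullifying three of the twelve features.

Windows are 400 samples (≈ 0.32 s at 1259.26 Hz), indexed by 0-based
start sample, half-open, never crossing a recording boundary.  Stride
is a first-class parameter: the published analysis uses stride 1
(~ 300 k windows per recording); the desk-scale default here is
stride 50, which preserves the statistical structure (windows still
overlap 87.5%) at 1/50 of the cost.

The 12 per-window statistics use population (1/n) moments throughout.
Kurtosis is non-excess (Gaussian → 3).  Crest factor uses max|x| in the
numerator so negative-dominated windows are well-defined; shape factor
is RMS over the mean of |x| (the mean itself is ≈ 0 for zero-mean EMG
and would make the ratio explode).  Degenerate windows (σ = 0 or
RMS = 0) yield zeros for the affected ratio features, flagged via a
warning and a table attribute, never NaN.  The feature table is
96 feature columns (Sensor 1 block first) plus Participant, EMG_Time
(window start) and Risk — 99 columns.

## Classifiers

Three small architectures, all ending in a single sigmoid unit and
trained with binary cross-entropy:

* MLP: dense 64 → 32 → 16, ReLU.  (The middle width of 32 is a design
  choice; only the 64→…→16 progression is fixed.)
* 1-D CNN: Conv1D with 32 filters, kernel 3, ReLU → max-pool width 2 →
  flatten → dense 64 → 16 → 1.  Input is the 96-vector as a 96-step ×
  1-channel sequence (a 12 × 8 feature-by-sensor layout is available).
* LSTM: 32 recurrent units (forget-gate bias 1) → dense 16 → 1.

The networks are implemented on a small seeded numpy backprop core
(`liftrisk._nn`) with Glorot-uniform initialization, Adam
(lr 1e-3, batch 512), at most 50 epochs and early stopping on a 10%
validation split (patience 5, best weights restored).  Training is
bit-identical under a fixed seed.  Gradients of every layer are
verified against central finite differences in the test suite.

Features are standardized with training-split statistics only.  The
default split is row-wise stratified 80/20 over windows, which — with
heavily overlapping windows — leaks information between train and test
exactly as the published analysis does; a grouped-by-participant split
is provided for honest generalization experiments.

## Evaluation

Positive class is high risk (label 1); this is the only convention
under which the published CNN confusion matrix reconciles with its
reported metric column, and the test suite verifies all five metrics
simultaneously from those counts.  Zero-denominator conventions:
precision/recall/F1 are 0 (flagged) when undefined; MCC is 0 (flagged)
when any factor of its denominator vanishes.  ROC-AUC is computed by
midrank statistics (tie-corrected Mann–Whitney) and is checked against
all-pairs counting and trapezoidal integration of the ROC curve.
Rendered reports show percentages at 2 decimals; machine-readable
outputs keep full precision.

## Problem sizes and determinism

The default experiment simulates 6 participants (12 recordings,
302,222 samples each), yielding 72,444 stride-50 windows; the test
suite uses this cohort for classifier-recovery checks and smaller
cohorts (2 participants, 30–60 s tasks) elsewhere.  Every random draw
flows from explicit `numpy.random.Generator` seeds; a pipeline run
directory contains the config snapshot and seed needed to replay it
bit-identically.

## Known limitations

* Single-task RNLE only: no composite or variable lifting index, no
  3-D posture estimation.
* The surrogate EMG is statistically, not physiologically, realistic
  (see above); absolute classifier accuracies on it should not be read
  as predictions for laboratory data.
* The LSTM treats the 96 standardized features as a sequence, which
  carries no genuine temporal structure; it trains noticeably slower
  and to lower accuracy than the other two architectures, consistent
  with its role as the weakest model in this analysis.
* No frequency-domain features or feature selection: the feature set is
  fixed at the twelve statistics by design.
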