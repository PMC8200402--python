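# Methods

This note documents the models, parameter choices and numerical conventions
behind `neobg`, in the order data flows through the pipeline.

## Synthetic EEG generator

The generator exists so the classification system can be developed and
tested end-to-end without clinical recordings. It realizes the seven-grade
scoring definitions generatively:

* **Carrier.** Band-limited (0.5–30 Hz) coloured noise with spectral
  exponent α = 1.2 (power ∝ 1/f^α), a canonical EEG-like spectrum. Each
  channel draws an independent carrier.
* **Amplitude convention.** Envelope values are peak-to-peak targets in µV.
  The carrier is scaled to RMS = env/5 and hard-clipped at ±env/2. The
  clipping makes the class bounds strict (a "< 5 µV" grade never exceeds
  5 µV peak-to-peak) while the realized 95th-percentile 2-s-window
  peak-to-peak amplitude tracks the requested envelope within 10 %.
* **Discontinuous grades (1, 2, 3, 5).** A burst gate alternates IBI and
  burst plateaus with raised-cosine edges (0.25 s). Durations are gamma
  distributed (shape 8, configured means), giving realistic variability
  with a well-defined mean IBI duration. All channels share the gate —
  background state is global — with independent carriers. Default
  parameters (configurable): TA grades use 35 µV IBIs (means 4 s / 9 s for
  grades 1 / 2) under 100 µV bursts; tracé discontinu 12 µV IBIs; burst
  suppression 2 µV IBIs under 60 µV, 2 s bursts.
* **Amplitude grades (0, 4, 6).** A slow (0.02–0.1 Hz) sinusoidal
  modulation sweeps the envelope across the configured range: 25–50 µV for
  continuous activity (the clinical table gives no number for grade 0; this
  default is a configurable convention), 6–14 µV for the depressed grade,
  1.5–4 µV for very low voltage.
* **Recordings.** Trajectories are sequences of (score, duration) segments
  (multiples of 5 min). Internal segments are generated with a 10 s tail and
  joined by raised-cosine overlap-add, so the total duration is exact and
  transitions are smooth. The ground-truth label of an epoch is the class
  occupying the majority of it (with aligned segment boundaries, all of it).
* **Artifacts.** Poisson events at a configured rate/hour: high-amplitude
  sine-squared pulses (620–900 µV peak, 0.5–2 s) and flat (constant-value)
  runs of 2–10 s.
* **Simulated experts.** Two independent raters are derived from the truth
  by flipping an epoch to a neighbouring grade with probability 0.10 and
  rejecting it with probability 0.02 — mimicking the neighbouring-score
  disagreement pattern of human scorers. These feed the CONS/ALL machinery.
* **Determinism.** One master seed per recording; every stage derives child
  seeds through a CRC-stable SeedSequence helper.

What the simulation does *not* capture: sleep graphoelements and state
cycling, seizures, spatially heterogeneous (focal) abnormalities, electrode
artifacts with realistic spectra, inter-subject amplitude variability, and
rater bias (one expert systematically scoring lower). Passing tests
therefore demonstrate that the machinery is correct and recovers
well-separated classes — not that clinical-grade accuracy transfers to real
neonatal EEG.

## Preprocessing

Fixed order: artifact scan → band-pass → resample → epoch → rejection.

* Artifact scan runs at the native rate (thresholding after filtering would
  blur true amplitudes): |x| > 500 µV (strictly greater — "exceeding" read
  as strict), constant-valued runs ≥ 1 s, and NaN samples. The mask is
  carried to 64 Hz by nearest-sample mapping.
* Band-pass: 5th-order Chebyshev type II with stopband edges 0.25/40 Hz and
  40 dB attenuation (the realized passband is 0.5–35 Hz), applied
  forward-backward (`sosfiltfilt`) for zero phase. Tests assert against the
  realized frequency response, not the nominal one.
* Resampling to 64 Hz uses a polyphase anti-aliasing filter; output length
  is round(n·64/fs). 300 s at any supported rate gives exactly 19,200
  samples.
* Rejection: a channel is rejected in an epoch when ≥ 25 % of its samples
  are masked; an epoch when ≥ 50 % of channels are rejected. Thresholds are
  arguments (the selection sweep uses 0/10/25/50 %). A threshold of 0 is
  interpreted as "reject on any artifactual sample" — a literal "≥ 0 %"
  would reject clean channels too.
* Retained channels keep all samples; rejection is all-or-nothing per
  channel per epoch.

## Feature bank (98 features)

Features are computed per channel on each 5-min epoch and pooled across
non-rejected channels with the median; synchrony features are computed on
channel pairs and pooled over pairs. Six categories: amplitude (20),
spectral (34), modulation (10), discontinuity (12), complexity (16),
synchrony (6). Five anchor features widely reported as informative for
background grading are present under stable ids: the mean and SD of the
amplitude modulation (`am_mean`, `am_sd`), the activation synchrony index
(`asi`), the multiscale-entropy slope (`mse_slope`) and 9–11 Hz band power
(`bp_9_11`).

Parameterizations that matter:

* **Spectra.** Welch periodogram, 8 s Hann windows, 50 % overlap (0.125 Hz
  resolution — enough to resolve the 2 Hz-wide 9–11 Hz band). Band power is
  the PSD integral over the half-open band [lo, hi).
* **Amplitude modulation.** Magnitude of the analytic signal, low-pass
  smoothed at 1 Hz (4th-order Butterworth, zero phase).
* **rEEG.** Peak-to-peak in non-overlapping 2 s windows.
* **Discontinuity.** A short-window peak-to-peak envelope (0.5 s windows,
  0.25 s step) feeds suppression ratios (fraction of time below 5/10/15/25
  µV) and interburst statistics: IBIs are runs below 25 µV lasting ≥ 1 s;
  the per-IBI voltage is the lower-quartile envelope over the run (robust to
  burst ramps at the edges), summarized by its 95th percentile across IBIs.
* **Entropies.** Sample entropy (m = 2, r = 0.15·SD, Chebyshev distance,
  template pairs i < j, `-ln(A/B)`), approximate entropy (self-matches
  included), and the multiscale curve over coarse-graining scales 1–20 with
  r fixed from the original series' SD. Entropy measures use the first
  1,800 samples (28.1 s) of the epoch — the analysis segment that keeps the
  O(n²) template matching tractable while scale 20 still retains 90 coarse
  samples. The slope is the least-squares fit of entropy vs scale.
* **ASI.** The activation synchrony index is parameterized here as the phi
  coefficient (Pearson correlation of binary indicators) of the two
  channels' smoothed envelopes, each binarized at its own 75th percentile.
  It is symmetric, 1 for identical channels, and defined as 0 when either
  envelope is degenerate (constant).
* **Scaling metadata.** Every registry entry declares its response to a
  signal gain (linear / quadratic / invariant / threshold-dependent), and a
  property test enforces the declaration at gains 0.5× and 2×.
* **Missing values.** Rejected epochs (or all channels rejected) yield NaN
  with a missing flag; imputation happens at classification time using
  training-fold feature medians, keeping LOSO leakage-free.

## Labels

* 7→5 merger: {0,1,2}→0, 3→1, 4→2, 5→3, 6→4; REJECT passes through.
* Smoothing: centred running median over non-REJECT neighbours; shrunken
  windows at the edges; REJECT positions are never overwritten. The median
  of an even count of ordinal values takes the lower middle value so the
  output is always a valid grade. Defaults: window 5 for annotations,
  window 7 for classifier output (both arguments). The pipeline order is
  fixed as merge → smooth.
* CONS keeps epochs where both raters agree (excluded if either rejects);
  ALL emits one row per rater per gradable epoch, so consensus epochs carry
  twice the weight (duplication, equivalent to weight 2).
* Hierarchies (three level-1 groups each): severity = normal {0,1,2} /
  moderate {3,4} / severe {5,6}; continuity = continuity-defined normal
  {0,1,2} / discontinuous {3,5} / amplitude-defined {4,6}. Both maps are
  configuration keys, since reasonable clinical groupings differ.
* SMOTE: minority classes oversampled to the majority count; each synthetic
  row is a convex combination of a minority row and one of its k = 10
  nearest minority neighbours (k capped at class size − 1). Implemented on
  sklearn's NearestNeighbors.

## Classifiers

All designs consume z-scored features (population SD, training fold only;
constant features are centred with a warning).

* **SVM.** One-vs-one error-correcting ensemble: K(K−1)/2 linear SVMs
  (sklearn SVC), each calibrated by a Platt sigmoid (logistic fit on
  training decision values), coupled to a multiclass posterior by the
  Wu–Lin quadratic method (KKT linear system per row; rows sum to 1
  exactly). The regularization strength C is tuned by Bayesian optimization
  — Gaussian process (Matern 5/2) with expected improvement over log₁₀C ∈
  [−3, 3], 30 evaluations by default — against an internal five-fold
  cross-validation grouped by subject.
* **MFNN.** Linear input, two tanh hidden layers (default 30/15,
  configurable — the optimum is data-dependent), tanh output; class
  probabilities are the softmax of the output activations. Training:
  full-batch gradient descent on the mean-squared error against ±1 one-hot
  targets, momentum 0.8, LR starting at 0.1 and multiplied by 0.25 after
  every 6,000 iterations (a repeating schedule); stops at 120,000
  iterations, train RMSE < 10⁻³, or no inner-validation improvement (10 %
  holdout, checked every 200 iterations, patience 25 checks).
* **RNN.** The second hidden layer receives its previous activation through
  a recurrent matrix with a one-epoch delay. Forward weights initialize
  from the trained MFNN; recurrent weights start N(0, 0.01²). Training is
  Real-Time Recurrent Learning: exact online sensitivities of the recurrent
  state are carried for the recurrent-layer parameters (W2, b2, Wr); the
  input and output layers use instantaneous gradients (sensitivity
  propagation truncated at the recurrent state — a deliberate trade of
  exactness for O(1) memory in the first layer). Per-class learning rates
  scale inversely with class frequency (base 10⁻³ × mean-count/count), the
  recorded interpretation of class-distribution-dependent fine-tuning. The
  hidden state resets at subject boundaries, so subject order is
  irrelevant.
* **Hierarchical mode.** A level-1 classifier over the three groups and a
  level-2 classifier within each group; the posterior is P(group) ×
  P(score | group) (law of total probability; single-score groups
  contribute their group mass directly). The RNN supports only the flat
  approach, since grouping disrupts the epoch sequence.
* **LOSO.** One fold per subject. Inside each training fold only:
  training-set construction (CONS/ALL), median imputation, z-scoring,
  SMOTE, hyperparameter search. Fold seeds derive deterministically from
  the master seed. Results are exposed as a `LosoResult` with per-subject
  posteriors, raw and smoothed predictions, references (consensus/E1/E2),
  provenance for leakage assertions, and a `summary()` table.

## Feature selection

GA wrapper over bitmask chromosomes: fitness-proportional (roulette)
selection with elitism 1, two-point crossover at rate 0.6, per-gene
mutation at rate 0.1, population 100, termination at 50 generations or
5,000 fitness evaluations (whichever first; evaluations are memoized, so
the budget counts unique subsets; the budget applies per threshold).
Fitness is the inner five-fold subject-grouped CV accuracy of a fixed-C
linear SVM on the masked features — a full LOSO inside the GA would be
cost-prohibitive. Chromosomes initialize at Bernoulli(0.3) so subset sizes
vary; all-zero chromosomes are repaired to a random single feature. The
threshold sweep re-runs rejection and the GA at channel thresholds
{0, 10, 25, 50} % and calls a feature *robust* when more than half of the
final population carries it at every threshold.

## Evaluation

* Cohen's κ = (pₒ − pₑ)/(1 − pₑ) with chance agreement from the marginals;
  when pₑ = 1, κ is defined as 1 if pₒ = 1 and 0 otherwise.
* Macro scores average over classes unweighted; weighted scores use
  reference support. A class absent from both series contributes 0 to the
  macro average, with a warning.
* All metrics exclude REJECT pairs symmetrically.
* Bootstrap CI₉₅: percentile method, 1,000 resamples of epochs with
  replacement, seeded. Epoch-level resampling is the default (subject-level
  is a coarser option); degenerate metrics give lo = point = hi.
* The composite-agreement report computes pairwise κ between both experts
  and the classifier and flags non-inferiority when the classifier agrees
  with each expert at least as well as the experts agree with each other.

## Visualization

The heatmap shows per-epoch score probabilities (severity-ordered rows)
through the monotone "hot" colormap, optionally renormalized per epoch;
REJECT epochs get a neutral grey. The Background Trend is the
probability-weighted mean class value, smoothed by a 3-epoch moving average
(shrunk at edges); its uncertainty band is the probability-weighted SD of
the class values — zero exactly for one-hot posteriors. The band definition
is a package convention (an inter-quantile alternative is configurable); on
the 5-score scale class values are {0..4} in severity order, kept linear
even though the depressed grade sits awkwardly on a one-dimensional scale.
SVG output is deterministic (fixed hash salt, no timestamps).

## Problem sizes used in tests and the acceptance script

The cohort experiment uses 10 subjects × 3 h × 4 channels (F3, F4, P3, P4 —
a typical restricted NICU montage) at 256 Hz native rate, with two
simulated raters, the flat SVM, ALL mode, the 5-score scheme and both
smoothing stages; the GA recovery experiment uses a planted
5-informative/93-noise dataset over 10 subjects with a reduced GA budget
(population 30, 15 generations, 10 seeded runs). These sizes keep a full
run in minutes on one CPU while exercising every pipeline stage.

## Known limitations

* The 98-feature registry fills the published category structure with the
  standard neonatal qEEG canon; exact numeric equivalence with any specific
  closed-source feature implementation is a non-goal.
* The ASI and the BT uncertainty band are documented parameterizations of
  ideas whose original constants are not public.
* The RNN's RTRL is exact only for the recurrent layer's parameters.
* Synthetic-data performance overstates clinical performance by
  construction; the generator's classes are cleanly separated.
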