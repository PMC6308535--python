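# Methods

This note documents the models, conventions and design choices behind
`harsel`, in the spirit of a package methods appendix.  Nothing here
states an empirical result that the test suite or `scripts/acceptance.py`
does not itself compute.

## Synthetic cohort model

The generator (`harsel.synth`) emulates the *structure* of a thigh-worn
MIMU study — 61 subjects × 7 activities × 5 repetitions × 60 s at
80 Hz — not the biomechanics of human gait.  Its purpose is to give the
downstream pipeline inputs with the statistical properties the method
assumes:

* **Static activities.**  Resting (A1) places gravity mostly off the
  vertical axis (mean vertical acceleration ≈ 0.3 m·s⁻²); standing (A2)
  places +9.81 m·s⁻² on the vertical (y) axis plus low-amplitude postural
  sway (≤ 0.15 m·s⁻², ≤ 0.5 Hz).  Gyroscope channels carry only sway and
  noise (sd 3 deg·s⁻¹ × subject multiplier), so the gyro-z variance is
  ~10–20 (deg·s⁻¹)², two orders of magnitude below the 600 rule
  threshold, while the acc-y means (≈ 0.3 vs ≈ 9.81) straddle the
  8.5 m·s⁻² boundary with wide margins.  The rule-separability guarantee
  is therefore by construction and holds for every seed (verified over a
  100-seed sweep in the acceptance tests).
* **Dynamic activities.**  A3–A7 are sums of 2–3 harmonics of a
  per-subject cadence (fundamental drawn uniformly from 1.4–2.2 steps/s,
  inside the admissible 1.2–2.5 range) on acc-x, acc-y and gyro-z, with a
  per-activity table of amplitudes, antero-posterior bias and gyro-z
  phase asymmetry: stairs have larger vertical amplitudes and stronger
  gyro-z asymmetry (opposite phase signs for up vs down), incline walking
  has a signed acc-x bias (+2.5 m·s⁻² uphill, −2.5 downhill) and distinct
  cadence factors (0.80–1.05 of the subject's cadence).  Gyro-z harmonic
  amplitudes (90–150 deg·s⁻¹) put the window variance in the thousands,
  far above 600, for the whole subject amplitude range (0.8–1.2×).
* **Noise** is additive i.i.d. Gaussian per channel (acc sd 0.10 m·s⁻²,
  gyro sd 3 deg·s⁻¹, scaled by a per-subject multiplier 0.7–1.3) — the
  simplest testable choice.  Magnetometer channels are generated (a
  constant field direction plus noise) but excluded from all features,
  mirroring an inertial-only analysis.

Determinism: each recording is a pure function of (profile, activity,
duration, rate, seed); cohort recordings derive their seeds from the
cohort seed and the (subject, activity, repetition) triple, so streams
are reproducible and order-independent.

What the generator does **not** model: stride-to-stride variability,
orientation drift, soft-tissue artefacts, double support, asymmetric
pathological gait, sensor saturation.  Consequently, a high end-to-end
accuracy on synthetic cohorts demonstrates that the pipeline's plumbing,
selection pressure and decoders work — it says nothing about accuracy on
real recordings.

## Segmentation, split, scaling

* Windows are 5 s with 3 s overlap (step 2 s), anchored at sample 0 of
  each recording; the incomplete tail is discarded and windows never
  cross recording boundaries (count = ⌊(n − m)/step⌋ + 1, giving 28 per
  60-s recording and 59,780 for the full design).
* The training set samples round(0.10 × stratum) windows (minimum 1) per
  (subject, activity) stratum without replacement; the validation set is
  the *entire* window pool, training rows included.  With the full
  design's 42,700 dynamic windows this yields exactly 4,270 training
  rows.  The training draw is taken from dynamic windows only, since the
  static classes never reach the learner.
* Min–max scaling parameters are learned on training rows only
  (delegated to scikit-learn's `MinMaxScaler` for the fit); validation
  values outside the training range are deliberately not clipped, and
  constant features map to 0 with a warning.

## Feature conventions

Choices the descriptor definitions leave open are fixed as follows (all
configurable where noted):

* **Moments** are population (biased) estimators; kurtosis is Pearson's
  (normal → 3), not excess-adjusted.  Skewness/kurtosis of a constant
  signal are 0 (0/0 convention).
* **Autocorrelation**: biased estimator normalized so lag 0 would be 1;
  lags 1–10 are reported (lag 0, trivially 1, is uninformative).
* **Spectra** come from the periodogram of the mean-removed window — the
  simplest estimator at 400 samples.  Median frequency is the first bin
  where cumulative normalized power reaches 0.5; entropy uses log₂ over
  strictly positive PSD bins.
* **Wavelets**: Daubechies-4 with symmetric padding (configurable), a
  single-step cascade keeping the approximation *and* detail norms at
  every level 1–7 — the only reading that yields 14 values.
* **Zero crossings / peaks**: the window mean is subtracted first
  (default, toggleable) — raw vertical acceleration rides on gravity and
  would never cross zero otherwise.  Crossings are strict sign changes;
  exact zeros inherit the previous sign.  Peaks exist only between two
  consecutive crossings (boundary segments are excluded); time-to-peak is
  measured from the segment's leading crossing.  Empty peak categories
  contribute 0 to all their statistics, keeping the vector width fixed;
  peak-statistic standard deviations are population form (one event →
  0).
* **Integration**: cumulative trapezoid, zero initial condition, mean
  removal before the first integration only; no further drift
  correction.

## Classifier decoding

* KNN: Kin = round(√N); the 5-bit code indexes {Kin−16 … Kin+15}, clipped
  to ≥ 1 (always 32 entries).  At N = 4270 the grid spans 49–80.
* FNN: first hidden layer one neuron per selected feature, the 3-bit
  code adds 1–8 layers, each round-half-up(previous/2) with floor 1;
  sigmoid hidden units, one linear output, prediction =
  round-half-up(output) snapped into the trained classes.  Training uses
  scikit-learn's `MLPRegressor` with a fixed seed and epoch budget
  (default 200) — reproducibility is preferred over fidelity to any
  particular unstated training regime.
* SVM: 2-bit kernel table frozen as {00 linear, 01 gaussian, 10 poly2,
  11 poly3}; C = 0.5, 1, or (value−1)·10 from the 4-bit value.  The
  gaussian kernel scale s (γ = 1/s²) is not part of the codification; it
  is a configuration scalar, default 10.  Multiclass is an explicit
  one-vs-one bank — k(k−1)/2 binary machines, majority vote, ties broken
  by summed decision margins and then the smallest class code.  The
  number of machines follows the training labels (21 for 7 classes, 10
  for the 5 dynamic classes).
* DT: CART with Gini impurity, grown until pure; no parameter bits.

## Genetic algorithm

* Fitness is evaluated on the validation table exactly as configured by
  the caller (the study protocol scores on the full pool; an honest
  held-out table can be passed instead).  A chromosome selecting zero
  features is assigned the worst possible fitness, 1.3, without
  training.
* Roulette selection on a minimized fitness uses weights
  (worst − fitness + 10⁻⁹), preserving "better fitness → strictly higher
  probability"; ε keeps the worst individual selectable.
* Each generation forms population/2 couples producing population
  children by 4-point crossover (probability 1); on problems whose
  chromosome is too short for 4 interior cuts the cut count drops to
  length − 1.
* **Mutation is per-individual**: with probability 0.2 exactly one
  uniformly chosen bit flips.  A per-bit mode exists, but a 0.2 per-bit
  rate on a ~230-bit chromosome would randomize ~46 bits per child and
  destroy convergence; the per-individual reading is the one consistent
  with calling 0.1–0.2 a "very low" rate.
* Survivor selection is elitist truncation of parents ∪ children to the
  population size, which makes the best-so-far fitness monotonically
  non-increasing (a tested invariant).  Stopping: 30 iterations or 15
  without improvement (defaults).
* Fitness evaluations are cached by bit-string; since every back-end is
  trained with a fixed seed, re-evaluating the returned best chromosome
  reproduces its stored fitness exactly (tested).

Library defaults (population 400, 30 iterations) correspond to an
overnight-run regime.  The test and acceptance configurations are
deliberately smaller — population 40 × 15 generations for the
planted-feature recovery study, population 20 × 6 for the end-to-end
run — sizes at which the studied properties are already stable.

## Post-processing and metrics

Majority voting assigns the modal label to consecutive non-overlapping
groups of five windows *within* one recording (never across recordings);
the trailing partial group votes over its own members; ties go to the
smallest activity code.  Block (not sliding) voting is the default, a
sliding variant being intentionally out of scope.

Overall accuracy is the unweighted (macro) mean of per-activity
accuracies, making it invariant to class-size imbalance; precision and
recall are one-vs-rest per class, macro-averaged, and combined into
F1 = 2PR/(P+R).  The micro average (plain fraction correct) is reported
alongside.  The paired two-tailed Student t-test for comparing two
feature sets across subjects is implemented directly (verified against
both the textbook formula and `scipy.stats.ttest_rel`) so that the
degenerate cases have defined conventions: identical vectors → (t = 0,
p = 1); zero-variance nonzero differences → (±∞, 0).

## Known limitations

* The synthetic cohort is far easier than real recordings: classes are
  periodic, stationary within a recording, and separable by construction.
* The FNN back-end is the least faithful component: its training
  algorithm, epochs and initialization are necessarily choices of this
  package, fixed for reproducibility.
* Fitness evaluated on a validation pool that contains the training rows
  (the configured protocol) is optimistically biased; pass a disjoint
  validation table for honest estimates.
* The 600 threshold is applied to a variance computed from deg·s⁻¹
  samples; its nominal unit is then (deg·s⁻¹)², and the number itself is
  treated as authoritative.
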