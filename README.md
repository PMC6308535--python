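# harsel

Human activity recognition (HAR) from wearable inertial sensors, built
around joint feature selection and classifier tuning with a genetic
algorithm.

## The problem

A thigh-worn inertial measurement unit streams tri-axial acceleration
(m·s⁻²) and rate of turn (deg·s⁻¹) at 80 Hz while a subject performs one
of seven everyday activities: resting (A1), upright standing (A2), level
walking (A3), ascending/descending stairs (A4/A5), and uphill/downhill
walking (A6/A7).  The classification unit is a 5-s window with 3-s
overlap.  Two competing window descriptor sets are supported:

* **FeatSet_A** — 222 features widely used in the HAR literature: per
  channel 20 time-domain statistics (moments, percentiles, the first ten
  autocorrelation lags), 3 spectral features (mean/median frequency,
  Shannon spectral entropy) and 14 wavelet-band norms (approximation and
  detail coefficients at seven DWT levels).
* **FeatSet_B** — 221 time-domain features with direct biomechanical
  meaning: zero-crossing counts, counts/durations/times-to-peak of the
  positive and negative peaks between consecutive zero crossings, and
  descriptors of integrated signals (velocity and displacement proxies).

The pipeline first separates static from dynamic windows with two fixed
rules (gyro-z variance < 600 → static; then mean vertical acceleration
< 8.5 m·s⁻² → resting, else standing).  Dynamic windows go to a machine
learning stage whose feature subset **and** hyperparameters are chosen
simultaneously by a genetic algorithm (GA): each chromosome is a binary
feature mask concatenated with a parameter substring (KNN 5 bits, FNN 3,
SVM 6, DT 0), and fitness (lower = better) is

```
fitness = 1 − acc + 0.3 · (max_a acc_a − min_a acc_a)
```

with `acc` the overall validation accuracy and `acc_a` the per-activity
accuracies — the second term penalizes class imbalance.  Selection is by
roulette wheel, crossover uses four random cut points, mutation flips one
bit per selected individual, and survivor selection is elitist.  Decoded
back-ends: K-nearest neighbours over a 32-value grid around √N, a
sigmoid-hidden/linear-output feedforward net with halving layer widths, a
one-vs-one SVM bank (k(k−1)/2 binary machines, majority vote with margin
tie-break) with C ∈ {0.5, 1, 10, …, 140} and four kernels, and a fully
grown CART/Gini decision tree.  Window predictions are finally smoothed
by majority voting over groups of five consecutive windows, and scored by
per-activity accuracy, macro accuracy, and F1 = 2PR/(P+R).

No public recordings accompany the original study design, so the package
ships a seeded synthetic MIMU generator (`harsel.synth`) that emulates
the cohort structure — 61 subjects × 7 activities × 5 repetitions × 60 s
— with static/dynamic separability and five distinguishable periodic
dynamic classes.  It is a statistical stand-in, not a gait model; see
`docs/methods.md`.

## Worked example

```python
from harsel import RunConfig, run_experiment
from harsel.ga import GaConfig

config = RunConfig(
    n_subjects=3, reps=2, classifier="dt", feature_set="B", seed=1,
    ga=GaConfig(population_size=10, max_iterations=3, plateau_patience=3, seed=1),
)
report = run_experiment(config)
print(report)
```

prints

```
activity  accuracy
  A1        1.0000
  A2        1.0000
  A3        1.0000
  A4        0.9702
  A5        1.0000
  A6        1.0000
  A7        1.0000
overall (macro) 0.9957
precision 0.9959  recall 0.9957  F1 0.9958
```

The two static activities are recognized perfectly by the rule stage
(their windows never reach the classifier), and the GA-tuned decision
tree recognizes the five dynamic gait classes from the biomechanical
features; per-activity accuracies, their macro mean, and the
macro-averaged precision/recall/F1 summarize the confusion structure
after majority voting.

The same stages are scriptable from a shell:

```bash
harsel simulate --subjects 2 --reps 1 --seed 3 --out recs/
harsel rules --recordings recs/ --out rules.csv
harsel segment --recordings recs/ --featset B --out features.csv
harsel optimize --features features.csv --classifier svm --out ga.json
harsel run --config config.yaml --seed 1 --out results/
```

Estimator-style entry points (`GASearchClassifier`,
`FeatureSetAExtractor`, `FeatureSetBExtractor`, `StaticRuleClassifier`)
follow scikit-learn conventions (`fit`/`predict`/`transform`,
`get_params`, trailing-underscore fitted attributes) and compose with
sklearn tooling.

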