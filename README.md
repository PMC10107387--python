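# pretermsig

Preterm-vs-term labour prediction from physiological signals recorded
during active labour: electrohysterogram (EHG) contraction envelopes and
maternal/foetal beat-to-beat RR interval series.

The package is aimed at biomedical-signal researchers who want a tested,
fully reproducible implementation of this analysis style: an
amplitude-threshold decomposition learner (LSDL) that selects the most
class-discriminative part of each signal, a 20-dimensional EMG-style
feature ensemble, SMOTE class balancing, an eight-classifier supervised
comparison, and a two-cluster unsupervised evaluation. Because clinical
labour recordings are rarely shareable, the package ships a synthetic
cohort generator that reproduces the statistical structure such cohorts
report (contraction burst rates for active labour, maternal RR
431.2 ± 31.0 ms term vs 413.2 ± 26.9 ms preterm, foetal baseline
110–170 bpm), so every stage is testable end to end without any data
download.

## The method

**LSDL.** For a reference amplitude *A* (the maximum |x| over the training
windows), candidate rules excise one dyadic amplitude band per
(region, iteration) pair: the *lower* region at iteration *i* retains
samples with |x| ≤ A·(2ⁱ−1)/2ⁱ, the *upper* region retains |x| ≥ A/2ⁱ,
with four iterations per region. Each candidate's decomposed windows are
featurized and scored by the separability cost

    J = ED(p, q) / σ_m

where *p*, *q* are the per-class mean feature vectors, ED their Euclidean
distance, and σ_m the mean over features of the per-feature population SD
across the pooled windows of both classes. The band maximising J is the
fitted decomposition rule, applied to every window before modelling.

**Features (20 per window).** MAV, WL, ZC, SSC, RMS, order-4 Burg AR
coefficients, sample entropy (m = 2, r = 0.2·SD), four AR-derived cepstral
coefficients, maximum fractal length, median and peak frequency, number of
peaks, simple squared integral, and variance. Threshold-bearing features
use 1 µV for EHG and 0 for RR series.

**Models.** DT, LDA, LR, linear/quadratic/cubic/fine-Gaussian SVM, and
1-NN (Euclidean), each evaluated with stratified 10-fold cross-validation
and SMOTE balancing inside training folds; metrics are pooled Acc, Sens,
Spec and AUC (preterm positive). Unsupervised: K-Means and a
full-covariance Gaussian mixture (regularisation 0.1), two clusters, best
of five restarts, scored by per-class accuracies and their truncated
macro-average.

## Worked example

`python examples/classify.py` fits the LSDL on a synthetic EHG cohort
(14 term / 10 preterm patients, 10 windows each) and compares the eight
classifiers on raw vs decomposed features:

```
Model  Raw-Acc (%)  LSDL-Acc (%)  Raw-Sens (%)  LSDL-Sens (%)  Raw-Spec (%)  LSDL-Spec (%)  Raw-AUC (%)  LSDL-AUC (%)
   DT         74.6          75.8          69.0           75.0          78.6           76.4         73.8          75.7
  LDA         79.2          82.5          66.0           67.0          88.6           93.6         85.6          85.9
   LR         76.2          79.6          70.0           72.0          80.7           85.0         82.9          85.5
 LSVM         77.1          79.6          72.0           69.0          80.7           87.1         83.2          85.8
 QSVM         78.8          85.8          67.0           79.0          87.1           90.7         85.5          89.2
 CSVM         81.7          85.8          73.0           81.0          87.9           89.3         87.1          90.6
FGSVM         70.4          69.2          40.0           35.0          92.1           93.6         79.7          82.5
  KNN         75.0          77.1          69.0           69.0          79.3           82.9         79.8          82.9

mean accuracy: raw 76.6%, LSDL 79.4%
```

Each row pairs one classifier's pooled 10-fold metrics on untouched
windows (Raw) and on windows decomposed by the fitted amplitude band
(LSDL). On this cohort the fitted rule is a lower-region band that excises
the artifact-occupied top of the amplitude range, which lifts most models
by a few points — the qualitative benefit the decomposition is designed to
deliver. The other scripts under `examples/` walk through cohort
generation, LSDL fitting, feature extraction, clustering, and the
one-config end-to-end experiment (`full_experiment.py`), whose outputs are
byte-identical across re-runs with the same master seed.

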