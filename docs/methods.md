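# Methods

## Problem setting

Women in active labour (≥ 4 distinct uterine contractions per 10 minutes)
are monitored with abdominal electrodes: the electrohysterogram (EHG)
captures uterine electrical activity, and beat-to-beat RR interval series
capture maternal (MHR) and foetal (FHR) heart-rate variability. The task
is a binary prediction — term (38–40 weeks) vs preterm (32–36 weeks)
delivery — from per-window feature vectors of these signals. Clinical
recordings of this kind are not publicly deposited, so the package pairs
the analysis pipeline with a synthetic cohort generator that reproduces
the cohort-level statistics the analysis assumes; everything downstream is
agnostic to whether records come from the generator or from delimited text
files of real exports.

## Synthetic cohort generator

**EHG envelopes.** The analysis consumes the contraction *envelope* — the
2-second epoch average of the absolute 900 Hz signal — so the generator
works directly at envelope scale (0.5 Hz). An envelope is rectified
Gaussian baseline noise (SD 1.5 µV) plus Gaussian-windowed contraction
bursts (σ ≈ 45 s, peak ≈ 10 µV lognormal) merged by pointwise maximum
(overlapping contractions do not superpose linearly in an envelope), plus
rare narrow motion-artifact spikes. Class structure: burst count per
record is Poisson at the class rate (term 4, preterm 6 per 10 min — the
active-labour criterion sets the floor of 4) and preterm bursts carry a
×1.35 amplitude gain. Artifacts are identical in law for both classes
(4 per 10 min, ~21–25 µV, 3 epochs wide) and deliberately occupy the top
of the amplitude range: they are the class-independent nuisance an
amplitude-band decomposition can excise. A 900 Hz "raw" mode
(envelope-modulated Gaussian carrier) exists only to exercise the
epoch-averaging step.

**RR series.** Stationary AR(1), RR_i = µ + φ(RR_{i−1} − µ) + ε_i, with ε
scaled so the stationary SD equals the class SD and φ = 0.6 by default
(realistic short-range beat-to-beat correlation; configurable). Maternal
class moments are 431.2 ± 31.0 ms (term) and 413.2 ± 26.9 ms (preterm).
No foetal RR moments are reported for such cohorts, so the foetal term
mean derives from the mid-baseline heart rate (140 bpm → ≈ 428.6 ms), the
foetal SD defaults to 25 ms, and the preterm effect applies the *maternal
standardised mean difference* at the foetal SD, with the foetal SD ratio
mirroring the maternal one. Record duration defaults to 40 min (2400 s);
statements about minimum record lengths in the source material are
internally inconsistent (likely second/minute typos), so duration is a
plain config knob.

**What the generator does not emulate.** Electrode configuration and
crosstalk, non-stationary labour progression within a record, foetal
movement/deceleration patterns, or any biophysical (Hodgkin–Huxley-style)
contraction model. Passing tests therefore demonstrate correctness of the
*pipeline mechanics and its statistical behaviour under the assumed class
structure*, not clinical performance on real recordings.

## LSDL

The decomposition operator is a dyadic amplitude-band excision: with
reference amplitude A = max |x| over training windows, the lower region at
iteration i retains |x| ≤ A(2ⁱ−1)/2ⁱ and the upper region retains
|x| ≥ A/2ⁱ, i = 1..4; retained samples are concatenated in time order.
This operator family was chosen because it yields exactly four iterations
per region and reproduces the qualitative published behaviour
(mid-amplitude optimum for EHG; upper-region optima and infeasible
lower-region candidates for RR series, whose strictly positive samples
cluster near the maximum so lower bands retain too few samples). The
operator sits behind a small interface so alternatives (adaptive
bisection, zero-filling instead of excision) can be swapped in; zero-fill
matters only for features sensitive to gaps.

The cost J = ED(p, q)/σ_m uses per-class mean feature vectors and the mean
of per-feature *population* SDs over pooled windows. The per-feature
reading of σ was chosen over "SD across features of one vector" because
the latter mixes units. J is scale-invariant, so features enter raw,
without standardisation. Candidates where any window leaves fewer than 16
samples (configurable) are recorded as invalid ("n/a" in the exported
candidate table) and excluded from the argmax; ties break toward (lower
region, smaller iteration). A is computed on training windows only, never
on test records.

## Features

20 values per window: MAV, WL, ZC, SSC, RMS, AR1–4, SampEn, Ceps1–4, MFL,
MedFrq, PeakFrq, NP, SSI, VAR. Unstated estimator choices were resolved
as: Burg for the AR fit (stable on short windows; statsmodels
implementation, predictive-coefficient convention), the standard LPC
recursion for the AR-derived cepstrum, a Hann-window periodogram for the
spectral features (Welch available), and strict local maxima with
amplitude prominence ≥ eps for NP. The amplitude tolerance eps defaults to
1 µV for EHG and 0 for RR series, where a µV threshold is meaningless.
Sample entropy uses m = 2 and r = 0.2·SD: an m of 0 (which appears in
printed accounts of this feature set) makes the statistic degenerate and
is treated as a typo; both knobs are exposed. SampEn and MFL return NaN on
windows where they are undefined (zero variance, no template matches);
model training imputes non-finite cells with training-fold column means,
and the LSDL cost drops non-finite feature columns for the affected
candidate.

## Balancing, supervised models, clustering

SMOTE oversamples the minority class to parity (k = 5 neighbours,
Euclidean, u ~ U(0,1) interpolation). Whether balancing preceded
cross-validation is not documented for this protocol; the default applies
it inside training folds only (global pre-split balancing biases pooled
metrics optimistically), with `before_split` as the replication flag.

The eight classifiers run in scaler+model pipelines with fixed, documented
hyperparameters (SVM C = 1, polynomial kernels with coef0 = 1, fine
Gaussian gamma = 16/P, 1-NN Euclidean); small per-model grids are
available behind `tuning="grid"` as a transparent stand-in for opaque
auto-tuning. Folds are stratified at window level by default — matching
the apparent published protocol — with patient-grouped folds available
because windows of one patient are correlated; the negative-control tests
use grouped folds for exactly this reason. Metrics are pooled over folds
(aggregate confusion matrix + concatenated scores); fold-level accuracies
are retained in the report. AUC scores come from decision functions where
available, class-1 probability for trees, and the nearest-neighbour
distance margin for 1-NN.

Clustering runs on standardised features of the decomposed arm by default.
The five-restart rule keeps the partition with the best *evaluated*
accuracy, replicating the published restart convention (which is
label-aware); label-free selection by inertia/likelihood is the documented
leakage-safe alternative. The overall clustering accuracy is the
*truncated* unweighted mean of the two per-class accuracies — the only
convention consistent with every published row, e.g. (98 + 37)/2 = 67.5
reported as 67 and (53 + 50)/2 = 51.5 as 51. GMM restarts that degenerate
are reported as failures with diagnostics; if all five fail the run is an
explicit error (mirroring published "n/a" GMM rows) rather than a silent
fallback.

## Orchestration and reproducibility

`run_experiment` derives every stage seed from one master seed via a CRC32
hash of the stage name, writes all artifacts (cohort files, LSDL model
JSON + candidate table, both feature tables, supervised and clustering
reports, PCA coordinates, run log, manifest) and is byte-deterministic.
PCA standardises features first (the ensemble spans orders of magnitude),
drops zero-variance columns with a warning, and fixes component signs by
making each component's largest-magnitude loading positive.

## Problem sizes used in the tests

The test suite runs reduced cohorts chosen to keep the full suite around a
minute while leaving every statistical check well-powered: 8 term /
6 preterm × 20 min records for unit fixtures, 14/10 × 40 min for the
ten-seed decomposition-benefit experiment and the negative controls, and
n = 10,000 beats for RR calibration (mean tolerance ±1 ms ≈ 1.6 standard
errors under AR(1) autocorrelation; SD tolerance 3 SE).

## Known limitations

- The decomposition operator is one plausible member of the family of
  threshold-decomposition schemes; published accounts do not pin down the
  operator, only the iteration counts, cost and qualitative optima.
- The generator's class effects are stationary and burst/mean driven;
  pipelines tuned on it may behave differently on non-stationary real
  labour recordings.
- Window-level cross-validation shares patients between train and test
  folds; the grouped-fold option is the defensible estimate of
  generalisation to new patients and typically scores lower.
- Reported percentages depend on cohort size; with 10 windows per patient
  the effective sample size is the patient count, not the window count.
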