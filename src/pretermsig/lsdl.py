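"""Linear Series Decomposition Learner (LSDL).

An amplitude-threshold decomposition learner: candidate rules excise the
part of a signal lying in a dyadic amplitude band, and the band whose
decomposed windows best separate the two classes — measured by the
normalised Euclidean separability cost J — is selected.

Candidate bands, expressed as fractions of the reference amplitude A (the
maximum absolute amplitude over the training windows):

* lower region, iteration i: retain samples with |x| <= A (2^i - 1) / 2^i
  (A/2, 3A/4, 7A/8, 15A/16 for i = 1..4) — progressively admits larger
  amplitudes from below;
* upper region, iteration i: retain samples with |x| >= A / 2^i
  (A/2, A/4, A/8, A/16) — progressively admits smaller amplitudes from
  above.

Retained samples are concatenated in time order (excision, not
zero-filling). With four iterations per region this gives eight candidates
per signal kind.

The separability cost of a candidate is

    J = ED(p, q) / sigma_m

where p and q are the per-class mean feature vectors of the decomposed
windows, ED their Euclidean distance, and sigma_m the mean over features of
the per-feature population SD across the pooled windows of both classes.
J = 0 iff the class means coincide, and J is invariant under a common
positive rescaling of all features.
"""

from __future__ import annotations

import json
import logging
from dataclasses import dataclass, field

import numpy as np

from .features import FEATURE_NAMES, FeatureConfig, extract_features
from .preprocess import WindowSet

__all__ = [
    "DecompositionError",
    "ThresholdCandidate",
    "LSDLModel",
    "threshold_fraction",
    "decompose",
    "cost_J",
    "select_best",
    "search_optimal",
    "permutation_null",
]

logger = logging.getLogger(__name__)

REGIONS = ("lower", "upper")


class DecompositionError(ValueError):
    """Raised when a decomposition rule leaves too few samples."""


@dataclass
class ThresholdCandidate:
    """One (region, iteration) decomposition rule and its evaluated cost."""

    region: str
    iteration: int
    threshold: float  # fraction of the reference amplitude A
    cost: float = float("nan")
    valid: bool = True
    note: str = ""


@dataclass
class LSDLModel:
    """A fitted decomposition rule, reusable on new records/windows."""

    best: ThresholdCandidate
    reference_amp: float
    candidates: list[ThresholdCandidate]
    feature_config: FeatureConfig = field(default_factory=FeatureConfig)
    min_samples: int = 16

    def apply_to_window(
        self, samples: np.ndarray, on_failure: str = "strict"
    ) -> np.ndarray:
        """Decompose one window with the fitted rule.

        ``on_failure='raw'`` returns the untouched window (with a warning)
        when too few samples survive; ``'strict'`` raises.
        """
        try:
            return decompose(
                samples, self.best.region, self.best.iteration,
                self.reference_amp, min_samples=self.min_samples,
            )
        except DecompositionError:
            if on_failure == "raw":
                logger.warning(
                    "LSDL rule left too few samples; falling back to raw window"
                )
                return np.asarray(samples, dtype=float)
            raise

    def apply(self, record, on_failure: str = "strict"):
        """Decompose a whole record, returning a record of the same metadata."""
        from .synth import Record

        out = self.apply_to_window(record.samples, on_failure=on_failure)
        return Record(record.patient_id, record.label, record.signal_kind, out, record.fs)

    def to_json(self, path: str) -> None:
        payload = {
            "best": vars(self.best),
            "reference_amp": self.reference_amp,
            "min_samples": self.min_samples,
            "feature_config": vars(self.feature_config),
            "candidates": [vars(c) for c in self.candidates],
        }
        with open(path, "w") as fh:
            json.dump(payload, fh, indent=2)

    @classmethod
    def from_json(cls, path: str) -> "LSDLModel":
        with open(path) as fh:
            payload = json.load(fh)
        return cls(
            best=ThresholdCandidate(**payload["best"]),
            reference_amp=payload["reference_amp"],
            candidates=[ThresholdCandidate(**c) for c in payload["candidates"]],
            feature_config=FeatureConfig(**payload["feature_config"]),
            min_samples=payload["min_samples"],
        )


def threshold_fraction(region: str, iteration: int) -> float:
    """The retained-band boundary as a fraction of the reference amplitude."""
    if region == "lower":
        return float(2**iteration - 1) / float(2**iteration)
    if region == "upper":
        return 1.0 / float(2**iteration)
    raise ValueError(f"region must be one of {REGIONS}")


def decompose(
    samples: np.ndarray, region: str, iteration: int, A: float,
    min_samples: int = 16,
) -> np.ndarray:
    """Excise the samples of one dyadic amplitude band, time order kept."""
    if A <= 0:
        raise ValueError("reference amplitude A must be positive")
    if not 1 <= iteration <= 8:
        raise ValueError("iteration out of range")
    x = np.asarray(samples, dtype=float)
    frac = threshold_fraction(region, iteration)
    if region == "lower":
        mask = np.abs(x) <= A * frac
    else:
        mask = np.abs(x) >= A * frac
    kept = x[mask]
    if kept.size < min_samples:
        raise DecompositionError(
            f"{region} iteration {iteration}: only {kept.size} samples survive "
            f"(minimum {min_samples})"
        )
    return kept


def cost_J(feats_class1: np.ndarray, feats_class2: np.ndarray) -> float:
    """Separability cost J = ED(p, q) / sigma_m between two feature matrices.

    p, q are the per-class column means; sigma_m is the mean of the
    per-feature population SDs over the pooled rows of both classes.
    """
    f1 = np.asarray(feats_class1, dtype=float)
    f2 = np.asarray(feats_class2, dtype=float)
    if f1.ndim != 2 or f2.ndim != 2 or f1.shape[1] != f2.shape[1]:
        raise ValueError("feature matrices must be 2-D with equal feature counts")
    if f1.shape[0] == 0 or f2.shape[0] == 0:
        raise ValueError("both classes must contribute at least one window")
    p = f1.mean(axis=0)
    q = f2.mean(axis=0)
    pooled = np.vstack([f1, f2])
    sigma = pooled.std(axis=0)  # population form, divisor Nw
    sigma_m = sigma.mean()
    if sigma_m == 0:
        raise ValueError("sigma_m is zero: all features constant across windows")
    return float(np.linalg.norm(p - q) / sigma_m)


def select_best(candidates: list[ThresholdCandidate]) -> ThresholdCandidate:
    """Argmax-J candidate; ties resolved toward (lower region, smaller iter)."""
    valid = [c for c in candidates if c.valid and np.isfinite(c.cost)]
    if not valid:
        raise ValueError("no valid decomposition candidate")
    order = {"lower": 0, "upper": 1}
    valid.sort(key=lambda c: (order[c.region], c.iteration))
    best = valid[0]
    for c in valid[1:]:
        if c.cost > best.cost:
            best = c
    return best


def _candidate_grid(max_iterations: int) -> list[tuple[str, int]]:
    return [(r, i) for r in REGIONS for i in range(1, max_iterations + 1)]


def _candidate_features(
    training: list[WindowSet],
    feature_config: FeatureConfig,
    max_iterations: int,
    min_samples: int,
) -> tuple[float, dict, np.ndarray]:
    """Decompose + featurize every window under every candidate rule.

    Returns (A, {candidate -> feature matrix or error note}, label array).
    """
    windows, labels, fss, kinds = [], [], [], []
    for ws in training:
        for w in ws.windows:
            windows.append(np.asarray(w, dtype=float))
            labels.append(ws.label)
            fss.append(ws.fs if ws.fs else 1.0)
            kinds.append(ws.signal_kind)
    labels = np.asarray(labels)
    if len(set(labels)) < 2:
        raise ValueError("both classes must be represented in the training set")
    A = max(float(np.max(np.abs(w))) if w.size else 0.0 for w in windows)
    if A <= 0:
        raise ValueError("training windows have zero amplitude")

    per_candidate: dict[tuple[str, int], object] = {}
    for region, it in _candidate_grid(max_iterations):
        rows = []
        failure = None
        for w, fs, kind in zip(windows, fss, kinds):
            cfg = feature_config.for_kind(kind)
            try:
                part = decompose(w, region, it, A, min_samples=min_samples)
            except DecompositionError as exc:
                failure = str(exc)
                break
            feats = extract_features(part, fs=fs, config=cfg)
            rows.append([feats[name] for name in FEATURE_NAMES])
        if failure is not None:
            per_candidate[(region, it)] = failure
        else:
            per_candidate[(region, it)] = np.asarray(rows, dtype=float)
    return A, per_candidate, labels


def _cost_from_matrix(mat: np.ndarray, labels: np.ndarray) -> float:
    """J on the finite-feature columns of a candidate's window matrix."""
    finite_cols = np.all(np.isfinite(mat), axis=0)
    if not finite_cols.any():
        raise ValueError("no finite feature columns")
    mat = mat[:, finite_cols]
    classes = sorted(set(labels))
    return cost_J(mat[labels == classes[0]], mat[labels == classes[1]])


def search_optimal(
    training: list[WindowSet],
    feature_config: FeatureConfig | None = None,
    max_iterations: int = 4,
    min_samples: int = 16,
) -> LSDLModel:
    """Fit the LSDL: evaluate J for every (region, iteration) candidate.

    The reference amplitude A is the maximum absolute amplitude over the
    training windows (training data only — never test records). Candidates
    for which any window fails the minimum-sample rule are recorded with an
    invalid cost and excluded from the argmax.
    """
    feature_config = feature_config or FeatureConfig()
    A, per_candidate, labels = _candidate_features(
        training, feature_config, max_iterations, min_samples
    )
    candidates = []
    for (region, it), payload in per_candidate.items():
        cand = ThresholdCandidate(region, it, threshold_fraction(region, it))
        if isinstance(payload, str):
            cand.valid = False
            cand.note = payload
        else:
            try:
                cand.cost = _cost_from_matrix(payload, labels)
            except ValueError as exc:
                cand.valid = False
                cand.note = str(exc)
        candidates.append(cand)
    best = select_best(candidates)
    return LSDLModel(
        best=best,
        reference_amp=A,
        candidates=candidates,
        feature_config=feature_config,
        min_samples=min_samples,
    )


def permutation_null(
    training: list[WindowSet],
    feature_config: FeatureConfig | None = None,
    max_iterations: int = 4,
    min_samples: int = 16,
    n_permutations: int = 49,
    seed: int = 0,
) -> tuple[float, np.ndarray]:
    """Best-J under the true labels vs. a label-permutation null.

    Candidate feature matrices are computed once; each permutation only
    re-splits the classes, so the null is cheap. Returns (observed best J,
    array of permuted best-J values).
    """
    feature_config = feature_config or FeatureConfig()
    _, per_candidate, labels = _candidate_features(
        training, feature_config, max_iterations, min_samples
    )
    mats = [m for m in per_candidate.values() if isinstance(m, np.ndarray)]
    if not mats:
        raise ValueError("no valid decomposition candidate")

    def best_j(labs: np.ndarray) -> float:
        costs = []
        for m in mats:
            try:
                costs.append(_cost_from_matrix(m, labs))
            except ValueError:
                continue
        if not costs:
            raise ValueError("no valid candidate under this labelling")
        return max(costs)

    observed = best_j(labels)
    rng = np.random.default_rng(seed)
    null = np.array(
        [best_j(rng.permutation(labels)) for _ in range(n_permutations)]
    )
    return observed, null
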