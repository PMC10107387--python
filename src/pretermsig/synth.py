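"""Synthetic two-class labour cohorts: EHG contraction envelopes and RR series.

The study population this emulates is women in active labour (>= 4 distinct
uterine contractions per 10 minutes), recorded as

* an electrohysterogram (EHG) contraction *envelope* — a non-negative,
  slowly varying amplitude trace exported at one sample per 2-s epoch
  (0.5 Hz), on which contractions appear as Gaussian-shaped bursts;
* maternal and foetal beat-to-beat RR interval series in milliseconds.

The class signal is carried by the cohort statistics reported for the real
cohort: maternal RR 431.2 +/- 31.0 ms (term) vs 413.2 +/- 26.9 ms (preterm),
a foetal heart-rate baseline of 110-170 bpm, and a higher contraction burst
rate/amplitude for preterm labour. RR series follow a stationary AR(1) so
that short-range beat-to-beat correlation is present; EHG envelopes are
rectified Gaussian noise plus Gaussian-windowed bursts, with occasional
class-independent high-amplitude motion artifacts (the realistic nuisance
that amplitude-band decomposition is meant to excise).
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np

__all__ = [
    "CohortParams",
    "Record",
    "generate_ehg",
    "generate_ehg_raw",
    "generate_rr",
    "generate_cohort",
]

LABELS = ("term", "preterm")
SIGNAL_KINDS = ("EHG", "MHR", "FHR")


@dataclass
class Record:
    """One patient's signal: EHG envelope (uV, uniform fs) or RR series (ms).

    ``fs`` is None for RR series, which are indexed by beat, not by time.
    """

    patient_id: str
    label: str
    signal_kind: str
    samples: np.ndarray
    fs: float | None = None
    meta: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        self.samples = np.asarray(self.samples, dtype=float)
        if self.label not in LABELS:
            raise ValueError(f"label must be one of {LABELS}, got {self.label!r}")
        if self.signal_kind not in SIGNAL_KINDS:
            raise ValueError(f"signal_kind must be one of {SIGNAL_KINDS}")
        if self.samples.size == 0:
            raise ValueError("record has no samples")
        if self.signal_kind in ("MHR", "FHR") and np.any(self.samples <= 0):
            raise ValueError("RR intervals must be strictly positive")

    def __len__(self) -> int:
        return int(self.samples.size)


@dataclass
class CohortParams:
    """Cohort-level generator settings.

    Defaults encode the study conditions: 27 term / 20 preterm patients,
    maternal RR means/SDs from the cohort table, foetal baseline 110-170 bpm,
    and >= 4 contractions per 10 min (active labour), with preterm labour
    showing more frequent (6/10 min) and stronger (x1.35) bursts.
    """

    n_term: int = 27
    n_preterm: int = 20
    signal_kind: str = "EHG"
    fs: float = 0.5  # Hz; EHG envelope rate, one sample per 2-s epoch
    duration: float = 2400.0  # s per record (40 min of active labour)
    rr_mean_term: float = 431.2  # ms
    rr_sd_term: float = 31.0  # ms
    rr_mean_preterm: float = 413.2  # ms
    rr_sd_preterm: float = 26.9  # ms
    fhr_baseline_bpm: tuple[float, float] = (110.0, 170.0)
    fhr_rr_sd: float = 25.0  # ms; foetal beat-to-beat SD (not reported; typical)
    burst_rate_per_10min: dict = field(
        default_factory=lambda: {"term": 4.0, "preterm": 6.0}
    )
    burst_amp_gain: dict = field(
        default_factory=lambda: {"term": 1.0, "preterm": 1.35}
    )
    burst_base_amp: float = 10.0  # uV, typical contraction envelope peak
    burst_width_s: float = 45.0  # Gaussian sigma of a contraction burst
    noise_sd: float = 1.5  # uV, envelope baseline noise scale
    artifact_rate_per_10min: float = 4.0  # class-independent motion spikes
    artifact_amp: float = 25.0  # uV; sits above every contraction burst
    artifact_width: int = 3  # samples (epochs) per spike
    ar1_coeff: float = 0.6  # beat-to-beat correlation of RR series
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_term < 1 or self.n_preterm < 1:
            raise ValueError("n_term and n_preterm must each be >= 1")
        if self.signal_kind not in SIGNAL_KINDS:
            raise ValueError(f"signal_kind must be one of {SIGNAL_KINDS}")
        for sd in (self.rr_sd_term, self.rr_sd_preterm, self.fhr_rr_sd):
            if sd < 0:
                raise ValueError("standard deviations must be >= 0")
        if not abs(self.ar1_coeff) < 1:
            raise ValueError("|ar1_coeff| must be < 1 for a stationary AR(1)")
        for lab in LABELS:
            if self.burst_rate_per_10min[lab] < 4.0:
                raise ValueError(
                    "burst rate must be >= 4 per 10 min (active-labour criterion)"
                )
        if self.fs <= 0 or self.duration <= 0:
            raise ValueError("fs and duration must be positive")


def _check_label(label: str) -> None:
    if label not in LABELS:
        raise ValueError(f"label must be one of {LABELS}, got {label!r}")


def _envelope(
    params: CohortParams, label: str, rng: np.random.Generator
) -> tuple[np.ndarray, int]:
    n = int(round(params.duration * params.fs))
    t = np.arange(n) / params.fs
    env = np.abs(rng.normal(0.0, params.noise_sd, n))

    # Contraction bursts: Poisson count at the class rate, Gaussian windows.
    # Overlapping contractions merge (pointwise max) rather than superpose:
    # the envelope tracks the momentary contraction strength, so the burst
    # amplitude scale stays bounded by the per-burst peak draw.
    rate = params.burst_rate_per_10min[label]
    n_bursts = rng.poisson(rate * params.duration / 600.0)
    gain = params.burst_amp_gain[label]
    bursts = np.zeros_like(env)
    for _ in range(n_bursts):
        centre = rng.uniform(0.0, params.duration)
        width = params.burst_width_s * rng.lognormal(0.0, 0.2)
        amp = gain * params.burst_base_amp * rng.lognormal(0.0, 0.15)
        np.maximum(bursts, amp * np.exp(-0.5 * ((t - centre) / width) ** 2), out=bursts)
    env += bursts

    # Motion/electrode artifacts: rare narrow spikes, identical in law for
    # both classes, occupying the top of the amplitude range.
    n_art = rng.poisson(params.artifact_rate_per_10min * params.duration / 600.0)
    for _ in range(n_art):
        pos = int(rng.integers(0, n))
        amp = params.artifact_amp * rng.uniform(0.85, 1.0)
        for k in range(params.artifact_width):
            if pos + k < n:
                env[pos + k] += amp * (1.0 - k / params.artifact_width)
    return env, int(n_bursts)


def generate_ehg(
    params: CohortParams, label: str, seed: int | None = None,
    patient_id: str = "synthetic",
) -> Record:
    """Generate one EHG contraction-envelope record at envelope scale.

    The envelope is rectified baseline noise plus ``Poisson(rate)`` Gaussian
    bursts whose peak amplitude is drawn per class (preterm gain > term gain
    by a configurable effect size), plus class-independent artifact spikes.
    """
    _check_label(label)
    if params.duration < 600.0:
        raise ValueError(
            "duration must be >= 600 s to host the active-labour burst pattern"
        )
    rng = np.random.default_rng(params.seed if seed is None else seed)
    env, n_bursts = _envelope(params, label, rng)
    return Record(
        patient_id, label, "EHG", env, fs=params.fs, meta={"n_bursts": n_bursts}
    )


def generate_ehg_raw(
    params: CohortParams, label: str, seed: int | None = None,
    carrier_fs: float = 900.0, patient_id: str = "synthetic",
) -> Record:
    """Generate an EHG record at acquisition scale (default 900 Hz).

    A zero-mean Gaussian carrier is amplitude-modulated by the envelope, so
    that 2-s epoch averaging of the absolute signal recovers the envelope up
    to the rectified-Gaussian factor sqrt(2/pi). Provided to exercise the
    epoch-averaging step; the analysis itself consumes envelopes.
    """
    _check_label(label)
    rng = np.random.default_rng(params.seed if seed is None else seed)
    env, _ = _envelope(params, label, rng)
    upsample = int(round(carrier_fs / params.fs))
    carrier = rng.standard_normal(env.size * upsample)
    x = np.repeat(env, upsample) * carrier
    return Record(patient_id, label, "EHG", x, fs=carrier_fs)


def _rr_class_moments(params: CohortParams, label: str, kind: str) -> tuple[float, float]:
    if kind == "MHR":
        if label == "term":
            return params.rr_mean_term, params.rr_sd_term
        return params.rr_mean_preterm, params.rr_sd_preterm
    # FHR: term mean from the mid-baseline heart rate; the class effect is
    # the maternal standardised mean difference applied at the foetal SD
    # (no foetal RR statistics are reported for the cohort).
    lo, hi = params.fhr_baseline_bpm
    mean_term = 60000.0 / ((lo + hi) / 2.0)
    if label == "term":
        return mean_term, params.fhr_rr_sd
    smd = (params.rr_mean_term - params.rr_mean_preterm) / (
        (params.rr_sd_term + params.rr_sd_preterm) / 2.0
    )
    sd_pre = params.fhr_rr_sd * (params.rr_sd_preterm / params.rr_sd_term)
    return mean_term - smd * params.fhr_rr_sd, sd_pre


def generate_rr(
    params: CohortParams, label: str, kind: str = "MHR",
    n_beats: int | None = None, seed: int | None = None,
    patient_id: str = "synthetic",
) -> Record:
    """Generate a beat-to-beat RR series (ms) as a stationary AR(1).

    RR_i = mu + phi * (RR_{i-1} - mu) + eps_i, with eps scaled so the
    stationary SD equals the class SD; intervals are clipped at 1 ms.
    """
    _check_label(label)
    if kind not in ("MHR", "FHR"):
        raise ValueError("kind must be 'MHR' or 'FHR'")
    mu, sd = _rr_class_moments(params, label, kind)
    phi = params.ar1_coeff
    if n_beats is None:
        n_beats = int(round(params.duration * 1000.0 / mu))
    if n_beats < 2:
        raise ValueError("need at least 2 beats")
    rng = np.random.default_rng(params.seed if seed is None else seed)
    eps_sd = sd * math.sqrt(1.0 - phi * phi)
    x = np.empty(n_beats)
    x[0] = rng.normal(mu, sd)
    innov = rng.normal(0.0, eps_sd, n_beats - 1)
    for i in range(1, n_beats):
        x[i] = mu + phi * (x[i - 1] - mu) + innov[i - 1]
    np.maximum(x, 1.0, out=x)
    return Record(patient_id, label, kind, x, fs=None)


def generate_cohort(params: CohortParams) -> list[Record]:
    """Generate the full labelled cohort (term records first).

    Per-record seeds are spawned deterministically from ``params.seed`` so a
    fixed master seed reproduces the cohort bitwise.
    """
    n_total = params.n_term + params.n_preterm
    children = np.random.SeedSequence(params.seed).spawn(n_total)
    seeds = [int(c.generate_state(1)[0] % (2**31)) for c in children]
    records: list[Record] = []
    idx = 0
    for label, count, prefix in (
        ("term", params.n_term, "T"),
        ("preterm", params.n_preterm, "P"),
    ):
        for i in range(count):
            pid = f"{prefix}{i + 1:03d}"
            if params.signal_kind == "EHG":
                rec = generate_ehg(params, label, seed=seeds[idx], patient_id=pid)
            else:
                rec = generate_rr(
                    params, label, kind=params.signal_kind,
                    seed=seeds[idx], patient_id=pid,
                )
            records.append(rec)
            idx += 1
    return records
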