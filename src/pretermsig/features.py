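"""The 20-dimensional per-window feature vector.

Fourteen named features from the surface-EMG tradition — time-domain
amplitude statistics, order-4 Burg autoregression, AR-derived cepstrum,
sample entropy, fractal and spectral descriptors — of which the AR fit and
the cepstrum each contribute four coefficients:

MAV, WL, ZC, SSC, RMS, AR1-AR4, SampEN, Ceps1-Ceps4, MFL, MedFrq, PeakFrq,
NP, SSI, VAR.

Threshold-bearing features (ZC, SSC, NP) use an amplitude tolerance of
1 uV for EHG; the threshold is meaningless on RR series in ms and defaults
to 0 there. Sample entropy uses template length m=2 and tolerance
r = 0.2 x SD(window) (the conventional settings; an m of 0 would make the
statistic degenerate).
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass, replace

import numpy as np
import pandas as pd
from scipy import signal as sps
from statsmodels.regression.linear_model import burg as _burg

__all__ = ["FeatureConfig", "FEATURE_NAMES", "extract_features", "featurize_cohort"]

logger = logging.getLogger(__name__)

FEATURE_NAMES = (
    "MAV", "WL", "ZC", "SSC", "RMS",
    "AR1", "AR2", "AR3", "AR4",
    "SampEN",
    "Ceps1", "Ceps2", "Ceps3", "Ceps4",
    "MFL", "MedFrq", "PeakFrq", "NP", "SSI", "VAR",
)


@dataclass
class FeatureConfig:
    """Settings for the feature ensemble.

    eps_threshold is in signal units (uV for EHG envelopes); sampen_r is a
    fraction of the window SD.
    """

    eps_threshold: float = 1.0
    sampen_m: int = 2
    sampen_r: float = 0.2
    ar_order: int = 4
    ceps_order: int = 4
    spectrum_estimator: str = "periodogram"  # or "welch"

    def __post_init__(self) -> None:
        if self.eps_threshold < 0:
            raise ValueError("eps_threshold must be >= 0")
        if self.sampen_m < 1:
            raise ValueError("sampen_m must be >= 1")
        if self.sampen_r <= 0:
            raise ValueError("sampen_r must be > 0")
        if self.spectrum_estimator not in ("periodogram", "welch"):
            raise ValueError("spectrum_estimator must be 'periodogram' or 'welch'")

    def for_kind(self, signal_kind: str) -> "FeatureConfig":
        """RR series (ms) get eps=0; the uV threshold only fits EHG."""
        if signal_kind in ("MHR", "FHR") and self.eps_threshold == 1.0:
            return replace(self, eps_threshold=0.0)
        return self


def sample_entropy(x: np.ndarray, m: int = 2, r: float | None = None) -> float:
    """SampEn(m, r): -ln(A/B) with Chebyshev distance, self-matches excluded.

    B counts template pairs of length m within r; A the pairs of length
    m+1. r defaults to 0.2 x population SD. Returns NaN when the window has
    zero variance or no length-m matches exist.
    """
    x = np.asarray(x, dtype=float)
    n = x.size
    if n < m + 2:
        raise ValueError("window too short for sample entropy")
    sd = x.std()
    if sd == 0:
        return float("nan")
    if r is None:
        r = 0.2 * sd

    def _count(mm: int) -> int:
        n_templates = n - m  # fixed count for both lengths (Richman-Moorman)
        emb = np.lib.stride_tricks.sliding_window_view(x, mm)[:n_templates]
        # pairwise Chebyshev distances, upper triangle only
        d = np.abs(emb[:, None, :] - emb[None, :, :]).max(axis=2)
        iu = np.triu_indices(n_templates, k=1)
        return int(np.count_nonzero(d[iu] <= r))

    b = _count(m)
    a = _count(m + 1)
    if b == 0 or a == 0:
        return float("nan")
    return float(-math.log(a / b))


def ar_to_cepstrum(ar: np.ndarray, order: int) -> np.ndarray:
    """Cepstral coefficients of an AR model via the LPC recursion.

    ``ar`` holds the predictive coefficients rho (x_t = sum rho_k x_{t-k});
    with polynomial coefficients a = -rho the recursion is
    c_1 = -a_1, c_p = -a_p - sum_{l=1}^{p-1} (1 - l/p) a_l c_{p-l}.
    """
    a = -np.asarray(ar, dtype=float)
    p_max = min(order, a.size)
    c = np.zeros(order)
    for p in range(1, p_max + 1):
        acc = -a[p - 1]
        for ell in range(1, p):
            acc -= (1.0 - ell / p) * a[ell - 1] * c[p - ell - 1]
        c[p - 1] = acc
    return c


def _spectrum(x: np.ndarray, fs: float, estimator: str) -> tuple[np.ndarray, np.ndarray]:
    if estimator == "periodogram":
        return sps.periodogram(x, fs=fs, window="hann", detrend=False)
    nperseg = min(256, x.size)
    return sps.welch(x, fs=fs, window="hann", nperseg=nperseg, detrend=False)


def extract_features(
    window: np.ndarray, fs: float = 1.0, config: FeatureConfig | None = None
) -> dict[str, float]:
    """Compute the 20 named features of one window; returns an ordered dict.

    Zero-variance windows yield NaN for SampEn (undefined) and MFL
    (log of zero length), with a logged note; every other feature is
    well defined.
    """
    config = config or FeatureConfig()
    x = np.asarray(window, dtype=float)
    n = x.size
    min_len = max(config.ar_order + 1, config.sampen_m + 2, 8)
    if n < min_len:
        raise ValueError(f"window of {n} samples is shorter than {min_len}")
    eps = config.eps_threshold
    d = np.diff(x)

    out: dict[str, float] = {}
    out["MAV"] = float(np.mean(np.abs(x)))
    out["WL"] = float(np.sum(np.abs(d)))
    out["ZC"] = float(
        np.count_nonzero((x[:-1] * x[1:] < 0) & (np.abs(d) >= eps))
    )
    left = x[1:-1] - x[:-2]
    right = x[1:-1] - x[2:]
    out["SSC"] = float(
        np.count_nonzero(
            (left * right > 0) & (np.maximum(np.abs(left), np.abs(right)) >= eps)
        )
    )
    out["RMS"] = float(np.sqrt(np.mean(x**2)))

    if x.std() == 0:
        ar = np.full(config.ar_order, 0.0)
        logger.debug("zero-variance window: AR coefficients set to 0")
    else:
        ar, _ = _burg(x, order=config.ar_order, demean=False)
    for k in range(4):
        out[f"AR{k + 1}"] = float(ar[k])

    sampen = sample_entropy(x, m=config.sampen_m, r=config.sampen_r * x.std())
    if math.isnan(sampen):
        logger.debug("SampEn undefined on this window (returned NaN)")
    out["SampEN"] = sampen

    ceps = ar_to_cepstrum(ar, config.ceps_order)
    for k in range(4):
        out[f"Ceps{k + 1}"] = float(ceps[k])

    ssd = float(np.sum(d**2))
    out["MFL"] = float(np.log10(np.sqrt(ssd))) if ssd > 0 else float("nan")

    f, pxx = _spectrum(x, fs, config.spectrum_estimator)
    total = pxx.sum()
    if total > 0:
        cum = np.cumsum(pxx)
        out["MedFrq"] = float(f[np.searchsorted(cum, total / 2.0)])
        out["PeakFrq"] = float(f[1 + int(np.argmax(pxx[1:]))])
    else:
        out["MedFrq"] = 0.0
        out["PeakFrq"] = 0.0

    if eps > 0:
        peaks, _ = sps.find_peaks(x, prominence=eps)
        out["NP"] = float(peaks.size)
    else:
        out["NP"] = float(np.count_nonzero((x[1:-1] > x[:-2]) & (x[1:-1] > x[2:])))

    out["SSI"] = float(np.sum(x**2))
    out["VAR"] = float(np.var(x, ddof=1))
    return out


def featurize_cohort(
    window_sets: list,
    config: FeatureConfig | None = None,
    lsdl=None,
) -> pd.DataFrame:
    """One row per window: patient_id, label, window_index + the 20 features.

    If an LSDL model is given, every window is decomposed by its fitted rule
    first (falling back to the raw window, with a warning, when too few
    samples survive).
    """
    config = config or FeatureConfig()
    rows = []
    for ws in window_sets:
        cfg = config.for_kind(ws.signal_kind)
        fs = ws.fs if ws.fs else 1.0
        for j, win in enumerate(ws.windows):
            if lsdl is not None:
                win = lsdl.apply_to_window(win, on_failure="raw")
            feats = extract_features(win, fs=fs, config=cfg)
            rows.append(
                {"patient_id": ws.record_ref, "label": ws.label, "window_index": j, **feats}
            )
    columns = ["patient_id", "label", "window_index", *FEATURE_NAMES]
    return pd.DataFrame(rows, columns=columns)
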