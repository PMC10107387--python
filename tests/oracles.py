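"""Independent naive-loop oracles used to validate the implementation.

Everything here is written as directly as possible (explicit loops, no
shared code with the package) so it can serve as a second, independent
route to the same quantities.
"""

from __future__ import annotations

import math

import numpy as np


# ---------------------------------------------------------------- features

def naive_mav(x):
    return sum(abs(v) for v in x) / len(x)


def naive_wl(x):
    return sum(abs(x[i + 1] - x[i]) for i in range(len(x) - 1))


def naive_zc(x, eps):
    count = 0
    for i in range(len(x) - 1):
        if x[i] * x[i + 1] < 0 and abs(x[i] - x[i + 1]) >= eps:
            count += 1
    return count


def naive_ssc(x, eps):
    count = 0
    for i in range(1, len(x) - 1):
        left = x[i] - x[i - 1]
        right = x[i] - x[i + 1]
        if left * right > 0 and max(abs(left), abs(right)) >= eps:
            count += 1
    return count


def naive_rms(x):
    return math.sqrt(sum(v * v for v in x) / len(x))


def naive_ssi(x):
    return sum(v * v for v in x)


def naive_var(x):
    n = len(x)
    mu = sum(x) / n
    return sum((v - mu) ** 2 for v in x) / (n - 1)


def naive_mfl(x):
    ssd = sum((x[i + 1] - x[i]) ** 2 for i in range(len(x) - 1))
    return math.log10(math.sqrt(ssd))


def naive_burg(x, order):
    """Textbook Burg recursion; returns predictive coefficients rho."""
    x = np.asarray(x, dtype=float)
    f = x[1:].copy()
    b = x[:-1].copy()
    a = np.array([1.0])
    for _ in range(order):
        k = -2.0 * np.dot(f, b) / (np.dot(f, f) + np.dot(b, b))
        a = np.concatenate([a, [0.0]]) + k * np.concatenate([[0.0], a[::-1]])
        f_new = f + k * b
        b_new = b + k * f
        f = f_new[1:]
        b = b_new[:-1]
    return -a[1:]


def naive_cepstrum_fft(rho, order, n_fft=8192):
    """Cepstrum of the AR model via the log-spectrum inverse FFT."""
    a = np.concatenate([[1.0], -np.asarray(rho, dtype=float)])
    A = np.fft.fft(a, n_fft)
    c = np.fft.ifft(-np.log(A)).real
    return c[1 : order + 1]


def naive_sampen(x, m, r):
    """O(N^2) template counting, Chebyshev distance, self-matches excluded."""
    x = np.asarray(x, dtype=float)
    n = len(x)
    n_templates = n - m

    def count(mm):
        total = 0
        for i in range(n_templates):
            for j in range(i + 1, n_templates):
                d = max(abs(x[i + k] - x[j + k]) for k in range(mm))
                if d <= r:
                    total += 1
        return total

    b = count(m)
    a = count(m + 1)
    if a == 0 or b == 0:
        return float("nan")
    return -math.log(a / b)


def naive_periodogram(x, fs):
    """Hann-window one-sided periodogram via an explicit DFT (density scaling)."""
    x = np.asarray(x, dtype=float)
    n = len(x)
    w = np.array(
        [0.5 - 0.5 * math.cos(2 * math.pi * k / n) for k in range(n)]
    )
    xw = x * w
    n_freq = n // 2 + 1
    freqs = np.array([k * fs / n for k in range(n_freq)])
    p = np.zeros(n_freq)
    for k in range(n_freq):
        re = sum(xw[t] * math.cos(2 * math.pi * k * t / n) for t in range(n))
        im = -sum(xw[t] * math.sin(2 * math.pi * k * t / n) for t in range(n))
        p[k] = (re * re + im * im) / (fs * np.sum(w**2))
        if 0 < k < n_freq - 1 or (k == n_freq - 1 and n % 2 == 1):
            p[k] *= 2.0
    return freqs, p


def naive_medfrq(x, fs):
    f, p = naive_periodogram(x, fs)
    total = p.sum()
    cum = 0.0
    for k in range(len(p)):
        cum += p[k]
        if cum >= total / 2.0:
            return f[k]
    return f[-1]


def naive_peakfrq(x, fs):
    f, p = naive_periodogram(x, fs)
    best = 1
    for k in range(2, len(p)):
        if p[k] > p[best]:
            best = k
    return f[best]


def naive_np(x, eps):
    """Strict local maxima; when eps > 0, keep peaks with prominence >= eps."""
    x = np.asarray(x, dtype=float)
    n = len(x)
    peaks = [i for i in range(1, n - 1) if x[i - 1] < x[i] > x[i + 1]]
    if eps <= 0:
        return len(peaks)
    count = 0
    for i in peaks:
        # walk left to the first strictly higher sample; base = min in between
        j = i - 1
        left_base = x[i]
        while j >= 0 and x[j] <= x[i]:
            left_base = min(left_base, x[j])
            j -= 1
        if j < 0:
            left_base = min(x[: i + 1])
        j = i + 1
        right_base = x[i]
        while j < n and x[j] <= x[i]:
            right_base = min(right_base, x[j])
            j += 1
        if j >= n:
            right_base = min(x[i:])
        prominence = x[i] - max(left_base, right_base)
        if prominence >= eps:
            count += 1
    return count


# ----------------------------------------------------------------- J cost

def brute_cost_j(f1, f2):
    """Direct evaluation: Euclidean distance of class means over the mean of
    the per-feature population SDs of the pooled windows."""
    f1 = np.asarray(f1, dtype=float)
    f2 = np.asarray(f2, dtype=float)
    nw = f1.shape[1]
    p = [sum(f1[:, w]) / f1.shape[0] for w in range(nw)]
    q = [sum(f2[:, w]) / f2.shape[0] for w in range(nw)]
    ed = math.sqrt(sum((p[w] - q[w]) ** 2 for w in range(nw)))
    pooled = np.vstack([f1, f2])
    n = pooled.shape[0]
    sigmas = []
    for w in range(nw):
        mu = sum(pooled[:, w]) / n
        sigmas.append(math.sqrt(sum((r - mu) ** 2 for r in pooled[:, w]) / n))
    sigma_m = sum(sigmas) / nw
    return ed / sigma_m


# ------------------------------------------------------------------- AUC

def pair_count_auc(labels, scores):
    """Mann-Whitney pair counting with 0.5 credit for tied scores."""
    pos = [s for s, y in zip(scores, labels) if y == 1]
    neg = [s for s, y in zip(scores, labels) if y == 0]
    total = 0.0
    for sp in pos:
        for sn in neg:
            if sp > sn:
                total += 1.0
            elif sp == sn:
                total += 0.5
    return total / (len(pos) * len(neg))
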