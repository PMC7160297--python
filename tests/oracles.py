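"""Independent brute-force oracles used by the test suite.

These deliberately avoid the library code paths they are checked against:
the wavelet oracle uses direct time-domain convolution via np.convolve, the
AUC oracle enumerates pairs with Python loops, and the t-test oracle is the
closed-form pooled-variance formula.
"""

from __future__ import annotations

import math

import numpy as np


def brute_force_binned_power(data: np.ndarray, time_ms: np.ndarray,
                             sfreq: float, freqs: np.ndarray,
                             cycles: np.ndarray, t_window: tuple[float, float],
                             n_times: int, support_sd: float = 3.5) -> np.ndarray:
    """Time-domain Morlet power, binned; data is (n_trials, n_ch, n_samp)."""
    n_trials, n_ch, n_samp = data.shape
    out = np.empty((n_trials, len(freqs), n_times, n_ch))
    t0, t1 = t_window
    width = (t1 - t0) / n_times
    bin_idx = []
    for b in range(n_times):
        lo, hi = t0 + b * width, t0 + (b + 1) * width
        bin_idx.append(np.flatnonzero((time_ms >= lo - 1e-9) & (time_ms < hi - 1e-9)))

    kernels = []
    for f, c in zip(freqs, cycles):
        sigma = c / (2.0 * math.pi * f)
        half = int(np.ceil(support_sd * sigma * sfreq))
        t = np.arange(-half, half + 1) / sfreq
        env = np.exp(-0.5 * (t / sigma) ** 2)
        k = env * np.exp(2j * np.pi * f * t)
        kernels.append(k / (env.sum() / 2.0))
    pad = max(len(k) // 2 for k in kernels)

    for tr in range(n_trials):
        for ch in range(n_ch):
            x = np.pad(data[tr, ch], pad, mode="reflect")
            for fi, k in enumerate(kernels):
                conv = np.convolve(x, k, mode="same")[pad:pad + n_samp]
                power = np.abs(conv) ** 2
                for b, idx in enumerate(bin_idx):
                    out[tr, fi, b, ch] = power[idx].mean()
    return out


def brute_force_auc(scores, labels, positive="ADHD") -> float:
    """Exhaustive concordant-pair counting."""
    pos = [s for s, l in zip(scores, labels) if l == positive]
    neg = [s for s, l in zip(scores, labels) if l != positive]
    total = 0.0
    for p in pos:
        for n in neg:
            if p > n:
                total += 1.0
            elif p == n:
                total += 0.5
    return total / (len(pos) * len(neg))


def closed_form_ttest(a, b) -> tuple[float, float]:
    """Pooled-variance two-sample t statistic and two-sided p-value."""
    from scipy.stats import t as tdist

    a, b = np.asarray(a, float), np.asarray(b, float)
    na, nb = len(a), len(b)
    sp2 = (((na - 1) * a.var(ddof=1) + (nb - 1) * b.var(ddof=1))
           / (na + nb - 2))
    t = (a.mean() - b.mean()) / math.sqrt(sp2 * (1.0 / na + 1.0 / nb))
    p = 2.0 * tdist.sf(abs(t), na + nb - 2)
    return t, p


def gamma_moments(shape: float, mean: float) -> tuple[float, float]:
    """Mean and variance of a Gamma with given shape and mean."""
    return mean, mean ** 2 / shape
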