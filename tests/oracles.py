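"""Independent brute-force oracles used to cross-check the package.

Everything here is written loop-by-loop from the defining formulas, on
purpose — these implementations must not share code with the package.
"""

from __future__ import annotations

import math

import numpy as np


def oracle_moments(x) -> tuple[float, float, float, float]:
    """(mean, sd, skew, kurtosis), population moments, degenerate -> 0."""
    n = len(x)
    mu = sum(x) / n
    m2 = sum((v - mu) ** 2 for v in x) / n
    if m2 == 0:
        return mu, 0.0, 0.0, 0.0
    m3 = sum((v - mu) ** 3 for v in x) / n
    m4 = sum((v - mu) ** 4 for v in x) / n
    return mu, math.sqrt(m2), m3 / m2**1.5, m4 / m2**2


def _symmetric_pad(x, left, right):
    x = list(x)
    out = x[:left][::-1] + x
    if right > 0:
        out = out + x[-right:][::-1]
    return out


def oracle_boxcar(x, size):
    """Centred boxcar mean with symmetric-reflection padding, same length.

    Uses a cumulative-sum window average rather than a convolution.
    """
    if size == 1:
        return list(x)
    left = size // 2
    right = size - 1 - left
    padded = np.array(_symmetric_pad(x, left, right), dtype=float)
    cs = np.concatenate([[0.0], np.cumsum(padded)])
    return [(cs[i + size] - cs[i]) / size for i in range(len(x))]


def oracle_smoothed_rms(x, size):
    sm = oracle_boxcar(x, size)
    return math.sqrt(sum(v * v for v in sm) / len(sm))


def oracle_histogram(x):
    """Counts in 9 unit bins centred at z = -4..4, edges at half-integers."""
    n = len(x)
    mu = sum(x) / n
    sd = math.sqrt(sum((v - mu) ** 2 for v in x) / n)
    counts = [0] * 9
    if sd == 0:
        counts[4] = n
        return counts
    for v in x:
        z = (v - mu) / sd
        placed = False
        for b, c in enumerate(range(-4, 5)):
            if c - 0.5 <= z < c + 0.5:
                counts[b] += 1
                placed = True
                break
        if not placed:
            counts[0 if z < -4.5 else 8] += 1
    return counts


def oracle_dft_magnitudes(x):
    """One-sided DFT magnitudes of a real signal from the defining sums.

    Builds the cos/sin basis explicitly (no FFT) for bins 0..n//2.
    """
    x = np.asarray(x, dtype=float)
    n = len(x)
    k = np.arange(n // 2 + 1)[:, None]
    t = np.arange(n)[None, :]
    re = (np.cos(-2 * np.pi * k * t / n) * x).sum(axis=1)
    im = (np.sin(-2 * np.pi * k * t / n) * x).sum(axis=1)
    return list(np.hypot(re, im))


def oracle_fourier_samples(x, n_samples=32, rate=20.0):
    """Linear interpolation of the magnitude spectrum at evenly spaced freqs."""
    n = len(x)
    mags = oracle_dft_magnitudes(x)
    bin_freqs = [k * rate / n for k in range(n // 2 + 1)]
    out = []
    for i in range(n_samples):
        f = i * (rate / 2) / (n_samples - 1)
        j = min(int(f / (rate / n)), len(mags) - 2)
        w = (f - bin_freqs[j]) / (bin_freqs[j + 1] - bin_freqs[j])
        out.append(mags[j] * (1 - w) + mags[j + 1] * w)
    return out


def oracle_jerk_score(samples):
    """Raw per-sample squared-change score, then 2 s / 40-sample boxcar."""
    n = len(samples)
    raw = [0.0] * n
    for i in range(1, n):
        raw[i] = sum((samples[i][j] - samples[i - 1][j]) ** 2 for j in range(3))
    return oracle_boxcar(raw, 40)


def oracle_hourly_argmax(timestamps, score):
    """Exhaustive per-hour maximum search over a uniform score series."""
    t0 = timestamps[0]
    n_hours = int((timestamps[-1] - t0) // 3600)
    picks = []
    for h in range(n_hours):
        best_i = None
        for i, t in enumerate(timestamps):
            if t0 + 3600 * h <= t < t0 + 3600 * (h + 1):
                if best_i is None or score[i] > score[best_i]:
                    best_i = i
        picks.append((timestamps[best_i], score[best_i]))
    return picks
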