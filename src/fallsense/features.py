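"""The 178-value time-series feature bank computed from each 10 s clip.

Nine groups, in frozen registry order: per-axis moments (15), moments of
successive differences (12), smoothed root mean squares (9), extremes (12),
z-score histogram counts (27), sampled Fourier magnitudes (96), mean
acceleration magnitude (1), mean cross products (3) and their absolute
values (3).  All per-axis groups are laid out axis-major (x block, y block,
z block), so permuting input axes permutes the corresponding blocks.

Estimator conventions: population (biased) moments; kurtosis is m₄/m₂²
(non-excess); skew and kurtosis of a zero-variance signal are defined as 0.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .signal_io import RATE, CLIP_SAMPLES, UniformClip

AXES = ("x", "y", "z")
_PAIRS = (("x", "y"), ("x", "z"), ("y", "z"))
_RMS_KERNELS = (1, 5, 10)
_HIST_CENTERS = tuple(range(-4, 5))  # unit-width z-score bins centred at -4..4
N_FOURIER_SAMPLES = 32

GROUP_SIZES = {
    "moments": 15,
    "diff_moments": 12,
    "smoothed_rms": 9,
    "extremes": 12,
    "histogram": 27,
    "fourier": 96,
    "magnitude": 1,
    "cross_products": 3,
    "abs_cross_products": 3,
}
GROUP_ORDER = tuple(GROUP_SIZES)


def _build_registry() -> list[tuple[str, str]]:
    reg: list[tuple[str, str]] = []
    for ax in AXES:
        reg += [("moments", f"{s}_{ax}")
                for s in ("mean", "abs_mean", "std", "skew", "kurt")]
    for ax in AXES:
        reg += [("diff_moments", f"d{s}_{ax}")
                for s in ("mean", "std", "skew", "kurt")]
    for ax in AXES:
        reg += [("smoothed_rms", f"rms{k}_{ax}") for k in _RMS_KERNELS]
    for ax in AXES:
        reg += [("extremes", f"{s}_{ax}")
                for s in ("min", "max", "abs_min", "abs_max")]
    for ax in AXES:
        reg += [("histogram", f"hist_{ax}_{'m' if c < 0 else 'p'}{abs(c)}")
                for c in _HIST_CENTERS]
    for ax in AXES:
        reg += [("fourier", f"fft_{ax}_{i:02d}") for i in range(N_FOURIER_SAMPLES)]
    reg.append(("magnitude", "mean_magnitude"))
    reg += [("cross_products", f"cross_{a}{b}") for a, b in _PAIRS]
    reg += [("abs_cross_products", f"abs_cross_{a}{b}") for a, b in _PAIRS]
    return reg


FEATURE_REGISTRY: list[tuple[str, str]] = _build_registry()
FEATURE_NAMES: list[str] = [name for _, name in FEATURE_REGISTRY]
N_FEATURES = len(FEATURE_REGISTRY)
assert N_FEATURES == sum(GROUP_SIZES.values()) == 178


@dataclass
class FeatureVector:
    """The 178 feature values of one clip, in registry order."""

    values: np.ndarray

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        if self.values.shape != (N_FEATURES,):
            raise ValueError(f"expected {N_FEATURES} values")

    def as_dict(self) -> dict[str, float]:
        return dict(zip(FEATURE_NAMES, self.values))


def _moments(x: np.ndarray) -> tuple[float, float, float, float]:
    """(mean, sd, skew, kurtosis) with population moments; degenerate -> 0."""
    mu = float(np.mean(x))
    d = x - mu
    m2 = float(np.mean(d**2))
    if m2 == 0.0:
        return mu, 0.0, 0.0, 0.0
    m3 = float(np.mean(d**3))
    m4 = float(np.mean(d**4))
    return mu, float(np.sqrt(m2)), m3 / m2**1.5, m4 / m2**2


def moment_features(clip: UniformClip) -> np.ndarray:
    """Per axis: mean, |mean|, standard deviation, skew, kurtosis (15 values)."""
    out = []
    for j in range(3):
        mu, sd, sk, ku = _moments(clip.samples[:, j])
        out += [mu, abs(mu), sd, sk, ku]
    return np.array(out)


def diff_moment_features(clip: UniformClip) -> np.ndarray:
    """Per axis, the four moments of the successive-difference series (12)."""
    out = []
    for j in range(3):
        mu, sd, sk, ku = _moments(np.diff(clip.samples[:, j]))
        out += [mu, sd, sk, ku]
    return np.array(out)


def _boxcar_smooth(x: np.ndarray, size: int) -> np.ndarray:
    if size == 1:
        return x
    left, right = size // 2, size - 1 - size // 2
    padded = np.pad(x, (left, right), mode="symmetric")
    return np.convolve(padded, np.full(size, 1.0 / size), mode="valid")


def smoothed_rms_features(clip: UniformClip) -> np.ndarray:
    """Per axis, RMS of the raw signal after 1/5/10-point boxcar smoothing (9)."""
    out = []
    for j in range(3):
        x = clip.samples[:, j]
        out += [float(np.sqrt(np.mean(_boxcar_smooth(x, k) ** 2)))
                for k in _RMS_KERNELS]
    return np.array(out)


def extreme_features(clip: UniformClip) -> np.ndarray:
    """Per axis: min, max, |min|, |max| (12 values)."""
    out = []
    for j in range(3):
        lo, hi = float(np.min(clip.samples[:, j])), float(np.max(clip.samples[:, j]))
        out += [lo, hi, abs(lo), abs(hi)]
    return np.array(out)


def histogram_features(clip: UniformClip) -> np.ndarray:
    """Per axis, counts in 9 unit-width z-score bins centred at −4…+4 (27).

    Samples are z-scored with the axis's own clip mean and population sd;
    values beyond ±4.5 are clipped into the nearest extreme bin.  A
    zero-variance axis puts all 200 samples in the centre bin.
    """
    out = []
    for j in range(3):
        x = clip.samples[:, j]
        sd = float(np.std(x))
        if sd == 0.0:
            counts = np.zeros(9)
            counts[4] = CLIP_SAMPLES
        else:
            z = (x - np.mean(x)) / sd
            idx = np.clip(np.floor(z + 0.5), -4, 4).astype(int) + 4
            counts = np.bincount(idx, minlength=9).astype(float)
        out.append(counts)
    return np.concatenate(out)


def fourier_features(clip: UniformClip) -> np.ndarray:
    """Per axis, 32 samples of the one-sided Fourier magnitude spectrum (96).

    The 200-sample DFT gives 101 magnitude bins from DC to the 10 Hz
    Nyquist frequency; these are linearly interpolated at 32 evenly spaced
    frequencies over [0, 10] Hz inclusive.
    """
    nyquist = RATE / 2.0
    bin_freqs = np.fft.rfftfreq(CLIP_SAMPLES, d=1.0 / RATE)
    target = np.linspace(0.0, nyquist, N_FOURIER_SAMPLES)
    out = []
    for j in range(3):
        mags = np.abs(np.fft.rfft(clip.samples[:, j]))
        out.append(np.interp(target, bin_freqs, mags))
    return np.concatenate(out)


def magnitude_feature(clip: UniformClip) -> np.ndarray:
    """Mean Euclidean norm of the (x, y, z) samples — 9.8 m/s² at rest (1)."""
    return np.array([float(np.mean(np.linalg.norm(clip.samples, axis=1)))])


def cross_product_features(clip: UniformClip) -> np.ndarray:
    """Means of the elementwise products xy, xz, yz, then their |·| (6)."""
    x, y, z = clip.samples[:, 0], clip.samples[:, 1], clip.samples[:, 2]
    means = np.array([np.mean(x * y), np.mean(x * z), np.mean(y * z)])
    return np.concatenate([means, np.abs(means)])


_GROUP_FUNCS = {
    "moments": moment_features,
    "diff_moments": diff_moment_features,
    "smoothed_rms": smoothed_rms_features,
    "extremes": extreme_features,
    "histogram": histogram_features,
    "fourier": fourier_features,
    "magnitude": magnitude_feature,
}


def extract_features(clip: UniformClip) -> FeatureVector:
    """Concatenate all groups in registry order into one 178-vector."""
    parts = [_GROUP_FUNCS[g](clip) for g in GROUP_ORDER[:7]]
    parts.append(cross_product_features(clip))  # covers both cross groups
    values = np.concatenate(parts)
    if not np.all(np.isfinite(values)):
        bad = [FEATURE_NAMES[i] for i in np.flatnonzero(~np.isfinite(values))]
        raise ValueError(f"non-finite feature value(s): {bad}")
    return FeatureVector(values)
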