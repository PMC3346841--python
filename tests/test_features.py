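"""The Table-of-features bank: group values, registry order and oracle equivalence."""

import numpy as np
import pytest
from hypothesis import given, strategies as st

from fallsense import UniformClip, extract_features
from fallsense.features import (FEATURE_NAMES, FEATURE_REGISTRY, GROUP_SIZES,
                                N_FEATURES, cross_product_features,
                                diff_moment_features, extreme_features,
                                fourier_features, histogram_features,
                                magnitude_feature, moment_features,
                                smoothed_rms_features)

import oracles


def _clip(samples):
    return UniformClip(np.asarray(samples, dtype=float), center_time=5.0)


def _const(x, y, z):
    return _clip(np.tile([x, y, z], (200, 1)))


def test_registry_group_sizes():
    assert tuple(GROUP_SIZES.values()) == (15, 12, 9, 12, 27, 96, 1, 3, 3)
    assert N_FEATURES == 178 == len(FEATURE_NAMES)
    counts = {}
    for group, _ in FEATURE_REGISTRY:
        counts[group] = counts.get(group, 0) + 1
    assert counts == GROUP_SIZES


def test_moments_of_constant_clip_follow_degenerate_rule():
    vals = moment_features(_const(-2.0, 0.0, 3.5))
    assert np.allclose(vals.reshape(3, 5),
                       [[-2, 2, 0, 0, 0], [0, 0, 0, 0, 0], [3.5, 3.5, 0, 0, 0]])


def test_moments_of_alternating_signal():
    samples = np.zeros((200, 3))
    samples[:, 1] = np.tile([1.0, -1.0], 100)
    mean, abs_mean, sd, skew, kurt = moment_features(_clip(samples))[5:10]
    assert (mean, abs_mean, sd, skew, kurt) == (0.0, 0.0, 1.0, 0.0, 1.0)


def test_diff_moments_of_ramp():
    samples = np.zeros((200, 3))
    samples[:, 0] = np.arange(200) * 0.25  # slope 5 m/s³ at 20 Hz, exact steps
    dmean, dsd, dskew, dkurt = diff_moment_features(_clip(samples))[:4]
    assert dmean == pytest.approx(5.0 * 0.05)
    assert (dsd, dskew, dkurt) == (0.0, 0.0, 0.0)


def test_smoothed_rms_preserves_constants_and_rest_anchor(rest_clip):
    vals = smoothed_rms_features(_const(-3.0, 0.0, 2.0)).reshape(3, 3)
    assert np.allclose(vals, [[3.0] * 3, [0.0] * 3, [2.0] * 3])
    rest = smoothed_rms_features(rest_clip).reshape(3, 3)
    assert np.allclose(rest[0], 9.8, atol=0.05)


def test_smoothing_shrinks_rms_of_zero_mean_noise(make_clip):
    vals = smoothed_rms_features(make_clip(seed=3, offset=(0, 0, 0))).reshape(3, 3)
    assert np.all(vals[:, 2] <= vals[:, 0])  # 10-pt kernel vs no kernel


def test_extremes():
    samples = np.tile([1.0, 0.0, 0.0], (200, 1))
    samples[10, 1], samples[20, 1] = -2.0, 5.0
    vals = extreme_features(_clip(samples)).reshape(3, 4)
    assert np.allclose(vals[1], [-2.0, 5.0, 2.0, 5.0])
    assert np.allclose(vals[0], [1.0, 1.0, 1.0, 1.0])


def test_histogram_counts_sum_and_degenerate_rule(make_clip):
    counts = histogram_features(make_clip(seed=8)).reshape(3, 9)
    assert np.all(counts.sum(axis=1) == 200)
    const = histogram_features(_const(1.0, 2.0, 3.0)).reshape(3, 9)
    assert np.all(const[:, 4] == 200) and np.all(np.delete(const, 4, axis=1) == 0)


def test_histogram_clips_outliers_into_extreme_bins():
    samples = np.zeros((200, 3))
    samples[0, 0] = 1000.0  # z-score ~ +14 ends up in the +4 bin
    counts = histogram_features(_clip(samples)).reshape(3, 9)
    assert counts[0, 8] == 1


def test_fourier_constant_clip_is_pure_dc():
    vals = fourier_features(_const(2.5, 0.0, 0.0)).reshape(3, 32)
    assert vals[0, 0] == pytest.approx(200 * 2.5)
    assert np.allclose(vals[0, 1:], 0.0, atol=1e-9)


def test_fourier_sinusoid_concentrates_near_its_frequency():
    t = np.arange(200) / 20.0
    samples = np.zeros((200, 3))
    samples[:, 2] = np.sin(2 * np.pi * 2.0 * t)
    vals = fourier_features(_clip(samples)).reshape(3, 32)
    freqs = np.linspace(0, 10, 32)
    assert abs(freqs[np.argmax(vals[2, 1:]) + 1] - 2.0) < 0.5


def test_magnitude_feature_examples(rest_clip):
    assert magnitude_feature(rest_clip)[0] == pytest.approx(9.8, abs=0.05)
    assert magnitude_feature(_const(0, 0, 0))[0] == 0.0
    assert magnitude_feature(_const(3.0, 4.0, 0.0))[0] == pytest.approx(5.0)


def test_cross_products_and_sign_flip(make_clip):
    vals = cross_product_features(_const(1.0, 2.0, 3.0))
    assert np.allclose(vals, [2.0, 3.0, 6.0, 2.0, 3.0, 6.0])
    clip = make_clip(seed=12)
    flipped = UniformClip(clip.samples * np.array([1.0, -1.0, 1.0]),
                          center_time=clip.center_time)
    v0, v1 = cross_product_features(clip), cross_product_features(flipped)
    assert np.allclose(v1[:3], [-v0[0], v0[1], -v0[2]])  # xy and yz negate
    assert np.allclose(v1[3:], v0[3:])  # absolute values unchanged


def test_extract_features_is_deterministic_and_finite(make_clip):
    clip = make_clip(seed=4)
    a, b = extract_features(clip), extract_features(clip)
    assert np.array_equal(a.values, b.values)
    assert a.values.shape == (178,) and np.all(np.isfinite(a.values))


def test_rest_clip_anchors(rest_clip):
    fv = extract_features(rest_clip).as_dict()
    assert fv["mean_magnitude"] == pytest.approx(9.8, abs=0.05)
    assert fv["hist_x_p0"] + fv["hist_x_p1"] + fv["hist_x_m1"] > 100


def test_axis_permutation_permutes_feature_blocks(make_clip):
    """Swapping y and z swaps their per-axis blocks (x block untouched)."""
    clip = make_clip(seed=6)
    swapped = UniformClip(clip.samples[:, [0, 2, 1]], center_time=clip.center_time)
    m0 = moment_features(clip).reshape(3, 5)
    m1 = moment_features(swapped).reshape(3, 5)
    assert np.allclose(m1, m0[[0, 2, 1]])
    h0 = histogram_features(clip).reshape(3, 9)
    h1 = histogram_features(swapped).reshape(3, 9)
    assert np.allclose(h1, h0[[0, 2, 1]])
    c0, c1 = cross_product_features(clip), cross_product_features(swapped)
    # pairs (xy, xz, yz) relabel to (xz, xy, yz)
    assert np.allclose(c1[:3], c0[[1, 0, 2]])


@given(st.integers(0, 10_000))
def test_feature_groups_match_bruteforce_oracles(seed):
    r = np.random.default_rng(seed)
    clip = _clip(np.array([9.8, 0, 0]) + r.normal(size=(200, 3)) * r.uniform(0.1, 5))
    _assert_matches_oracles(clip)


def _assert_matches_oracles(clip):
    cols = [clip.samples[:, j] for j in range(3)]
    assert np.allclose(
        moment_features(clip),
        np.ravel([(m, abs(m), sd, sk, ku) for m, sd, sk, ku in
                  (oracles.oracle_moments(list(c)) for c in cols)]), rtol=1e-9)
    assert np.allclose(
        diff_moment_features(clip),
        np.ravel([oracles.oracle_moments(list(np.diff(c))) for c in cols]),
        rtol=1e-9)
    assert np.allclose(
        smoothed_rms_features(clip),
        [oracles.oracle_smoothed_rms(list(c), k) for c in cols for k in (1, 5, 10)],
        rtol=1e-9)
    assert np.allclose(
        histogram_features(clip),
        np.ravel([oracles.oracle_histogram(list(c)) for c in cols]))
    assert np.allclose(
        fourier_features(clip),
        np.ravel([oracles.oracle_fourier_samples(list(c)) for c in cols]),
        rtol=1e-9, atol=1e-8)
    mags = [float(np.sqrt(x * x + y * y + z * z)) for x, y, z in clip.samples]
    assert magnitude_feature(clip)[0] == pytest.approx(sum(mags) / 200, rel=1e-12)
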