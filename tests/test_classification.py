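"""Classification images, TFCE, permutation masks, region summaries."""

import warnings

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from sirkit.classification import (ci_eeg_stack, ci_map, eye_region_summary,
                                   lateralization_index, max_mi_summary,
                                   permutation_significance, tfce_enhance)
from sirkit.cohort import EpochArray
from sirkit.infocore import equiprobable_bin, scale_mi


def _planted_stack(n=180, h=6, w=6, seed=0):
    rng = np.random.default_rng(seed)
    return rng.random((n, h, w))


def test_ci_map_lights_up_the_driving_pixel():
    stack = _planted_stack()
    drive = equiprobable_bin(stack[:, 2, 3], 3).labels.astype(float)
    img = ci_map(stack, drive + 0.01 * np.random.default_rng(1).random(len(drive)))
    expected = scale_mi(np.log2(3), len(drive))
    assert img.mi[2, 3] == pytest.approx(expected, rel=0.05)
    off = np.delete(img.mi.ravel(), 2 * 6 + 3)
    assert off.max() < 0.3 * img.mi[2, 3]


def test_identical_pixel_columns_get_identical_mi():
    stack = _planted_stack()
    stack[:, 4, 4] = stack[:, 1, 1]
    resp = np.random.default_rng(2).random(stack.shape[0])
    img = ci_map(stack, resp)
    assert img.mi[4, 4] == img.mi[1, 1]


def test_ci_map_refuses_tiny_samples():
    with pytest.raises(ValueError):
        ci_map(_planted_stack(n=20), np.random.default_rng(0).random(20))


def test_eeg_stack_step_consistency():
    rng = np.random.default_rng(3)
    n, h, w = 120, 4, 4
    vis = rng.random((n, h, w))
    times = np.arange(-50, 101, 2.0)
    data = rng.normal(size=(n, 2, len(times)))
    ep = EpochArray(data, times, ("LE", "RE"))
    s2, t2 = ci_eeg_stack(vis, ep, "RE", (0, 100), step_ms=2)
    s4, t4 = ci_eeg_stack(vis, ep, "RE", (0, 100), step_ms=4)
    assert np.array_equal(t4, t2[::2])
    assert np.allclose(s4, s2[::2])
    with pytest.raises(ValueError):
        ci_eeg_stack(vis, ep, "RE", (0, 500))


def test_max_mi_summary_tie_and_single_entry_rules():
    times = np.arange(200.0, 210.0, 2.0)
    stack = np.zeros((5, 3, 3))
    series, img = max_mi_summary(stack, times)
    assert series.peak_latency_ms == 200.0  # earliest time on an all-tie
    assert not img.any()
    stack[2, 1, 2] = 1.0  # t = 204 ms
    series, img = max_mi_summary(stack, times)
    assert series.peak_latency_ms == 204.0
    assert img[1, 2] == 1.0 and img.sum() == 1.0


# -------------------------------------------------------------------- TFCE

def _tfce_bruteforce(m, e=0.5, h_exp=2.0, dh=None):
    """Independent oracle: rebuild clusters by flood fill at every threshold."""
    m = np.asarray(m, dtype=float)
    vmax = m.max()
    if dh is None:
        dh = vmax / 100.0 if vmax > 0 else 1.0
    n_steps = int(np.floor(vmax / dh + 1e-9))
    out = np.zeros_like(m)
    H, W = m.shape
    for k in range(1, n_steps + 1):
        h = k * dh
        supra = m >= h
        seen = np.zeros_like(supra)
        for sy in range(H):
            for sx in range(W):
                if supra[sy, sx] and not seen[sy, sx]:
                    stackpix = [(sy, sx)]
                    seen[sy, sx] = True
                    members = []
                    while stackpix:
                        y, x = stackpix.pop()
                        members.append((y, x))
                        for dy in (-1, 0, 1):
                            for dx in (-1, 0, 1):
                                yy, xx = y + dy, x + dx
                                if (0 <= yy < H and 0 <= xx < W
                                        and supra[yy, xx] and not seen[yy, xx]):
                                    seen[yy, xx] = True
                                    stackpix.append((yy, xx))
                    inc = dh * len(members) ** e * h**h_exp
                    for y, x in members:
                        out[y, x] += inc
    return out


def test_tfce_zero_map_and_isolated_pixel():
    assert not tfce_enhance(np.zeros((8, 8))).any()
    m = np.zeros((11, 11))
    m[5, 5] = 1.0
    score = tfce_enhance(m, dh=0.005)[5, 5]
    assert score == pytest.approx(1.0 / 3.0, rel=0.02)  # integral of h^2 dh


def test_tfce_matches_bruteforce_on_random_maps():
    rng = np.random.default_rng(10)
    for _ in range(10):
        m = rng.random((8, 8))
        m[m < 0.3] = 0.0
        assert np.max(np.abs(tfce_enhance(m) - _tfce_bruteforce(m))) < 1e-9


@settings(max_examples=15, derandomize=True, deadline=None)
@given(st.integers(0, 2**31 - 1), st.floats(1.1, 5.0))
def test_tfce_monotone_under_positive_scaling(seed, c):
    m = np.random.default_rng(seed).random((6, 6))
    base = tfce_enhance(m, dh=m.max() / 50)
    scaled = tfce_enhance(c * m, dh=c * m.max() / 50)
    assert np.all(scaled >= base - 1e-12)


def test_tfce_rejects_bad_inputs():
    with pytest.raises(ValueError):
        tfce_enhance(-np.ones((4, 4)))
    with pytest.raises(ValueError):
        tfce_enhance(np.ones((4, 4)), dh=0.0)


# -------------------------------------------------------- permutation masks

def test_alpha_one_marks_every_positive_statistic():
    stack = _planted_stack(n=120)
    resp = np.random.default_rng(4).random(120)
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        sig = permutation_significance(stack, resp, n_permutations=50, alpha=1.0,
                                       seed=0)
    assert sig.mask.sum() > 0.9 * sig.mask.size


def test_permutation_mask_invariant_to_bin_relabeling():
    stack = _planted_stack(n=150, seed=6)
    resp = stack[:, 1, 1] + 0.2 * np.random.default_rng(5).random(150)
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        a = permutation_significance(stack, resp, 500, seed=2)
        b = permutation_significance(stack, -resp, 500, seed=2)  # reverses bins
    assert np.array_equal(a.mask, b.mask)


def test_insufficient_permutations_rejected():
    stack = _planted_stack(n=100)
    with pytest.raises(ValueError):
        permutation_significance(stack, stack[:, 0, 0], n_permutations=10,
                                 alpha=0.01)


# -------------------------------------------------------- scalar summaries

def test_eye_region_summary_masks():
    img = np.zeros((5, 5))
    img[1, 1] = 2.0
    full = np.ones((5, 5), dtype=bool)
    assert eye_region_summary(img, full) == 2.0
    disjoint = np.zeros((5, 5), dtype=bool)
    disjoint[4, 4] = True
    assert eye_region_summary(img, disjoint) == 0.0
    with pytest.raises(ValueError):
        eye_region_summary(img, np.zeros((5, 5), dtype=bool))


def test_lateralization_index_arithmetic():
    assert lateralization_index(0.41, 0.59) == pytest.approx(-0.18)
    assert lateralization_index(1.0, 0.0) == 1.0
    assert lateralization_index(0.7, 0.7) == 0.0
    with pytest.warns(UserWarning):
        assert np.isnan(lateralization_index(0.0, 0.0))
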