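"""Estimator unit and property tests: binning, plug-in MI, GCMI, co-information."""

import warnings

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from sirkit.infocore import (DegenerateDataWarning, coinformation,
                             copula_normalize, equiprobable_bin, gcmi,
                             mi_discrete, miller_madow, scale_mi)

LN2 = np.log(2.0)


# --------------------------------------------------------------------- binning

def test_equiprobable_bin_splits_1_to_9_evenly():
    b = equiprobable_bin(np.arange(1.0, 10.0), 3)
    assert np.array_equal(b.labels, [0, 0, 0, 1, 1, 1, 2, 2, 2])
    assert not b.degenerate


def test_ties_go_to_the_lower_bin_and_flag_degeneracy():
    b = equiprobable_bin(np.array([0, 0, 0, 0, 0, 0, 1, 2, 3.0]), 3)
    assert np.all(b.labels[:6] == 0)
    assert b.degenerate


def test_binning_rejects_bad_inputs():
    with pytest.raises(ValueError):
        equiprobable_bin(np.arange(10.0), 1)
    with pytest.raises(ValueError):
        equiprobable_bin(np.array([1.0, 2.0]), 3)


@settings(max_examples=25, derandomize=True)
@given(st.integers(0, 2**31 - 1))
def test_bin_labels_invariant_to_monotone_transforms(seed):
    x = np.random.default_rng(seed).normal(size=30)
    a = equiprobable_bin(x, 3).labels
    b = equiprobable_bin(np.exp(x), 3).labels
    assert np.array_equal(a, b)


# --------------------------------------------------------------- discrete MI

def test_identity_variable_reaches_log2_bins():
    x = np.tile([0, 1, 2], 30)
    assert mi_discrete(x, x).value == pytest.approx(np.log2(3), rel=1e-12)


def test_uniform_joint_table_gives_zero_bits():
    x = np.repeat([0, 1, 2], 3)
    y = np.tile([0, 1, 2], 3)
    assert mi_discrete(x, y).value == pytest.approx(0.0, abs=1e-12)


def test_two_by_two_table_hand_computed():
    x = np.repeat([0, 0, 1, 1], [30, 10, 10, 30])
    y = np.repeat([0, 1, 0, 1], [30, 10, 10, 30])
    est = mi_discrete(x, y)
    assert est.value == pytest.approx(0.18872, abs=5e-6)
    assert scale_mi(est.value, 80) == pytest.approx(20.93, abs=0.01)


@settings(max_examples=25, derandomize=True)
@given(st.integers(0, 2**31 - 1))
def test_mi_is_symmetric(seed):
    rng = np.random.default_rng(seed)
    x = rng.integers(0, 3, 60)
    y = rng.integers(0, 4, 60)
    assert mi_discrete(x, y).value == pytest.approx(mi_discrete(y, x).value, abs=1e-14)


def test_coarser_binning_never_gains_information_on_average():
    """Data-processing sanity: merging bins cannot increase MI in expectation."""
    rng = np.random.default_rng(0)
    mi2, mi3 = [], []
    for _ in range(500):
        z = rng.multivariate_normal([0, 0], [[1, 0.5], [0.5, 1]], 60)
        x3 = equiprobable_bin(z[:, 0], 3)
        y3 = equiprobable_bin(z[:, 1], 3)
        mi3.append(mi_discrete(x3, y3).value)
        x2 = (x3.labels >= 2).astype(int)  # merge the lower two bins
        y2 = (y3.labels >= 2).astype(int)
        mi2.append(mi_discrete(x2, y2).value)
    assert np.mean(mi2) <= np.mean(mi3)


# ------------------------------------------------------------------- scaling

def test_scale_mi_arithmetic():
    assert scale_mi(0.0, 100) == 0.0
    assert scale_mi(1.0, 1) == pytest.approx(2 * LN2, rel=1e-12)


def test_miller_madow_correction_values():
    # 3x3 table with 35 observations: correction = 4 / (70 ln 2)
    assert miller_madow(0.5, 3, 3, 35) == pytest.approx(0.5 - 4 / (70 * LN2), rel=1e-12)
    # correction vanishes for very large samples
    assert abs(miller_madow(0.5, 3, 3, 10**6) - 0.5) < 1e-5


def test_miller_madow_removes_most_plugin_bias():
    rng = np.random.default_rng(1)
    vals = []
    for _ in range(1000):
        x = equiprobable_bin(rng.normal(size=100), 3)
        y = equiprobable_bin(rng.normal(size=100), 3)
        vals.append(mi_discrete(x, y, correction="miller_madow").value)
    assert abs(np.mean(vals)) < 0.01


# ---------------------------------------------------------------------- gcmi

def test_copula_normalize_closed_form_quantiles():
    from scipy.special import ndtri
    z = copula_normalize(np.array([10.0, 20.0, 30.0]))
    assert z == pytest.approx(ndtri([0.25, 0.5, 0.75]), abs=1e-12)


def test_copula_normalize_rank_invariance_and_degeneracy():
    x = np.random.default_rng(2).normal(size=50)
    assert np.allclose(copula_normalize(np.exp(x)), copula_normalize(x))
    with pytest.warns(DegenerateDataWarning):
        z = copula_normalize(np.full(10, 3.0))
    assert np.all(z == 0)


def test_gcmi_matches_bivariate_gaussian_closed_form():
    rho = 0.5
    xy = np.random.default_rng(3).multivariate_normal(
        [0, 0], [[1, rho], [rho, 1]], 100_000)
    true = -0.5 * np.log2(1 - rho**2)
    assert gcmi(xy[:, 0], xy[:, 1]).value == pytest.approx(true, abs=0.01)


def test_gcmi_null_bias_is_small():
    rng = np.random.default_rng(4)
    est = [gcmi(rng.normal(size=10_000), rng.normal(size=10_000)).value
           for _ in range(200)]
    assert np.mean(est) > 0  # small positive estimator bias
    assert np.quantile(est, 0.95) < 0.005


def test_gcmi_invariant_to_monotone_marginal_transform():
    rng = np.random.default_rng(5)
    xy = rng.multivariate_normal([0, 0], [[1, 0.6], [0.6, 1]], 2000)
    a = gcmi(xy[:, 0], xy[:, 1]).value
    b = gcmi(xy[:, 0] ** 3, xy[:, 1]).value
    assert a == pytest.approx(b, abs=1e-12)


def test_gcmi_bias_correction_shrinks_null_estimates():
    rng = np.random.default_rng(6)
    x, y = rng.normal(size=500), rng.normal(size=500)
    assert gcmi(x, y, biascorrect=True).value < gcmi(x, y).value


def test_gcmi_input_validation():
    with pytest.raises(ValueError):
        gcmi(np.arange(4.0), np.arange(4.0))  # too few observations
    with pytest.raises(ValueError):
        gcmi(np.arange(10.0), np.arange(11.0))


# ------------------------------------------------------------- co-information

def test_coinformation_copy_equals_pairwise_mi():
    f = np.random.default_rng(7).normal(size=10_000)
    featred = coinformation(f, f, f)
    mi = gcmi(f, f).value
    assert featred == pytest.approx(mi, rel=0.05)


def test_coinformation_null_near_zero():
    rng = np.random.default_rng(8)
    featred = coinformation(rng.normal(size=10_000), rng.normal(size=10_000),
                            rng.normal(size=10_000))
    assert abs(featred) < 0.01


def test_xor_is_synergistic_with_discrete_estimator():
    rng = np.random.default_rng(9)
    a = rng.integers(0, 2, 4000)
    b = rng.integers(0, 2, 4000)
    f = a ^ b
    assert coinformation(f, a, b, estimator="discrete") < -0.9
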