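"""Synthetic behaviour and EEG: nulls, injected effects, reproducibility."""

import numpy as np
import pytest
from scipy.stats import chi2

from sirkit.cohort import EpochArray, simulate_behavior, simulate_eeg, simulate_participant
from sirkit.config import CohortConfig
from sirkit.infocore import equiprobable_bin, mi_discrete, scale_mi


def _scaled_mi(v, rt):
    x = equiprobable_bin(v, 3)
    y = equiprobable_bin(rt, 3)
    return scale_mi(mi_discrete(x, y).value, len(v))


def test_rt_carries_no_eye_information_when_slope_is_zero():
    ccfg = CohortConfig.demo(seed=0, rt_eye_slope=0.0)
    p = simulate_participant(ccfg, "young", 5)
    face = p.trials.is_face
    stat = _scaled_mi(p.trials.eye_visibility["left"][face], p.trials.rt_ms[face])
    assert stat < chi2.ppf(0.95, 4)


def test_group_median_rt_difference_near_configured_200ms():
    ccfg = CohortConfig.demo(seed=0, n_trials=1100)
    med = {}
    for group, seeds in (("young", (50, 51, 52, 53)), ("older", (60, 61, 62, 63))):
        vals = []
        for s in seeds:
            p = simulate_participant(ccfg, group, s)
            sel = p.trials.is_face & p.trials.correct
            vals.append(np.median(p.trials.rt_ms[sel]))
        med[group] = np.median(vals)
    assert med["older"] - med["young"] == pytest.approx(200.0, abs=20.0)


def test_noiseless_rt_strictly_decreasing_in_eye_visibility():
    ccfg = CohortConfig.demo(seed=0, rt_noise=0.0)
    p = simulate_participant(ccfg, "young", 9)
    face = p.trials.is_face
    v = p.trials.eye_visibility["left"][face]
    rt = p.trials.rt_ms[face]
    order = np.argsort(v)
    dv = np.diff(v[order])
    drt = np.diff(rt[order])
    assert np.all(drt[dv > 0] < 0)


def test_noise_trial_rt_independent_of_eye_visibility():
    ccfg = CohortConfig.demo(seed=0)
    p = simulate_participant(ccfg, "young", 13)
    noise = ~p.trials.is_face
    stat = _scaled_mi(p.trials.eye_visibility["left"][noise], p.trials.rt_ms[noise])
    assert stat < chi2.ppf(0.95, 4)


def test_configuration_requires_lateral_electrodes():
    with pytest.raises(ValueError):
        CohortConfig(electrodes=("Oz", "Pz"))


def test_simulate_eeg_smoke_shapes():
    ccfg = CohortConfig.demo(seed=0)
    rng = np.random.default_rng(0)
    is_face = np.ones(20, dtype=bool)
    ev = {k: rng.random(20) for k in ("left", "right", "center")}
    ep = simulate_eeg(is_face, ev, ccfg, "young", rng)
    assert ep.data.shape == (20, len(ccfg.electrodes), len(ep.times))


def test_epoch_axes_and_trial_alignment(young_participant):
    p = young_participant
    ep = p.epochs
    assert np.any(ep.times == 0.0)
    assert np.all(np.diff(ep.times) > 0)
    assert ep.n_trials == p.trials.n_trials
    assert ep.get("RE").shape == (p.trials.n_trials, len(ep.times))
    with pytest.raises(KeyError):
        ep.get("Cz")


def test_participant_reproducible_bit_identical(demo_cfg):
    a = simulate_participant(demo_cfg, "older", 77)
    b = simulate_participant(demo_cfg, "older", 77)
    assert np.array_equal(a.trials.rt_ms, b.trials.rt_ms)
    assert np.array_equal(a.trials.masks, b.trials.masks)
    assert np.array_equal(a.epochs.data, b.epochs.data)
    c = simulate_participant(demo_cfg, "older", 78)
    assert not np.array_equal(a.trials.rt_ms, c.trials.rt_ms)


def test_zero_eye_gain_leaves_no_visibility_information_in_eeg():
    """With the feature gain at zero, the max scaled MI over pixels and time
    is exchangeable with response-shuffled nulls."""
    from sirkit.classification import ci_eeg_stack
    from sirkit.stimuli import oval_mask

    ccfg = CohortConfig.demo(seed=0, eeg_eye_gain={"young": 0.0, "older": 0.0},
                             n_trials=200)
    p = simulate_participant(ccfg, "young", 21)
    face = p.trials.is_face
    valid = oval_mask(ccfg.stimulus, ccfg.analysis_size_px)
    ep = EpochArray(p.epochs.data[face], p.epochs.times, p.epochs.electrodes)
    stack, _ = ci_eeg_stack(p.trials.visibility[face], ep, "RE", (100, 300),
                            valid_mask=valid)
    observed = stack.max()
    rng = np.random.default_rng(1)
    null_max = []
    for _ in range(19):
        perm = rng.permutation(ep.n_trials)
        ep_null = EpochArray(ep.data[perm], ep.times, ep.electrodes)
        s, _ = ci_eeg_stack(p.trials.visibility[face], ep_null, "RE", (100, 300),
                            valid_mask=valid)
        null_max.append(s.max())
    assert observed < max(null_max)


def test_epoch_array_validates_time_axis():
    times = np.arange(-10, 11, 2.0)
    data = np.zeros((3, 2, len(times)))
    EpochArray(data, times, ("LE", "RE"))
    with pytest.raises(ValueError):
        EpochArray(data, times + 1.0, ("LE", "RE"))  # no 0 ms sample
    with pytest.raises(ValueError):
        EpochArray(data, times[::-1], ("LE", "RE"))
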