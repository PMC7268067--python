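"""Feature redundancy (co-information) within and across participants.

Within a participant, ``FeatRed(t)`` measures the stimulus information about
eye visibility that EEG activity and reaction time share:

    FeatRed(t) = MI([V(t), dV(t)]; eye) + MI(RT; eye) - MI([V(t), dV(t), RT]; eye)

with each term estimated by Gaussian-copula MI and the EEG treated as a
two-dimensional signal (voltage plus its instantaneous temporal derivative,
here a centred first difference with edge replication). The latency of the
trace maximum is the feature-redundancy peak time (FRP).

Across participants, GroupRed quantifies how much the FRP and the median RT
make a *common* prediction of age group:

    GroupRed = MI(FRP; group) + MI(RT; group) - MI([FRP, RT]; group)

after tertile quantisation of FRP and RT across all participants, with
Miller-Madow bias correction on every term and a percentile bootstrap over
participants for the confidence interval.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .cohort import EpochArray
from .infocore import gcmi, mi_discrete

__all__ = [
    "RedundancyTrace",
    "GroupRedundancyResult",
    "featred_timecourse",
    "tertile_quantize",
    "group_redundancy",
]


@dataclass
class RedundancyTrace:
    times: np.ndarray  # ms
    featred: np.ndarray  # bits per time point
    peak_value: float
    peak_latency_ms: float  # FRP (earliest tie)


@dataclass
class GroupRedundancyResult:
    mi_frp_group: float  # bits
    mi_rt_group: float
    mi_joint_group: float
    group_red: float  # = mi_frp + mi_rt - mi_joint, exact arithmetic
    redundancy_fraction: float  # group_red / mi_frp_group
    ci_low: float
    ci_high: float
    n_boot: int
    alpha: float
    seed: int
    bootstrap_values: np.ndarray = field(repr=False, default=None)


def _temporal_derivative(volts: np.ndarray) -> np.ndarray:
    """Centred first difference along time with edge replication."""
    padded = np.concatenate([volts[:, :1], volts, volts[:, -1:]], axis=1)
    return (padded[:, 2:] - padded[:, :-2]) / 2.0


def featred_timecourse(
    eye_visibility: np.ndarray,
    epochs: EpochArray,
    electrode: str,
    rt_ms: np.ndarray,
    window_ms: tuple[float, float] = (0.0, 400.0),
    select: np.ndarray | None = None,
) -> RedundancyTrace:
    """FeatRed at every sample of ``window_ms`` for one electrode.

    ``eye_visibility`` is the per-trial mean mask value in the eye region
    contralateral to the electrode (left eye for RE, right eye for LE).
    ``select`` optionally restricts to a trial subset (e.g. face trials).
    """
    v = np.asarray(eye_visibility, dtype=float)
    rt = np.asarray(rt_ms, dtype=float)
    volts = epochs.get(electrode)
    if select is not None:
        v, rt, volts = v[select], rt[select], volts[select]
    if len(v) != len(rt) or len(v) != volts.shape[0]:
        raise ValueError("misaligned trial counts")
    if np.all(v == v[0]):
        raise ValueError("degenerate eye visibility: all trials equal")
    dv = _temporal_derivative(volts)
    sel = (epochs.times >= window_ms[0]) & (epochs.times <= window_ms[1])
    times = epochs.times[sel]
    volts, dv = volts[:, sel], dv[:, sel]

    mi_rt = gcmi(rt, v).value
    trace = np.empty(len(times))
    rt_col = rt[:, None]
    for i in range(len(times)):
        eeg = np.column_stack([volts[:, i], dv[:, i]])
        mi_eeg = gcmi(eeg, v).value
        mi_joint = gcmi(np.concatenate([eeg, rt_col], axis=1), v).value
        trace[i] = mi_eeg + mi_rt - mi_joint
    peak_idx = int(np.argmax(trace))
    return RedundancyTrace(times, trace, float(trace[peak_idx]),
                           float(times[peak_idx]))


def tertile_quantize(x: np.ndarray, n_bins: int = 3) -> np.ndarray:
    """Equally populated bins across observations, ties broken by stable
    rank order; bin sizes differ by at most one when N % n_bins != 0."""
    x = np.asarray(x)
    n = len(x)
    order = np.argsort(x, kind="stable")
    labels = np.empty(n, dtype=np.int64)
    labels[order] = (np.arange(n) * n_bins) // n
    return labels


def _groupred_terms(frp_q, rt_q, group) -> tuple[float, float, float]:
    joint = frp_q * 3 + rt_q
    mi_f = mi_discrete(frp_q, group, correction="miller_madow").value
    mi_r = mi_discrete(rt_q, group, correction="miller_madow").value
    mi_j = mi_discrete(joint, group, correction="miller_madow").value
    return mi_f, mi_r, mi_j


def group_redundancy(
    frp_ms: np.ndarray,
    median_rt_ms: np.ndarray,
    group_labels: np.ndarray,
    n_boot: int = 1000,
    alpha: float = 0.05,
    seed: int = 0,
) -> GroupRedundancyResult:
    """GroupRed with a percentile bootstrap CI over participants.

    FRP and RT are tertile-quantised across *all* participants (quantisation
    is recomputed inside every bootstrap resample); group labels are encoded
    as integers. Requires at least six participants per group so tertiles
    are meaningful. Negative Miller-Madow corrected terms are kept as-is.
    """
    frp = np.asarray(frp_ms, dtype=float)
    rt = np.asarray(median_rt_ms, dtype=float)
    groups = np.unique(np.asarray(group_labels))
    g = np.searchsorted(groups, np.asarray(group_labels)).astype(np.int64)
    n = len(frp)
    if len(rt) != n or len(g) != n:
        raise ValueError("misaligned participant vectors")
    counts = np.bincount(g)
    if counts.min() < 6:
        raise ValueError("need at least six participants per group")
    if np.all(frp == frp[0]) or np.all(rt == rt[0]):
        raise ValueError("degenerate FRP or RT: all participants identical")

    def statistic(idx):
        fq = tertile_quantize(frp[idx])
        rq = tertile_quantize(rt[idx])
        mi_f, mi_r, mi_j = _groupred_terms(fq, rq, g[idx])
        return mi_f, mi_r, mi_j

    all_idx = np.arange(n)
    mi_f, mi_r, mi_j = statistic(all_idx)
    gred = mi_f + mi_r - mi_j

    rng = np.random.default_rng(seed)
    boot = np.empty(n_boot)
    for b in range(n_boot):
        idx = rng.integers(0, n, n)
        bf, br, bj = statistic(idx)
        boot[b] = bf + br - bj
    lo, hi = np.quantile(boot, [alpha / 2, 1 - alpha / 2])
    frac = gred / mi_f if mi_f != 0 else float("nan")
    return GroupRedundancyResult(mi_f, mi_r, mi_j, gred, frac,
                                 float(lo), float(hi), n_boot, alpha, seed,
                                 bootstrap_values=boot)
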