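"""Event-related potentials: condition means, N170 peak, ERP_STD onset.

The N170 is the occipito-temporal negative deflection ~170 ms poststimulus;
its latency per participant is the argmin of the mean ERP between 110 and
230 ms. ERP_STD -- the standard deviation across electrodes of the mean ERP,
baseline-centred -- summarises the whole-scalp evoked response in a single
time course; its onset marks the first cortical response to the stimulus.

Onsets are estimated in two steps: (1) locate the first poststimulus local
maximum at least ``peak_factor`` (default 5) times the largest baseline peak
(absolute extrema); (2) fit, on the segment up to that peak, a continuous
two-segment piecewise-linear model -- intercept plus two hinge bases, the
same model class as a three-basis-function regression spline -- by exhaustive
least squares over candidate knots, and report the best-fitting knot as the
onset. The exhaustive grid search is deterministic and, at this problem
size, equivalent to an adaptive spline fit.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy.signal import argrelextrema

from .cohort import EpochArray

__all__ = [
    "ERP",
    "N170Peak",
    "OnsetEstimate",
    "condition_erp",
    "n170_peak",
    "erp_std_timecourse",
    "detect_onset",
]


@dataclass
class ERP:
    data: np.ndarray  # (electrodes, samples) mean voltage
    times: np.ndarray
    electrodes: tuple
    condition: str
    n_trials: int

    def get(self, label: str) -> np.ndarray:
        return self.data[self.electrodes.index(label)]


@dataclass
class N170Peak:
    latency_ms: float
    amplitude: float
    boundary_warning: bool  # minimum sits at a window edge


@dataclass
class OnsetEstimate:
    found: bool
    onset_ms: float = float("nan")
    first_peak_ms: float = float("nan")
    knot_ms: float = float("nan")
    slopes: tuple = (float("nan"), float("nan"))
    sse: float = float("nan")


def condition_erp(epochs: EpochArray, select: np.ndarray, condition: str) -> ERP:
    """Mean ERP across the selected trials (boolean or index array)."""
    sel = np.asarray(select)
    data = epochs.data[sel].mean(axis=0)
    n = int(sel.sum()) if sel.dtype == bool else len(sel)
    if n == 0:
        raise ValueError("no trials selected")
    return ERP(data, epochs.times, tuple(epochs.electrodes), condition, n)


def n170_peak(erp: ERP, electrode: str,
              window_ms: tuple[float, float] = (110.0, 230.0)) -> N170Peak:
    """Latency and amplitude of the minimum mean ERP in ``window_ms``.

    Ties resolve to the earliest sample. A minimum at either window edge is
    flagged (the trace may be monotone there rather than peaked).
    """
    v = erp.get(electrode)
    sel = (erp.times >= window_ms[0]) & (erp.times <= window_ms[1])
    if not sel.any():
        raise ValueError("N170 window outside the epoch time axis")
    tw, vw = erp.times[sel], v[sel]
    i = int(np.argmin(vw))
    return N170Peak(float(tw[i]), float(vw[i]), i == 0 or i == len(vw) - 1)


def erp_std_timecourse(
    erp: ERP, baseline_window_ms: tuple[float, float] | None = None
) -> tuple[np.ndarray, np.ndarray]:
    """SD across electrodes of the mean ERP, mean-baseline centred.

    Sample SD (ddof=1) at each time point; the mean over the prestimulus
    baseline window (default: everything before 0 ms) is subtracted.
    """
    if erp.data.shape[0] < 2:
        raise ValueError("ERP_STD needs at least two electrodes")
    series = erp.data.std(axis=0, ddof=1)
    t0, t1 = baseline_window_ms if baseline_window_ms is not None else (erp.times[0], 0.0)
    base = (erp.times >= t0) & (erp.times < t1)
    if not base.any():
        raise ValueError("baseline window contains no samples")
    return erp.times, series - series[base].mean()


def _local_maxima(values: np.ndarray) -> np.ndarray:
    """Indices of strict interior local maxima."""
    return argrelextrema(values, np.greater)[0]


def _hinge_fit(t: np.ndarray, y: np.ndarray, knot: float) -> tuple[float, np.ndarray]:
    """Least-squares fit of y ~ 1 + (t - k)_+ + (k - t)_+ ; returns (SSE, beta)."""
    X = np.column_stack([np.ones_like(t),
                         np.maximum(t - knot, 0.0),
                         np.maximum(knot - t, 0.0)])
    beta, *_ = np.linalg.lstsq(X, y, rcond=None)
    resid = y - X @ beta
    return float(resid @ resid), beta


def detect_onset(
    times: np.ndarray,
    values: np.ndarray,
    baseline_window_ms: tuple[float, float] = (-300.0, 0.0),
    peak_factor: float = 5.0,
    search_window_ms: tuple[float, float] | None = None,
) -> OnsetEstimate:
    """Onset of an ERP_STD-like time course via the first-peak criterion and
    a two-segment piecewise-linear fit.

    Scaling the signal by any positive constant leaves the onset unchanged
    (both the peak criterion and least squares are scale-equivariant). When
    no poststimulus peak reaches ``peak_factor`` times the largest baseline
    peak, a "no onset" result is returned (``found=False``), distinct from a
    raised error.
    """
    times = np.asarray(times, dtype=float)
    values = np.asarray(values, dtype=float)
    b0, b1 = baseline_window_ms
    if b1 > 0:
        raise ValueError("baseline window must precede stimulus onset")
    base_sel = (times >= b0) & (times < b1)
    post_sel = times >= 0
    if search_window_ms is not None:
        post_sel &= times <= search_window_ms[1]

    # "any peak in the baseline": largest absolute local extremum there
    bvals = values[base_sel]
    bpeaks = np.abs(bvals)[_local_maxima(np.abs(bvals))] if len(bvals) > 2 else np.array([])
    base_height = float(bpeaks.max()) if len(bpeaks) else 0.0

    post_idx = np.flatnonzero(post_sel)
    pv = values[post_idx]
    cand = [i for i in _local_maxima(pv) if pv[i] >= peak_factor * base_height and pv[i] > 0]
    if not cand:
        return OnsetEstimate(found=False)
    peak_i = post_idx[cand[0]]
    first_peak_ms = float(times[peak_i])

    fit_sel = (times >= b0) & (times <= first_peak_ms)
    t, y = times[fit_sel], values[fit_sel]
    # candidate knots on the sample grid, excluding the segment endpoints
    knots = t[1:-1]
    if len(knots) == 0:
        return OnsetEstimate(found=False)
    best = None
    for k in knots:
        sse, beta = _hinge_fit(t, y, k)
        if best is None or sse < best[0] - 1e-12:
            best = (sse, k, beta)
    sse, knot, beta = best
    return OnsetEstimate(True, float(knot), first_peak_ms, float(knot),
                         (float(beta[1]), float(-beta[2])), sse)
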