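"""Robust group statistics: Harrell-Davis quantiles, percentile bootstrap
confidence intervals, trimmed means.

Group summaries throughout the pipeline are Harrell-Davis estimates of the
median (a weighted sum of all order statistics with Beta((n+1)q, (n+1)(1-q))
CDF-increment weights), with 95% percentile-bootstrap confidence intervals
from 1,000 resamples; group differences bootstrap each group independently
and take quantiles of the difference.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
from scipy.stats import trim_mean as _scipy_trim_mean
from scipy.stats.mstats import hdquantiles

__all__ = [
    "BootstrapCI",
    "harrell_davis_quantile",
    "harrell_davis_median",
    "percentile_bootstrap_ci",
    "group_difference_ci",
    "trimmed_mean",
]


@dataclass(frozen=True)
class BootstrapCI:
    estimate: float
    ci_low: float
    ci_high: float
    n_boot: int
    alpha: float
    seed: int

    def contains(self, value: float) -> bool:
        return self.ci_low <= value <= self.ci_high

    def as_dict(self) -> dict:
        return {"estimate": self.estimate, "ci_low": self.ci_low,
                "ci_high": self.ci_high, "n_boot": self.n_boot,
                "alpha": self.alpha, "seed": self.seed}


def harrell_davis_quantile(x: np.ndarray, q: float = 0.5) -> float:
    """Harrell-Davis estimate of the q-th quantile."""
    x = np.asarray(x, dtype=float)
    if len(x) < 2:
        raise ValueError("need at least two observations")
    if not 0.0 < q < 1.0:
        raise ValueError("q must lie strictly between 0 and 1")
    return float(hdquantiles(x, prob=[q])[0])


def harrell_davis_median(x: np.ndarray) -> float:
    return harrell_davis_quantile(x, 0.5)


def _resample_statistics(x, statistic, n_boot, rng):
    x = np.asarray(x, dtype=float)
    idx = rng.integers(0, len(x), (n_boot, len(x)))
    samples = x[idx]
    try:  # vectorised fast path for axis-aware statistics
        out = np.asarray(statistic(samples, axis=1), dtype=float)
        if out.shape == (n_boot,):
            return out
    except TypeError:
        pass
    return np.array([statistic(samples[b]) for b in range(n_boot)], dtype=float)


def percentile_bootstrap_ci(
    x: np.ndarray,
    statistic=np.median,
    n_boot: int = 1000,
    alpha: float = 0.05,
    seed: int = 0,
) -> BootstrapCI:
    """CI from the (alpha/2, 1-alpha/2) quantiles of ``n_boot`` resampled
    statistics. Deterministic for a fixed seed."""
    if n_boot < 100:
        warnings.warn("fewer than 100 bootstrap samples: CI is unstable",
                      stacklevel=2)
    rng = np.random.default_rng(seed)
    x = np.asarray(x, dtype=float)
    boot = _resample_statistics(x, statistic, n_boot, rng)
    lo, hi = np.quantile(boot, [alpha / 2, 1 - alpha / 2])
    return BootstrapCI(float(statistic(x)), float(lo), float(hi),
                       n_boot, alpha, seed)


def group_difference_ci(
    x: np.ndarray,
    y: np.ndarray,
    statistic=np.median,
    n_boot: int = 1000,
    alpha: float = 0.05,
    seed: int = 0,
) -> BootstrapCI:
    """Percentile bootstrap CI of ``statistic(x) - statistic(y)``; the two
    groups are resampled independently."""
    rng = np.random.default_rng(seed)
    bx = _resample_statistics(x, statistic, n_boot, rng)
    by = _resample_statistics(y, statistic, n_boot, rng)
    diff = bx - by
    lo, hi = np.quantile(diff, [alpha / 2, 1 - alpha / 2])
    est = float(statistic(np.asarray(x, dtype=float))
                - statistic(np.asarray(y, dtype=float)))
    return BootstrapCI(est, float(lo), float(hi), n_boot, alpha, seed)


def trimmed_mean(x: np.ndarray, trim: float = 0.2) -> float:
    """Mean after removing ``floor(trim * n)`` smallest and largest values."""
    x = np.asarray(x, dtype=float)
    if not 0.0 <= trim < 0.5:
        raise ValueError("trim must lie in [0, 0.5)")
    if trim > 0 and len(x) < 5:
        raise ValueError("too few observations for trimming")
    return float(_scipy_trim_mean(x, trim))
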