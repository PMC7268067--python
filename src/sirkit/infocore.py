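"""Information-theoretic estimators.

Two estimator families are used throughout the pipeline:

* discrete plug-in MI on equiprobably binned variables (three bins by
  default), with the ``2 N ln 2`` scaling that turns MI in bits into the G
  log-likelihood statistic of an independence test, and an optional
  Miller-Madow small-sample bias correction;
* Gaussian-copula MI (GCMI): each margin is rank-normalised to a standard
  normal and the MI of the resulting Gaussian copula is computed from
  covariance determinants. GCMI is a robust lower bound on the true MI,
  invariant to monotone marginal transforms, and extends naturally to
  multivariate responses, which the co-information (redundancy) measure
  needs.

Co-information of a stimulus feature with two responses is
``MI(a; f) + MI(b; f) - MI([a, b]; f)``: positive values are redundancy
(overlapping information about the feature), negative values synergy.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
from scipy.special import ndtri, psi
from scipy.stats import rankdata

__all__ = [
    "DegenerateDataWarning",
    "BinnedVariable",
    "MIEstimate",
    "equiprobable_bin",
    "bin_stack",
    "mi_discrete",
    "mi_from_counts",
    "scale_mi",
    "miller_madow",
    "copula_normalize",
    "gcmi",
    "coinformation",
]

LN2 = np.log(2.0)


class DegenerateDataWarning(UserWarning):
    """Raised when ties or constant input defeat equiprobable binning."""


@dataclass(frozen=True)
class BinnedVariable:
    """Integer labels 0..n_bins-1 per observation plus the quantile edges."""

    labels: np.ndarray
    n_bins: int
    edges: np.ndarray
    degenerate: bool = False

    def __len__(self) -> int:
        return len(self.labels)


@dataclass(frozen=True)
class MIEstimate:
    value: float
    units: str  # "bits" or "scaled"
    n_obs: int
    estimator: str  # "plugin", "plugin_mm", "gcmi"

    def scaled(self) -> "MIEstimate":
        if self.units != "bits":
            return self
        return MIEstimate(scale_mi(self.value, self.n_obs), "scaled",
                          self.n_obs, self.estimator)


def equiprobable_bin(x: np.ndarray, n_bins: int = 3) -> BinnedVariable:
    """Bin a continuous vector at its empirical k/B quantiles.

    Values exactly on an edge go to the lower bin (deterministic tie rule; no
    jitter). When ties make the bin occupancies differ by more than one the
    result is flagged degenerate rather than rejected.
    """
    x = np.asarray(x, dtype=float)
    if n_bins < 2:
        raise ValueError("need at least two bins")
    if x.ndim != 1 or len(x) < n_bins:
        raise ValueError("input must be a vector with length >= n_bins")
    qs = np.arange(1, n_bins) / n_bins
    edges = np.quantile(x, qs)
    labels = np.zeros(len(x), dtype=np.int64)
    for e in edges:
        labels += x > e
    occ = np.bincount(labels, minlength=n_bins)
    degenerate = bool(occ.max() - occ.min() > 1)
    return BinnedVariable(labels, n_bins, edges, degenerate)


def bin_stack(stack: np.ndarray, n_bins: int = 3) -> tuple[np.ndarray, np.ndarray]:
    """Vectorised :func:`equiprobable_bin` over the columns of (N, P) data.

    Returns ``(labels, degenerate)`` with labels (N, P) int8 and a boolean
    degeneracy flag per column. Identical tie rule to the scalar version.
    """
    stack = np.asarray(stack, dtype=float)
    n, p = stack.shape
    qs = np.arange(1, n_bins) / n_bins
    edges = np.quantile(stack, qs, axis=0)  # (B-1, P)
    labels = np.zeros((n, p), dtype=np.int8)
    for k in range(n_bins - 1):
        labels += stack > edges[k]
    occ = np.stack([(labels == b).sum(axis=0) for b in range(n_bins)])
    degenerate = (occ.max(axis=0) - occ.min(axis=0)) > 1
    return labels, degenerate


def _as_labels(v) -> tuple[np.ndarray, int]:
    if isinstance(v, BinnedVariable):
        return v.labels, v.n_bins
    v = np.asarray(v)
    if not np.issubdtype(v.dtype, np.integer):
        raise TypeError("expected integer labels or a BinnedVariable")
    return v, int(v.max()) + 1 if len(v) else 0


def mi_from_counts(counts: np.ndarray) -> float:
    """Plug-in MI in bits from a contingency table (last two axes)."""
    counts = np.asarray(counts, dtype=float)
    n = counts.sum(axis=(-2, -1), keepdims=True)
    pxy = counts / n
    px = pxy.sum(axis=-1, keepdims=True)
    py = pxy.sum(axis=-2, keepdims=True)
    with np.errstate(divide="ignore", invalid="ignore"):
        term = pxy * np.log2(pxy / (px * py))
    return float(np.nansum(term)) if counts.ndim == 2 else np.nansum(term, axis=(-2, -1))


def mi_discrete(x, y, correction: str | None = None) -> MIEstimate:
    """Plug-in MI (bits) between two discrete variables.

    ``correction="miller_madow"`` subtracts the analytic small-sample bias
    using the number of *occupied* categories; the corrected value may be
    negative, signalling information indistinguishable from zero.
    """
    xl, bx = _as_labels(x)
    yl, by = _as_labels(y)
    if len(xl) != len(yl):
        raise ValueError("inputs must have equal length")
    if len(xl) == 0:
        raise ValueError("empty input")
    n = len(xl)
    counts = np.bincount(xl * by + yl, minlength=bx * by).reshape(bx, by)
    mi = mi_from_counts(counts)
    if correction is None:
        return MIEstimate(mi, "bits", n, "plugin")
    if correction != "miller_madow":
        raise ValueError(f"unknown correction {correction!r}")
    kx = int((counts.sum(axis=1) > 0).sum())
    ky = int((counts.sum(axis=0) > 0).sum())
    kxy = int((counts > 0).sum())
    # MI = Hx + Hy - Hxy with each entropy Miller-Madow corrected by (K-1)/2N
    mi_mm = mi + ((kx - 1) + (ky - 1) - (kxy - 1)) / (2.0 * n * LN2)
    return MIEstimate(mi_mm, "bits", n, "plugin_mm")


def scale_mi(mi_bits: float, n_obs: int) -> float:
    """``2 * N * ln 2 * MI``: the G statistic of a log-likelihood
    independence test; used so MI maps are comparable across participants
    with different trial counts."""
    if n_obs < 1:
        raise ValueError("n_obs must be >= 1")
    return 2.0 * n_obs * LN2 * float(mi_bits)


def miller_madow(mi_plugin_bits: float, rx: int, ry: int, n_obs: int) -> float:
    """Miller-Madow corrected MI for an ``rx`` x ``ry`` table:
    ``MI - (rx-1)(ry-1) / (2 N ln 2)``.

    ``rx``/``ry`` count the occupied categories of each margin (equal to the
    table dimensions when every cell row/column is populated). The corrected
    value is reported even when negative.
    """
    return float(mi_plugin_bits) - (rx - 1) * (ry - 1) / (2.0 * n_obs * LN2)


# --------------------------------------------------------------------------
# Gaussian-copula MI
# --------------------------------------------------------------------------

def copula_normalize(x: np.ndarray) -> np.ndarray:
    """Map each column of ``x`` through its empirical copula to standard
    normal scores: rank r (ties averaged) -> Phi^{-1}(r / (N + 1)).

    Invariant to strictly monotone transforms of each margin. Constant
    columns come out all-zero and trigger :class:`DegenerateDataWarning`.
    """
    x = np.asarray(x, dtype=float)
    squeeze = x.ndim == 1
    if squeeze:
        x = x[:, None]
    n = x.shape[0]
    out = np.empty_like(x)
    for j in range(x.shape[1]):
        if np.all(x[:, j] == x[0, j]):
            warnings.warn("constant input column in copula_normalize",
                          DegenerateDataWarning, stacklevel=2)
            out[:, j] = 0.0
        else:
            out[:, j] = ndtri(rankdata(x[:, j], method="average") / (n + 1))
    return out[:, 0] if squeeze else out


def _chol_logdet_sum(c: np.ndarray) -> float:
    """Sum of log diagonal Cholesky factors (= 0.5 * logdet)."""
    return float(np.sum(np.log(np.diag(np.linalg.cholesky(c)))))


def _gauss_mi_bits(z: np.ndarray, kx: int, biascorrect: bool) -> float:
    """Gaussian MI between the first ``kx`` and remaining columns of ``z``."""
    n, d = z.shape
    c = np.cov(z, rowvar=False).reshape(d, d)
    # tiny ridge keeps exact-copy constructions finite (regularised estimate)
    c = c + np.eye(d) * (1e-9 * np.trace(c) / d)
    try:
        hx = _chol_logdet_sum(c[:kx, :kx])
        hy = _chol_logdet_sum(c[kx:, kx:])
        hxy = _chol_logdet_sum(c)
    except np.linalg.LinAlgError as err:
        raise np.linalg.LinAlgError("singular joint covariance in gcmi") from err
    if biascorrect:
        psiterms = psi((n - np.arange(1, d + 1)) / 2.0) / 2.0
        dterm = np.log(2.0 / (n - 1)) / 2.0
        ky = d - kx
        hx -= kx * dterm + psiterms[:kx].sum()
        hy -= ky * dterm + psiterms[:ky].sum()
        hxy -= d * dterm + psiterms.sum()
    return (hx + hy - hxy) / LN2


def gcmi(x: np.ndarray, y: np.ndarray, biascorrect: bool = False) -> MIEstimate:
    """Gaussian-copula MI (bits) between continuous variables.

    ``x`` (N,) or (N, k) and ``y`` (N,) or (N, m). Each dimension is copula-
    normalised, then the parametric Gaussian MI is computed from empirical
    covariance determinants. The parametric digamma bias correction is
    available but off by default.
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    x2 = x[:, None] if x.ndim == 1 else x
    y2 = y[:, None] if y.ndim == 1 else y
    if x2.shape[0] != y2.shape[0]:
        raise ValueError("x and y must have the same number of observations")
    n, kx = x2.shape
    km = y2.shape[1]
    if n <= kx + km + 2:
        raise ValueError("too few observations for the joint dimensionality")
    z = copula_normalize(np.concatenate([x2, y2], axis=1))
    return MIEstimate(_gauss_mi_bits(z, kx, biascorrect), "bits", n, "gcmi")


def coinformation(feature, resp_a, resp_b, estimator: str = "gcmi") -> float:
    """Co-information (feature redundancy) of two responses about a feature:

        FeatRed = MI(a; f) + MI(b; f) - MI([a, b]; f)

    Positive values quantify redundancy (overlapping information about the
    feature in both responses), negative values synergy. ``estimator="gcmi"``
    treats all inputs as continuous (``resp_a`` may be multi-dimensional);
    ``estimator="discrete"`` expects integer labels and uses plug-in MI --
    required for purely higher-order (e.g. XOR) structure, to which a
    covariance-based estimator is blind.
    """
    if estimator == "gcmi":
        a = np.asarray(resp_a, dtype=float)
        b = np.asarray(resp_b, dtype=float)
        a2 = a[:, None] if a.ndim == 1 else a
        b2 = b[:, None] if b.ndim == 1 else b
        ab = np.concatenate([a2, b2], axis=1)
        return (
            gcmi(a2, feature).value
            + gcmi(b2, feature).value
            - gcmi(ab, feature).value
        )
    if estimator == "discrete":
        fl, _ = _as_labels(np.asarray(feature))
        al, nb_a = _as_labels(np.asarray(resp_a))
        bl, nb_b = _as_labels(np.asarray(resp_b))
        joint = al * nb_b + bl
        return (
            mi_discrete(al, fl).value
            + mi_discrete(bl, fl).value
            - mi_discrete(joint, fl).value
        )
    raise ValueError(f"unknown estimator {estimator!r}")
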