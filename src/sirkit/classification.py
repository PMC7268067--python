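"""MI classification images, TFCE, permutation significance, lateralization.

A classification image is the per-pixel scaled MI between single-trial pixel
visibility and a response (RT, correctness, response category, or the EEG
voltage at one time point). Stacking the EEG variant over poststimulus time
(every sample between 0 and 400 ms by default) yields a pixel x time array
whose maximum traces when and where the brain represents stimulus features.

Significance is assessed with a permutation test on the maximum statistic of
threshold-free cluster enhancement (TFCE) applied to the scaled-MI map, which
controls the familywise error over pixels while favouring spatially
contiguous effects. TFCE parameters default to the technique's standard 2-D
values (E = 0.5, H = 2) with 8-connected clusters.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
from numba import njit

from .cohort import EpochArray
from .infocore import LN2, bin_stack, equiprobable_bin

__all__ = [
    "ClassificationImage",
    "MITimeSeries",
    "SignificanceMask",
    "ci_map",
    "ci_eeg_stack",
    "max_mi_summary",
    "tfce_enhance",
    "permutation_significance",
    "eye_region_summary",
    "lateralization_index",
]


@dataclass
class ClassificationImage:
    mi: np.ndarray  # (H, W) scaled MI (G-statistic units), >= 0
    response_tag: str
    subset_tag: str = "face"
    n_trials: int = 0
    valid: np.ndarray | None = None  # pixels actually tested


@dataclass
class MITimeSeries:
    times: np.ndarray  # ms
    max_mi: np.ndarray  # max over pixels per time point
    argmax_pixel: np.ndarray  # (T, 2) row/col of per-time argmax
    peak_latency_ms: float  # earliest time attaining the global max
    peak_value: float


@dataclass
class SignificanceMask:
    mask: np.ndarray  # boolean, FWER-controlled at alpha
    alpha: float
    n_permutations: int
    threshold: float
    null_max: np.ndarray  # permutation distribution of the max TFCE statistic


def _mi_maps_scaled(pix_labels: np.ndarray, resp_labels: np.ndarray,
                    n_bins: int) -> np.ndarray:
    """Scaled-MI maps for one or many responses sharing the pixel labels.

    ``pix_labels`` (N, P) int, ``resp_labels`` (M, N) int. Returns (M, P)
    scaled MI. The joint table per pixel is accumulated with one bincount per
    response, which keeps the permutation and time-course paths fast.
    """
    n, p = pix_labels.shape
    b = n_bins
    base = np.arange(p, dtype=np.int64)[None, :] * (b * b) + pix_labels.astype(np.int64) * b
    out = np.empty((resp_labels.shape[0], p))
    for m in range(resp_labels.shape[0]):
        idx = base + resp_labels[m].astype(np.int64)[:, None]
        counts = np.bincount(idx.ravel(), minlength=p * b * b).reshape(p, b, b).astype(float)
        pxy = counts / n
        px = pxy.sum(axis=2, keepdims=True)
        py = pxy.sum(axis=1, keepdims=True)
        with np.errstate(divide="ignore", invalid="ignore"):
            term = pxy * np.log2(pxy / (px * py))
        out[m] = np.nansum(term, axis=(1, 2))
    return out * (2.0 * n * LN2)


def _prepare_pixels(vis_stack: np.ndarray, n_bins: int,
                    valid_mask: np.ndarray | None):
    n, h, w = vis_stack.shape
    flat = vis_stack.reshape(n, h * w)
    if valid_mask is not None:
        keep = valid_mask.ravel()
    else:
        keep = np.ones(h * w, dtype=bool)
    labels, degenerate = bin_stack(flat[:, keep], n_bins)
    return labels, degenerate, keep, (h, w)


def ci_map(
    vis_stack: np.ndarray,
    response: np.ndarray,
    n_bins: int = 3,
    valid_mask: np.ndarray | None = None,
    response_tag: str = "RT",
    subset_tag: str = "face",
) -> ClassificationImage:
    """Per-pixel scaled MI between visibility and a per-trial response.

    The response is binned once into ``n_bins`` equiprobable bins; each pixel
    is binned separately (visibility distributions differ strongly across
    pixels). Pixels with degenerate binning, or outside ``valid_mask``, are
    set to zero. Requires at least ``3 * n_bins**2`` trials for stable joint
    tables.
    """
    n = len(response)
    if vis_stack.shape[0] != n:
        raise ValueError("visibility stack and response are misaligned")
    if n < 3 * n_bins**2:
        raise ValueError(f"need at least {3 * n_bins**2} trials")
    labels, degenerate, keep, (h, w) = _prepare_pixels(vis_stack, n_bins, valid_mask)
    resp = equiprobable_bin(response, n_bins).labels[None, :]
    mi = _mi_maps_scaled(labels, resp, n_bins)[0]
    mi[degenerate] = 0.0
    out = np.zeros(h * w)
    out[keep] = mi
    bad = np.zeros(h * w, dtype=bool)
    bad[keep] = degenerate
    return ClassificationImage(out.reshape(h, w), response_tag, subset_tag, n,
                               valid=(keep & ~bad).reshape(h, w))


def ci_eeg_stack(
    vis_stack: np.ndarray,
    epochs: EpochArray,
    electrode: str,
    window_ms: tuple[float, float] = (0.0, 400.0),
    step_ms: float | None = None,
    n_bins: int = 3,
    valid_mask: np.ndarray | None = None,
) -> tuple[np.ndarray, np.ndarray]:
    """Classification images using the single-trial voltage at every sample
    of ``window_ms`` as the response. Returns ``(stack, times)`` with stack
    shape (T, H, W) in scaled MI units.
    """
    volts = epochs.get(electrode)
    t0, t1 = window_ms
    if t0 < epochs.times[0] or t1 > epochs.times[-1]:
        raise ValueError("analysis window outside the epoch range")
    sel = (epochs.times >= t0) & (epochs.times <= t1)
    times = epochs.times[sel]
    if step_ms is not None:
        native = np.median(np.diff(times))
        stride = int(round(step_ms / native))
        if abs(stride * native - step_ms) > 1e-9 or stride < 1:
            raise ValueError("step_ms must be a multiple of the sampling step")
        times = times[::stride]
        sel = np.isin(epochs.times, times)
    labels, degenerate, keep, (h, w) = _prepare_pixels(vis_stack, n_bins, valid_mask)
    resp_cont = volts[:, sel].T  # (T, N)
    resp_labels, _ = bin_stack(resp_cont.T, n_bins)
    mi = _mi_maps_scaled(labels, resp_labels.T, n_bins)
    mi[:, degenerate] = 0.0
    stack = np.zeros((len(times), h * w))
    stack[:, keep] = mi
    return stack.reshape(len(times), h, w), times


def max_mi_summary(stack: np.ndarray, times: np.ndarray) -> tuple[MITimeSeries, np.ndarray]:
    """Summarise a (T, H, W) MI stack.

    Returns the per-time maximum over pixels (with argmax pixel), the global
    peak latency (earliest time attaining the stack maximum), and the
    per-pixel maximum-over-time image.
    """
    t, h, w = stack.shape
    flat = stack.reshape(t, h * w)
    per_time_max = flat.max(axis=1)
    arg = flat.argmax(axis=1)
    argmax_pixel = np.stack([arg // w, arg % w], axis=1)
    peak_idx = int(np.argmax(per_time_max))  # earliest on ties
    series = MITimeSeries(times, per_time_max, argmax_pixel,
                          float(times[peak_idx]), float(per_time_max[peak_idx]))
    return series, stack.max(axis=0)


# --------------------------------------------------------------------------
# TFCE
# --------------------------------------------------------------------------

@njit(cache=True)
def _tfce_kernel(vals, order, n_steps, dh, ext_exp, height_exp):  # pragma: no cover
    h_img, w_img = vals.shape
    n = h_img * w_img
    flat = vals.ravel()
    parent = np.full(n, -1, dtype=np.int64)
    size = np.zeros(n, dtype=np.int64)
    scores = np.zeros(n)
    ptr = 0
    for k in range(n_steps, 0, -1):
        h = k * dh
        while ptr < n and flat[order[ptr]] >= h:
            p = order[ptr]
            parent[p] = p
            size[p] = 1
            py, px = p // w_img, p % w_img
            for dy in range(-1, 2):
                for dx in range(-1, 2):
                    if dy == 0 and dx == 0:
                        continue
                    qy, qx = py + dy, px + dx
                    if 0 <= qy < h_img and 0 <= qx < w_img:
                        q = qy * w_img + qx
                        if parent[q] >= 0:
                            # union by size with path compression
                            ra = p
                            while parent[ra] != ra:
                                parent[ra] = parent[parent[ra]]
                                ra = parent[ra]
                            rb = q
                            while parent[rb] != rb:
                                parent[rb] = parent[parent[rb]]
                                rb = parent[rb]
                            if ra != rb:
                                if size[ra] < size[rb]:
                                    ra, rb = rb, ra
                                parent[rb] = ra
                                size[ra] += size[rb]
            ptr += 1
        inc = dh * h**height_exp
        for i in range(ptr):
            p = order[i]
            r = p
            while parent[r] != r:
                parent[r] = parent[parent[r]]
                r = parent[r]
            scores[p] += inc * size[r] ** ext_exp
    return scores


def tfce_enhance(
    mi_map: np.ndarray,
    extent_exponent: float = 0.5,
    height_exponent: float = 2.0,
    dh: float | None = None,
) -> np.ndarray:
    """Threshold-free cluster enhancement of a non-negative map.

    Per-pixel score: ``sum over thresholds h (from dh up to the pixel value,
    in steps of dh) of dh * extent(h)^E * h^H``, where extent(h) is the size
    of the 8-connected suprathreshold cluster containing the pixel. ``dh``
    defaults to max/100.
    """
    mi_map = np.asarray(mi_map, dtype=float)
    if mi_map.ndim != 2:
        raise ValueError("expected a 2-D map")
    if np.any(mi_map < 0):
        raise ValueError("TFCE input must be non-negative")
    vmax = float(mi_map.max())
    if dh is None:
        dh = vmax / 100.0 if vmax > 0 else 1.0
    if dh <= 0:
        raise ValueError("dh must be positive")
    if vmax == 0:
        return np.zeros_like(mi_map)
    n_steps = int(np.floor(vmax / dh + 1e-9))
    if n_steps == 0:
        return np.zeros_like(mi_map)
    order = np.argsort(mi_map.ravel(), kind="stable")[::-1].copy()
    scores = _tfce_kernel(mi_map, order, n_steps, float(dh),
                          float(extent_exponent), float(height_exponent))
    return scores.reshape(mi_map.shape)


def permutation_significance(
    vis_stack: np.ndarray,
    response: np.ndarray,
    n_permutations: int = 1000,
    alpha: float = 0.05,
    n_bins: int = 3,
    valid_mask: np.ndarray | None = None,
    seed: int = 0,
    extent_exponent: float = 0.5,
    height_exponent: float = 2.0,
) -> SignificanceMask:
    """Max-statistic permutation test on the TFCE-enhanced scaled-MI map.

    The response labels are shuffled ``n_permutations`` times; the threshold
    is the (1 - alpha) empirical quantile (method "higher") of the null
    distribution of the maximum TFCE score, and pixels whose observed TFCE
    exceeds it are significant. ``dh`` is fixed from the observed map so
    observed and null statistics share the same threshold grid. The mask is
    invariant to any relabeling of response bins because MI itself is.
    """
    if (n_permutations + 1) * alpha < 1:
        raise ValueError("insufficient permutations for the requested alpha")
    if n_permutations < 500:
        warnings.warn("fewer than 500 permutations: threshold estimate is coarse",
                      stacklevel=2)
    n = len(response)
    labels, degenerate, keep, (h, w) = _prepare_pixels(vis_stack, n_bins, valid_mask)
    resp = equiprobable_bin(response, n_bins).labels
    rng = np.random.default_rng(seed)
    perms = np.empty((n_permutations + 1, n), dtype=resp.dtype)
    perms[0] = resp
    for m in range(1, n_permutations + 1):
        perms[m] = resp[rng.permutation(n)]
    mi = _mi_maps_scaled(labels, perms, n_bins)
    mi[:, degenerate] = 0.0
    maps = np.zeros((n_permutations + 1, h * w))
    maps[:, keep] = mi
    maps = maps.reshape(-1, h, w)

    obs_map = maps[0]
    vmax = float(obs_map.max())
    dh = vmax / 100.0 if vmax > 0 else 1.0
    obs_tfce = tfce_enhance(obs_map, extent_exponent, height_exponent, dh)
    null_max = np.empty(n_permutations)
    for m in range(1, n_permutations + 1):
        null_max[m - 1] = tfce_enhance(maps[m], extent_exponent,
                                       height_exponent, dh).max()
    if alpha >= 1.0:  # degenerate request: every positive statistic passes
        threshold = 0.0
    else:
        threshold = float(np.quantile(null_max, 1.0 - alpha, method="higher"))
    mask = obs_tfce > threshold
    return SignificanceMask(mask, alpha, n_permutations, threshold, null_max)


def eye_region_summary(ci: ClassificationImage | np.ndarray,
                       region_mask: np.ndarray) -> float:
    """Sum of MI inside a boolean region mask (e.g. the left-eye circle)."""
    mi = ci.mi if isinstance(ci, ClassificationImage) else np.asarray(ci)
    region_mask = np.asarray(region_mask, dtype=bool)
    if region_mask.shape != mi.shape:
        raise ValueError("region mask shape mismatch")
    if not region_mask.any():
        raise ValueError("empty region mask")
    return float(mi[region_mask].sum())


def lateralization_index(mi_left_max: float, mi_right_max: float) -> float:
    """Hemispheric contrast ``(L - R) / (L + R)`` of per-participant MI
    maxima normalised to [0, 1]; negative values mean right-lateralized.
    Returns NaN (with a warning) when both maxima are zero."""
    if mi_left_max < 0 or mi_right_max < 0:
        raise ValueError("maxima must be non-negative")
    total = mi_left_max + mi_right_max
    if total == 0:
        warnings.warn("lateralization undefined: both maxima are zero",
                      stacklevel=2)
        return float("nan")
    return (mi_left_max - mi_right_max) / total
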