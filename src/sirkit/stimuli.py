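"""Bubbles stimuli: schematic faces, phase-coherence mixing, Gaussian apertures.

Face images are procedurally drawn schematic faces (oval, eyes, brows, nose,
mouth) rather than photographs, so the package carries no image assets. All
stimuli share a single amplitude spectrum (the mean over the base identities);
a unique image per trial is obtained by mixing the original phase with random
phase at coherence ``c`` (c = 0.7 for faces, c = 0 for noise textures).
Bubble masks reveal the image through ``n_bubbles`` Gaussian apertures whose
centres fall inside the face oval; overlapping apertures combine by pointwise
maximum so mask values stay interpretable as revelation in [0, 1].
"""

from __future__ import annotations

import numpy as np

from .config import BubbleConfig, StimulusConfig

__all__ = [
    "make_base_faces",
    "generate_stimuli",
    "sample_bubble_centers",
    "render_bubble_mask",
    "generate_bubble_mask",
    "bubble_mask_stack",
    "oval_mask",
    "eye_region_masks",
    "downsample_stack",
]


def _grid(size: int) -> tuple[np.ndarray, np.ndarray]:
    c = (size - 1) / 2.0
    y, x = np.mgrid[0:size, 0:size].astype(float)
    return y - c, x - c


def oval_mask(cfg: StimulusConfig, size: int | None = None) -> np.ndarray:
    """Boolean map of pixels inside the face oval, at image or analysis size."""
    size = cfg.image_size_px if size is None else size
    scale = cfg.image_size_px / size
    a, b = cfg.oval_semi_axes_px
    y, x = _grid(size)
    y, x = y * scale, x * scale
    return (x / a) ** 2 + (y / b) ** 2 <= 1.0


def eye_region_masks(cfg: StimulusConfig, size: int | None = None) -> dict[str, np.ndarray]:
    """Boolean left/right eye-region masks (circles of ``eye_radius_deg``).

    Mirrors the red-circle eye masks used to summarise classification images.
    """
    size = cfg.image_size_px if size is None else size
    scale = cfg.image_size_px / size
    r = cfg.eye_radius_deg * cfg.px_per_deg
    c_img = (cfg.image_size_px - 1) / 2.0
    c = (size - 1) / 2.0
    out = {}
    for side, (ey, ex) in cfg.eye_centers_px().items():
        y, x = np.mgrid[0:size, 0:size].astype(float)
        yy = (y - c) * scale - (ey - c_img)
        xx = (x - c) * scale - (ex - c_img)
        out[side] = yy**2 + xx**2 <= r**2
    return out


def _draw_schematic_face(cfg: StimulusConfig, rng: np.random.Generator) -> np.ndarray:
    """One schematic identity: dark features on a light oval, mid-gray surround.

    Identities differ through small jitters of feature positions, sizes and
    contrasts, giving the base set a non-degenerate mean amplitude spectrum.
    """
    size = cfg.image_size_px
    ppd = cfg.px_per_deg
    y, x = _grid(size)
    a, b = cfg.oval_semi_axes_px
    img = np.zeros((size, size))
    inside = (x / a) ** 2 + (y / b) ** 2 <= 1.0
    img[inside] = 0.25  # face surface brighter than surround

    def blob(cy, cx, ry, rx, value):
        m = ((x - cx) / rx) ** 2 + ((y - cy) / ry) ** 2 <= 1.0
        img[m & inside] = value

    jit = lambda s: rng.normal(0.0, s * ppd)
    eyes = cfg.eye_centers_px()
    c = (size - 1) / 2.0
    for side in ("left", "right"):
        ey, ex = eyes[side]
        ey, ex = ey - c + jit(0.05), ex - c + jit(0.05)
        r = cfg.eye_radius_deg * ppd * rng.uniform(0.85, 1.1)
        blob(ey, ex, 0.75 * r, r, -0.6 + rng.normal(0, 0.05))  # eye
        blob(ey - 1.3 * r, ex, 0.3 * r, 1.3 * r, -0.3)  # brow
    # nose and mouth
    blob(0.45 * ppd + jit(0.05), jit(0.03), 0.9 * ppd, 0.28 * ppd, -0.25)
    blob(cfg.mouth_offset_deg * ppd + jit(0.05), jit(0.05),
         0.28 * ppd, 1.0 * ppd * rng.uniform(0.85, 1.15), -0.5)
    # mild identity-specific texture inside the oval
    img[inside] += rng.normal(0.0, 0.02, inside.sum())
    return img


def _normalize(img: np.ndarray, scale: float) -> np.ndarray:
    """Fixed affine map to [0, 1] around mid-gray.

    The same scale is applied to every stimulus built from one base set, so
    the map only rescales the (zero) DC component and leaves the relative
    amplitude spectrum untouched. Clipping is a safety net that is inactive
    for the headroom used.
    """
    return np.clip(0.5 + 0.5 * img / scale, 0.0, 1.0)


def normalization_scale(base: np.ndarray) -> float:
    """Common normalisation scale for all stimuli from ``base`` (10% headroom
    over the largest base-face excursion)."""
    return float(1.1 * np.abs(base).max())


def make_base_faces(cfg: StimulusConfig, rng: np.random.Generator) -> tuple[np.ndarray, np.ndarray]:
    """Return (base_faces, amplitude) for ``cfg.n_identities`` identities.

    The drawn faces are made zero-mean (mid-gray = 0 in texture units) and
    amplitude-equalised: each identity's spectrum is replaced by the mean
    amplitude of the set, with zero DC, so every stimulus built from them
    shares that spectrum exactly -- including the DC term after the common
    affine display mapping.
    """
    raw = np.stack([_draw_schematic_face(cfg, rng) for _ in range(cfg.n_identities)])
    raw -= raw.mean(axis=(-2, -1), keepdims=True)
    amp = np.abs(np.fft.fft2(raw, axes=(-2, -1))).mean(axis=0)
    amp[0, 0] = 0.0
    phases = np.angle(np.fft.fft2(raw, axes=(-2, -1)))
    base = np.fft.ifft2(amp * np.exp(1j * phases), axes=(-2, -1)).real
    return base, amp


def _mix_phase(phase: np.ndarray, coherence: float, rng: np.random.Generator) -> np.ndarray:
    """Circular interpolation between original and random phase.

    The random phase field is taken from the spectrum of a white-noise image,
    which keeps it antisymmetric so the mixed spectrum stays Hermitian and the
    output image real.
    """
    noise = rng.standard_normal(phase.shape)
    rand = np.angle(np.fft.fft2(noise))
    mixed = coherence * np.exp(1j * phase) + (1.0 - coherence) * np.exp(1j * rand)
    return np.angle(mixed)


def generate_stimuli(
    cfg: StimulusConfig,
    n_face: int,
    n_noise: int,
    rng: np.random.Generator,
    base: np.ndarray | None = None,
    amplitude: np.ndarray | None = None,
) -> dict[str, np.ndarray]:
    """Generate face stimuli (phase coherence ``phase_coherence_face``) and
    noise textures (coherence 0), all with the common amplitude spectrum.

    Returns a dict with ``face`` (n_face, H, W), ``noise`` (n_noise, H, W),
    ``base`` (normalised, for reference) and ``amplitude``. Images are
    normalised to [0, 1] by one common affine map, which preserves the shared
    spectrum; the mid-gray surround of the displayed stimulus arises from
    bubble masking (see :func:`apply_bubbles`), since aperture centres stay
    inside the face oval.
    """
    if base is None or amplitude is None:
        base, amplitude = make_base_faces(cfg, rng)
    scale = normalization_scale(base)
    base_phases = np.angle(np.fft.fft2(base, axes=(-2, -1)))

    def build(n: int, coherence: float) -> np.ndarray:
        out = np.empty((n, cfg.image_size_px, cfg.image_size_px))
        for i in range(n):
            phase = base_phases[rng.integers(cfg.n_identities)]
            mixed = _mix_phase(phase, coherence, rng)
            img = np.fft.ifft2(amplitude * np.exp(1j * mixed)).real
            out[i] = _normalize(img, scale)
        return out

    return {
        "face": build(n_face, cfg.phase_coherence_face),
        "noise": build(n_noise, cfg.phase_coherence_noise),
        "base": _normalize(base, scale),
        "amplitude": amplitude,
    }


def apply_bubbles(stimulus: np.ndarray, mask: np.ndarray) -> np.ndarray:
    """Reveal a stimulus through a bubble mask on a mid-gray field:
    ``0.5 + mask * (stimulus - 0.5)``. Away from the apertures (and hence
    everywhere outside the face oval) the displayed image is mid-gray."""
    return 0.5 + mask * (stimulus - 0.5)


def sample_bubble_centers(
    bcfg: BubbleConfig, scfg: StimulusConfig, rng: np.random.Generator
) -> np.ndarray:
    """Uniform-random aperture centres inside the face oval, shape (n, 2) as
    (row, col) in image coordinates."""
    a, b = scfg.oval_semi_axes_px
    cy, cx = scfg.center_px
    centers = np.empty((bcfg.n_bubbles, 2))
    for i in range(bcfg.n_bubbles):
        while True:
            dx = rng.uniform(-a, a)
            dy = rng.uniform(-b, b)
            if (dx / a) ** 2 + (dy / b) ** 2 <= 1.0:
                break
        centers[i] = (cy + dy, cx + dx)
    return centers


def render_bubble_mask(
    centers: np.ndarray, sigma_px: float, size: int
) -> np.ndarray:
    """Pointwise maximum of unit-peak Gaussian apertures at ``centers``.

    Each aperture is evaluated on a local window (+-4 sigma) as the outer
    product of two 1-D Gaussians, which is exact for isotropic apertures.
    """
    mask = np.zeros((size, size))
    half = int(np.ceil(4 * sigma_px))
    for cy, cx in np.atleast_2d(centers) if len(centers) else []:
        y0, y1 = max(0, int(cy) - half), min(size, int(cy) + half + 1)
        x0, x1 = max(0, int(cx) - half), min(size, int(cx) + half + 1)
        gy = np.exp(-0.5 * ((np.arange(y0, y1) - cy) / sigma_px) ** 2)
        gx = np.exp(-0.5 * ((np.arange(x0, x1) - cx) / sigma_px) ** 2)
        patch = gy[:, None] * gx[None, :]
        np.maximum(mask[y0:y1, x0:x1], patch, out=mask[y0:y1, x0:x1])
    return mask


def generate_bubble_mask(
    bcfg: BubbleConfig,
    scfg: StimulusConfig,
    rng: np.random.Generator,
    centers: np.ndarray | None = None,
) -> np.ndarray:
    """One bubble mask (H x W in [0, 1]). ``n_bubbles = 0`` yields all zeros."""
    if centers is None:
        centers = sample_bubble_centers(bcfg, scfg, rng)
    sigma_px = bcfg.sigma_deg * scfg.px_per_deg
    return render_bubble_mask(centers, sigma_px, scfg.image_size_px)


def bubble_mask_stack(
    n_trials: int,
    bcfg: BubbleConfig,
    scfg: StimulusConfig,
    rng: np.random.Generator,
) -> np.ndarray:
    stack = np.empty((n_trials, scfg.image_size_px, scfg.image_size_px), dtype=np.float32)
    for i in range(n_trials):
        stack[i] = generate_bubble_mask(bcfg, scfg, rng)
    return stack


def downsample_stack(stack: np.ndarray, out_size: int) -> np.ndarray:
    """Block-mean downsampling of a (..., H, W) stack to (..., out, out)."""
    *lead, h, w = stack.shape
    if h % out_size or w % out_size:
        raise ValueError("output size must divide the input size")
    f = h // out_size
    return stack.reshape(*lead, out_size, f, out_size, f).mean(axis=(-3, -1))
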