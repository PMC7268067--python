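"""Configuration objects for the synthetic Bubbles/EEG experiment.

The defaults encode the study conditions emulated by the generator: a
face-versus-noise detection task with 2,200 bubbled trials per participant,
128x128 stimuli spanning 9.3 degrees of visual angle, ten Gaussian apertures
(sigma = 0.36 deg) per trial, 500 Hz epochs from -300 to 1000 ms, and two age
groups whose reaction-time base and N170-window eye-coding latency differ by
known amounts (the recoverable ground truth).
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
from dataclasses import dataclass, field
from typing import Mapping, Sequence

GROUPS = ("young", "older")


@dataclass(frozen=True)
class StimulusConfig:
    """Geometry and phase-coherence parameters of the stimulus set.

    ``px_per_deg`` defaults to 13.8 (128 px spanning ~9.3 deg). The face oval
    has semi-axes 2.45 x 3.5 deg (from a 4.9 x 7.0 deg oval). Eye regions are
    circles of radius ``eye_radius_deg`` centred at the canonical eye
    coordinates of the schematic template face.
    """

    image_size_px: int = 128
    px_per_deg: float = 13.8
    oval_semi_axes_deg: tuple[float, float] = (2.45, 3.5)
    phase_coherence_face: float = 0.7
    phase_coherence_noise: float = 0.0
    n_identities: int = 10
    eye_offset_deg: tuple[float, float] = (1.1, 1.1)  # (|dx| from midline, dy above centre)
    eye_radius_deg: float = 0.5
    mouth_offset_deg: float = 1.8  # below centre

    def __post_init__(self) -> None:
        if self.image_size_px <= 0:
            raise ValueError("image_size_px must be positive")
        for c in (self.phase_coherence_face, self.phase_coherence_noise):
            if not 0.0 <= c <= 1.0:
                raise ValueError(f"phase coherence must lie in [0, 1], got {c}")
        a, b = self.oval_semi_axes_px
        if 2 * a >= self.image_size_px or 2 * b >= self.image_size_px:
            raise ValueError("face oval does not fit inside the image")
        if self.n_identities < 1:
            raise ValueError("need at least one base identity")

    @property
    def oval_semi_axes_px(self) -> tuple[float, float]:
        a_deg, b_deg = self.oval_semi_axes_deg
        return a_deg * self.px_per_deg, b_deg * self.px_per_deg

    @property
    def center_px(self) -> tuple[float, float]:
        c = (self.image_size_px - 1) / 2.0
        return c, c

    def eye_centers_px(self) -> dict[str, tuple[float, float]]:
        """Pixel coordinates (row, col) of the left/right eye centres.

        "left" is viewer-left, i.e. the left side of the image, which projects
        to the right hemisphere (electrode RE).
        """
        cy, cx = self.center_px
        dx = self.eye_offset_deg[0] * self.px_per_deg
        dy = self.eye_offset_deg[1] * self.px_per_deg
        return {"left": (cy - dy, cx - dx), "right": (cy - dy, cx + dx)}


@dataclass(frozen=True)
class BubbleConfig:
    """Number and size of the Gaussian apertures revealed on each trial."""

    n_bubbles: int = 10
    sigma_deg: float = 0.36

    def __post_init__(self) -> None:
        if self.n_bubbles < 0:
            raise ValueError("n_bubbles must be >= 0")
        if self.sigma_deg <= 0:
            raise ValueError("sigma_deg must be positive")


# Relative evoked gain of each electrode: a fixed topography so that the
# across-electrode SD of the mean ERP (ERP_STD) rises at the evoked onset.
DEFAULT_ELECTRODE_GAINS: Mapping[str, float] = {
    "LE": 5.0,
    "RE": 5.0,
    "Oz": 8.0,
    "POz": 7.0,
    "Pz": 5.5,
    "CPz": 4.0,
    "P7": 6.0,
    "P8": 6.0,
}


@dataclass(frozen=True)
class CohortConfig:
    """Full description of a simulated two-group cohort.

    Group-keyed fields map ``{"young": value, "older": value}``. The group
    difference in ``n170_latency_ms`` is the injected neural delay that the
    downstream classification-image and redundancy analyses must recover; the
    difference in ``rt_base_ms`` is the behavioural delay.
    """

    n_per_group: Mapping[str, int] = field(
        default_factory=lambda: {"young": 17, "older": 18}
    )
    n_trials: int = 2200  # split evenly face/noise
    analysis_size_px: int = 64  # MI maps computed at this resolution

    stimulus: StimulusConfig = field(default_factory=StimulusConfig)
    bubbles: BubbleConfig = field(default_factory=BubbleConfig)

    # --- behaviour ---
    rt_base_ms: Mapping[str, float] = field(
        default_factory=lambda: {"young": 380.0, "older": 580.0}
    )
    rt_eye_slope: float = 180.0  # ms reduction per unit left-eye visibility
    rt_noise: float = 0.08  # log-scale SD of multiplicative RT noise
    rt_participant_sd: float = 10.0  # between-participant spread of the base
    face_accuracy_base: float = 0.6
    face_accuracy_gain: float = 0.35
    noise_accuracy: float = 0.95

    # --- EEG ---
    n170_latency_ms: Mapping[str, float] = field(
        default_factory=lambda: {"young": 170.0, "older": 210.0}
    )
    n170_width_ms: float = 10.0
    latency_jitter_ms: float = 2.0  # trial-to-trial latency jitter (SD)
    participant_latency_sd_ms: float = 1.5
    n170_base_amp: float = 10.0
    eeg_eye_gain: Mapping[str, float] = field(
        default_factory=lambda: {"young": 90.0, "older": 65.0}
    )
    contra_ipsi_ratio: float = 0.5  # LE feature gain relative to RE (right-hemisphere dominance)
    evoked_onset_ms: float = 70.0
    evoked_tau_ms: float = 60.0
    evoked_amp: float = 6.0
    eeg_noise_sd: float = 6.0
    sample_rate_hz: float = 500.0
    epoch_window_ms: tuple[float, float] = (-300.0, 1000.0)
    electrodes: Sequence[str] = tuple(DEFAULT_ELECTRODE_GAINS)
    electrode_gains: Mapping[str, float] = field(
        default_factory=lambda: dict(DEFAULT_ELECTRODE_GAINS)
    )

    # --- analysis defaults carried with the cohort ---
    mi_window_ms: tuple[float, float] = (0.0, 400.0)
    n_bins: int = 3
    n_permutations: int = 200
    alpha: float = 0.05

    seed: int = 0

    def __post_init__(self) -> None:
        for g in GROUPS:
            for m in (self.n_per_group, self.rt_base_ms, self.n170_latency_ms,
                      self.eeg_eye_gain):
                if g not in m:
                    raise ValueError(f"group-keyed field missing group {g!r}")
        if self.n_trials < 2 or self.n_trials % 2:
            raise ValueError("n_trials must be even (split face/noise)")
        for name in ("LE", "RE"):
            if name not in self.electrodes:
                raise ValueError(f"electrode list must include {name!r}")
        step = 1000.0 / self.sample_rate_hz
        t0, t1 = self.epoch_window_ms
        if t0 >= 0 or t1 <= 0:
            raise ValueError("epoch window must straddle stimulus onset")
        if abs(t0 / step - round(t0 / step)) > 1e-9:
            raise ValueError("epoch start must align with the sampling grid")
        # every unit of eye visibility subtracts rt_eye_slope; visibility <= 1
        for g in GROUPS:
            if self.rt_base_ms[g] - self.rt_eye_slope <= 0:
                raise ValueError(
                    "rt_eye_slope too large: reaction times could reach zero"
                )
        if self.stimulus.image_size_px % self.analysis_size_px:
            raise ValueError("analysis_size_px must divide image_size_px")

    @property
    def sample_step_ms(self) -> float:
        return 1000.0 / self.sample_rate_hz

    @classmethod
    def demo(cls, seed: int = 0, **overrides) -> "CohortConfig":
        """Desk-scale configuration: 6+6 participants, 400 trials, 32x32 maps,
        200 permutations. Completes end-to-end in minutes on one CPU."""
        defaults = dict(
            n_per_group={"young": 6, "older": 6},
            n_trials=400,
            analysis_size_px=32,
            n_permutations=200,
            seed=seed,
        )
        defaults.update(overrides)
        return cls(**defaults)

    # --- plain-text round trip -------------------------------------------
    def to_dict(self) -> dict:
        d = dataclasses.asdict(self)
        d["stimulus"] = dataclasses.asdict(self.stimulus)
        d["bubbles"] = dataclasses.asdict(self.bubbles)
        return d

    def to_json(self, path=None) -> str:
        text = json.dumps(self.to_dict(), indent=2, sort_keys=True, default=list)
        if path is not None:
            with open(path, "w") as fh:
                fh.write(text)
        return text

    @classmethod
    def from_dict(cls, d: Mapping) -> "CohortConfig":
        d = dict(d)
        if isinstance(d.get("stimulus"), Mapping):
            s = dict(d["stimulus"])
            for k in ("oval_semi_axes_deg", "eye_offset_deg"):
                if k in s:
                    s[k] = tuple(s[k])
            d["stimulus"] = StimulusConfig(**s)
        if isinstance(d.get("bubbles"), Mapping):
            d["bubbles"] = BubbleConfig(**d["bubbles"])
        for k in ("epoch_window_ms", "mi_window_ms"):
            if k in d:
                d[k] = tuple(d[k])
        if "electrodes" in d:
            d["electrodes"] = tuple(d["electrodes"])
        return cls(**d)

    @classmethod
    def from_json(cls, path) -> "CohortConfig":
        with open(path) as fh:
            return cls.from_dict(json.load(fh))

    def config_hash(self) -> str:
        """Stable hash of the full configuration, recorded in every manifest."""
        payload = json.dumps(self.to_dict(), sort_keys=True, default=list)
        return hashlib.sha256(payload.encode()).hexdigest()[:16]
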