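"""Synthetic participants: trial structure, behaviour and single-trial EEG.

Each simulated participant performs a face-versus-noise detection task on
bubbled stimuli. Ground truth injected by the generator:

* behaviour -- reaction times are drawn lognormally around
  ``rt_base - rt_eye_slope * left-eye visibility``, so the left eye is the
  diagnostic feature and the group difference in ``rt_base`` (~200 ms by
  default) is the behavioural delay;
* EEG -- an N170-window Gaussian component on the right-hemisphere electrode
  (RE) has single-trial amplitude proportional to *left*-eye visibility (and
  vice versa on LE: contralateral coding), centred at the group's
  ``n170_latency_ms``. The between-group latency difference (40 ms by
  default) is the neural delay the analysis pipeline must recover. Feature
  coupling exists on face trials only, emulating the absence of eye-location
  sensitivity on noise trials. All other electrodes carry evoked but
  feature-independent signal, so the global ERP_STD onset is group-equal.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .config import CohortConfig, GROUPS
from .stimuli import bubble_mask_stack, downsample_stack, eye_region_masks

__all__ = [
    "TrialSet",
    "EpochArray",
    "ParticipantData",
    "simulate_behavior",
    "simulate_eeg",
    "simulate_participant",
    "simulate_cohort",
]


@dataclass
class TrialSet:
    """Per-trial stimulus sampling and behaviour for one participant."""

    is_face: np.ndarray  # bool per trial
    masks: np.ndarray  # (trials, H, W) bubble masks in [0, 1]
    visibility: np.ndarray  # (trials, h, w) analysis-resolution stack
    eye_visibility: dict  # {"left": (trials,), "right": ..., "center": ...}
    rt_ms: np.ndarray
    response_face: np.ndarray  # bool: responded "face"
    correct: np.ndarray  # bool

    def __post_init__(self) -> None:
        n = len(self.is_face)
        for arr in (self.masks, self.visibility, self.rt_ms,
                    self.response_face, self.correct):
            if len(arr) != n:
                raise ValueError("inconsistent trial counts in TrialSet")
        if np.any(self.rt_ms <= 0):
            raise ValueError("reaction times must be positive")

    @property
    def n_trials(self) -> int:
        return len(self.is_face)

    @property
    def category(self) -> np.ndarray:
        return np.where(self.is_face, "face", "noise")


@dataclass
class EpochArray:
    """Single-trial voltages (trials x electrodes x samples) with metadata."""

    data: np.ndarray
    times: np.ndarray  # ms relative to stimulus onset, strictly increasing
    electrodes: tuple

    def __post_init__(self) -> None:
        self.electrodes = tuple(self.electrodes)
        if self.data.shape[1] != len(self.electrodes):
            raise ValueError("electrode axis does not match labels")
        if self.data.shape[2] != len(self.times):
            raise ValueError("time axis does not match samples")
        if np.any(np.diff(self.times) <= 0):
            raise ValueError("time axis must be strictly increasing")
        if not np.any(self.times == 0):
            raise ValueError("time axis must include stimulus onset (0 ms)")

    @property
    def n_trials(self) -> int:
        return self.data.shape[0]

    def electrode_index(self, label: str) -> int:
        try:
            return self.electrodes.index(label)
        except ValueError:
            raise KeyError(f"electrode {label!r} not in epoch array") from None

    def get(self, label: str) -> np.ndarray:
        """(trials, samples) voltages at one electrode."""
        return self.data[:, self.electrode_index(label), :]


@dataclass
class ParticipantData:
    participant_id: str
    group: str
    seed: int
    trials: TrialSet
    epochs: EpochArray
    rt_base_ms: float = 0.0
    latency_ms: float = 0.0  # realised eye-coding latency (ground truth)
    extras: dict = field(default_factory=dict)


def epoch_times(ccfg: CohortConfig) -> np.ndarray:
    t0, t1 = ccfg.epoch_window_ms
    step = ccfg.sample_step_ms
    n = int(round((t1 - t0) / step)) + 1
    return t0 + step * np.arange(n)


def simulate_behavior(
    is_face: np.ndarray,
    eye_visibility: np.ndarray,
    ccfg: CohortConfig,
    group: str,
    rng: np.random.Generator,
    rt_base_ms: float | None = None,
) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """Draw (rt_ms, response_face, correct) for one participant.

    RT = (base - slope * left-eye visibility) * exp(eps), eps ~ N(0, rt_noise).
    The multiplicative noise keeps RTs strictly positive, so no redraws are
    needed; configurations in which ``base - slope`` could reach zero are
    rejected at configuration time. With ``rt_noise = 0`` RT is strictly
    decreasing in eye visibility. Face-trial accuracy increases with eye
    visibility; noise-trial accuracy is a high constant.
    """
    base = ccfg.rt_base_ms[group] if rt_base_ms is None else rt_base_ms
    n = len(is_face)
    # the diagnostic feature speeds responses on face trials only; noise-trial
    # RTs are feature-independent (no eye-location information to recover)
    mean_rt = base - ccfg.rt_eye_slope * eye_visibility * is_face
    if np.any(mean_rt <= 0):
        raise ValueError("rt_eye_slope drives mean RT below zero")
    rt = mean_rt * np.exp(rng.normal(0.0, ccfg.rt_noise, n)) if ccfg.rt_noise > 0 else mean_rt.copy()
    p_correct = np.where(
        is_face,
        np.clip(ccfg.face_accuracy_base
                + ccfg.face_accuracy_gain * np.tanh(4.0 * eye_visibility), 0.0, 1.0),
        ccfg.noise_accuracy,
    )
    correct = rng.random(n) < p_correct
    response_face = np.where(is_face, correct, ~correct)
    return rt, response_face, correct


def _alpha_kernel(times: np.ndarray, onset: float, tau: float) -> np.ndarray:
    """Unit-peak alpha function starting at ``onset`` (linear initial rise)."""
    t = np.maximum(times - onset, 0.0) / tau
    return t * np.exp(1.0 - t)


def simulate_eeg(
    is_face: np.ndarray,
    eye_visibility: dict,
    ccfg: CohortConfig,
    group: str,
    rng: np.random.Generator,
    latency_ms: float | None = None,
) -> EpochArray:
    """Broadband noise + evoked template + contralateral eye-coding component.

    On RE (LE) a negative Gaussian deflection of width ``n170_width_ms``
    centred at the group latency (plus per-trial jitter) has amplitude
    ``n170_base_amp + eeg_eye_gain * visibility`` of the left (right) eye on
    face trials; on noise trials the amplitude is feature-independent. Oz
    carries a weaker component mixing several features. Remaining electrodes
    are evoked-only, with fixed gains, so ERP_STD onsets carry no group
    information.
    """
    for name in ("LE", "RE"):
        if name not in ccfg.electrodes:
            raise ValueError(f"electrode list must include {name!r}")
    times = epoch_times(ccfg)
    n = len(is_face)
    n_e = len(ccfg.electrodes)
    lat = ccfg.n170_latency_ms[group] if latency_ms is None else latency_ms

    data = rng.normal(0.0, ccfg.eeg_noise_sd, (n, n_e, len(times))).astype(np.float32)
    evoked = ccfg.evoked_amp * _alpha_kernel(times, ccfg.evoked_onset_ms, ccfg.evoked_tau_ms)
    gains = np.array([ccfg.electrode_gains.get(e, 1.0) for e in ccfg.electrodes])
    data += (gains[:, None] * evoked[None, :]).astype(np.float32)[None]

    jitter = rng.normal(0.0, ccfg.latency_jitter_ms, n)
    trial_lat = lat + jitter
    width = ccfg.n170_width_ms
    g = np.exp(-0.5 * ((times[None, :] - trial_lat[:, None]) / width) ** 2)  # (n, T)

    face = is_face.astype(float)
    feat = {
        "RE": eye_visibility["left"] * face,
        "LE": eye_visibility["right"] * face,
    }
    gain = ccfg.eeg_eye_gain[group]
    amp = {
        "RE": ccfg.n170_base_amp + gain * feat["RE"],
        "LE": ccfg.n170_base_amp + ccfg.contra_ipsi_ratio * gain * feat["LE"],
    }
    if "Oz" in ccfg.electrodes:
        mixed = (eye_visibility["left"] + eye_visibility["right"]
                 + eye_visibility["center"]) / 3.0 * face
        amp["Oz"] = 0.5 * ccfg.n170_base_amp + 0.4 * gain * mixed
    for label, a in amp.items():
        idx = ccfg.electrodes.index(label)
        data[:, idx, :] -= (a[:, None] * g).astype(np.float32)
    return EpochArray(data, times, ccfg.electrodes)


def simulate_participant(
    ccfg: CohortConfig,
    group: str,
    seed: int,
    participant_id: str | None = None,
) -> ParticipantData:
    """Generate one participant: masks, visibility, behaviour and epochs.

    All randomness derives from ``seed``; identical seeds give bit-identical
    participants.
    """
    if group not in GROUPS:
        raise ValueError(f"unknown group {group!r}")
    rng = np.random.default_rng(seed)
    n = ccfg.n_trials
    is_face = np.zeros(n, dtype=bool)
    is_face[rng.permutation(n)[: n // 2]] = True

    masks = bubble_mask_stack(n, ccfg.bubbles, ccfg.stimulus, rng)
    eyes = eye_region_masks(ccfg.stimulus)
    center_row = int(round(ccfg.stimulus.center_px[0]))
    eye_visibility = {
        "left": masks[:, eyes["left"]].mean(axis=1),
        "right": masks[:, eyes["right"]].mean(axis=1),
        "center": masks[:, center_row - 4 : center_row + 5,
                        center_row - 4 : center_row + 5].mean(axis=(1, 2)),
    }
    visibility = downsample_stack(masks, ccfg.analysis_size_px)

    # participant-level offsets: modest inter-individual variability
    rt_base = ccfg.rt_base_ms[group] + rng.normal(0.0, ccfg.rt_participant_sd)
    latency = ccfg.n170_latency_ms[group] + rng.normal(0.0, ccfg.participant_latency_sd_ms)

    rt, resp, correct = simulate_behavior(
        is_face, eye_visibility["left"], ccfg, group, rng, rt_base_ms=rt_base)
    epochs = simulate_eeg(is_face, eye_visibility, ccfg, group, rng,
                          latency_ms=latency)
    trials = TrialSet(is_face, masks, visibility, eye_visibility,
                      rt, resp, correct)
    pid = participant_id or f"{group}_{seed}"
    return ParticipantData(pid, group, seed, trials, epochs,
                           rt_base_ms=rt_base, latency_ms=latency)


def simulate_cohort(ccfg: CohortConfig, seed: int | None = None) -> list[ParticipantData]:
    """Simulate both groups; per-participant seeds are spawned from the
    cohort seed so any participant can be regenerated independently."""
    root = ccfg.seed if seed is None else seed
    out = []
    for gi, group in enumerate(GROUPS):
        for i in range(ccfg.n_per_group[group]):
            child = int(np.random.SeedSequence((root, gi, i))
                        .generate_state(1)[0] % (2**31))
            out.append(simulate_participant(
                ccfg, group, child, participant_id=f"{group}{i:02d}"))
    return out
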