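"""End-to-end orchestration: generate -> analyze -> summarize.

``run_pipeline`` simulates a two-group cohort, runs the behavioural and EEG
classification-image analyses, ERP/onset extraction, and the redundancy
stages, and writes per-participant HDF5 files, CSV/JSON summaries, PNG
classification images, and a run manifest. Every stage derives its
randomness from the cohort seed, so rerunning with the same configuration
reproduces all numeric outputs bit-identically.
"""

from __future__ import annotations

import json
import time
from dataclasses import dataclass, field
from pathlib import Path

import h5py
import numpy as np
import pandas as pd

from . import classification as ci
from . import erp as erpmod
from . import redundancy as red
from .cohort import ParticipantData, simulate_cohort
from .config import GROUPS, CohortConfig
from .robust import group_difference_ci, harrell_davis_median
from .stimuli import eye_region_masks, oval_mask

__all__ = ["ParticipantSummary", "CohortResult", "analyze_participant",
           "run_pipeline", "ALL_STAGES"]

ALL_STAGES = ("synth", "ci", "erp", "redundancy", "group")


@dataclass
class ParticipantSummary:
    participant_id: str
    group: str
    seed: int
    n_trials: int
    median_rt_ms: float
    accuracy_face: float
    accuracy_noise: float
    n170_latency_ms: float = np.nan
    n170_amplitude: float = np.nan
    onset_ms: float = np.nan
    mi_peak_latency_ms: float = np.nan  # RE, face trials
    mi_peak_value: float = np.nan
    eye_sum_left: float = np.nan
    eye_sum_right: float = np.nan
    n_sig_pixels_behavior: int = -1
    frp_ms: float = np.nan  # FeatRed peak latency, RE
    frp_value: float = np.nan
    lateralization: float = np.nan


@dataclass
class CohortResult:
    config: CohortConfig
    participants: pd.DataFrame
    group_stats: dict
    artifacts: dict = field(default_factory=dict)


def _median_rt(p: ParticipantData) -> float:
    """Median RT over correct face trials (the behavioural summary)."""
    sel = p.trials.is_face & p.trials.correct
    return float(np.median(p.trials.rt_ms[sel]))


def analyze_participant(
    p: ParticipantData,
    ccfg: CohortConfig,
    stages: set[str],
    run_permutations: bool = True,
) -> tuple[ParticipantSummary, dict]:
    """All single-participant analyses; returns a summary row and the dense
    artifacts (CI maps, MI stacks, traces) for storage."""
    size = ccfg.analysis_size_px
    valid = oval_mask(ccfg.stimulus, size)
    eyes = eye_region_masks(ccfg.stimulus, size)
    face = p.trials.is_face
    s = ParticipantSummary(
        p.participant_id, p.group, p.seed, p.trials.n_trials,
        _median_rt(p),
        float(p.trials.correct[face].mean()),
        float(p.trials.correct[~face].mean()),
    )
    art: dict = {}

    if "ci" in stages:
        vis_face = p.trials.visibility[face]
        beh = ci.ci_map(vis_face, p.trials.rt_ms[face], ccfg.n_bins,
                        valid_mask=valid, response_tag="RT")
        art["ci_behavior"] = beh.mi
        s.eye_sum_left = ci.eye_region_summary(beh, eyes["left"])
        s.eye_sum_right = ci.eye_region_summary(beh, eyes["right"])
        if run_permutations and ccfg.n_permutations > 0:
            import warnings
            with warnings.catch_warnings():
                warnings.simplefilter("ignore")
                sig = ci.permutation_significance(
                    vis_face, p.trials.rt_ms[face], ccfg.n_permutations,
                    ccfg.alpha, ccfg.n_bins, valid_mask=valid, seed=p.seed)
            art["sig_behavior"] = sig.mask
            s.n_sig_pixels_behavior = int(sig.mask.sum())
        stacks = {}
        for electrode in ("RE", "LE"):
            stack, times = ci.ci_eeg_stack(
                vis_face, _subset_epochs(p, face), electrode,
                ccfg.mi_window_ms, n_bins=ccfg.n_bins, valid_mask=valid)
            stacks[electrode] = (stack, times)
            series, max_img = ci.max_mi_summary(stack, times)
            art[f"ci_eeg_max_{electrode}"] = max_img
            art[f"mi_timecourse_{electrode}"] = np.column_stack([times, series.max_mi])
            if electrode == "RE":
                s.mi_peak_latency_ms = series.peak_latency_ms
                s.mi_peak_value = series.peak_value
        s.lateralization = ci.lateralization_index(
            float(stacks["LE"][0].max()), float(stacks["RE"][0].max()))

    if "erp" in stages:
        erp_face = erpmod.condition_erp(p.epochs, face, "face")
        peak = erpmod.n170_peak(erp_face, "RE")
        s.n170_latency_ms = peak.latency_ms
        s.n170_amplitude = peak.amplitude
        times, std_tc = erpmod.erp_std_timecourse(erp_face)
        onset = erpmod.detect_onset(times, std_tc)
        s.onset_ms = onset.onset_ms if onset.found else np.nan
        art["erp_face"] = erp_face.data
        art["erp_std"] = np.column_stack([times, std_tc])

    if "redundancy" in stages:
        trace = red.featred_timecourse(
            p.trials.eye_visibility["left"], p.epochs, "RE",
            p.trials.rt_ms, ccfg.mi_window_ms, select=face)
        s.frp_ms = trace.peak_latency_ms
        s.frp_value = trace.peak_value
        art["featred_RE"] = np.column_stack([trace.times, trace.featred])
        trace_le = red.featred_timecourse(
            p.trials.eye_visibility["right"], p.epochs, "LE",
            p.trials.rt_ms, ccfg.mi_window_ms, select=face)
        art["featred_LE"] = np.column_stack([trace_le.times, trace_le.featred])
    return s, art


def _subset_epochs(p: ParticipantData, sel: np.ndarray):
    from .cohort import EpochArray
    return EpochArray(p.epochs.data[sel], p.epochs.times, p.epochs.electrodes)


def _write_participant_h5(path: Path, p: ParticipantData, ccfg: CohortConfig,
                          art: dict) -> None:
    with h5py.File(path, "w") as f:
        f.attrs["participant_id"] = p.participant_id
        f.attrs["group"] = p.group
        f.attrs["seed"] = p.seed
        f.attrs["config_hash"] = ccfg.config_hash()
        # visibility stack at analysis resolution; full-resolution masks are
        # regenerable from the stored seed
        f.create_dataset("masks", data=p.trials.visibility.astype(np.float32),
                         compression="gzip")
        f.create_dataset("epochs", data=p.epochs.data, compression="gzip")
        f.create_dataset("epoch_times_ms", data=p.epochs.times)
        f.attrs["electrodes"] = ",".join(p.epochs.electrodes)
        beh = f.create_group("behavior")
        beh.create_dataset("is_face", data=p.trials.is_face)
        beh.create_dataset("rt_ms", data=p.trials.rt_ms)
        beh.create_dataset("response_face", data=p.trials.response_face)
        beh.create_dataset("correct", data=p.trials.correct)
        for key in ("left", "right", "center"):
            beh.create_dataset(f"eye_visibility_{key}",
                               data=p.trials.eye_visibility[key])
        g = f.create_group("results")
        for k, v in art.items():
            g.create_dataset(k, data=np.asarray(v))


def _behavior_csv(path: Path, p: ParticipantData) -> None:
    pd.DataFrame({
        "trial": np.arange(p.trials.n_trials),
        "category": p.trials.category,
        "rt_ms": p.trials.rt_ms,
        "response": np.where(p.trials.response_face, "face", "noise"),
        "correct": p.trials.correct.astype(int),
    }).to_csv(path, index=False)


def _save_png(path: Path, img: np.ndarray) -> None:
    import matplotlib
    matplotlib.use("Agg", force=False)
    import matplotlib.pyplot as plt
    plt.imsave(path, img, cmap="viridis")


def _group_diff(df: pd.DataFrame, col: str, seed: int) -> dict:
    vals = {g: df.loc[df.group == g, col].dropna().to_numpy() for g in GROUPS}
    out = {}
    for g in GROUPS:
        out[g] = harrell_davis_median(vals[g]) if len(vals[g]) >= 2 else float("nan")
    diff = group_difference_ci(vals[GROUPS[1]], vals[GROUPS[0]],
                               harrell_davis_median, seed=seed)
    out["difference_older_minus_young"] = diff.as_dict()
    return out


def run_pipeline(
    config: CohortConfig | str | Path,
    out_dir: str | Path,
    stages=ALL_STAGES,
    seed: int | None = None,
    force: bool = False,
) -> CohortResult:
    """Run the requested stages and write all artifacts under ``out_dir``.

    Refuses to reuse an output directory whose manifest records a different
    configuration hash unless ``force`` is given.
    """
    if not isinstance(config, CohortConfig):
        config = CohortConfig.from_json(config)
    if seed is not None:
        config = CohortConfig.from_dict({**config.to_dict(), "seed": seed})
    stages = set(stages)
    unknown = stages - set(ALL_STAGES)
    if unknown:
        raise ValueError(f"unknown stages: {sorted(unknown)}")
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    manifest_path = out / "manifest.json"
    chash = config.config_hash()
    if manifest_path.exists() and not force:
        prev = json.loads(manifest_path.read_text())
        if prev.get("config_hash") != chash:
            raise RuntimeError(
                "output directory holds results for a different configuration; "
                "use force=True / --force to overwrite")

    timings: dict[str, float] = {}
    files: list[str] = []
    t0 = time.perf_counter()
    participants = simulate_cohort(config)
    timings["simulate"] = time.perf_counter() - t0
    analysis_stages = stages & {"ci", "erp", "redundancy"}

    rows = []
    for p in participants:
        t0 = time.perf_counter()
        if analysis_stages:
            summary, art = analyze_participant(p, config, analysis_stages)
            rows.append(summary.__dict__)
        else:
            art = {}
        timings[f"analyze_{p.participant_id}"] = time.perf_counter() - t0
        if "synth" in stages:
            h5 = out / f"{p.participant_id}.h5"
            _write_participant_h5(h5, p, config, art)
            csv = out / f"{p.participant_id}_behavior.csv"
            _behavior_csv(csv, p)
            files += [h5.name, csv.name]
        if "ci" in stages:
            for key in ("ci_behavior", "ci_eeg_max_RE"):
                if key in art:
                    png = out / f"{p.participant_id}_{key}.png"
                    _save_png(png, art[key])
                    files.append(png.name)
        print(f"[sir] {p.participant_id}: group={p.group} seed={p.seed} "
              f"n={p.trials.n_trials} "
              f"elapsed={timings[f'analyze_{p.participant_id}']:.1f}s")

    df = pd.DataFrame(rows)
    group_stats: dict = {}
    if "group" in stages and analysis_stages:
        counts = df.group.value_counts()
        t0 = time.perf_counter()
        group_stats["median_rt_ms"] = _group_diff(df, "median_rt_ms", config.seed)
        if "erp" in analysis_stages:
            group_stats["n170_latency_ms"] = _group_diff(df, "n170_latency_ms", config.seed)
            group_stats["onset_ms"] = _group_diff(df, "onset_ms", config.seed)
        if "ci" in analysis_stages:
            group_stats["mi_peak_latency_ms"] = _group_diff(df, "mi_peak_latency_ms", config.seed)
            group_stats["lateralization"] = {
                g: float(np.median(df.loc[df.group == g, "lateralization"].dropna()))
                for g in GROUPS}
        if "redundancy" in analysis_stages:
            group_stats["frp_ms"] = _group_diff(df, "frp_ms", config.seed)
        if "redundancy" in analysis_stages and counts.min() >= 6:
            gred = red.group_redundancy(
                df["frp_ms"].to_numpy(), df["median_rt_ms"].to_numpy(),
                df["group"].to_numpy(), seed=config.seed)
            group_stats["group_redundancy"] = {
                "mi_frp_group_bits": gred.mi_frp_group,
                "mi_rt_group_bits": gred.mi_rt_group,
                "mi_joint_group_bits": gred.mi_joint_group,
                "group_red_bits": gred.group_red,
                "redundancy_fraction": gred.redundancy_fraction,
                "ci_low": gred.ci_low, "ci_high": gred.ci_high,
                "n_boot": gred.n_boot, "seed": gred.seed,
            }
        timings["group"] = time.perf_counter() - t0

    if rows:
        df.to_csv(out / "participants.csv", index=False)
        files.append("participants.csv")
    if group_stats:
        (out / "group_summary.json").write_text(
            json.dumps(group_stats, indent=2, default=float))
        files.append("group_summary.json")

    manifest = {
        "config_hash": chash,
        "seed": config.seed,
        "config": config.to_dict(),
        "stages": sorted(stages),
        "timings_s": {k: round(v, 3) for k, v in timings.items()},
        "outputs": sorted(set(files)) + ["manifest.json"],
    }
    manifest_path.write_text(json.dumps(manifest, indent=2, default=list))
    return CohortResult(config, df, group_stats)
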