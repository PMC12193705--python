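"""End-to-end wiring of the pipeline stages.

simulate/ingest -> per-subject-session thresholds -> event segmentation ->
trial kinematics -> word-level metrics and density curves -> assessment
scoring -> mixed-model fits, with a run manifest recording every decision
knob, seed and output hash so a run is bit-for-bit reproducible.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

from . import __version__
from .config import PipelineConfig, ScreenGeometry
from .event_segmentation import (SpeedThreshold, compute_speeds,
                                 events_to_frames, median_speed_threshold,
                                 segment, trial_kinematics)
from .reading_metrics import density_by_group, records_to_frame, word_fixation_records
from .stats_models import fit_kinematics_model, marginal_contrast
from .stimulus_engine import WordBox
from .synthetic_data import CohortConfig, sentence_word_boxes, simulate_cohort
from .trajectory_io import Trajectory, write_trajectories

log = logging.getLogger("digitrace")


def subject_session_thresholds(trajectories: Sequence[Trajectory],
                               geometry: ScreenGeometry,
                               ) -> dict[tuple[str, int], SpeedThreshold]:
    """Median-speed thresholds pooled per (subject, session) across trials."""
    pools: dict[tuple[str, int], list] = {}
    for tr in trajectories:
        pools.setdefault((tr.subject_id, tr.session), []).append(
            compute_speeds(tr, geometry))
    return {key: median_speed_threshold(series)
            for key, series in pools.items()}


def segment_cohort(trajectories: Sequence[Trajectory],
                   geometry: ScreenGeometry,
                   subjects: pd.DataFrame | None = None,
                   ) -> tuple[pd.DataFrame, dict]:
    """Segment every trial and aggregate per-trial kinematics.

    Returns the trial-level kinematics table (one row per trial, with the
    subject's decoding label merged in when a subject table is given) and
    the raw events keyed by (subject, session, trial).
    """
    thresholds = subject_session_thresholds(trajectories, geometry)
    rows = []
    events = {}
    for tr in trajectories:
        thr = thresholds[(tr.subject_id, tr.session)]
        fixations, saccades = segment(tr, thr, geometry)
        events[(tr.subject_id, tr.session, tr.trial_id)] = (fixations, saccades)
        kin = trial_kinematics(fixations, saccades)
        rows.append({"subject_id": tr.subject_id, "group": tr.group,
                     "phase": tr.phase, "session": tr.session,
                     "trial_id": tr.trial_id, "threshold_mm_s": thr.value,
                     **dataclasses.asdict(kin)})
    frame = pd.DataFrame(rows)
    if subjects is not None and "decoding" in subjects.columns:
        frame = frame.merge(subjects[["subject_id", "decoding"]],
                            on="subject_id", how="left")
    log.info("segmented %d trials from %d subject-sessions",
             len(frame), len(thresholds))
    return frame, events


def word_metrics_cohort(trajectories: Sequence[Trajectory], events: Mapping,
                        word_boxes: Sequence[WordBox]) -> pd.DataFrame:
    """Word-level first-landing / fixation-count table for sentence trials."""
    frames = []
    for tr in trajectories:
        fixations, _ = events[(tr.subject_id, tr.session, tr.trial_id)]
        records = word_fixation_records(fixations, word_boxes, tr.subject_id)
        f = records_to_frame(records, trial_id=tr.trial_id)
        f["session"] = tr.session
        f["phase"] = tr.phase
        frames.append(f)
    return pd.concat(frames, ignore_index=True)


def recovered_group_contrast(kinematics: pd.DataFrame, response: str,
                             reml: bool = True) -> dict[str, float]:
    """Good - poor marginal contrast for one kinematic response via the
    Decoding x Session x Phase mixed model."""
    data = kinematics.dropna(subset=[response]).reset_index(drop=True)
    fit = fit_kinematics_model(data, response, reml=reml)
    return marginal_contrast(fit, data)


def recovery_experiment(seed: int,
                        cohort: CohortConfig | None = None) -> dict[str, float]:
    """Simulate one cohort under the default study conditions, run the full
    pipeline (thresholds -> segmentation -> kinematics -> word metrics ->
    mixed models) and report the recovered quantities next to their
    generative truths."""
    cfg = cohort if cohort is not None else CohortConfig(seed=seed)
    trajectories, subjects = simulate_cohort(cfg)
    kinematics, events = segment_cohort(trajectories, cfg.geometry, subjects)
    speed = recovered_group_contrast(kinematics, "mean_saccade_speed")
    duration = recovered_group_contrast(kinematics, "mean_fixation_duration")
    words = sentence_word_boxes(cfg.sentence, cfg.geometry)
    word_frame = word_metrics_cohort(trajectories, events, words)
    landing = word_frame.groupby("length_class")["first_landing"].mean()
    return {
        "saccade_speed_gap": speed["estimate"],
        "saccade_speed_gap_ci": (speed["ci_low"], speed["ci_high"]),
        "fixation_duration_gap": duration["estimate"],
        "fixation_duration_mean": float(
            kinematics["mean_fixation_duration"].mean()),
        "p_regressive_pooled": float(kinematics["n_regressive"].sum()
                                     / kinematics["n_saccades"].sum()),
        "landing_short": float(landing.get("short", np.nan)),
        "landing_long": float(landing.get("long", np.nan)),
        "n_trials": int(len(kinematics)),
        "n_saccades": int(kinematics["n_saccades"].sum()),
    }


def permutation_null_coverage(seed: int, n_cohorts: int = 10,
                              n_permutations: int = 5) -> dict[str, float]:
    """Null calibration: permute decoding labels across subjects of
    simulated cohorts and count how often the good-poor speed contrast's
    95% CI covers zero."""
    rng = np.random.default_rng(seed)
    hits = total = 0
    for c in range(n_cohorts):
        cfg = CohortConfig(seed=int(rng.integers(2 ** 31)))
        trajectories, subjects = simulate_cohort(cfg)
        kinematics, _ = segment_cohort(trajectories, cfg.geometry, subjects)
        kinematics = kinematics.drop(columns=["decoding"])
        labels = subjects["decoding"].to_numpy()
        for _ in range(n_permutations):
            perm = dict(zip(subjects["subject_id"], rng.permutation(labels)))
            k = kinematics.assign(
                decoding=kinematics["subject_id"].map(perm))
            contrast = recovered_group_contrast(k, "mean_saccade_speed")
            hits += contrast["ci_low"] <= 0.0 <= contrast["ci_high"]
            total += 1
    return {"coverage": hits / total, "n_replicates": total}


# --- manifest ----------------------------------------------------------------

@dataclass
class RunManifest:
    version: str
    seed: int
    config: dict
    outputs: dict = field(default_factory=dict)   # path -> sha256
    stages: list = field(default_factory=list)

    def record(self, path: Path) -> None:
        digest = hashlib.sha256(path.read_bytes()).hexdigest()
        self.outputs[path.name] = digest

    def write(self, path: Path) -> None:
        path.write_text(json.dumps(dataclasses.asdict(self), indent=2,
                                   default=str))


def run_pipeline(config: PipelineConfig | str, out_dir: str | Path,
                 cohort: CohortConfig | None = None) -> RunManifest:
    """Execute the full synthetic pipeline and write every stage output
    plus a manifest of hashes and decision knobs."""
    if isinstance(config, str):
        config = PipelineConfig.from_yaml(config)
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    geometry = config.geometry
    cohort = cohort or CohortConfig(seed=config.seed, geometry=geometry)
    manifest = RunManifest(version=__version__, seed=config.seed,
                           config=config.to_dict())
    manifest.config["cohort"] = {
        "n_per_group": cohort.n_per_group,
        "trials_per_session": cohort.trials_per_session,
        "sessions": list(cohort.sessions), "sentence": cohort.sentence,
        "seed": cohort.seed}

    log.info("stage simulate: %d subjects/group", cohort.n_per_group)
    trajectories, subjects = simulate_cohort(cohort)
    traj_path = out / "trajectories.csv"
    write_trajectories(trajectories, traj_path)
    subjects.to_csv(out / "subjects.csv", index=False)
    manifest.stages.append({"stage": "simulate", "n_trajectories": len(trajectories)})

    log.info("stage segment")
    kinematics, events = segment_cohort(trajectories, geometry, subjects)
    kinematics.to_csv(out / "kinematics.csv", index=False)
    fix_frames, sac_frames = [], []
    for tr in trajectories:
        f, s = events_to_frames(tr, *events[(tr.subject_id, tr.session, tr.trial_id)])
        fix_frames.append(f)
        sac_frames.append(s)
    pd.concat(fix_frames, ignore_index=True).to_csv(out / "fixations.csv", index=False)
    pd.concat(sac_frames, ignore_index=True).to_csv(out / "saccades.csv", index=False)
    manifest.stages.append({"stage": "segment", "n_trials": len(kinematics)})

    log.info("stage metrics")
    words = sentence_word_boxes(cohort.sentence, geometry)
    word_frame = word_metrics_cohort(trajectories, events, words)
    word_frame.to_csv(out / "word_metrics.csv", index=False)
    groups = dict(zip(subjects["subject_id"], subjects["decoding"]))
    first = word_frame.groupby(["word", "subject_id"], as_index=False).agg(
        first_landing=("first_landing", "mean"))
    curves = density_by_group(first, groups,
                              bandwidth_factor=config.bandwidth_factor)
    pd.concat([pd.DataFrame({"word": c.word, "group": c.group,
                             "x_chars": c.support, "density": c.values})
               for c in curves], ignore_index=True).to_csv(
        out / "density_curves.csv", index=False)
    manifest.stages.append({"stage": "metrics", "n_words": len(words),
                            "n_curves": len(curves)})

    log.info("stage fit")
    fits = {}
    for response in ("mean_saccade_speed", "mean_fixation_duration",
                     "proportion_regressive"):
        contrast = recovered_group_contrast(kinematics, response,
                                            reml=config.reml)
        fits[response] = contrast
    (out / "model_fits.json").write_text(json.dumps(fits, indent=2))
    manifest.stages.append({"stage": "fit", "responses": list(fits)})

    for name in ("trajectories.csv", "subjects.csv", "kinematics.csv",
                 "fixations.csv", "saccades.csv", "word_metrics.csv",
                 "density_curves.csv", "model_fits.json"):
        manifest.record(out / name)
    manifest.write(out / "manifest.json")
    return manifest


def render_report(out_dir: str | Path) -> list[Path]:
    """Session-curve and density-overlay figures from a finished run."""
    import matplotlib
    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    out = Path(out_dir)
    kin = pd.read_csv(out / "kinematics.csv")
    paths = []
    fig, axes = plt.subplots(2, 2, figsize=(10, 7), sharex=True)
    measures = [("mean_saccade_speed", "saccade speed (mm/s)"),
                ("mean_saccade_length", "saccade length (mm)"),
                ("proportion_regressive", "prop. regressive"),
                ("mean_fixation_duration", "fixation duration (ms)")]
    for ax, (col, label) in zip(axes.ravel(), measures):
        for dec, g in kin.groupby("decoding"):
            m = g.groupby("session")[col].mean()
            ax.plot(m.index, m.values, marker="o", label=dec)
        ax.set_ylabel(label)
        ax.set_xlabel("session")
    axes[0, 0].legend()
    fig.tight_layout()
    p = out / "session_curves.png"
    fig.savefig(p, dpi=100)
    plt.close(fig)
    paths.append(p)

    dens = pd.read_csv(out / "density_curves.csv")
    if len(dens):
        words = dens["word"].unique()
        fig, axes = plt.subplots(1, len(words), figsize=(3 * len(words), 3))
        axes = np.atleast_1d(axes)
        for ax, word in zip(axes, words):
            for grp, g in dens[dens["word"] == word].groupby("group"):
                ax.plot(g["x_chars"], g["density"], label=grp)
            ax.set_title(word)
            ax.set_xlabel("chars")
        axes[0].legend()
        fig.tight_layout()
        p = out / "density_overlays.png"
        fig.savefig(p, dpi=100)
        plt.close(fig)
        paths.append(p)
    return paths
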