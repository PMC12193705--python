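"""Segmentation of finger trajectories into digital fixations and saccades.

The event model: per subject and session, the median of all strictly
positive sample-to-sample movement speeds is the individual threshold.
Maximal streaks of contiguous samples moving slower than (or at) the
threshold are *digital fixations*; maximal faster streaks are *digital
saccades*.  A fixation's position is the barycenter of its member samples,
whose spread must stay below 5.8 px in X and 6.4 px in Y — wider slow
streaks are split greedily.  A saccade's length is the distance between the
barycenters of its flanking fixations (mm); its speed is the mean speed of
its member samples (mm/s); it is progressive if the X-coordinate of its
last point exceeds that of its first point, and regressive otherwise.

Conventions (documented, not part of the study's description): a speed is
attributed to the later sample of each pair; samples with no defined speed
(the first sample, or samples following a finger-lift) join the class of
the nearest following classified sample; at-threshold speeds count as slow.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from typing import Iterable, Sequence

import numpy as np
import pandas as pd

from .config import (DISPERSION_LIMIT_X_PX, DISPERSION_LIMIT_Y_PX,
                     ScreenGeometry)
from .trajectory_io import Trajectory, percent_to_pixels

_FIX, _SAC, _GAP, _UNK = 0, 1, 2, 3


@dataclass
class SpeedSeries:
    """Per-sample movement speeds in mm/s, attributed to the later sample of
    each pair (length n_samples - 1); NaN where a finger-lift interrupts."""

    subject_id: str
    session: int
    trial_id: str
    values: np.ndarray

    def positive(self) -> np.ndarray:
        v = self.values
        return v[np.isfinite(v) & (v > 0)]


@dataclass(frozen=True)
class SpeedThreshold:
    subject_id: str
    session: int
    value: float  # mm/s

    def __post_init__(self) -> None:
        if not self.value > 0:
            raise ValueError("threshold must be positive")


@dataclass
class DigitalFixation:
    start_t: float
    end_t: float
    barycenter_x: float  # px
    barycenter_y: float  # px
    n_samples: int
    sample_indices: tuple = field(repr=False, default=())

    @property
    def duration(self) -> float:
        return self.end_t - self.start_t


@dataclass
class DigitalSaccade:
    from_fixation: int | None
    to_fixation: int | None
    length: float          # mm, NaN when a flanking fixation is missing
    mean_speed: float      # mm/s
    direction: str         # 'progressive' | 'regressive'
    start_t: float = 0.0
    end_t: float = 0.0
    n_samples: int = 0
    sample_indices: tuple = field(repr=False, default=())


@dataclass
class TrialKinematics:
    n_fixations: int
    mean_fixation_duration: float   # ms
    n_saccades: int
    n_progressive: int
    n_regressive: int
    proportion_regressive: float    # NaN when n_saccades == 0
    mean_saccade_length: float      # mm
    mean_saccade_speed: float       # mm/s


# --- speeds and threshold ----------------------------------------------------

def compute_speeds(trajectory: Trajectory, geometry: ScreenGeometry) -> SpeedSeries:
    """Euclidean pixel displacement x pixel pitch / elapsed time, in mm/s.

    Pairs spanning a touch-up gap carry no value (NaN).
    """
    n = len(trajectory)
    if n < 2:
        warnings.warn("trajectory has fewer than 2 samples; empty speed series")
        values = np.empty(0)
    else:
        x, y = percent_to_pixels(trajectory.x_pct, trajectory.y_pct, geometry)
        d_px = np.hypot(np.diff(x), np.diff(y))
        dt_s = np.diff(trajectory.t) / 1000.0
        values = d_px * geometry.pixel_pitch / dt_s
        both = trajectory.touching[1:] & trajectory.touching[:-1]
        values = np.where(both, values, np.nan)
    return SpeedSeries(subject_id=trajectory.subject_id,
                       session=trajectory.session,
                       trial_id=trajectory.trial_id, values=values)


def median_speed_threshold(speeds: Sequence[SpeedSeries] | SpeedSeries,
                           ) -> SpeedThreshold:
    """Median of strictly positive speeds pooled across all trials of one
    subject-session (null values and missing frames excluded)."""
    if isinstance(speeds, SpeedSeries):
        speeds = [speeds]
    if not speeds:
        raise ValueError("no speed series supplied")
    subj = {s.subject_id for s in speeds}
    sess = {s.session for s in speeds}
    if len(subj) > 1 or len(sess) > 1:
        raise ValueError("speed series span more than one subject-session")
    pooled = np.concatenate([s.positive() for s in speeds]) if speeds else np.empty(0)
    if pooled.size == 0:
        raise ValueError("degenerate trace: all speeds are zero or missing")
    return SpeedThreshold(subject_id=speeds[0].subject_id,
                          session=speeds[0].session,
                          value=float(np.median(pooled)))


# --- segmentation ------------------------------------------------------------

def _classify_samples(trajectory: Trajectory, speeds: np.ndarray,
                      threshold: float) -> np.ndarray:
    n = len(trajectory)
    label = np.full(n, _UNK, dtype=np.int8)
    label[~trajectory.touching] = _GAP
    if n >= 2:
        defined = np.isfinite(speeds)
        later = np.arange(1, n)
        fast = defined & (speeds > threshold)
        slow = defined & ~fast
        label[later[fast & (label[later] != _GAP)]] = _SAC
        label[later[slow & (label[later] != _GAP)]] = _FIX
    # resolve unknowns: nearest following FIX/SAC, else nearest preceding,
    # else a lone fixation
    nxt = _UNK
    for i in range(n - 1, -1, -1):
        if label[i] in (_FIX, _SAC):
            nxt = label[i]
        elif label[i] == _UNK and nxt != _UNK:
            label[i] = nxt
    prev = _UNK
    for i in range(n):
        if label[i] in (_FIX, _SAC):
            prev = label[i]
        elif label[i] == _UNK:
            label[i] = prev if prev != _UNK else _FIX
    return label


def _runs(label: np.ndarray) -> list[tuple[int, int, int]]:
    """(label, start, stop) runs of equal labels."""
    out = []
    n = len(label)
    i = 0
    while i < n:
        j = i
        while j + 1 < n and label[j + 1] == label[i]:
            j += 1
        out.append((int(label[i]), i, j + 1))
        i = j + 1
    return out


def _split_fixation_run(t: np.ndarray, x: np.ndarray, y: np.ndarray,
                        start: int, stop: int,
                        limit_x: float, limit_y: float,
                        min_duration_ms: float) -> list[DigitalFixation]:
    """Greedy left-to-right split of a slow streak at the first sample that
    would push the within-fixation spread to the dispersion limit."""
    fixations = []
    i = start
    while i < stop:
        min_x = max_x = x[i]
        min_y = max_y = y[i]
        j = i + 1
        while j < stop:
            nx0, nx1 = min(min_x, x[j]), max(max_x, x[j])
            ny0, ny1 = min(min_y, y[j]), max(max_y, y[j])
            if nx1 - nx0 >= limit_x or ny1 - ny0 >= limit_y:
                break
            min_x, max_x, min_y, max_y = nx0, nx1, ny0, ny1
            j += 1
        idx = np.arange(i, j)
        fix = DigitalFixation(
            start_t=float(t[i]), end_t=float(t[j - 1]),
            barycenter_x=float(np.mean(x[idx])),
            barycenter_y=float(np.mean(y[idx])),
            n_samples=j - i, sample_indices=tuple(int(k) for k in idx))
        # no minimum duration is imposed by default (floor of 0 ms)
        if fix.duration >= min_duration_ms:
            fixations.append(fix)
        i = j
    return fixations


def segment(trajectory: Trajectory, threshold: SpeedThreshold,
            geometry: ScreenGeometry,
            dispersion_limit_px: tuple[float, float] = (
                DISPERSION_LIMIT_X_PX, DISPERSION_LIMIT_Y_PX),
            min_fixation_ms: float = 0.0,
            ) -> tuple[list[DigitalFixation], list[DigitalSaccade]]:
    """Segment one trial into digital fixations and saccades.

    Returns time-ordered, non-overlapping events.  Trajectories with no
    fast samples yield fixations only.
    """
    n = len(trajectory)
    if n == 0:
        return [], []
    speeds = compute_speeds(trajectory, geometry).values
    label = _classify_samples(trajectory, speeds, threshold.value)
    x, y = percent_to_pixels(trajectory.x_pct, trajectory.y_pct, geometry)
    t = trajectory.t
    lim_x, lim_y = dispersion_limit_px

    # temporally ordered events; gaps never enter the list but their sample
    # indices break contiguity, which severs saccade-fixation linkage
    ordered: list[tuple[str, object, int, int]] = []  # kind, payload, start, stop
    for lab, start, stop in _runs(label):
        if lab == _FIX:
            for fix in _split_fixation_run(t, x, y, start, stop,
                                           lim_x, lim_y, min_fixation_ms):
                s0, s1 = fix.sample_indices[0], fix.sample_indices[-1] + 1
                ordered.append(("fix", fix, s0, s1))
        elif lab == _SAC:
            ordered.append(("sac", None, start, stop))

    fixations: list[DigitalFixation] = [p for k, p, *_ in ordered if k == "fix"]
    fix_index = {id(f): i for i, f in enumerate(fixations)}
    saccades: list[DigitalSaccade] = []

    for pos, (kind, _, start, stop) in enumerate(ordered):
        if kind != "sac":
            continue
        from_i = to_i = None
        if pos > 0 and ordered[pos - 1][0] == "fix" and ordered[pos - 1][3] == start:
            from_i = fix_index[id(ordered[pos - 1][1])]
        if pos + 1 < len(ordered) and ordered[pos + 1][0] == "fix" \
                and ordered[pos + 1][2] == stop:
            to_i = fix_index[id(ordered[pos + 1][1])]
        if from_i is not None and to_i is not None:
            f0, f1 = fixations[from_i], fixations[to_i]
            length = float(np.hypot(f1.barycenter_x - f0.barycenter_x,
                                    f1.barycenter_y - f0.barycenter_y)
                           * geometry.pixel_pitch)
        else:
            length = float("nan")
        # a sample's speed lives at index sample-1 (attributed to the later
        # sample of each pair); resolved-unknown members carry no speed
        idx = np.arange(start, stop)
        valid = idx[idx >= 1] - 1
        member_speeds = speeds[valid][np.isfinite(speeds[valid])] \
            if valid.size else np.empty(0)
        mean_speed = float(np.mean(member_speeds)) if member_speeds.size else float("nan")
        direction = "progressive" if x[stop - 1] > x[start] else "regressive"
        saccades.append(DigitalSaccade(
            from_fixation=from_i, to_fixation=to_i, length=length,
            mean_speed=mean_speed, direction=direction,
            start_t=float(t[start]), end_t=float(t[stop - 1]),
            n_samples=stop - start,
            sample_indices=tuple(int(k) for k in idx)))
    return fixations, saccades


# --- per-trial aggregates ----------------------------------------------------

def trial_kinematics(fixations: Sequence[DigitalFixation],
                     saccades: Sequence[DigitalSaccade]) -> TrialKinematics:
    """Aggregate one trial's events; the regressive proportion is missing
    (NaN), not zero, for saccade-free trials."""
    n_fix = len(fixations)
    n_sac = len(saccades)
    n_reg = sum(1 for s in saccades if s.direction == "regressive")
    n_pro = n_sac - n_reg
    with warnings.catch_warnings():
        warnings.simplefilter("ignore", RuntimeWarning)
        mean_dur = float(np.mean([f.duration for f in fixations])) if n_fix else float("nan")
        lengths = np.array([s.length for s in saccades], dtype=float)
        speeds = np.array([s.mean_speed for s in saccades], dtype=float)
        mean_len = float(np.nanmean(lengths)) if n_sac else float("nan")
        mean_speed = float(np.nanmean(speeds)) if n_sac else float("nan")
    prop = n_reg / n_sac if n_sac > 0 else float("nan")
    return TrialKinematics(
        n_fixations=n_fix, mean_fixation_duration=mean_dur,
        n_saccades=n_sac, n_progressive=n_pro, n_regressive=n_reg,
        proportion_regressive=prop, mean_saccade_length=mean_len,
        mean_saccade_speed=mean_speed)


def threshold_sweep(trajectory: Trajectory,
                    candidates: Sequence[float],
                    geometry: ScreenGeometry) -> dict[float, int]:
    """Diagnostic: number of fixations detected under each candidate
    threshold (the study chose the median because it maximised this count;
    the sweep reports, never asserts, that property)."""
    if len(candidates) == 0:
        raise ValueError("no candidate thresholds")
    out: dict[float, int] = {}
    for c in candidates:
        thr = SpeedThreshold(subject_id=trajectory.subject_id,
                             session=trajectory.session, value=float(c))
        fixations, _ = segment(trajectory, thr, geometry)
        out[float(c)] = len(fixations)
    return out


# --- serialisation -----------------------------------------------------------

def events_to_frames(trajectory: Trajectory,
                     fixations: Sequence[DigitalFixation],
                     saccades: Sequence[DigitalSaccade],
                     ) -> tuple[pd.DataFrame, pd.DataFrame]:
    """One row per fixation and per saccade, ready for CSV export."""
    meta = dict(subject_id=trajectory.subject_id, group=trajectory.group,
                phase=trajectory.phase, session=trajectory.session,
                trial_id=trajectory.trial_id)
    fix = pd.DataFrame([{**meta, "start_t": f.start_t, "duration_ms": f.duration,
                         "x_px": f.barycenter_x, "y_px": f.barycenter_y,
                         "n_samples": f.n_samples} for f in fixations])
    sac = pd.DataFrame([{**meta, "start_t": s.start_t, "length_mm": s.length,
                         "speed_mm_s": s.mean_speed, "direction": s.direction,
                         "n_samples": s.n_samples} for s in saccades])
    return fix, sac
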