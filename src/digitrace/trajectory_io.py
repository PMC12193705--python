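"""Reading, validating and converting finger-trajectory logs.

The raw signal is a 60 Hz stream of touch samples per trial, with finger
position logged as percent of screen width/height.  This module round-trips
the CSV / JSON-lines log dialects, validates timestamps and ranges, and
converts between percent, pixel and millimetre coordinate frames.

Coordinate convention: 0-based, x rightward, y downward, origin top-left;
(100%, 100%) maps to (width_px, height_px) as continuous coordinates.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, NamedTuple

import numpy as np
import pandas as pd

from .config import SAMPLING_TOLERANCE, ConfigurationError, ScreenGeometry, ValidationError

CSV_COLUMNS = ["subject_id", "group", "phase", "session", "trial_id",
               "exercise_type", "t_ms", "x_pct", "y_pct", "touching"]


class TouchSample(NamedTuple):
    """One time-stamped finger position (percent-of-screen coordinates)."""

    t: float          # ms from trial onset
    x_pct: float      # percent of screen width, [0, 100]
    y_pct: float      # percent of screen height, [0, 100]
    touching: bool = True


@dataclass
class Trajectory:
    """All samples of one trial, stored as parallel arrays for speed."""

    subject_id: str
    group: int
    phase: int
    session: int
    trial_id: str
    exercise_type: str
    t: np.ndarray          # ms, strictly increasing
    x_pct: np.ndarray
    y_pct: np.ndarray
    touching: np.ndarray   # bool
    meta: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        self.t = np.asarray(self.t, dtype=float)
        self.x_pct = np.asarray(self.x_pct, dtype=float)
        self.y_pct = np.asarray(self.y_pct, dtype=float)
        self.touching = np.asarray(self.touching, dtype=bool)
        n = len(self.t)
        if not (len(self.x_pct) == len(self.y_pct) == len(self.touching) == n):
            raise ValidationError("trajectory arrays must have equal length")

    def __len__(self) -> int:
        return len(self.t)

    @property
    def samples(self) -> list[TouchSample]:
        return [TouchSample(float(t), float(x), float(y), bool(g))
                for t, x, y, g in zip(self.t, self.x_pct, self.y_pct, self.touching)]

    def validate(self, geometry: ScreenGeometry | None = None,
                 interval_tolerance: float = SAMPLING_TOLERANCE) -> None:
        """Raise :class:`ValidationError` on non-monotone timestamps,
        out-of-range coordinates or grossly off-nominal sampling intervals."""
        dt = np.diff(self.t)
        bad = np.flatnonzero(dt <= 0)
        if bad.size:
            raise ValidationError(
                f"non-monotone timestamps at sample rows {bad + 1} "
                f"(trial {self.trial_id}, subject {self.subject_id})")
        for name, arr in (("x_pct", self.x_pct), ("y_pct", self.y_pct)):
            out = np.flatnonzero((arr < 0) | (arr > 100))
            if out.size:
                raise ValidationError(f"{name} outside [0, 100] at rows {out}")
        if np.any(self.t < 0):
            raise ValidationError("negative timestamps")
        if geometry is not None and len(dt):
            nominal = geometry.dt_ms
            off = np.flatnonzero(np.abs(dt - nominal) > interval_tolerance * nominal)
            if off.size:
                raise ValidationError(
                    f"{off.size} inter-sample intervals deviate more than "
                    f"{interval_tolerance:.0%} from the nominal {nominal:.2f} ms")


# --- coordinate conversions --------------------------------------------------

def percent_to_pixels(x_pct, y_pct, geometry: ScreenGeometry):
    """Percent-of-screen -> continuous pixel coordinates."""
    x = np.asarray(x_pct, dtype=float) / 100.0 * geometry.width_px
    y = np.asarray(y_pct, dtype=float) / 100.0 * geometry.height_px
    if np.ndim(x_pct) == 0:
        return float(x), float(y)
    return x, y


def pixels_to_percent(x_px, y_px, geometry: ScreenGeometry):
    x = np.asarray(x_px, dtype=float) / geometry.width_px * 100.0
    y = np.asarray(y_px, dtype=float) / geometry.height_px * 100.0
    if np.ndim(x_px) == 0:
        return float(x), float(y)
    return x, y


def pixels_to_mm(delta_px, geometry: ScreenGeometry):
    """Pixel displacement -> millimetres via the configured pixel pitch."""
    if geometry.pixel_pitch is None or geometry.pixel_pitch <= 0:
        raise ConfigurationError("pixel_pitch is not configured")
    out = np.asarray(delta_px, dtype=float) * geometry.pixel_pitch
    if np.ndim(delta_px) == 0:
        return float(out)
    return out


# --- file I/O ----------------------------------------------------------------

def trajectories_to_frame(trajectories: Iterable[Trajectory]) -> pd.DataFrame:
    rows = []
    for tr in trajectories:
        rows.append(pd.DataFrame({
            "subject_id": tr.subject_id, "group": tr.group, "phase": tr.phase,
            "session": tr.session, "trial_id": tr.trial_id,
            "exercise_type": tr.exercise_type, "t_ms": tr.t,
            "x_pct": tr.x_pct, "y_pct": tr.y_pct,
            "touching": tr.touching.astype(int),
        }))
    if not rows:
        return pd.DataFrame(columns=CSV_COLUMNS)
    return pd.concat(rows, ignore_index=True)[CSV_COLUMNS]


def write_trajectories(trajectories: Iterable[Trajectory], path: str | Path) -> None:
    """Write the one-row-per-sample CSV dialect (or JSON-lines for .jsonl)."""
    path = Path(path)
    frame = trajectories_to_frame(trajectories)
    if path.suffix == ".jsonl":
        with open(path, "w") as fh:
            for rec in frame.to_dict(orient="records"):
                fh.write(json.dumps(rec) + "\n")
    else:
        frame.to_csv(path, index=False)


def _frame_to_trajectories(frame: pd.DataFrame) -> list[Trajectory]:
    missing = [c for c in CSV_COLUMNS if c not in frame.columns]
    if missing:
        raise ValidationError(f"missing columns: {missing}")
    out: list[Trajectory] = []
    keys = ["subject_id", "session", "trial_id"]
    for _, g in frame.groupby(keys, sort=True):
        g = g.sort_values("t_ms", kind="stable")
        t = g["t_ms"].to_numpy(dtype=float)
        dup = np.flatnonzero(np.diff(t) == 0)
        if dup.size:
            row = g.index[dup[0] + 1]
            raise ValidationError(
                f"duplicated timestamp t={t[dup[0]]} at input row {row}")
        tr = Trajectory(
            subject_id=str(g["subject_id"].iloc[0]),
            group=int(g["group"].iloc[0]), phase=int(g["phase"].iloc[0]),
            session=int(g["session"].iloc[0]),
            trial_id=str(g["trial_id"].iloc[0]),
            exercise_type=str(g["exercise_type"].iloc[0]),
            t=t, x_pct=g["x_pct"].to_numpy(dtype=float),
            y_pct=g["y_pct"].to_numpy(dtype=float),
            touching=g["touching"].to_numpy().astype(bool))
        tr.validate()
        out.append(tr)
    return out


def read_trajectories(path: str | Path) -> list[Trajectory]:
    """Read a trajectory log (CSV or .jsonl), one Trajectory per
    (subject, session, trial), samples ordered by time."""
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(path)
    if path.suffix == ".jsonl":
        with open(path) as fh:
            records = [json.loads(line) for line in fh if line.strip()]
        frame = pd.DataFrame.from_records(records)
    else:
        frame = pd.read_csv(path)
    return _frame_to_trajectories(frame)
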