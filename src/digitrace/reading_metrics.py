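"""Word-level reading metrics from segmented fixations.

Maps fixation barycenters onto word character geometry to produce first
landing positions (continuous character units, first letter spanning
[0, 1)), per-word fixation counts (visit streaks), the short/long
word-length classification, and group-level first-fixation kernel density
curves scaled by group size.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

from .config import (DENSITY_BANDWIDTH_FACTOR, LONG_WORD_RANGE,
                     SHORT_WORD_RANGE, ConfigurationError)
from .event_segmentation import DigitalFixation
from .stimulus_engine import WordBox


@dataclass
class WordFixationRecord:
    word: WordBox
    subject_id: str
    first_landing: float        # character units, clipped to [0, n_chars]
    first_landing_raw: float    # unclipped value (padding may push outside)
    n_fixations: int
    n_visits: int
    length_class: str | None


@dataclass
class DensityCurve:
    """First-fixation landing density for one word and decoding group,
    scaled by the number of subjects in the group."""

    word: str
    group: str
    support: np.ndarray   # character units
    values: np.ndarray
    bandwidth: float
    n: int

    def integral(self) -> float:
        return float(np.trapezoid(self.values, self.support))


# --- fixation-to-word assignment ---------------------------------------------

def padded_bounds(box: WordBox, pad_x: float | None = None,
                  pad_y: float | None = None) -> tuple[float, float, float, float]:
    """Word region of interest: the character box padded by half the
    inter-word space horizontally and one line height vertically."""
    px = box.char_width / 2.0 if pad_x is None else pad_x
    py = box.height if pad_y is None else pad_y
    return (box.origin_x - px, box.x_end + px,
            box.origin_y - py, box.origin_y + box.height + py)


def assign_fixations(fixations: Sequence[DigitalFixation],
                     word_boxes: Sequence[WordBox],
                     pad_x: float | None = None,
                     pad_y: float | None = None,
                     ) -> dict[int, list[list[DigitalFixation]]]:
    """Assign each fixation to the word whose padded box contains its
    barycenter; consecutive fixations on the same word form one visit
    streak.  Returns word index -> ordered list of visit streaks."""
    bounds = [padded_bounds(b, pad_x, pad_y) for b in word_boxes]
    for i in range(len(bounds)):
        for j in range(i + 1, len(bounds)):
            if word_boxes[i].line_index != word_boxes[j].line_index:
                continue
            x0a, x1a, *_ = bounds[i]
            x0b, x1b, *_ = bounds[j]
            if min(x1a, x1b) - max(x0a, x0b) > 1e-9:
                raise ConfigurationError(
                    f"padded boxes of {word_boxes[i].text!r} and "
                    f"{word_boxes[j].text!r} overlap; reduce padding")
    visits: dict[int, list[list[DigitalFixation]]] = {i: [] for i in range(len(word_boxes))}
    current: int | None = None
    for fix in fixations:
        hit = None
        for i, (x0, x1, y0, y1) in enumerate(bounds):
            if x0 <= fix.barycenter_x < x1 and y0 <= fix.barycenter_y < y1:
                hit = i
                break
        if hit is None:
            current = None  # unassigned fixation breaks the streak
            continue
        if hit != current:
            visits[hit].append([fix])
        else:
            visits[hit][-1].append(fix)
        current = hit
    return visits


def first_fixation_landing(word: WordBox,
                           visits: Sequence[Sequence[DigitalFixation]]) -> float:
    """Landing of the very first fixation on the word, in character units;
    NaN when the word received no fixation."""
    if not visits or not visits[0]:
        return float("nan")
    first = visits[0][0]
    return (first.barycenter_x - word.origin_x) / word.char_width


def length_class(word: WordBox | int) -> str | None:
    """'short' for 1-6 letters, 'long' for 7-11; None outside 1-11
    (excluded from length analyses)."""
    n = word if isinstance(word, int) else word.n_chars
    if SHORT_WORD_RANGE[0] <= n <= SHORT_WORD_RANGE[1]:
        return "short"
    if LONG_WORD_RANGE[0] <= n <= LONG_WORD_RANGE[1]:
        return "long"
    return None


def word_fixation_records(fixations: Sequence[DigitalFixation],
                          word_boxes: Sequence[WordBox],
                          subject_id: str = "",
                          pad_x: float | None = None,
                          pad_y: float | None = None) -> list[WordFixationRecord]:
    visits = assign_fixations(fixations, word_boxes, pad_x, pad_y)
    records = []
    for i, box in enumerate(word_boxes):
        v = visits[i]
        raw = first_fixation_landing(box, v)
        records.append(WordFixationRecord(
            word=box, subject_id=subject_id,
            first_landing=float(np.clip(raw, 0.0, box.n_chars)),
            first_landing_raw=raw,
            n_fixations=sum(len(s) for s in v),
            n_visits=len(v),
            length_class=length_class(box)))
    return records


def records_to_frame(records: Sequence[WordFixationRecord],
                     trial_id: str = "") -> pd.DataFrame:
    return pd.DataFrame([{
        "subject_id": r.subject_id, "trial_id": trial_id, "word": r.word.text,
        "n_chars": r.word.n_chars, "length_class": r.length_class,
        "first_landing": r.first_landing, "first_landing_raw": r.first_landing_raw,
        "n_fixations": r.n_fixations, "n_visits": r.n_visits,
    } for r in records])


# --- density curves ----------------------------------------------------------

def nrd0_bandwidth(values: np.ndarray) -> float:
    """Reference rule 0.9 x min(sd, IQR/1.34) x n^(-1/5) (sample sd,
    denominator n-1)."""
    values = np.asarray(values, dtype=float)
    n = values.size
    sd = float(np.std(values, ddof=1))
    q75, q25 = np.percentile(values, [75, 25])
    iqr = float(q75 - q25)
    spread = min(sd, iqr / 1.34) if iqr > 0 else sd
    return 0.9 * spread * n ** (-1 / 5)


def first_fixation_density(landings: Sequence[float], group: str,
                           word: str = "", group_size: int | None = None,
                           bandwidth_factor: float = DENSITY_BANDWIDTH_FACTOR,
                           grid: np.ndarray | None = None,
                           n_grid: int = 512) -> DensityCurve:
    """Gaussian kernel density of first-fixation landings, bandwidth =
    ``bandwidth_factor`` x the nrd0-style reference rule, scaled by the
    group size so curves are comparable across groups of different n."""
    x = np.asarray([v for v in landings if np.isfinite(v)], dtype=float)
    if x.size < 2 or np.unique(x).size < 2:
        raise ValueError(
            f"degenerate landing sample for word {word!r}: need >= 2 "
            "distinct values")
    h = bandwidth_factor * nrd0_bandwidth(x)
    if not h > 0:
        raise ValueError(f"zero-spread landing sample for word {word!r}")
    group_size = x.size if group_size is None else int(group_size)
    if grid is None:
        lo, hi = x.min() - 5 * h, x.max() + 5 * h
        grid = np.linspace(lo, hi, n_grid)
    z = (grid[:, None] - x[None, :]) / h
    dens = np.exp(-0.5 * z ** 2).sum(axis=1) / (x.size * h * np.sqrt(2 * np.pi))
    return DensityCurve(word=word, group=group, support=grid,
                        values=dens * group_size, bandwidth=h, n=x.size)


def density_by_group(frame: pd.DataFrame, groups: Mapping[str, str],
                     bandwidth_factor: float = DENSITY_BANDWIDTH_FACTOR,
                     ) -> list[DensityCurve]:
    """Per-word, per-group density curves from a word-metrics frame
    (columns word, subject_id, first_landing) and a subject -> group map."""
    curves = []
    frame = frame.assign(group=frame["subject_id"].map(groups))
    for (word, group), g in frame.groupby(["word", "group"], sort=True):
        landings = g["first_landing"].to_numpy()
        if np.isfinite(landings).sum() >= 2 and np.unique(
                landings[np.isfinite(landings)]).size >= 2:
            curves.append(first_fixation_density(
                landings, group=str(group), word=str(word),
                bandwidth_factor=bandwidth_factor))
    return curves
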