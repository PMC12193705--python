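"""Synthetic finger-trajectory cohorts with known generative structure.

The generator emulates 60 Hz finger traces during sentence reading:
fixation phases are low-speed jitter (small pixel-quantised steps confined
well inside the within-fixation dispersion box) of sampled duration;
saccade phases are straight-line transitions with a symmetric triangular
speed ramp, so the mean saccade speed is half the peak; regressions (a
backward jump to the previous word plus a forward return) are inserted
with a calibrated per-opportunity probability so the pooled regressive
proportion matches the profile's ``p_regressive``; the first landing on
each word is drawn around the profile's landing mean for its length class.

Group profiles default to the printed study conditions: pooled fixation
duration 400 ms with a good-poor gap of -68.6 ms, pooled mean saccade
speed 60 mm/s with a gap of +13.57 mm/s, pooled regressive proportion
0.25 with a gap of -0.03, and landing means 1.60 (short words) / 3.14
(long words).  Session-drift multipliers mimic the published
session-by-session trends and average to exactly 1.0 so marginal group
gaps equal the profile gaps.

Every artifact is a pure function of (config, seed); no global random
state is touched.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from typing import Sequence

import numpy as np
import pandas as pd

from .assessment_scoring import TEST_STRUCTURE, ItemResponse
from .config import ScreenGeometry
from .stimulus_engine import StimulusImage, WordBox, layout_words
from .reading_metrics import length_class
from .trajectory_io import Trajectory, pixels_to_percent

DEFAULT_SENTENCE = "La souris regarde le lapin"


def _drift(*values: float) -> tuple[float, ...]:
    return tuple(values)


@dataclass(frozen=True)
class ReaderProfile:
    """Generative reading-kinematics parameters for one decoding group."""

    label: str
    fixation_duration_ms: float       # mean fixation duration
    fixation_duration_sd: float = 80.0
    saccade_peak_speed: float = 120.0  # mm/s; mean speed = peak / 2
    saccade_speed_sd: float = 5.0      # per-saccade sd of the mean speed
    saccade_amplitude_mm: float = 8.0  # nominal jump when no geometry guides
    p_regressive: float = 0.25
    landing_mean_short: float = 1.60   # character units
    landing_mean_long: float = 3.14
    landing_sd: float = 0.6
    refixation_rate: float = 0.15      # expected refixations per character
    p_correct: float = 0.75            # item success prob in assessments
    # fixation jitter: per-axis move probability and maximum excursion (px);
    # kept sparse and small so the median-speed threshold separates regimes
    jitter_p_move: float = 0.2
    jitter_max_px: int = 2
    # optional additive base of the saccade speed ramp (fraction of the
    # triangular peak weight); 0 keeps the pure symmetric triangular ramp
    saccade_ramp_floor: float = 0.0
    # per-session multiplicative trends; average exactly 1.0 over sessions
    session_drift: dict = field(default_factory=lambda: {
        "saccade_speed": _drift(0.93, 0.96, 0.99, 1.03, 1.05, 1.04),
        "fixation_duration": _drift(1.08, 1.04, 1.00, 0.97, 0.955, 0.955),
        "p_regressive": _drift(1.10, 1.06, 1.00, 0.95, 0.945, 0.945),
        "saccade_amplitude": _drift(0.90, 0.95, 1.00, 1.04, 1.06, 1.05),
    })

    def __post_init__(self) -> None:
        if self.fixation_duration_ms <= 0 or self.saccade_peak_speed <= 0:
            raise ValueError("means must be positive")
        if not 0 <= self.p_regressive <= 1:
            raise ValueError("p_regressive must be in [0, 1]")

    @property
    def mean_saccade_speed(self) -> float:
        return self.saccade_peak_speed / 2.0

    def drift(self, name: str, session: int) -> float:
        trend = self.session_drift.get(name)
        return 1.0 if trend is None else trend[session - 1]


#: pooled fixation duration 400 ms, gap -68.6 ms (good - poor)
#: pooled mean speed 60 mm/s, gap +13.57 mm/s
#: pooled regressive proportion 0.25, gap -0.03
GOOD_DECODER = ReaderProfile(
    label="good", fixation_duration_ms=365.7, saccade_peak_speed=133.57,
    p_regressive=0.235, refixation_rate=0.15, p_correct=0.85,
    saccade_amplitude_mm=9.5)
POOR_DECODER = ReaderProfile(
    label="poor", fixation_duration_ms=434.3, saccade_peak_speed=106.43,
    p_regressive=0.265, refixation_rate=0.15, p_correct=0.60,
    saccade_amplitude_mm=8.0)


@dataclass
class CohortConfig:
    n_per_group: int = 10
    good: ReaderProfile = field(default_factory=lambda: GOOD_DECODER)
    poor: ReaderProfile = field(default_factory=lambda: POOR_DECODER)
    sessions: tuple = (1, 2, 3, 4, 5, 6)
    trials_per_session: int = 5
    sentence: str = DEFAULT_SENTENCE
    seed: int = 0
    geometry: ScreenGeometry = field(default_factory=ScreenGeometry)
    # between-subject sd of each parameter (additive on the profile mean)
    subject_sd: dict = field(default_factory=lambda: {
        "mean_speed": 7.0, "fixation_duration": 35.0,
        "p_regressive": 0.03, "landing": 0.12})

    def __post_init__(self) -> None:
        if self.n_per_group < 1:
            raise ValueError("n_per_group must be >= 1")


def _triangle_fold(c: np.ndarray, amp: int) -> np.ndarray:
    """Fold an unbounded +-1 walk into [-amp, amp] keeping unit steps."""
    period = 4 * amp
    return np.abs((c - amp) % period - 2 * amp) - amp


def _fixation_samples(rng: np.random.Generator, x0: float, y0: float,
                      n: int, p_move: float, max_px: int) -> tuple[np.ndarray, np.ndarray]:
    steps_x = rng.integers(0, 2, size=n) * 2 - 1
    steps_y = rng.integers(0, 2, size=n) * 2 - 1
    steps_x *= rng.random(n) < p_move
    steps_y *= rng.random(n) < p_move
    cx = np.concatenate([[0], np.cumsum(steps_x[:-1])])
    cy = np.concatenate([[0], np.cumsum(steps_y[:-1])])
    return x0 + _triangle_fold(cx, max_px), y0 + _triangle_fold(cy, max_px)


def _saccade_samples(x0: float, y0: float, x1: float, y1: float,
                     mean_speed_mm_s: float, geometry: ScreenGeometry,
                     ramp_floor: float = 0.27) -> tuple[np.ndarray, np.ndarray]:
    """Intermediate samples of a straight saccade: a symmetric
    accelerate/decelerate ramp on top of a velocity floor, so the mean
    sample speed is exactly the requested mean and the slowest sample stays
    at roughly half of it; the arrival point itself belongs to the next
    fixation."""
    d_mm = float(np.hypot(x1 - x0, y1 - y0)) * geometry.pixel_pitch
    dt_s = 1.0 / geometry.sampling_rate
    m = max(2, int(round(d_mm / (mean_speed_mm_s * dt_s))))
    w = np.minimum(np.arange(1, m + 1), np.arange(m, 0, -1)).astype(float)
    w += ramp_floor * m
    frac = np.cumsum(w) / w.sum()
    xs = x0 + (x1 - x0) * frac[:-1]
    ys = y0 + (y1 - y0) * frac[:-1]
    return xs, ys


def _plan_fixations(rng: np.random.Generator, words: Sequence[WordBox],
                    profile: ReaderProfile, session: int,
                    landing_shift: float) -> list[tuple[float, float, int, str]]:
    """Planned fixation points: (x_px, y_px, word_index, kind)."""
    plan: list[tuple[float, float, int, str]] = []
    for i, box in enumerate(words):
        mean = (profile.landing_mean_short if length_class(box) != "long"
                else profile.landing_mean_long) + landing_shift
        c = float(np.clip(rng.normal(mean, profile.landing_sd),
                          0.2, max(box.n_chars - 0.2, 0.3)))
        y = box.origin_y + box.height / 2.0 + rng.normal(0.0, 1.5)
        plan.append((box.origin_x + c * box.char_width, y, i, "landing"))
        n_refix = rng.poisson(profile.refixation_rate * box.n_chars)
        if n_refix:
            # refixations step at least ~1 character forward so the jump is
            # large enough to register as a saccade, not drift
            hi = max(box.n_chars - 0.2, c + 1.0)
            cs = np.sort(rng.uniform(c + 0.8, hi, size=n_refix))
            for cr in cs:
                yr = box.origin_y + box.height / 2.0 + rng.normal(0.0, 1.5)
                plan.append((box.origin_x + cr * box.char_width, yr, i, "refix"))
    return plan


def _insert_regressions(rng: np.random.Generator,
                        plan: list[tuple[float, float, int, str]],
                        words: Sequence[WordBox],
                        p_regressive: float) -> list[tuple[float, float, int, str]]:
    """Insert backward-jump / return pairs after forward fixations so the
    expected regressive proportion equals ``p_regressive``."""
    n_forward = len(plan) - 1  # forward saccades in the base plan
    if n_forward <= 0 or p_regressive <= 0:
        return list(plan)
    q = min(p_regressive / max(1.0 - 2.0 * p_regressive, 1e-9), 0.95)
    out = [plan[0]]
    for point in plan[1:]:
        out.append(point)
        if rng.random() < q:
            x, y, wi, _ = point
            if wi > 0:
                bx, by = words[wi - 1].center
            else:
                bx, by = x - 3 * words[wi].char_width, y
            by += rng.normal(0.0, 1.5)
            out.append((bx, by, max(wi - 1, 0), "regression"))
            # forward return lands just right of the departure point so the
            # return saccade is unambiguously progressive
            out.append((x + 0.2 * words[wi].char_width, y, wi, "return"))
    return out


def simulate_trial(profile: ReaderProfile,
                   stimulus: StimulusImage | Sequence[WordBox],
                   geometry: ScreenGeometry | None = None,
                   seed: int | np.random.Generator = 0,
                   session: int = 1,
                   subject_id: str = "S1", group: int = 1, phase: int = 1,
                   trial_id: str = "t1", exercise_type: str = "SE",
                   effects: dict | None = None) -> Trajectory:
    """One synthetic sentence-reading trial sampled at the screen rate.

    ``effects`` holds additive subject-level offsets (mean_speed,
    fixation_duration, p_regressive, landing); the session drift of the
    profile applies on top.
    """
    geometry = geometry or ScreenGeometry()
    rng = seed if isinstance(seed, np.random.Generator) \
        else np.random.default_rng(seed)
    words = stimulus.word_boxes if isinstance(stimulus, StimulusImage) \
        else list(stimulus)
    if not words:
        raise ValueError("stimulus has no word boxes")
    effects = effects or {}

    dur_mean = (profile.fixation_duration_ms
                * profile.drift("fixation_duration", session)
                + effects.get("fixation_duration", 0.0))
    speed_mean = (profile.mean_saccade_speed
                  * profile.drift("saccade_speed", session)
                  + effects.get("mean_speed", 0.0))
    p_reg = float(np.clip(profile.p_regressive
                          * profile.drift("p_regressive", session)
                          + effects.get("p_regressive", 0.0), 0.0, 0.45))

    plan = _plan_fixations(rng, words, profile, session,
                           effects.get("landing", 0.0))
    plan = _insert_regressions(rng, plan, words, p_reg)

    dt_ms = geometry.dt_ms
    xs: list[np.ndarray] = []
    ys: list[np.ndarray] = []
    for k, (px, py, _, _) in enumerate(plan):
        dur = max(rng.normal(dur_mean, profile.fixation_duration_sd), 3 * dt_ms)
        n_fix = max(2, int(round(dur / dt_ms)))
        fx, fy = _fixation_samples(rng, px, py, n_fix,
                                   profile.jitter_p_move, profile.jitter_max_px)
        xs.append(fx)
        ys.append(fy)
        if k + 1 < len(plan):
            nx, ny, _, _ = plan[k + 1]
            v = max(rng.normal(speed_mean, profile.saccade_speed_sd), 10.0)
            sx, sy = _saccade_samples(fx[-1], fy[-1], nx, ny, v, geometry,
                                      profile.saccade_ramp_floor)
            xs.append(sx)
            ys.append(sy)
    x = np.concatenate(xs)
    y = np.concatenate(ys)
    x = np.clip(x, 0.0, geometry.width_px - 1e-6)
    y = np.clip(y, 0.0, geometry.height_px - 1e-6)
    t = np.arange(len(x)) * dt_ms
    x_pct, y_pct = pixels_to_percent(x, y, geometry)
    return Trajectory(subject_id=subject_id, group=group, phase=phase,
                      session=session, trial_id=trial_id,
                      exercise_type=exercise_type, t=t, x_pct=x_pct,
                      y_pct=y_pct, touching=np.ones(len(x), dtype=bool),
                      meta={"n_planned_fixations": len(plan)})


def sentence_word_boxes(sentence: str = DEFAULT_SENTENCE,
                        geometry: ScreenGeometry | None = None) -> list[WordBox]:
    geometry = geometry or ScreenGeometry()
    return layout_words(sentence, geometry)


def simulate_cohort(config: CohortConfig,
                    stimuli: Sequence[WordBox] | None = None,
                    ) -> tuple[list[Trajectory], pd.DataFrame]:
    """Full cohort: one Trajectory per subject x session x trial, plus a
    subject truth table (true group labels and per-subject parameters)
    for parameter-recovery scoring.

    Finger data exist only for a subject's digit-tracking phase, so each
    subject's trajectories all carry that phase; phase assignment is
    balanced within groups (crossover design).
    """
    rng = np.random.default_rng(config.seed)
    words = stimuli if stimuli is not None else sentence_word_boxes(
        config.sentence, config.geometry)
    sd = config.subject_sd
    trajectories: list[Trajectory] = []
    rows = []
    k = 0
    for gi, profile in enumerate((config.good, config.poor), start=1):
        for j in range(config.n_per_group):
            k += 1
            sid = f"S{k:03d}"
            phase = 1 if j < (config.n_per_group + 1) // 2 else 2
            effects = {
                "mean_speed": rng.normal(0.0, sd["mean_speed"]),
                "fixation_duration": rng.normal(0.0, sd["fixation_duration"]),
                "p_regressive": rng.normal(0.0, sd["p_regressive"]),
                "landing": rng.normal(0.0, sd["landing"]),
            }
            rows.append({
                "subject_id": sid, "decoding": profile.label, "group": gi,
                "phase": phase,
                "true_mean_speed": profile.mean_saccade_speed + effects["mean_speed"],
                "true_fixation_duration": profile.fixation_duration_ms
                + effects["fixation_duration"],
                "true_p_regressive": profile.p_regressive + effects["p_regressive"],
                "true_landing_short": profile.landing_mean_short + effects["landing"],
                "true_landing_long": profile.landing_mean_long + effects["landing"],
            })
            for session in config.sessions:
                for trial in range(1, config.trials_per_session + 1):
                    trajectories.append(simulate_trial(
                        profile, words, config.geometry, rng,
                        session=session, subject_id=sid, group=gi,
                        phase=phase, trial_id=f"{session}-{trial:02d}",
                        effects=effects))
    return trajectories, pd.DataFrame(rows)


def simulate_assessment(profile: ReaderProfile | float, test: str,
                        seed: int | np.random.Generator = 0,
                        n_items: int | None = None) -> list[ItemResponse]:
    """Item-level responses with a profile-linked success probability;
    supports discontinuation and change-score fixtures."""
    if test not in TEST_STRUCTURE:
        raise ValueError(f"unknown test label {test!r}")
    rng = seed if isinstance(seed, np.random.Generator) \
        else np.random.default_rng(seed)
    p = profile.p_correct if isinstance(profile, ReaderProfile) else float(profile)
    n = n_items if n_items is not None else TEST_STRUCTURE[test]["max_items"]
    correct = rng.random(n) < p
    return [ItemResponse(item=i + 1, correct=bool(c))
            for i, c in enumerate(correct)]


# --- reading-change cohort (score level, no trajectories) --------------------

def simulate_reading_change_cohort(
        n_subjects: int = 54, seed: int = 0,
        modality_effect: float = 3.33,   # digit-tracking minus paper, points
        phase_effect: float = -6.17,     # phase 2 minus phase 1
        age_effect: float = -17.72,      # per year of age
        intercept: float = 8.28,
        subject_sd: float = 4.0, resid_sd: float = 5.0) -> pd.DataFrame:
    """Crossover reading-change table: one row per subject x phase with the
    modality schedule of the study design (group 1 digit-first), the eight
    cognitive covariates and age, and a known modality effect."""
    rng = np.random.default_rng(seed)
    rows = []
    cov_effects = {c: 0.2 for c in ("similarities", "matrix", "vocabulary",
                                    "oral_comprehension", "memory_span",
                                    "cancellation")}
    cov_effects["selective_attention"] = -0.01
    cov_effects["motor_skills"] = 0.2
    for i in range(n_subjects):
        sid = f"R{i + 1:03d}"
        grp = 1 if i < n_subjects // 2 else 2
        age = rng.uniform(5.9, 6.8)
        cov_centers = {c: (120.0 if c == "selective_attention" else 10.0)
                       for c in cov_effects}
        covs = {c: rng.normal(cov_centers[c],
                              80.0 if c == "selective_attention" else 3.0)
                for c in cov_effects}
        u = rng.normal(0.0, subject_sd)
        for phase in (1, 2):
            modality = ("digit" if (grp == 1) == (phase == 1) else "paper")
            gain = (intercept + modality_effect * (modality == "digit")
                    + phase_effect * (phase == 2)
                    + age_effect * (age - 6.3)
                    + sum(cov_effects[c] * (covs[c] - cov_centers[c])
                          for c in covs)
                    + u + rng.normal(0.0, resid_sd))
            rows.append({"subject_id": sid, "group": grp, "phase": phase,
                         "modality": modality, "gain": gain, "age": age,
                         **covs})
    return pd.DataFrame(rows)
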