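"""Training stimuli and the crowding-free presentation frames.

Builds pseudoword catalogues from a taught grapheme inventory, plans the
trial mix of each training session, renders text with recorded character
geometry (monospace, so letter positions are affine in the letter index),
and produces the blurred / finger-contingent-unblurred display frames that
suppress parafoveal crowding.

Exercise types: WPW (written pseudoword matching), Sy (syllable
visual-auditory matching), OPW (oral pseudoword matching), SE (sentence
reading comprehension).
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterable, Sequence

import numpy as np
from PIL import Image, ImageDraw, ImageFont
from scipy import ndimage

from .config import (BLUR_SIGMA_PX, UNBLUR_RADIUS_PX, ConfigurationError,
                     ScreenGeometry)


class GenerationError(RuntimeError):
    """The inventory cannot satisfy the requested stimulus counts."""


class LayoutError(ValueError):
    """Text does not fit the raster under the configured font metrics."""


# --- grapheme inventory ------------------------------------------------------

@dataclass(frozen=True)
class GraphemeInventory:
    """Taught graphemes with phoneme labels and the session each may first
    appear in.  Multi-letter or accented graphemes count as complex."""

    graphemes: dict  # grapheme -> phoneme label
    vowels: frozenset
    consonants: frozenset
    introduction_session: dict  # grapheme -> first session (1-6)

    def __post_init__(self) -> None:
        if not self.graphemes:
            raise ConfigurationError("grapheme inventory is empty")
        for g, p in self.graphemes.items():
            if not p:
                raise ConfigurationError(f"grapheme {g!r} has no phoneme label")

    def taught_by(self, session: int) -> set[str]:
        return {g for g in self.graphemes
                if self.introduction_session.get(g, 1) <= session}

    @staticmethod
    def is_complex(grapheme: str) -> bool:
        return len(grapheme) > 1 or not grapheme.isascii()


def default_inventory() -> GraphemeInventory:
    """A first-grade-style French inventory: simple letters first, complex
    (multi-letter / accented) graphemes introduced in later sessions."""
    vowels_simple = {"a": 1, "i": 1, "o": 1, "u": 2, "e": 2}
    vowels_complex = {"é": 3, "ou": 3, "on": 4, "an": 4, "in": 5, "oi": 5}
    cons_simple = {"l": 1, "r": 1, "m": 1, "s": 2, "f": 2, "v": 2, "t": 3,
                   "p": 3, "n": 3, "d": 4, "b": 4, "j": 5, "c": 5}
    cons_complex = {"ch": 4, "ph": 5, "gn": 6}
    graphemes = {}
    intro = {}
    for d in (vowels_simple, vowels_complex, cons_simple, cons_complex):
        for g, sess in d.items():
            graphemes[g] = f"/{g}/"
            intro[g] = sess
    return GraphemeInventory(
        graphemes=graphemes,
        vowels=frozenset(vowels_simple) | frozenset(vowels_complex),
        consonants=frozenset(cons_simple) | frozenset(cons_complex),
        introduction_session=intro)


# --- pseudowords -------------------------------------------------------------

TIERS = ("simple-CV", "complex-grapheme-CV", "complex-syllable")


@dataclass(frozen=True)
class PseudowordSpec:
    """A pronounceable non-word: its surface form, syllabification and
    structural complexity tier."""

    surface: str
    syllable_count: int
    complexity_tier: str
    syllables: tuple = ()
    graphemes: tuple = ()

    def __post_init__(self) -> None:
        if self.syllable_count not in (1, 2, 3):
            raise ValueError("syllable_count must be 1, 2 or 3")
        if self.complexity_tier not in TIERS:
            raise ValueError(f"unknown complexity tier {self.complexity_tier!r}")


def _restrict(inv: GraphemeInventory, session: int) -> GraphemeInventory:
    """Sub-inventory of graphemes introduced by a given session."""
    taught = inv.taught_by(session)
    return GraphemeInventory(
        graphemes={g: p for g, p in inv.graphemes.items() if g in taught},
        vowels=frozenset(v for v in inv.vowels if v in taught),
        consonants=frozenset(c for c in inv.consonants if c in taught),
        introduction_session={g: s for g, s in inv.introduction_session.items()
                              if g in taught})


def _sample_syllable(rng: np.random.Generator, inv: GraphemeInventory,
                     tier: str) -> tuple[str, tuple[str, ...], str]:
    """Sample one syllable; returns (surface, graphemes, effective tier) —
    the tier downgrades to simple-CV when the inventory cannot support it."""
    simple_c = sorted(g for g in inv.consonants if not inv.is_complex(g))
    simple_v = sorted(g for g in inv.vowels if not inv.is_complex(g))
    all_c = sorted(inv.consonants)
    all_v = sorted(inv.vowels)
    if tier == "complex-grapheme-CV" and not any(
            inv.is_complex(g) for g in (*all_c, *all_v)):
        tier = "simple-CV"   # early sessions teach no complex graphemes yet
    if tier == "simple-CV":
        parts = (rng.choice(simple_c), rng.choice(simple_v))
    elif tier == "complex-grapheme-CV":
        # at least one complex grapheme in a CV frame
        complex_c = [g for g in all_c if inv.is_complex(g)]
        complex_v = [g for g in all_v if inv.is_complex(g)]
        if rng.random() < 0.5 and complex_c:
            parts = (rng.choice(complex_c), rng.choice(all_v))
        elif complex_v:
            parts = (rng.choice(all_c), rng.choice(complex_v))
        else:
            parts = (rng.choice(complex_c), rng.choice(all_v))
    else:  # complex-syllable: CVC or CCV from simple graphemes
        if rng.random() < 0.5:
            parts = (rng.choice(simple_c), rng.choice(simple_v),
                     rng.choice(simple_c))
        else:
            parts = (rng.choice(simple_c), rng.choice(simple_c),
                     rng.choice(simple_v))
    parts = tuple(str(p) for p in parts)
    return "".join(parts), parts, tier


def build_pseudoword_catalogue(
        inventory: GraphemeInventory | None = None,
        phase_spec: dict[int, int] | None = None,
        seed: int = 0,
        blocklist: Iterable[str] = (),
        tier_weights: Sequence[float] = (0.4, 0.3, 0.3),
) -> list[PseudowordSpec]:
    """Seeded catalogue with exact counts per syllable class.

    The default phase spec introduces 20 monosyllabic, 60 bisyllabic and 40
    trisyllabic pseudowords, spanning the three complexity tiers.  Each item
    is assigned an introduction session (1-6) and uses only graphemes taught
    by then, so session plans can draw decodable stimuli from the start of
    training.  Real-word collisions are rejected against a user-supplied
    ``blocklist``.
    """
    inventory = inventory or default_inventory()
    phase_spec = {1: 20, 2: 60, 3: 40} if phase_spec is None else dict(phase_spec)
    if any(v < 0 for v in phase_spec.values()):
        raise ValueError("phase_spec counts must be non-negative")
    rng = np.random.default_rng(seed)
    blocked = {w.lower() for w in blocklist}
    catalogue: list[PseudowordSpec] = []
    seen: set[str] = set()
    for n_syll in sorted(phase_spec):
        want = phase_spec[n_syll]
        made = 0
        attempts = 0
        limit = max(1000, want * 200)
        while made < want:
            attempts += 1
            if attempts > limit:
                raise GenerationError(
                    f"inventory too small to build {want} distinct "
                    f"{n_syll}-syllable pseudowords")
            tier = TIERS[int(rng.choice(len(TIERS), p=np.asarray(tier_weights)
                                        / np.sum(tier_weights)))]
            sub = _restrict(inventory, int(rng.integers(1, 7)))
            sylls, graphs, tiers_used = [], [], []
            for _ in range(n_syll):
                s, g, eff = _sample_syllable(rng, sub, tier)
                sylls.append(s)
                graphs.extend(g)
                tiers_used.append(eff)
            tier = max(tiers_used, key=TIERS.index)
            surface = "".join(sylls)
            if surface in seen or surface in blocked:
                continue
            seen.add(surface)
            catalogue.append(PseudowordSpec(
                surface=surface, syllable_count=n_syll, complexity_tier=tier,
                syllables=tuple(sylls), graphemes=tuple(graphs)))
            made += 1
    return catalogue


# --- session plans -----------------------------------------------------------

SESSION_MIX_EARLY = {"WPW": 10, "Sy": 10, "SE": 0, "OPW": 10}   # sessions 1-3
SESSION_MIX_LATE = {"WPW": 10, "Sy": 5, "SE": 5, "OPW": 10}     # sessions 4-6


@dataclass(frozen=True)
class SessionPlan:
    session_index: int
    trials: tuple  # of (exercise_type, stimulus id)

    def counts(self) -> dict[str, int]:
        out = {"WPW": 0, "Sy": 0, "SE": 0, "OPW": 0}
        for ex, _ in self.trials:
            out[ex] += 1
        return out


def session_mix(session_index: int) -> dict[str, int]:
    if not 1 <= session_index <= 6:
        raise ValueError(f"session_index must be in 1-6, got {session_index}")
    return dict(SESSION_MIX_EARLY if session_index <= 3 else SESSION_MIX_LATE)


def schedule_session(session_index: int,
                     catalogue: Sequence[PseudowordSpec],
                     seed: int = 0,
                     inventory: GraphemeInventory | None = None,
                     sentences: Sequence[str] = ()) -> SessionPlan:
    """Trial plan for one session: the session's fixed exercise mix, with
    pseudoword stimuli restricted to graphemes already introduced."""
    mix = session_mix(session_index)
    inventory = inventory or default_inventory()
    taught = inventory.taught_by(session_index)
    rng = np.random.default_rng(seed)
    eligible = [pw for pw in catalogue
                if not pw.graphemes or set(pw.graphemes) <= taught]
    if len(eligible) == 0 and (mix["WPW"] or mix["OPW"]):
        raise GenerationError(
            f"no catalogue items decodable with session-{session_index} graphemes")

    def draw_words(n: int) -> list[str]:
        replace = len(eligible) < n
        idx = rng.choice(len(eligible), size=n, replace=replace)
        return [eligible[i].surface for i in idx]

    syllables = sorted({s for pw in eligible for s in pw.syllables}) or ["sy"]
    trials: list[tuple[str, str]] = []
    trials += [("WPW", w) for w in draw_words(mix["WPW"])]
    trials += [("Sy", syllables[int(i)])
               for i in rng.choice(len(syllables), size=mix["Sy"],
                                   replace=len(syllables) < mix["Sy"])]
    if mix["SE"]:
        pool = list(sentences) or [f"sentence-{k}" for k in range(1, 6)]
        idx = rng.choice(len(pool), size=mix["SE"], replace=len(pool) < mix["SE"])
        trials += [("SE", pool[int(i)]) for i in idx]
    trials += [("OPW", w) for w in draw_words(mix["OPW"])]
    order = rng.permutation(len(trials))
    return SessionPlan(session_index=session_index,
                       trials=tuple(trials[i] for i in order))


# --- decodability ------------------------------------------------------------

def segment_graphemes(segmented: str | Sequence[str]) -> list[str]:
    """Accepts either a pre-segmented string ('l|a s|ou|r|i|s') or an
    explicit list of grapheme tokens."""
    if isinstance(segmented, str):
        tokens = [g for word in segmented.split() for g in word.split("|") if g]
    else:
        tokens = [g for g in segmented if g]
    return tokens


def decodability_fraction(segmented: str | Sequence[str],
                          inventory: GraphemeInventory | None = None) -> float:
    """Fraction of phonemes whose grapheme is taught.  The caller supplies
    the grapheme segmentation; no automatic French syllabification here."""
    inventory = inventory or default_inventory()
    tokens = segment_graphemes(segmented)
    if not tokens:
        raise ValueError("empty sentence: no graphemes to assess")
    taught = sum(1 for g in tokens if g in inventory.graphemes)
    return taught / len(tokens)


def is_admissible(segmented: str | Sequence[str],
                  inventory: GraphemeInventory | None = None,
                  minimum: float = 0.60) -> bool:
    """Strictly more than 60% of phonemes must be decodable."""
    return decodability_fraction(segmented, inventory) > minimum


# --- rendered stimuli --------------------------------------------------------

@dataclass(frozen=True)
class WordBox:
    """One word's on-screen character geometry (monospace)."""

    text: str
    origin_x: float   # px, left edge of first letter cell
    origin_y: float   # px, top of line
    char_width: float  # px
    height: float      # px
    line_index: int = 0

    @property
    def n_chars(self) -> int:
        return len(self.text)

    @property
    def width(self) -> float:
        return self.n_chars * self.char_width

    @property
    def x_end(self) -> float:
        return self.origin_x + self.width

    @property
    def center(self) -> tuple[float, float]:
        return (self.origin_x + self.width / 2.0,
                self.origin_y + self.height / 2.0)


@dataclass
class StimulusImage:
    raster: np.ndarray                 # grayscale HxW, float in [0, 255]
    word_boxes: list[WordBox]
    blur_sigma: float = 0.0

    def __post_init__(self) -> None:
        self.raster = np.asarray(self.raster, dtype=float)
        if self.blur_sigma < 0:
            raise ValueError("blur_sigma must be >= 0")


def layout_words(text: str, geometry: ScreenGeometry,
                 origin: tuple[float, float] = (200.0, 560.0),
                 char_width: float = 20.0, line_height: float = 40.0,
                 space_width: float | None = None) -> list[WordBox]:
    """Place whitespace-delimited tokens in reading order, wrapping lines;
    raises :class:`LayoutError` on overflow."""
    if not text.strip():
        raise LayoutError("empty text")
    space_width = char_width if space_width is None else space_width
    x, y = origin
    line = 0
    boxes: list[WordBox] = []
    for token in text.split():
        w = len(token) * char_width
        if x + w > geometry.width_px:
            line += 1
            x = origin[0]
            y = origin[1] + line * (2 * line_height)
            if x + w > geometry.width_px:
                raise LayoutError(f"word {token!r} wider than the screen")
        if y + line_height > geometry.height_px:
            raise LayoutError("text overflows the raster vertically")
        boxes.append(WordBox(text=token, origin_x=x, origin_y=y,
                             char_width=char_width, height=line_height,
                             line_index=line))
        x += w + space_width
    return boxes


def render_text(text: str, geometry: ScreenGeometry | None = None,
                origin: tuple[float, float] = (200.0, 560.0),
                char_width: float = 20.0, line_height: float = 40.0) -> StimulusImage:
    """Render text to a grayscale raster with one WordBox per token.

    Glyphs are drawn one per character cell so that character positions are
    exactly affine in the letter index (monospace assumption).
    """
    geometry = geometry or ScreenGeometry()
    boxes = layout_words(text, geometry, origin, char_width, line_height)
    img = Image.new("L", (geometry.width_px, geometry.height_px), color=255)
    draw = ImageDraw.Draw(img)
    font = ImageFont.load_default()
    for box in boxes:
        for i, ch in enumerate(box.text):
            draw.text((box.origin_x + i * box.char_width + 2, box.origin_y + 4),
                      ch, fill=0, font=font)
    return StimulusImage(raster=np.asarray(img, dtype=float),
                         word_boxes=boxes, blur_sigma=0.0)


def blur_image(image: StimulusImage, sigma: float = BLUR_SIGMA_PX) -> StimulusImage:
    """Gaussian-blur the raster (word geometry unchanged)."""
    if sigma < 0:
        raise ValueError("sigma must be >= 0")
    if sigma == 0:
        raster = image.raster.copy()
    else:
        raster = ndimage.gaussian_filter(image.raster, sigma=sigma,
                                         mode="nearest")
    return StimulusImage(raster=raster, word_boxes=list(image.word_boxes),
                         blur_sigma=sigma)


def unblur_window(blurred: StimulusImage, original: StimulusImage,
                  finger_xy: tuple[float, float],
                  radius: float = UNBLUR_RADIUS_PX) -> np.ndarray:
    """Compose one display frame: original pixels inside a hard-edged circle
    around the finger, blurred pixels elsewhere.  A finger outside the
    raster yields the fully blurred frame."""
    if blurred.raster.shape != original.raster.shape:
        raise ValueError("blurred and original rasters differ in geometry")
    frame = blurred.raster.copy()
    fx, fy = finger_xy
    h, w = frame.shape
    if radius <= 0 or not (0 <= fx < w and 0 <= fy < h):
        return frame
    yy, xx = np.ogrid[:h, :w]
    mask = (xx - fx) ** 2 + (yy - fy) ** 2 <= radius ** 2
    frame[mask] = original.raster[mask]
    return frame
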