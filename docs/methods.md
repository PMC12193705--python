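# Methods

`digitrace` reimplements the computational pipeline of a digit-tracking
reading-acquisition study: first-graders read blurred text on a tablet and
unblur it locally by sliding a finger, so the 60 Hz finger trace serves as a
proxy for the gaze path.  The package covers stimulus preparation, event
segmentation of the finger trace, word-level reading metrics, assessment
scoring, and the mixed-model analyses, exercised end to end on synthetic
cohorts with known generative structure.

## Event model

For each child and session, all sample-to-sample movement speeds are pooled
across trials; speeds are Euclidean pixel displacements converted to mm via
the pixel pitch and divided by the inter-sample interval.  The **median of
the strictly positive speeds** is the individual threshold.  Maximal streaks
of contiguous samples moving slower than (or exactly at) the threshold are
*digital fixations*; faster streaks are *digital saccades*.  A fixation's
position is the barycenter of its member samples; member spread must stay
below 5.8 px in X and 6.4 px in Y, and wider slow streaks are split greedily
left-to-right at the first violating sample.  A saccade's length is the
distance between the barycenters of its flanking fixations (mm), its speed
the mean of its member-sample speeds (mm/s), and it is progressive iff the
X-coordinate of its last point strictly exceeds that of its first point —
regressive otherwise, so a one-sample saccade counts as regressive.

Conventions the event description leaves open, fixed here and exposed as
config knobs:

- a speed belongs to the *later* sample of each pair; samples with no
  defined speed (the trial's first sample, or the sample after a
  finger-lift) join the class of the nearest following classified sample;
- at-threshold speeds join the slow (fixation) class — conservative, since
  only strict `<` and `>` are defined;
- finger-lift samples (`touching = false`) break streaks and belong to no
  event; a saccade separated from a fixation by a gap has no defined length;
- no minimum fixation duration is imposed (a configurable floor defaults
  to 0 ms);
- the dispersion limits (5.8 / 6.4 px ≈ 0.3% / 0.5% of screen), the
  sampling rate (60 Hz), screen size (1920×1280) and blur sigma (20 px) are
  config constants.

The pixel pitch is nowhere stated by the protocol; the default 0.1354 mm/px
derives from a 12.3-inch 3:2 panel (312.42 mm diagonal) at 1920×1280, a
plausible convertible-tablet geometry.  Every mm-valued output scales with
this constant.

## Stimuli

Pseudoword catalogues (default 20 mono-, 60 bi-, 40 trisyllabic items per
phase) are sampled from a taught-grapheme inventory across three complexity
tiers (simple CV, complex-grapheme CV, CVC/CCV), each item restricted to
graphemes introduced by its assigned session.  Sessions 1–3 mix 10 WPW +
10 Sy + 10 OPW trials; sessions 4–6 mix 10 WPW + 5 Sy + 5 SE + 10 OPW.
Sentences are admissible when strictly more than 60% of their phonemes are
decodable under the inventory (the caller supplies the grapheme
segmentation; no automatic French syllabification is attempted).  Rendering
assumes a monospace grid so character positions are affine in letter index;
display frames blur the raster with a Gaussian (σ = 20 px) and restore the
original pixels inside a hard-edged circle of 78 px (≈ 2° of visual angle at
300 mm) around the finger.  The window's shape and exact size are this
package's defaults, not protocol values.

## Word-level metrics

A fixation belongs to the word whose padded box contains its barycenter
(padding: half the inter-word space horizontally, one line height
vertically); consecutive fixations on a word form one visit streak.  The
first landing position is `(barycenter_x − origin_x) / char_width`,
continuous, with the first letter spanning [0, 1); values are clipped to
[0, n_chars] for reporting and kept raw alongside.  Words of 1–6 letters
are *short*, 7–11 *long*; other lengths are excluded from length analyses.
First-fixation density curves use a Gaussian kernel with bandwidth
0.4 × the nrd0-style reference rule 0.9·min(sd, IQR/1.34)·n^(−1/5)
(sample sd, denominator n−1), scaled by group size.

## Assessment scoring

The letter/syllable list stops after five consecutive errors, with an
85-item maximum; its score is the number of correct items.  Timed readings
report accuracy (percent of attempted items correct) and fluency (items
correct per minute; the meaningless text runs 3 minutes, the meaningful
text 1 minute).  Change scores are post − pre on the native scale.  The
good/poor decoding split cuts at the median; scores exactly at the median
go to "poor" by default (configurable), recorded in output metadata.  The
real instruments are copyrighted: the package ships only their scoring
structure and generates synthetic response fixtures.

## Mixed models

Reading change: `gain ~ Modality × Phase + age + 8 cognitive covariates +
(1 | subject)`, reference levels paper / phase 1.  Kinematics:
`response ~ Decoding × Session × Phase + (1 | subject) [+ (1 | word)]`,
reference poor / session 1 / phase 1, session categorical (the per-session
contrasts imply it).  Estimates are unstandardised (native units), with SE,
t, CI, and semi-partial R² computed Nakagawa–Schielzeth-style with the
Johnson modification: the drop in fixed-prediction variance when a term's
coefficients are zeroed, over total model variance (fixed + random
intercepts + residual); negative drops are clipped at 0, so every term R²
is bounded by the model R².  AIC = 2k − 2·logL and BIC = k·ln n − 2·logL
with k counting fixed effects, covariance parameters and the residual
scale; model comparisons across fixed structures should use ML fits
(`reml=False`), REML is the default for final estimates, and the choice is
recorded per fit.  RMSE uses conditional residuals where the random-effect
prediction exists, marginal residuals for boundary (singular) fits, which
are flagged rather than dropped.  Two-group descriptive comparisons apply a
Shapiro–Wilk gate at α = 0.05 per group: both normal → two-sample t,
otherwise Wilcoxon rank-sum; all tests two-sided, no multiple-testing
correction (none is applied by design, and reports say so).

The backend is statsmodels `MixedLM` (crossed word intercepts via variance
components on a single supergroup).  Degrees of freedom use a
between-within approximation: terms constant within subjects get
`n_subjects − n_between_terms` df, within-subject terms get residual df.
This is not the Satterthwaite method; on balanced random-intercept designs
the two agree (the test suite cross-checks b, SE and df against
lme4/lmerTest through Rscript), but they can diverge on unbalanced data.
The marginal good−poor contrast averages fixed-effect predictions over a
balanced session × phase grid (emmeans-style), with t-intervals on
`n_subjects − 2` df.

## Synthetic cohorts

The generator is the study-conditions oracle: every pipeline claim is
tested as parameter recovery against it.

- **Fixations**: duration ~ Normal(μ, 80 ms) truncated at 3 samples;
  position jitter is a ±1 px reflected random walk per axis (move
  probability 0.2 per axis), confined to ±2 px so the dispersion rule never
  splits a true fixation.
- **Saccades**: straight lines with a symmetric triangular speed ramp, so
  the mean sample speed equals the profile mean and the peak is twice it;
  the sample count follows from distance / mean speed at 60 Hz.
- **Scanpath**: words visited left to right; first landing per word drawn
  Normal(landing mean for its length class, 0.6 chars) clipped to the word;
  refixations (Poisson, 0.15 per character, both groups) step at least ~1
  character forward; after each forward fixation a regression (backward
  jump to the previous word plus a forward return) is inserted with
  probability q = p/(1 − 2p), which makes the expected regressive fraction
  of saccades equal p.
- **Profiles**: the pooled defaults equal the study conditions — fixation
  duration 400 ms, mean saccade speed 60 mm/s, regressive proportion
  0.25, landing means 1.60 (short) / 3.14 (long) — and the good−poor gaps
  equal the printed contrasts (+13.57 mm/s, −68.6 ms, −0.03).  The
  refixation rate is deliberately equal across groups so the speed
  contrast is identified by speed alone and not confounded by a different
  short/long saccade mix.
- **Drift and heterogeneity**: per-session multiplicative trends mimic the
  published session curves (speeds and lengths rise to session 5 and
  plateau, durations and regressions fall) and average to exactly 1.0
  across the six sessions, so marginal group gaps equal profile gaps.
  Between-subject offsets: speed sd 7 mm/s, duration sd 35 ms, regression
  sd 0.03, landing sd 0.12 chars — chosen as plausible between-child
  variability.  Each subject contributes finger data in one phase
  (crossover), balanced within groups.

What the generator does *not* emulate: biomechanical finger dynamics,
return sweeps over multiple lines, the feedback loop between the unblur
window and movement, oculomotor noise distributions (none are published for
this paradigm — all distributional forms here are this package's
assumptions, labelled in config).  Passing recovery tests therefore shows
the pipeline is correct and well-calibrated *for data of this structure*,
not that the published child data would be reproduced.

### Known measurement biases (by design of the event model)

- The median threshold sits in the low tail of the saccade speed
  distribution, so the slow ends of each ramp are absorbed into the
  flanking fixations: measured mean saccade speeds exceed generative means
  by roughly the half-threshold (~15–20%), an offset nearly equal across
  groups, which leaves the good−poor *contrast* within ~10–15% of truth.
- Measured fixation durations run ~5–7% short (edge-sample attribution at
  60 Hz).
- The pooled regressive proportion runs ~1–2 points above p because
  regression-heavy trials contribute more saccades.
- Landing targets are clipped into the word, so two-letter words cannot
  realise a landing mean of 1.60 characters; the realised short-word mean
  sits ~10% below the nominal value for the default five-word sentence,
  while long-word landings are essentially unbiased.

These are properties of the published measurement rule applied to
continuous traces, not implementation errors; the acceptance suite asserts
recovery within the 10–20% bands with these biases included.

## Problem sizes

Default desk-scale experiments use 2 × 10 subjects × 6 sessions × 5
sentence trials (600 trajectories, ~350 samples each).  The recovery suite
runs 50 seeded replicates; null calibration permutes decoding labels 50
times across 10 cohorts.  These sizes put Monte-Carlo error well inside the
acceptance bands while keeping a full run in minutes on one CPU.
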