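# digitrace

Analysis pipeline for **digit-tracking reading data**: a tablet shows
blurred text that a child unblurs locally by sliding a finger along it, so
the 60 Hz finger trace proxies the gaze path during reading acquisition.
The package is written for researchers who study early reading with this
paradigm: it prepares the crowding-free stimuli, segments finger
trajectories into *digital fixations* and *digital saccades*, computes
word-level reading kinematics (landing positions, refixations, density
maps), scores the reading assessments, and fits the associated linear mixed
models — with a synthetic-cohort generator so the whole chain is testable
without any child data.

## The core method

Finger positions are logged as percent of screen at 60 Hz and converted to
pixels and millimetres.  For each child *i* and session *s*, the event
threshold is the median of all strictly positive sample speeds

```
θ_is = median{ v_t : v_t > 0 },   v_t = ‖Δx_t‖ · pitch / Δt   [mm/s]
```

Maximal streaks with `v < θ` are digital fixations (position = barycenter
of member samples, within-fixation spread < 5.8 px in X and 6.4 px in Y);
faster streaks are digital saccades (length = distance between flanking
fixation barycenters, speed = mean member speed, regressive unless the last
X strictly exceeds the first).  Word-level landing positions are continuous
character units (first letter spans [0, 1)); first-fixation densities use a
Gaussian kernel with bandwidth `0.4 · 0.9·min(sd, IQR/1.34)·n^(−1/5)`,
scaled by group size.  Kinematic responses are analysed with

```
response ~ Decoding × Session × Phase + (1 | subject) [+ (1 | word)]
gain     ~ Modality × Phase + age + cognitive covariates + (1 | subject)
```

reporting unstandardised *b*, SE, *t*, CI, semi-partial R²
(Nakagawa–Schielzeth/Johnson) and AIC/BIC/RMSE.  See `docs/methods.md` for
every convention and default.

## Worked example

Simulate a 2 × 10-subject cohort (6 sessions × 5 sentence trials) whose
good/poor decoder profiles differ by the study's printed contrasts, run the
full pipeline, and recover the group gaps with the mixed model:

```python
from digitrace.pipeline import recovery_experiment

result = recovery_experiment(seed=0)
for key in ("saccade_speed_gap", "fixation_duration_gap",
            "p_regressive_pooled", "landing_short", "landing_long"):
    print(key, round(result[key], 3))
```

prints

```
saccade_speed_gap 14.26
fixation_duration_gap -78.952
p_regressive_pooled 0.267
landing_short 1.386
landing_long 3.088
```

The recovered good−poor saccade-speed gap (14.26 mm/s, generative truth
+13.57) and fixation-duration gap (−79 ms, truth −68.6) come from the
Decoding × Session × Phase mixed model on 600 segmented trials; the pooled
regressive proportion recovers the generative 0.25 and the first-landing
means recover the 1.60 (short words) / 3.14 (long words) conditions, the
short-word mean sitting slightly low because landings are clipped into
two-letter words.

The same stages are scriptable from the shell:

```bash
digitrace simulate --seed 7 --subjects 10 --out data/
digitrace segment --in data/trajectories.csv --out events/
digitrace run --seed 7 --out run/          # full pipeline + manifest
digitrace report --run-dir run/            # session curves, density overlays
```

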