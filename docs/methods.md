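# Methods

## Coordinate and time conventions

Positions are chamber millimetres with the origin at the lower-left
corner (rectangles) or centre (circles) and y increasing upward; camera
pixels (origin top-left, y down) are converted through `px_per_mm` with
an explicit y-flip.  Time is an integer-second 1-Hz grid starting at
introduction.  Analysis bins (5, 30 or 720 min) are aligned to the wall
clock — the light schedule's 08:00 grid — not to session start, because
the day/phase definitions are clock-based; a session starting mid-bin
therefore has a truncated first bin, which is included in the metrics
and averaged over the seconds it actually contains.  The experimental
day increments at the day boundary (default 08:00, lights-on), and the
light phase is the half-open interval [lights-on, lights-off).

## Imputation

When a marker is not identified at a second, the position from when it
was last identified is carried forward with `observed=False`
(last-observation-carried-forward).  Imputation is idempotent, never
alters observed samples, and fails loudly on an unobservable prefix
(no earlier identification to carry).  Downstream choices that follow
from it:

- *Activity* is computed on the imputed positions as-is: zero
  displacement through a gap, one catch-up step at re-identification.
- *Approacher attribution* instead zeroes any lookback displacement step
  that touches an imputed sample, since a carried position is not
  locomotion; with a 3-s lookback the path length uses up to 4 samples
  (3 steps).  An exact tie marks the approacher undefined and records
  the lexicographically smaller id, deterministically.

## Event and huddle definitions

The interaction area is a 60-mm-radius circle.  An approach onset is a
genuine downward crossing (`d(t) < 60 ≤ d(t−1)`); exactly 60 mm counts
as outside, which makes onsets and ends complementary and the below-
radius seconds an exact disjoint union of `[onset, end)` episodes —
except for a pair already inside the radius at the first sample, which
never *became* close and yields no event (it still huddles).  Episodes
cut off by session end are flagged truncated.  Huddling is a strict
`mean < 60 mm` over a clock-aligned 30-min bin; latency uses the
end-of-bin convention (bin k → 0.5·(k+1) h) because binned data cannot
resolve onset within the bin, and never-huddling pairs return a censored
latency carrying the observed span.  Huddle order uses dense ranks of
the first-huddle bin (ties share the earlier category; never-huddling
pairs rank after all huddling pairs).  Interaction durations are
partitioned as <2 s, 2–3 s, >3 s; with an integer grid these are
{1}, {2,3}, {≥4} seconds.

## Identification layer

Matching uses zero-normalised cross-correlation (robust to brightness
offsets), the canonical statistic for template matching, evaluated at
0/90/180/270° rotations with the maximum taken, acceptance threshold
0.7.  There is deliberately no motion model: identification is
memoryless per frame, so re-identification after occlusion is immediate
by construction and imputation is the only temporal fill.  When two
templates peak within half a template width of each other, assignment is
greedy by descending score (lexicographic id on ties) and the loser
re-searches with the claimed zone suppressed.  Synthetic glyphs are
random 2-px block patterns whose pairwise ZNCC stays below 0.55 over
*all* relative shifts and rotations, including partial overlaps against
the dark background — without the shift condition an absent glyph can
spuriously match a fragment of a present one above threshold.

## Split-plot ANOVA and permutation scheme

The inferential layer implements the classical univariate decomposition
for one between-subject factor (group) crossed with up to two
within-subject factors (day, light/dark phase): the between effect is
tested against subjects-within-groups; each within effect and its group
interaction against the corresponding subject × factor error.  No
sphericity correction is applied — the permutation route does not need
the assumption.  Permutation tests exchange whole subjects between group
labels (each subject's within-cell vector moves intact), the only
exchangeability unit valid for between-group effects in repeated
measures; the statistic is the F of the named effect and
`p = (1 + #{F_perm ≥ F_obs}) / (1 + n_iter)` with 5000 iterations by
default, so p is never exactly zero and its floor is `1/(n_iter+1)`.
Note the floor is only attained when no random shuffle recreates the
observed split: with 6 subjects per group a 5000-draw run re-draws the
identity split ~11 times in expectation, giving p ≈ 0.002 rather than
0.0002 even for arbitrarily separated groups.  Simple effects re-test
the group factor inside each level of the sliced factor using
slice-specific error terms (robust to heteroscedasticity across phases),
Holm-corrected across slices.  Degenerate inputs: constant data reports
F = 0 (p = 1); a non-zero effect over a zero error term reports F = ∞.

## Colony simulator

The generator is an agent-based model of 4–8 co-housed mice on the 1-Hz
grid in a 240 × 240 mm chamber with reflecting walls, built to emulate
the statistical structure the analyses assume: circadian rest/active
alternation, social attraction producing pairwise huddles, rearing-
phenotype contrasts, and anaesthetised (immobile) agents.  Per second,
each agent:

1. switches rest↔active through a Markov chain whose activation rate is
   scaled by `(1 + amplitude)` in the dark and `(1 − amplitude)` in the
   light (mice are nocturnal);
2. if active, steps with truncated-normal speed and a heading drawn as a
   von Mises perturbation of a direction interpolated between its
   previous heading and the bearing of its *nearest cagemate*, with
   interpolation weight equal to its current sociability (nearest
   cagemate, not group centroid, so pairwise huddles form first, as the
   pair-based analysis expects);
3. if resting beside a *stationary* nearest cagemate (resting or
   anaesthetised) within the 60-mm attraction radius, keeps resting with
   its activation probability multiplied by `rest_stickiness` (default
   0.15).

The stickiness term is the model's rendering of the observed mechanism
that a low-reactive partner promotes proximity: it lets huddles persist
once formed, and it is why immobile cagemates shorten the huddle latency
of otherwise asocial agents.  Its value, like all phenotype parameters,
is a calibration choice, not a measured quantity.

Phenotype defaults (frozen after calibrating once against the
qualitative phenomenology the generator must emulate — socially-reared
pairs huddling within a few hours, isolation-reared pairs delayed by
roughly a day, isolation-reared mice hyperactive, dark phase more
active):

| parameter | GH | SI | immobile |
|---|---|---|---|
| bout speed (mm/s) | 40 | 60 | — |
| p(rest→active) /s | 0.02 | 0.06 | — |
| p(active→rest) /s | 0.06 | 0.03 | — |
| circadian amplitude | 0.6 | 0.6 | — |
| sociability₀ | 0.2 | 0.0 | 0 |
| sociability ramp /h | 0 | 0.015 | 0 |

The SI ramp encodes gradual familiarisation: SI sociability reaches GH
level after ~13 h and saturates at 1 by ~67 h.  All random draws
(switch uniforms, von Mises heading noise, speeds, initial state) are
pre-generated from one numpy `Generator`, so a seed fixes the session
bit-for-bit; the sequential update loop itself is deterministic and
JIT-compiled with numba.

What the simulator does *not* emulate: body shape and contact mechanics
(huddling is proximity, not touch), thigmotaxis, olfactory/ultrasonic
communication, aggression, and any learning beyond the sociability ramp.
Passing tests therefore show that the pipeline measures what it claims
on trajectories with the assumed statistical structure — not that real
mice behave like the model.

## Problem sizes and numerical choices

Tests and the acceptance script run the designs at reduced scale chosen
by us as faithful analogues: oracle equivalence on one hundred 2-h
sessions; identification fidelity on a 600-frame 4-agent stack (clean
and with an exactly-20% occlusion schedule); permutation calibration on
500 null datasets of 6+6 subjects in a 2×2 within design at 1000
iterations (the rejection-rate estimate is insensitive to the iteration
count; single tests use the 5000 default); phenotype orderings over 20
seeded replicates of 24–60 h sessions.  The acceptance script uses the
study's chamber counts (3+3 homogeneous, 7 mixed, 4 model) at the full
preset durations.  Floating-point guards: F statistics treat effect sums
of squares below `1e-12 × SS_total` as zero; the circular-wall bounce
pulls agents a relative 1e-12 inside the radius so positions never
leave the chamber even after roundoff; in-chamber validation of input
tables allows 5 mm slack for marker centres overhanging walls.

## Known limitations

- The 1-Hz grid cannot resolve sub-second interactions; duration classes
  below 2 s contain only the 1-s bin.
- The identification layer assumes rigid, axis-aligned-or-90°-rotated
  glyphs; real tags tilt continuously and blur.
- Unequal group sizes are accepted by the ANOVA layer using weighted
  (size-proportional) means; with severe imbalance a dedicated
  general-linear-model route would be preferable.
- The real-data reproduction path only needs a per-second position table
  per mouse, but the deposited archive must be fetched manually; no
  downloader is included.
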