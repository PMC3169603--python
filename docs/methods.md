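# Methods

`perffields` simulates and analyzes *visual performance fields*: the reliable
inhomogeneity of discrimination accuracy across isoeccentric locations of the
visual field, consisting of a horizontal-vertical anisotropy (HVA: horizontal
meridian better than vertical) and a vertical-meridian asymmetry (VMA: the
location directly below fixation better than directly above). The scientific
question the pipeline addresses is which spatial reference frame anchors this
shape when egocentric and allocentric coordinates are dissociated — by rolling
the head about the line of sight, or by displacing the fixation dot away from
the head/screen center.

## Coordinate conventions

Angles use the mathematical convention (0° = East/right, counterclockwise
positive); distances are degrees of visual angle (dva). The tilted head
posture is defined *operationally* as the roll that carries retinal East onto
screen North-East (+45° CCW in this convention), because that is the
relationship the shifted meridians require; verbal sign conventions for head
tilt are notoriously ambiguous, so the package pins the geometry rather than
the label. Ocular counter-roll is ignored: the retinal frame is taken to roll
rigidly with the head about the line of sight.

The displacement table for fixation shifts is computed from first principles:
targets on a 6 dva ring, fixation displaced 4 dva toward a cardinal direction,
Euclidean distance from the displaced dot to each target, rounded half-up to
two decimals. Every row is a permutation of
{2, 4.25, 4.25, 7.21, 7.21, 9.27, 9.27, 10}.

## Generative observer model

No raw behavioral data are consumed; the synthetic-observer module is a
first-class, tested component that supplies trial-level data at the full
experimental design sizes. A synthetic observer performs a two-alternative (CW/CCW) tilt
discrimination; its probability correct is

```
p(c) = γ + (1 − γ − λ) · (1 − exp(−(c · s / α₀)^β))
s     = m(θ) · E(e) · (1 − δ_obl · [distractors oblique])
m(θ)  = 1 − h·|sin θ| − v·max(sin θ, 0)
E(e)  = (1 + e₀/e₂) / (1 + e/e₂),   e₀ = 6 dva
```

with (θ, e) the target's polar coordinates *in the observer's anchoring
frame*: retinotopic (fixation-relative, axes rolled with the head),
head-centric (head/screen-centered, axes rolled), or allocentric
(screen-centered, gravity-aligned axes). The separable form is the most
parsimonious generator reproducing the qualitative features the analysis must
be sensitive to: an HVA of amplitude `h`, an upper-vertical penalty `v`
(applied as a penalty rather than a lower-field bonus so that the horizontal
meridian is the reference), intermediate intercardinal accuracy, a hyperbolic
eccentricity decline in the manner of cortical magnification (normalized to 1
at the 6 dva ring), and a multiplicative oblique-effect decrement when the
distractor array is tilted away from a cardinal axis. Richer angular models
(e.g. cosine harmonics) would add parameters without changing what the tests
can detect.

Defaults: `γ = 0.5`, `λ = 0.01`, `h = 0.2`, `v = 0.07` (the VMA is
consistently the weaker of the two asymmetries in human observers, so it is
set well below `h`), `e₂ = 8` dva, `α₀ = 0.1`, `β = 3`,
`δ_obl = 0.05`. Cohorts of synthetic observers jitter `h`, `v` and `α₀`
(seeded) to emulate the minor between-observer fluctuations of field shape.

Gaze deviations are a bolt-on noise channel whose only purpose is to exercise
the 1 dva exclusion filter: a half-normal with scale 0.3 dva truncated at
2 dva in the pipeline (expected exclusion ≈ 0.1% per condition, well below the
1% ceiling the protocol reports), and truncated at 0.3 dva in the single-trial
API default (never excluded).

## Adaptive thresholding

Contrast is set per condition by a grid QUEST staircase: a discrete posterior
over 201 candidate log10 thresholds spanning the Gaussian prior mean ± 3 SD,
updated by the Weibull likelihood of each outcome, with the next trial placed
at the criterion point (75% correct) of the posterior-mode threshold. The MAP
estimator and mode-placement rule were chosen for transparency and testability
over the original parabolic approximation; ties on the grid break toward the
lower contrast. One track is run per condition. Over 100 simulated 200-trial
runs the median absolute threshold error is ≈ 0.02 log10 units.

## Statistical layer

Accuracies are transformed by `2·arcsin(√p)` before inference, stabilizing
variance near the 1.0 ceiling. The head-tilt analysis is a fully crossed
2 (posture) × 2 (distractor orientation) × 8 (location) within-subject ANOVA
with each effect tested against its own effect-by-subject interaction (no
sphericity correction; noted in the report
metadata), plus paired meridian contrasts whose location sets rotate with the
analysis frame (under the tilted frame, horizontal = {NE, SW}, vertical =
{NW, SE}). Contrasts pool the two distractor orientations, giving 8 paired
units (4 observers × 2 distractor conditions, hence df = 7); treating those
units as independent is a deliberate convention of this analysis style, not a
claim about their true dependence. Tests are two-sided; no multiple-testing
correction is applied.
On uniform-field observers (h = v = 0) the horizontal-vertical contrast
rejects at 5% ± 2% over 1,000 replicates.

## Bootstrap model comparison

Each fixation-shift cell (4 shifts × 8 locations) is mapped to a baseline
cell under two models: retinotopic (ring = the displacement-table
eccentricity; direction = the retinal direction snapped to the nearest
canonical angle, ties breaking counterclockwise) and head-centric (the
unchanged location on the 6 dva ring). The snap rule is configurable
(`nearest` vs `label`, which keeps the screen label) because the angular
assignment of shifted cells to baseline directions is underdetermined by
retinal distance alone; `nearest` is the default since a retinotopic model
should match by retinal direction.

Per observer and cell, the bootstrap draws k = 10 outcomes with replacement
per iteration (read as standard i.i.d. resampling) and records the transformed
mean, for n_iter = 10,000 iterations by default; per-cell substreams derive
deterministically from one master seed and the cell's canonical sorted
position, so row order cannot change results. Observer-level summaries (mean
over iterates) feed a paired t over all observer × cell points (df = n·32 − 1;
with four observers, df = 127) and an OLS
regression of observed on predicted summaries. The winner is the model with
the higher R²; a flag records whether the winner's paired difference is
non-significant at 0.05.

**Known limitation.** The 128 paired points are not independent: each baseline
cell serves several shift cells (all of them, for the head-centric model), so
the df = 127 paired test is anticonservative and can flag a "significant"
difference for a correctly specified model more than 5% of the time. The
pairing is retained because it is the convention this analysis follows; the R²
comparison, which drives the decision, is unaffected and recovers the
generating frame in ≥ 19/20 seeded replicates for both ground truths at the
default effect sizes.

## Problem sizes and determinism

Designs reproduce the protocol exactly: head-tilt sessions of 8 blocks × 112
trials (14 per location per block, split 7/7 over distractor orientations;
the 8-block count is inferred from 14 × 8 = 112 per location), fixation-shift
sessions of 4 × 400 trials (50 per shift × location cell), and six baseline
rings of 400 trials each (2,400 total, ring order counterbalanced across
observers by Latin-square rotation). Target tilt direction is balanced 50/50
per cell with odd residuals assigned randomly.

The test suite and the acceptance script run scaled-down replication studies
chosen as the smallest sizes at which the recovery properties are stable:
frame recovery uses 4 observers and 1,000 bootstrap iterations per replicate
(20 seeded replicates per ground-truth frame in the tests, 10 in the script);
Monte-Carlo dispersion is checked at n_iter ∈ {100, 400, 1600} against the
expected −1/2 log-log slope. Everything is reproducible from a single integer
seed; reports are byte-identical across reruns apart from the manifest
timestamp.

## What passing tests do and do not show

The synthetic generator reproduces the *structure* of real performance-field
data — binomial trial outcomes, field shape anchored to a configurable frame,
eccentricity decline, psychometric contrast dependence, rare fixation
breaks — but not its nuisance structure: no sequential dependencies, learning
or fatigue, no lapses correlated across trials, no anisotropic gaze noise,
and inter-observer variability limited to three jittered parameters. Passing
recovery tests therefore shows that the analysis correctly identifies the
anchoring frame *given* data of the stated design and effect sizes, not that
real observers satisfy the generative assumptions. Published human-data
inferential statistics are reproduced structurally (same transforms, factors,
df), never numerically.
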