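# Methods

## The coupling model

Two sensory estimates of related spatial directions — the proprioceptively
felt hand direction P and the visually seen cursor direction V — are each
pulled toward the other by a proportional bias `b ∈ [0, 1]`:

    P' = (1 − b_P)·P + b_P·V,    V' = (1 − b_V)·V + b_V·P.

Assuming independent, zero-mean noises, the variance of a biased estimate
relative to its unbiased own-modality variance is

    var(P')/var(P) = (1 − b)² + b²·r,    r = var(V)/var(P),

strictly convex in `b` with minimum `r/(1+r)` at `b* = 1/(1+r)` —
inverse-variance weighting recovered as the optimal degree of partial
coupling. The same function serves both modalities: for the visual estimate
use `r = var(P)/var(V)`. The relative variance is below 1 for every
`0 < b < 2/(1+r)`, so even a weak coupling reduces the variability of the
*more* precise modality. `relative_variance` additionally accepts a noise
correlation `rho` (default 0, the independence assumption); the correlated
case adds `2·rho·b·(1−b)·√r`. The independence assumption is a modelling
choice: it reproduces the canonical family of variance-reduction curves
(ratios 0.2–0.7, minimum at intermediate bias) and is flagged rather than
derived, since correlated or non-Gaussian generalisations change `b*`.

## Geometry and the implicit measure

Directions are degrees, 0° = straight ahead from the central target T1 (the
+y axis of the digitizer plane), counter-clockwise positive, wrapped to
(−180, 180]. The zero axis is a free choice — every analysed quantity is a
difference of directions — but one convention is fixed package-wide to avoid
sign drift; degrees are used everywhere outside trigonometric kernels.

The implicit angular deviation α′ is computed from three points: T1, the end
of the outward second stroke (`end2`, on the 15-cm stopper ring) and the end
of the unseen return stroke (`end3`). The return line is shifted in parallel
until its endpoint lies on T1; the angle from the outward line (T1→end2) to
the shifted return line equals the angle from the direction of `end2 − t1`
to the direction of `end2 − end3`, which is how it is computed. If the felt
hand position is the actual one rotated by α about T1, a return stroke aimed
from the felt position at T1 yields exactly α′ = α for any return-stroke
length; the simulator constructs `end3` by this recipe, so the generator and
the measure are exact inverses (round-trip tested to 1e−9 degrees, and
recovery is invariant to return-length noise). Zero-length strokes make the
angle undefined; such trials are excluded with a logged warning, never
imputed.

## The synthetic session generator

One session is 144 trials: 12 feedback rotations (±5…±30° in 5° steps) × 2
explicit judgment types (hand, cursor) × 6 repetitions, in a seeded uniform
random order. Per trial, with rotation R:

* target direction ~ U(−60°, +60°);
* actual hand direction = target − R + N(0, motor_sd²) — the participant
  steers the rotated cursor to the remembered target; cursor = hand + R;
* explicit judged deviation = slope_eff·R + intercept + N(0, sd²), with
  slope/intercept/sd specific to the requested judgment type; the judged
  direction is the actual (hand or cursor) direction plus this deviation;
* implicit deviation α = slope_implicit,eff·R + N(0, sd_implicit²),
  materialised only through the stroke endpoints (α is generated on every
  trial, since the return stroke precedes the judgment instruction);
* with probability `outlier_rate` the explicit judgment is shifted by
  ±`outlier_shift`.

Sequential modulation: after a trial whose explicit judgment was of the same
type, the effective explicit slope magnitude grows by
`seq_delta_explicit_same`; after an explicit *hand* judgment the implicit
slope changes by `seq_delta_implicit_after_hand` (negative = weakened); both
deltas are multiplied by `repetition_multiplier` when the preceding type had
just run ≥ 2 trials.

Cohort seeding is counter-based (`numpy` `SeedSequence` spawn keys), so each
participant's stream is independent of simulation order and the whole cohort
is reproducible from one master seed.

### Default parameter choices

| parameter | young / older | basis |
|---|---|---|
| slope hand-explicit | 0.63 / 0.75 deg/deg | reported group means |
| slope cursor-explicit | −0.08 / −0.07 | reported group means |
| slope hand-implicit | 0.31 / 0.30 | reported group means |
| intercept hand-explicit | +3° | "a few degrees" CCW offset; others 0 |
| sd hand-explicit / cursor-explicit / implicit | 12 / 5 / 5° | assumption: reproduces the reported variability ordering (hand-explicit ≫ the other two); exact values are not published |
| motor aiming noise | 4° | assumption, typical aiming variable error |
| return-length noise | 5% (CV) | assumption; α′ is invariant to it |
| outlier rate / shift | 0.005 / 40° | matches the observed ~0.3–0.5% removal rates |
| sequential deltas / repetition multiplier | 0.02, −0.02 / 1.5 | assumption: direction from the observed pattern, magnitudes unpublished |
| cohort sizes | 16 young + 19 older | the retained sample |

SDs, deltas and the multiplier are declared assumptions, overridable via
YAML presets. The one-sided sequential increments mean recovered mean slopes
sit ~0.01 deg/deg above (explicit) or below (implicit) the nominal preset
values; this is inside the recovery tolerances used throughout.

What the generator does *not* emulate: kinematics (speed profiles, reaction
times, the ~5.7-s explicit-judgment delay and any memory decay over it),
between-participant variation in the true slopes, target-memory error, and
any drift over the session. Passing recovery tests therefore shows the
estimation pipeline is unbiased and correctly calibrated for data satisfying
the linear measurement model — not that real behaviour satisfies it.

## Estimation and screening

Per participant and judgment kind, angular deviation is regressed on
rotation by OLS; the slope is the proportional bias, the intercept the
offset. Implicit estimates pool trials across both explicit judgment types;
explicit estimates use only trials of the matching requested type.

Trial screening removes trials with |residual| > 3·SD(residuals) in a single
pass and refits (the iterate-to-fixed-point language applies to the
participant level). Residual SD is per participant (ddof = 2), since the
regressions are per participant. Under normality the rule removes ≈ 0.27% of
clean trials. Participant screening pools the bias parameters of both age
groups per judgment kind and iteratively excludes values outside mean ± 3 SD
until none remain; a participant excluded for any kind is excluded from all
analyses. With zero residual SD (degenerate data) nothing is removed.

## Inference

One-sample t-tests (two-sided) of slopes and intercepts against zero;
Pearson correlations between implicit and explicit biases per group;
Bonferroni-corrected pairwise t-tests. The mixed-design ANOVA handles one
between-participant factor (age group) crossed with any number of
within-participant factors, via the classical balanced sums-of-squares
decomposition (margins combined by inclusion–exclusion): the group effect is
tested against subjects-within-groups, and each within-effect combination V
(and V × group) against V × subjects-within-groups. Uncorrected univariate
F's are reported by default, matching common practice for these designs; a
Greenhouse–Geisser option (`correction="gg"`) shrinks the df's of effects
with more than one numerator df. With a single group the design degenerates
to repeated measures (the between test is skipped, and a 2-level within
factor reproduces F = t² of the paired t-test exactly). Cross-checked
against pingouin's mixed ANOVA for the one-within-factor case.

For the sequential strength ANOVA, explicit-cursor slopes (negative) are
sign-flipped so larger values mean stronger bias in every cell; raw outputs
are never flipped.

## Sequential classification

Trial t ≥ 2 is classified by (1) the explicit judgment type of trial t−1 and
(2) whether that type was a repetition: the run of same-type judgments
ending at t−1 has length ≥ 2 ("repeated") or 1 ("once"). The threshold is
configurable (`repeat_threshold`, default 2; the published axis labels imply
a binary split, not a graded count). The first trial is unclassifiable.
Breaks are not treated specially — history carries across them (a config
switch at the classification call would be the extension point). In a
balanced random schedule the two repetition categories are approximately
equally frequent, and preceding-run lengths of exactly k decay as 2^−k.
Subsets with fewer than 3 distinct rotations are dropped from subset
regressions with a log entry.

## Numerical and scale choices

Angles wrap to (−180, 180] via a modulo identity exact at the boundary.
ANOVA sums of squares are clamped at zero against floating-point
cancellation; a zero effect SS yields F = 0 even when the error stratum is
empty. The type-I-error calibration test uses 2000 replicates of an
8-participant-per-group cohort (calibration is size-independent) and a
0.05 ± 3·binomial-SE acceptance band; Monte-Carlo oracles for the variance
curves use 10⁶ draws with 3-SE bands; geometric round-trip checks use 10⁴
random constructions.

## Known limitations

* The ANOVA requires complete balanced designs; missing cells raise rather
  than fall back to a multilevel model.
* Variance heterogeneity between judgment kinds is part of the generative
  model but the ANOVA assumes homogeneous error strata, as the classical
  univariate analysis does.
* The generator's Gaussian, independent-trial noise cannot produce the
  heavy-tailed or drifting errors real sessions may contain; the outlier
  mechanism is a two-component mixture, not a realistic lapse model.
* Wrapping is safe because generated deviations are far from ±180°; data
  near the boundary would need circular statistics throughout.
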