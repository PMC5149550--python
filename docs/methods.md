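# Methods

This note documents the models, parameter choices and numerical
conventions behind `fiblab`, in the spirit of a statistical software
methods appendix. It states no empirical result that the test suite or
`scripts/acceptance.py` does not itself compute.

## 1. Movement quantification

**Model.** Movement is measured by frame differencing: per consecutive
frame pair, the absolute gray-level change of every pixel; changes
smaller than a fixed threshold `tau` are zeroed; the thresholded grids
are averaged per pixel over the clip into a heat map. The clip's total
movement is the mean of the heat map; region scores are means over
horizontal bands spanning the full frame width.

**Choices and rationale.**

- *Threshold before averaging.* The threshold exists to suppress
  per-frame sensor/illumination flicker, which only works if it is
  applied to each difference grid before they are averaged. A
  `threshold_after_averaging` flag provides the alternative reading for
  comparison.
- *Boundary semantics.* "Smaller than the threshold" is read strictly:
  a change equal to `tau` (default 25) is retained.
- *Grayscale.* RGB input is converted with ITU-R BT.601 luma weights
  (0.299, 0.587, 0.114), rounded and clamped; the conversion used for
  the original recordings is not documented anywhere, and BT.601 is the
  standard-definition convention of that equipment era.
- *Central crop.* `crop_central` keeps all rows and a horizontally
  centered column band (default 801 of 1920); an odd remainder drops the
  extra column on the right. Frames already narrower than the target
  are passed through by the pipeline.
- *Region bands* are 0-based, half-open row intervals, so the
  pixel-count-weighted mean of region scores equals the total exactly
  (a tested invariant). Boundaries are supplied per study (config/CSV);
  in practice they are set per clip by an analyst.
- *Arithmetic.* Differencing is done in int16 (no unsigned wrap),
  averaging in float64 (no overflow for any realistic clip length).

## 2. Statistical procedures

All tests are two-sided. The procedures are implemented from first
principles; only the reference distributions (t, F, normal) come from
scipy. The test suite validates each against an independent oracle
(hand-computed sums of squares, full 2^n enumeration, the classical
Spearman closed form) and against scipy/pingouin where those offer the
same computation.

- *One-sample t*: `t = (mean − μ₀)/(s/√n)`, df = n − 1; Cohen's d as
  effect size.
- *Repeated-measures ANOVA* (one-way, within-subject):
  `F = MS_cond / MS_(cond×subject)`, df = (k − 1, (k − 1)(n − 1)); no
  sphericity correction (matching the uncorrected integer dfs that
  perception studies conventionally report). The error SS is computed
  directly from interaction residuals rather than by subtraction, which
  keeps identical-column tables at exactly F = 0.
- *Bonferroni post hocs*: paired t per condition pair, p multiplied by
  k(k − 1)/2 and clamped to 1. A zero-variance pair yields a flagged
  placeholder result so the remaining comparisons survive.
- *Spearman*: Pearson correlation of mid-ranks; p from
  `t = rs√((n−2)/(1−rs²))` on n − 2 df, p = 0 at |rs| = 1; exact
  permutation p available for n ≤ 8. The study-scale use (n = 90 clips)
  is firmly in the approximation regime.
- *Wilcoxon signed-rank*: zero differences excluded (Wilcoxon's
  original treatment, consistent with SPSS-era reporting), mid-ranks
  for tied |differences|, statistic W = min(W⁺, W⁻). For n ≤ 25
  non-zero pairs the two-sided p is exact: the null distribution of W⁺
  over all 2ⁿ sign assignments is built by dynamic programming over
  doubled ranks (handles half-integer mid-ranks exactly), and
  p = min(1, 2·P(W⁺ ≤ W)). Beyond n = 25 a normal approximation with
  tie correction and 0.5 continuity correction is used and the signed Z
  is reported. Effect size r = |Z|/√n in both regimes. The exact branch
  is verified against brute enumeration for every n ≤ 12.
- *Head-vs-rest contrast*: per judge, head duration minus the mean of
  the other regions; paired t against zero squared into F with
  df = (1, n − 1). An identically zero contrast reports F = 0 rather
  than a degeneracy error; a non-zero constant contrast is degenerate.

Degenerate inputs (zero variance, all-tied pairs, constant rank inputs)
raise a dedicated `DegenerateSampleError` so callers can distinguish
"no information" from misuse.

## 3. Perception scoring

- Percent-lie per clip is the percentage of judges answering "lie";
  judge-level condition scores are the per-judge mean binary response
  (the unit of analysis for chance tests and the ANOVA, giving df 19
  for 20 judges).
- Cue-region frequencies use as denominator *all responses where the
  judge answered "lie"* — correct detections and false alarms alike —
  because the questionnaire's cue question is conditional on a "lie"
  answer, not on ground truth. Multi-select flags may sum above 100%.
- The movement–perception association pools all clips across conditions
  (n = children × 3) and is reported for the total score and per
  region.
- Incomplete data (a judge missing a condition, a child missing a
  clip, cue flags on "truth" answers) are excluded with logged warnings
  rather than imputed, matching a complete-case design.

## 4. Gaze analysis

- AOIs are axis-aligned, half-open rectangles in 0-based screen
  coordinates (x rightward, y downward): four stacked body areas plus a
  lower-left "noise" area that absorbs stray fixations and is excluded
  from all statistics.
- Manual near-miss correction is operationalized as deterministic
  reassignment: a fixation outside every body AOI but within
  `tolerance` (default 15 px, configurable — the tolerance a human
  corrector applies is unknowable) of the nearest one is assigned to
  it; ties break by nearest AOI center, then by the fixed order
  head > trunk > legs > feet. Tolerance 0 reduces to containment, and
  assignment counts are monotone in tolerance (tested invariants).
- Durations are summed per judge × condition × region over a completed
  grid (missing combinations are true zeros). The summary table
  reports across-judge means and SDs of these per-judge totals; whether
  a published "average gaze duration" is a total or a per-clip mean is
  often ambiguous, so the per-judge total is documented here as the
  package's convention.
- Fixation heat maps place duration-weighted unit-mass Gaussian kernels
  at fixation positions (so the un-normalized image mass equals total
  fixation time, a tested property) and are min-max normalized for
  display. Focus maps mask pixels below an order-statistic quantile of
  the heat image, so the q → 0 limit masks nothing and q → 1 keeps
  essentially only the peak.
- Fixation *detection* (dispersion/velocity algorithms on raw gaze) is
  out of scope; the module consumes fixation events as exported by
  eye-tracking software.

## 5. Synthetic-study generator

The generator's role is to produce studies with the statistical
structure the analyses assume, at desk scale, not photorealism.

- *Figure and frame.* An 80 × 108 px frame — a scale model of the
  801 × 1080 central crop of an HD recording — showing a dark schematic
  figure (gray 60) on a light wall (gray 230): head disc, trunk
  rectangle, two leg bars, two foot bars, with region boundary rows at
  30/65/95. Optional Gaussian sensor noise is available
  (`noise_sigma`, default 0 so zero-jitter clips are exactly static).
- *Jitter model.* Per frame, each body region is displaced
  independently by uniform jitter in ±amplitude (rounded to whole
  pixels) around its rest position — the simplest model giving
  region-controllable frame-to-frame pixel change. Displacements that
  would push a part off-frame are clamped.
- *Condition profiles.* Truth and the first lie attempt share identical
  amplitudes (head 2.0, trunk 1.2, legs 0.8, feet 0.8 px); the second
  attempt roughly doubles them (3.5/2.1/1.4/1.5). This encodes the
  "ironic effect": only the second, more self-conscious lie shows a
  movement signature, so paired condition tests find Tc-vs-Ly2 but not
  Tc-vs-Ly1. Per-condition movement magnitudes of real recordings are
  not published anywhere, so these amplitudes are chosen once for
  realistic test power, not fidelity to any dataset.
- *Between-child spread.* Each child gets an expressiveness factor
  uniform in 1 ± 0.3 multiplying all amplitudes, mimicking idiosyncratic
  differences between children while preserving within-child contrasts.
- *Judge model.* Each judge × clip response is Bernoulli with
  `p = logistic(intercept + slope·movement + condition offset)`.
  The movement term (slope 0.20 per score unit, intercept −1.40
  centered on the typical score) encodes "more movement looks more
  deceptive". The per-condition offsets (Tc −0.30, Ly1 +0.68,
  Ly2 −0.05) encode cues judges use that the movement score does not
  carry (facial behavior, hesitation). They are needed because judges
  empirically separate the first lie attempt from truth even when the
  two are indistinguishable at the movement level; a purely
  movement-driven judge cannot produce that dissociation. With slope
  and offsets zero (`JudgeModel.null()`) the response rate is exactly
  0.5 everywhere, the configuration used for type-I calibration.
  Defaults give condition means near 0.36/0.60/0.60 and a pooled
  movement–perception Spearman correlation around 0.45. Cue flags on
  "lie" answers are independent Bernoulli draws (face 0.76, feet 0.33,
  legs 0.30, shoulders 0.17, other 0.13).
- *Gaze model.* Fixation regions are multinomial (head 0.75,
  trunk 0.15, legs 0.06, feet 0.03, noise 0.01 — strong head
  dominance), positions uniform within the AOI, durations gamma
  (shape 2, scale 0.15 s; mean 0.3 s, a typical fixation length),
  20 fixations per clip. No duration law for real judges is published,
  so the gamma family was chosen for strictly positive, right-skewed
  durations.
- *Determinism.* Every generator is a pure function of its parameters
  and seed; per-clip, ratings and per-judge fixation seeds are derived
  from one master generator.

**What the generator does not emulate** — and hence what passing tests
do not establish about real data: photorealistic appearance, facial
expression and micro-expressions, camera shake, occlusion, autocorrelated
or strategic judge behavior, judge individual differences, saccade
dynamics, calibration error. Results on synthetic studies demonstrate
that the pipeline recovers the structure it was built to detect, not
that children behave like the model.

## 6. Problem sizes in the test suite

Unit tests run on compact studies (typically 6–10 children, 8–20-frame
clips). The end-to-end acceptance checks use the full default design —
30 children, 50-frame clips, 20 judges — with 500 rating replicates for
type-I calibration and 100 fully regenerated studies for pattern
recovery; these sizes give binomial bands tight enough to detect a
miscalibrated test while keeping the whole suite in the low minutes on
one CPU.

## 7. Known limitations

- The movement measure confounds motion with figure/background contrast;
  it is a pixel-change energy, not kinematics. No optical flow, person
  tracking or shake compensation is attempted.
- Region scores depend on manually supplied horizontal boundaries and
  assume the subject stays within its bands.
- The exact Wilcoxon p is defined as 2·P(W⁺ ≤ W) (clamped); other
  software may report the doubled smaller tail with slightly different
  tie conventions.
- Video container input relies on whatever imageio plugins are present;
  PNG frame directories are the first-class, dependency-free medium.
- The AOI tolerance reassignment is a reproducible surrogate for human
  judgment, not a model of it.
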