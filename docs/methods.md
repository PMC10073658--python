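# Methods

## The measurement problem

Group-housed mice climb on the wire lid of their home cage; the time they
spend doing so is a non-evoked motor readout with strong circadian
structure. The package turns side-view grayscale video (25 frames/s, 40 ms
per frame) into per-frame climbing labels, aggregates them on the
zeitgeber clock, and tests group differences with repeated-measures mixed
models. Every stage is specified below together with its defaults and the
choices that were genuinely open.

## Local trinary pattern descriptor (`ltp`)

For frame *t*, pixel *p*, and the 8 neighbor offsets at `neighbor_radius`
(clockwise from top-left; bit *i* of the code byte is offset *i*), the
descriptor compares patch SSDs toward the past and the future frame:

* `d⁻ᵢ` = SSD between the `(2·patch_half+1)²` patch at *p* in frame *t*
  and the patch at *p + nᵢ* in frame *t − Δ*; `d⁺ᵢ` likewise against
  *t + Δ*;
* trit +1 if `d⁻ᵢ − d⁺ᵢ > τ`, −1 if `d⁺ᵢ − d⁻ᵢ > τ`, else 0;
* the +1 trits form byte `B⁺`, the −1 trits byte `B⁻` (disjoint bits).

The ROI is tiled by a `grid_cols × grid_rows` cell grid (remainder pixels
join the last row/column); each cell contributes a 256-bin histogram of
`B⁺` then one of `B⁻`, L1-normalized per histogram by default. The feature
length is `grid_cols · grid_rows · 512` and therefore depends only on the
grid: the default 8 × 4 grid gives 16,384 dimensions on the full-size
690 × 385 lid region and on the reduced synthetic ROI alike.

Defaults: `patch_half = 1` (3 × 3 patches), `neighbor_radius = 2`,
`Δ = 2` frames, `τ = 0`, grid 8 × 4, L1 normalization. Patch size, radius,
gap and τ follow common usage of this descriptor family and are all
configurable; the 8 × 4 grid is the configuration that yields the
16,384-dimensional vector on the printed ROI.

Numerical choices: all SSDs are computed in exact integer arithmetic
(cumulative-sum box filters on int64), so SSD ties produce a 0 trit
deterministically — a float box filter can flip strict inequalities on
ties. Pixels within `patch_half + neighbor_radius` of the ROI border are
not coded and enter no histogram. Boundary frames (the first and last Δ)
replicate the nearest interior descriptor so that every frame receives a
label; degenerate static video yields the indicator of histogram bin 0 in
every cell.

## Frame classification and temporal voting (`classify`)

Raw decision: climbing iff `w·x + b > 0`; an exactly zero margin counts as
non-climbing (conservative detection). Training minimizes L2-regularized
hinge loss at strength C; the optimisation is delegated to liblinear
(scikit-learn `LinearSVC`, `random_state` fixed), the contract being only
the returned linear decision function. Class weighting is off by default.

Temporal voting: the final label of frame *t* is 1 iff the raw positives
in the truncated window `[max(0, t−k), min(n−1, t+k)]` strictly exceed
`θ ×` window size. `θ = 0.5` (strict majority) and truncation without
padding are the defaults; `k = 0` is the identity. The vote removes
isolated single-frame detections and heals single-frame gaps that would
split a long bout.

Parameter selection: leave-one-segment-out cross-validation over annotated
segments; for each candidate `(C, k, θ)` the classifier is trained on all
but one segment and scored on the held-out one after voting, with raw
frame accuracy as the default selection metric (balanced accuracy behind a
flag). Ties break toward smaller C, then smaller k (simpler, smoother
models). The default grid is `C ∈ {0.01, 0.1, 1, 10}`,
`k ∈ {0, 3, 6, 12, 25}`, `θ = 0.5`. Raw SVM predictions depend only on C,
so they are cached per (C, fold) and shared across voting candidates.

## Annotations and consensus (`annotations`)

Bouts are half-open 0-based frame intervals `[start, end)`; overlapping
intervals of one annotator merge on ingestion. The majority consensus of
*n* annotators marks a frame climbing iff more than *n/2* annotators did;
the any rule iff at least one did (used for training labels so no climbing
example is missed; it always marks at least as many frames as the majority
rule). Even-count majority ties default to non-climbing. Frame counts
convert to seconds as `frames × frame_duration_ms / 1000`, i.e.
`frames × 40 / 1000` at 25 frames/s.

## Validation metrics (`evaluate`)

Frame metrics use exact rational arithmetic on the confusion counts, so
`accuracy = prevalence·recall_climbing + (1−prevalence)·recall_nonclimbing`
holds as an identity; a recall whose gold class is absent is reported as
missing. Binned agreement converts both label streams to climbing seconds
per fixed-length bin (default 300 s), drops a trailing partial bin with a
warning, requires ≥ 3 complete bins, and reports Spearman's ρ with average
ranks for ties and the asymptotic two-sided t p-value (an exact permutation
p is available for ≤ 10 bins).

## Zeitgeber binning and windows (`ethogram`)

ZT0 is lights-on (07:00 by default; lights-off 19:00). The dark phase is
the half-open ZT interval [12, 24). Bins are aligned to ZT0; with 6-min
bins there are 240 per day. The transition windows are `end_of_dark` =
ZT [23.5, 24) (clock 06:30–07:00) and `end_of_light` = ZT [11.5, 12)
(18:30–19:00), each exactly 5 six-min bins; window summaries are the
arithmetic mean over those 5 bins per cage × day and are reported missing
(never imputed) when a bin is absent. Distance is computed per mouse as
the Euclidean displacement between consecutive position fixes — each step
is assigned to the bin of its ending fix — and summed over the cage's
mice; climbing is a single cage-level label stream (the detector cannot
attribute climbing to individuals), converted to seconds per bin.

## Mixed-model statistics (`stats`)

The response (mean activity per cage × day in a window or phase) is
Box-Cox transformed (`(x^λ−1)/λ`, `ln x` at λ = 0) with λ per response by
maximum profile likelihood over λ ∈ [−3, 3] (bounded Brent search);
non-positive values are shifted to a small positive minimum with a
warning. The model has categorical fixed effects Age, Genotype, Sex — the
full factorial by default, because estimated-marginal-means contrasts need
estimable cell means; the literal single three-way interaction term is
available — plus a random intercept per cage and a random day-of-recording
slope (day numeric 1–3). Fitting is REML via statsmodels `MixedLM`;
several optimizers are tried and the best optimum kept. A singular fit
(a variance component at the boundary) is reported, and by default the day
slope is then dropped and the model refit — mirroring the practice of
eliminating random effects that do not contribute.

Model comparison refits by ML and uses the likelihood-ratio χ²
(`2Δ loglik`, df = Δ parameters). EMMs are model-predicted cell means on
the reference grid averaged with equal weights over the levels of factors
not in the contrast; pairwise differences carry standard errors from the
fixed-effect covariance. Degrees of freedom are Satterthwaite by default,
computed numerically: `df = 2·f²/(gᵀA g)` with `f = cᵀΣ_β(θ̂)c`, `g` the
finite-difference gradient of *f* in the variance parameters θ, and `A`
the inverse numerical Hessian of the REML profile log-likelihood at θ̂
(fallback to residual df when the Hessian is degenerate, e.g. at a
boundary); residual-df and normal approximations are available behind a
flag. This implementation was cross-checked against R's
lmer/lmerTest/emmeans chain in the test suite. Benjamini–Hochberg
adjustment implements the step-up rule
`p_adj(i) = min_{j≥i} min(1, m·p(j)/j)` and spans the returned contrast
set. Empty cells are reported non-estimable. Significance stars follow the
ns / * / ** / *** / **** convention at 0.05/0.01/0.001/0.0001.

## Synthetic data (`synthetic`)

The generators define the conditions under which the pipeline is tested;
they are pure functions of (scenario, seed).

**Video.** Climbing alternates with pauses as a renewal process with
gamma-distributed durations (shape 2; means 60 s off, 8 s on — a climbing
fraction of ≈ 12%, the same order as real test footage). During a bout a
high-contrast textured blob (side 22 px) oscillates vertically inside the
lid ROI; a floor distractor moves outside the ROI throughout; Gaussian
pixel noise (sd 2 on the 0–255 scale) is added everywhere. Gold bouts are
exactly the frames with the climb texture active. The default desk scale
is a 96 × 160 ROI in a 120 × 200 frame at 25 frames/s; the descriptor
dimension is unaffected by ROI size. When extracting features from this
noisy synthetic video the pipeline sets the LTP dead zone τ = 300 squared
intensity units — above the SSD noise floor of a 3 × 3 patch at noise
sd 2 — so that trits respond to the planted motion rather than to pixel
noise; τ = 0 remains the descriptor default.

What the video generator does **not** emulate: real mouse shape and
texture, multiple simultaneous animals, lighting changes, camera shake,
or ambiguous part-in-ROI postures. Passing end-to-end tests therefore
demonstrate that the machinery is correct and recovers planted structure,
not that the measured accuracies transfer to real footage.

**Annotators.** Each gold bout is missed with probability 0.1; surviving
boundaries get rounded Gaussian jitter (sd 5 frames); false bouts arrive
at 2/h with ~2 s durations. Zero-noise models reproduce gold exactly.

**Activity.** Per cage × 6-min bin, expected activity is
`baseline(phase) × sex × age × genotype(bin)` with dark/light baselines
1000/300 units, female multiplier 1.3, old-age multiplier 0.8, and a
hemizygous deficit multiplier 0.5 applied only inside the end-of-dark
window — the localized, early-detectable deficit pattern the analysis is
designed to find. On top: cage random intercept (sd 40), day random slope
(sd 15), iid noise (sd 60), floored at 0 (baselines are high enough that
flooring is negligible). Default design: 2 ages × 2 genotypes × 2 sexes ×
3 cages = 24 cages, 3 days. A climbing-like channel is emitted at 0.1 ×
the distance channel.

## Problem sizes and test design

The test suite runs the classifier end to end at 10 segments × 2 min of
reduced-resolution video (30,000 frames), selected by leave-one-segment-out
CV over the default grid, and checks held-out frame accuracy ≥ 0.85,
climbing recall ≥ 0.70 and 5-min-bin Spearman ρ ≥ 0.8 — thresholds chosen
to echo the scale of performance achievable by this method class, not to
reproduce any particular recording. Statistical properties use seeded
replicate simulations: 95% Wald CI coverage of every fixed effect ≥ 90%
over 200 replicates; the genotype contrast significant at end-of-dark and
non-significant at end-of-light (after BH) in ≥ 90% of 100 replicates; and
false-discovery control of the BH-adjusted contrasts under a null
(deficit-free) scenario. Oracle-equivalence sweeps compare the LTP
descriptor, temporal vote, consensus rules, frame metrics, Spearman ρ and
BH adjustment against independent brute-force implementations on ≥ 1,000
randomized instances each.

The zero-random-variance check that the mixed model collapses to OLS uses
a residual scale of 10⁻⁶ so that the GLS–OLS gap — bounded by the residual
scale — sits below the comparison tolerance regardless of where the
boundary variance estimate lands.

## Known limitations

* The descriptor is not rotation- or scale-invariant and codes any
  high-contrast ROI motion as potential climbing; discrimination rests
  entirely on the classifier.
* Cage-level climbing cannot be attributed to individual mice.
* Satterthwaite df relies on numerical derivatives of the REML surface and
  falls back to residual df at variance boundaries.
* The literal three-way-interaction-only fixed model leaves lower-order
  cell-mean structure unmodelled; it is provided for fidelity, but the
  full factorial is the default for estimability.
* Positions are taken as given; no tracking is performed.
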