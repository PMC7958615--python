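# Methods

## Scope and model

`perikit` scores implant-landmark detectors on two tasks. The detection task
uses box IoU. The landmark task uses object keypoint similarity (OKS): for
implant *j*, the mean over ground-truth-labeled landmarks *i* of
`exp(−d²/(2 s² k²))`, with `s = √area` (segmented implant area) and
`k_i = 2 σ_i`. The factor 2 is a configuration knob (`k_constant`) left at its
conventional value. Distances are Euclidean in pixel space with no axis
weighting. Landmarks with visibility `v = 1` (labeled but not visible) count
toward OKS exactly like `v = 2`: the indicator is `v > 0`. An implant whose
ground truth labels no landmark has an undefined OKS (0/0) and is excluded
from matching and averaging rather than scored zero.

`σ_i` is the per-landmark annotation standard deviation normalized by implant
scale, calibrated from two annotation passes over the same implants as
`σ_i² = mean_j d_ji²/s_j²`, restricted to implants where landmark *i* is
labeled in both passes, with `s` taken from the first pass (deterministic,
and the first pass is the ground truth in practice). A landmark type with no
usable pair raises an error naming the type; returning 0 silently would make
OKS degenerate. The calibration is agnostic about which dataset was annotated
twice — it accepts any paired sets.

## Matching and AP/AR

Matching is greedy, per image, one-to-one: predictions in descending ranking
score each take the highest-similarity unmatched ground truth with similarity
≥ threshold. Score ties break by (image id, input order); similarity ties
keep the earliest ground truth. The ranking score defaults to the mean of the
six per-keypoint scores (`keypoint_score`), because box confidence does not
track landmark quality for this task; the mean is chosen over the max for
symmetry, and both the max and `box_score` ranking remain available.

AP is 101-point interpolated (mean over recall levels 0.00…1.00 of the
precision envelope), AR is recall with all detections retained, and
`AP(all)`/`AR(all)` average thresholds 0.50–0.95 in steps of 0.05. There is
deliberately no maximum-detections cap: radiographs carry a handful of
implants. Two numerical choices matter for exact reproducibility against an
independent implementation of the same protocol: recall levels are computed
as `i/100` (not `linspace`, which can differ by 1 ulp and flip a tie), and AP
is integrated from the uncollapsed per-detection cumulative points. The
public `pr_curve` collapses tied scores into one operating point — that is
what a score-threshold sweep plot shows — but under exact ties the collapsed
curve loses intermediate points the AP integral needs, so `evaluate` uses the
per-detection form internally. Results are reported pooled and stratified by
the jaw label (upper/lower) carried on each image record; the label is a
required input, not inferred.

## Mean OKS and its normal-model reading

Human observers emit no confidence scores, so observer comparison filters
detections at a single box-score threshold (> 0.7 by default), matches
survivors to ground truth by highest OKS one-to-one, and averages. The
analytic interpretation inverts the single-keypoint OKS:
`m = √(−8 ln OKS)` is the displacement, in units of `σ_i s`, that would
produce that OKS if every landmark were off by the same multiple of its
tolerance. Treating the signed 1-D projection of scale-normalized annotation
error as standard normal after dividing by `σ_i s`, the share of human
annotations closer than the detector is `2Φ(m) − 1`. This is the only reading
under which a mean OKS of 0.8885 maps to m = 0.9725 and a 66.92% human
percentile, and it is adopted as the definition. Observer comparison uses the
Welch t-test by default (the pooled-variance test is an option); Welch is the
safer default when only "independent t-test" is specified, and both are
two-sided with the sign convention mean(A) − mean(B).

## Bone loss

Total length = distance from apex midpoint to top midpoint; defect length =
distance from top midpoint to bone-level midpoint. The bone-level midpoint is
projected onto the apex→top axis: at or coronal to the top the defect clamps
to zero (bone gain must not read as loss), and the clamp is flagged in the
measurement record. A percentage above 100 (bone level apical to the apex
midpoint) clamps to 100 with the same flag — such radiographs occur and are
not errors. `defect ≤ total` is deliberately not asserted. Severity bins are
closed on the right: [0,10] normal, (10,25] early, (25,50] moderate,
(50,100] severe. The implant-top reference is the most coronal thread; the
known bias for tissue-level implants is documented here, not corrected.
Measurements accept ground-truth or predicted landmarks and record which.

## Synthetic generator

Each implant is a rotated rectangle: length 200–400 px, width 60–120 px, tilt
within ±20° of vertical, placed inside a 1000×800 px frame, one to three per
image, jaws balanced — plausible magnitudes for implants on periapical films.
The six landmarks derive exactly from the rectangle (apex corners, top
corners, bone-level points at the sampled loss fraction along each side), the
area is the rectangle area and the box its axis-aligned envelope, so
`measure_bone_loss` recovers the sampled percentage to machine precision.
Bone-loss percentages come from a mixture over the four severity bins with
weights (0.4, 0.3, 0.2, 0.1), uniform within bin — a caseload skewed toward
mild resorption, overridable per run.

Prediction noise is isotropic Gaussian per landmark — the minimal assumption
consistent with OKS's radial distance — with per-axis standard deviation
`s σ_i m/√2` so that `E[d²/s²] = m² σ_i²` exactly (m is a global multiplier,
default 1, `σ_true` defaults to the shipped calibration). A `fixed`
displacement mode moves every landmark by exactly `m σ_i s` in a uniform
random direction, pinning each implant's OKS to `exp(−m²/8)`; it exists to
close the loop with the analytic inversion above (Gaussian noise gives
`E[OKS] = 1/(1+m²/8)` by Jensen, slightly above the fixed-mode value). False
negatives drop implants at `fn_rate`; false positives inject implant-shaped
random geometry at `fp_rate` with low scores. True-positive scores are drawn
independent of displacement by default; a `correlated` mode makes keypoint
scores decay with normalized displacement so PR curves are informative.
Randomness uses one stream per (purpose, image), keyed by
(seed, purpose, image index): growing `n_images` never reshuffles earlier
images, and truth, predictions and the redundant pass are independent.

What the generator does not emulate: radiographic texture, graft material,
occlusion, annotation exclusion criteria, or correlated per-observer bias
(its redundant passes have zero mean error by construction). Passing tests
therefore demonstrate the correctness and calibration of the *metrics*, not
detector performance on clinical images.

## Visualization

Keypoint logit grids are min–max normalized per channel to [0,1] — min–max is
the one map that exactly achieves the stated range for arbitrary logits; a
sigmoid option exists. A constant channel maps to zeros, not 0.5: no signal
should paint nothing. Channels combine by per-pixel maximum, are colormapped
(perceptually uniform `viridis` by default, configurable) and alpha-blended
with per-pixel weight `alpha × value`, so an empty grid and `alpha = 0` are
both exact identities. Rendering is pure — fixed inputs give byte-identical
rasters (the text overlay uses the library's bundled bitmap font).

## Problem sizes and tolerances

Parameter-recovery checks run at 500 redundant pairs (10% relative error per
σ component) and 5000 pairs (3%); the mean-OKS inversion check uses 1000
implants within 0.01; protocol equivalence against the independent reference
evaluator uses 20 randomized fixtures of ≤ 10 implants at 1e-6; the Welch
type-I-error simulation uses 1000 replicates of n = 100 per group, accepting
3–7% at α = 0.05. These sizes put each stochastic check several standard
errors inside its tolerance while keeping the whole suite in seconds.

## Known limitations

No segmentation-mask AP, no DICOM ingestion, no nonparametric observer tests,
no baseline-radiograph differencing and no clinical diagnosis: radiographic
bone-loss grading is an assistant readout, not a peri-implantitis diagnosis,
which additionally requires probing and bleeding findings. The bone-level
σ entries dominate the OKS tolerance, so a detector that nails the (clinically
most important) bone level but misses apex/top is penalized more than the
reverse — a property of the metric itself worth keeping in mind when reading
mean-OKS comparisons.
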