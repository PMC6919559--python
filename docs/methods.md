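# Methods

This note documents the models, conventions and design choices behind
nucleval: what each component computes, which knobs matter, and what
the synthetic benchmarks do and do not demonstrate about real data.

## Object matching and metrics

Evaluation is at the object level. Given a target label mask and a
predicted label mask of one image, the IoU of every co-occurring
object pair is computed sparsely (only label pairs that share at least
one pixel are enumerated; all other pairs have IoU exactly 0, so the
result is identical to the dense all-pairs computation).

**Hit rule.** A pair qualifies at threshold t when `IoU > t`, strictly.
The strict rule makes the constructed IoU = 0.5 case well defined: the
pair counts at t ∈ {0.10..0.45}, i.e. 8 of the 18 default thresholds,
so its competition score is exactly 8/18. An `inclusive` flag
(`--inclusive-threshold` on the CLI) is available for sensitivity
checks.

**Matching rule.** Qualifying pairs are matched one-to-one: a greedy
pass in descending IoU (ties broken by lower target label, then lower
prediction label) followed by deterministic augmenting paths
(unmatched targets in ascending label order, candidate predictions in
ascending label order) so the matching always has maximum cardinality.
For t ≥ 0.5 the greedy pass alone is already the unique maximal
matching — a prediction cannot overlap two disjoint targets with
IoU > 0.5 each, by a pixel-count argument — and augmentation is a
no-op. Below 0.5 a purely greedy pass can strand a matchable pair
(a high-IoU pair can consume the only partner of a neighbouring
object); the augmentation step removes that artifact while leaving
the greedy pairing of high-IoU pairs intact. The result is unique and
platform-independent.

**Degenerate images.** TP = FP = FN = 0 (an empty target mask
correctly predicted as empty) is scored 1 on every metric: a correct
"nothing to find" answer is not penalized. Any other zero denominator
yields 0. Object-level true negatives are undefined and carried as a
constant 0.

**Thresholds.** The default set T = {0.10, 0.15, ..., 0.95} is
generated from integer hundredths (10..95 step 5, divided by 100) so
the 18 values are exact binary-reproducible floats of the decimal
grid, and the CLI `lo:hi:step` parser uses the same integer
arithmetic.

**Aggregation.** The competition score S and the threshold-averaged F1
are computed per image first and then averaged without weighting (each
image counts equally, as the challenge scored submissions). Recall,
Missed and Extra at IoU 0.7 are pooled object counts over all images,
reported as percentages: Recall + Missed = 100 by construction, and
Extra is normalized by the number of *predicted* objects (so it need
not sum with Recall; normalizing by targets instead would make Extra
unbounded). A pooled-counts mode for S and F1 is exposed via
`aggregate="pooled"`.

## Mask interchange

Label masks are canonicalized on construction: positive labels become
1..n in ascending original-id order; gaps and arbitrary ids are
accepted on read. A label's pixels need not be connected — no
connectivity check is imposed, because splitting disconnected labels
would silently change object counts. Zero-object masks are valid
everywhere.

The RLE dialect is the Kaggle submission format: pixels are numbered
1-based, top-to-bottom within a column, then left-to-right
(column-major); a record is a sorted, non-overlapping list of
(start, length) runs, one record per object, blank for an image with
no predictions. `decode(encode(m))` reproduces the exact label
geometry because objects are emitted and re-labelled in the same
ascending order. Overlaps between per-object inputs (binary mask
directories or RLE records) are either an error or resolved
first-wins, at the caller's choice; an object fully eclipsed under
first-wins disappears from the canonical mask.

## Synthetic image model

Each nucleus is an ellipse (axis ratio 0.75–1, random orientation)
whose radius is modulated by random harmonics of order 2–4; the
`irregularity` parameter (0–1) scales the modulation, with higher
defaults for tissue groups. Diameters are Normal(diameter_mean,
diameter_sd), clipped below at 4 px. Placement is sequential: with
probability `touching_prob` a nucleus is deliberately placed adjacent
to an existing one and carved to disjointness; otherwise a 2 px
clearance is enforced, so `touching_prob = 0` produces well-separated
objects by construction. Every placement (carved or border-clipped)
must retain at least 60% of the sampled shape, so objects cannot
degenerate into slivers that escape their own size distribution;
placement retries up to 250 times per object and then fails with an
explicit generation error. The returned mask is exactly the rendered
supports before noise.

Rendering: fluorescent groups are single-channel, background 0.06,
per-nucleus brightness uniform in 0.65–0.95 with a brighter center
(distance-transform profile). Tissue groups are three-channel; nucleus
and background reference colors are fixed per group (purple on white,
purple on pink, dark gray on light gray) and mixed linearly with a
stain-density profile that darkens nucleus cores — a deliberate
simplification over an optical-density stain model, sufficient to
exercise the color classifier and the polarity-inverting
pre-processing. Optional degradations: a linear illumination gradient
(multiplicative, random direction), additive Gaussian noise, and a
shot-noise mode that scales the Gaussian sigma with √intensity as a
desk-scale stand-in for Poisson statistics.

Default per-group presets: small fluorescent 128², 20 nuclei of
diameter 12±2; large fluorescent 256², 6 nuclei of 40±6; tissue groups
128², 18–22 nuclei of 12–16 px with `touching_prob` 0.4 and higher
irregularity; all with noise_sd 0.03 and a mild illumination gradient.
These are package defaults expressing the qualitative appearance
classes, not measurements of any dataset. The default five-group
mixture is anchored at the reported imbalance — 80% small fluorescent,
0.6% for the rarest group (large fluorescent) — with the three tissue
groups at 8.4/6.0/5.0% chosen once to fill the remainder in decreasing
order of prevalence. Dataset counts use largest-remainder rounding
with ties broken by group name, and per-image seeds derive from the
master seed via a seed sequence, so a dataset is byte-reproducible.

`perturb_annotation` emulates a second human annotator: a smooth
random field (coarse Gaussian grid, bilinear upsampling, normalized to
amplitude ≤ `boundary_jitter` pixels) thresholds each object's signed
distance transform, displacing boundaries; objects may only grow into
pixels that are background in both the original and the perturbed
mask, preserving disjointness; objects are independently dropped with
`drop_prob`.

**What passing synthetic tests does not show.** The generator has no
out-of-focus blur, chromatic aberration, debris, mitotic figures,
overlapping (out-of-plane) nuclei, or real stain variation; its noise
is Gaussian. Segmenter accuracy on these images is an upper bound on
real-data behaviour and validates the mechanics (polarity handling,
declumping, size priors), not clinical performance.

## Classical segmenter

The pipeline follows the classical three-step design: (1) transform to
a grayscale matrix with bright nuclei on a dark background; (2)
identify primary objects by thresholding, distance transforms and
watershed using the expected nuclear size; (3) revise with a seeded
watershed from the primary objects under additional size priors. All
parameters live in five fixed per-group presets; `segment()` takes
only the image.

The group classifier is a decision tree mirroring how the groups are
defined (colors, then object size): channels are smoothed (σ = 1.5)
before measuring inter-channel spread so independent sensor noise does
not register as color (95th percentile > 0.02 ⇒ color); background
polarity comes from which side of the Otsu split holds the majority of
pixels; fluorescent images split small/large at a rough median object
diameter of 25 px; color tissue splits purple vs pink-and-purple on
median background saturation (0.10); colorless with bright background
is grayscale tissue. A constant image returns the documented
low-confidence fallback (small fluorescent).

Numerical choices, stated for reproducibility: Otsu global threshold
by default (the canonical parameter-free choice); the grayscale-tissue
preset uses a local (Gaussian-weighted) threshold surface clipped to
[0.7, 1.3]× the global Otsu value so flat background cannot become
foreground; holes filled; declumping seeds are local maxima of the
Gaussian-smoothed (σ = max(1, min_diameter/4)) Euclidean distance
transform with a minimum separation of `seed_min_distance`
(≈ min_diameter/2 per group; 2 px for the crowded tissue presets), and
any foreground component whose plateau produced no peak receives one
seed at its distance maximum; watershed is 8-connected on the negated
distance transform. The size prior removes objects whose equivalent
diameter falls outside [min_diameter, max_diameter]; the
small-fluorescent lower bound is 3 px, matching the generator's
physical minimum so genuinely small nuclei are not discarded. Border
objects are kept (not discarded as some classical defaults do) because
the evaluation counts border nuclei as targets. The stain-contrast
transform is per-channel min–max normalization followed by luminance
inversion — not true stain deconvolution, for which no stain matrix is
assumed.

The secondary revision re-thresholds the grayscale image, unions the
primary support into the foreground, and floods from the primary
labels over the negated intensity: object count is preserved (each
marker grows exactly one region) or reduced by the size filter, never
split; an eroded primary recovers its support, and a perfect primary
moves only marginally (boundary pixels where the threshold disagrees
with the true edge by ≲1 px).

On the package's own benchmarks (seeded, regenerated at test time):
clean well-separated small-fluorescent images are recovered exactly
(object counts equal, pooled F1 at 0.5 IoU = 1 over 100 images), and
the default-noise 100-image five-group mixture reaches pooled F1 at
0.5 IoU ≈ 0.97, dominated by merged touching tissue nuclei — the
known failure mode of distance-transform declumping.

## Inter-observer agreement

Two segmentations of the same image are matched with the same matcher
at threshold 0 (any strictly positive overlap), so boundary
disagreement is captured even for weakly overlapping objects; the
matched pairs' IoUs form the agreement distribution, summarized by the
median, and accuracy agreement is F1 from a re-match at 0.7. The
matched-IoU multiset is symmetric in the two masks. Pooled medians
across images are taken over the concatenated per-object list
(object-weighted), matching per-object point-cloud summaries rather
than a mean of per-image medians. With a noiseless reference mask
playing the "model" against two independently jittered annotators, the
model-vs-annotator median IoU is at least the annotator-vs-annotator
one — the jitters are independent, so annotators accumulate both
displacement errors; this is the qualitative pattern the agreement
module is designed to expose.

## Problem sizes

The test suite and benchmarks use 128²–256² images, 6–22 nuclei per
image, 100-image benchmark sets and 1,000-mask RLE round trips; these
sizes exercise every code path and keep the full suite around tens of
seconds on one CPU. All randomness flows from explicit integer seeds;
there is no global random state.

## Known limitations

* The matcher's augmentation guarantees maximum cardinality, not
  maximum total IoU among maximum-cardinality matchings; below t = 0.5
  two equal-cardinality matchings can differ in which low-IoU pairs
  they select (counts, and hence all reported metrics, are identical).
* The group classifier is tuned for the synthetic appearance models;
  real counterstains (e.g. DAB, fluorescent multi-channel overlays)
  may defeat the color heuristics and should use the group override.
* The classical segmenter implements the three-step design, not any
  specific tool's exact module settings; it is a reference baseline,
  not a competitive method.
* RLE supports one dialect (column-major, 1-based); other run-length
  conventions must be converted upstream.
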