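# Methods

## Scope and model of the data

`rootclass` analyzes *root crowns*: the excavated, washed top portion of a
field-grown root system, photographed against a contrasting background and
segmented to a binary mask.  One image = one plant = one classification
unit.  Three architecture phenotypes are distinguished by rules on the
lateral roots emerging from the taproot:

| class | laterals | spacing along taproot | lateral thickness |
|-------|----------|----------------------|-------------------|
| B (branch) | 4–6 | 10–20 mm | thick (1.1–1.9 mm) |
| T (taproot) | 0–3 | 30–40 mm | thin (0.5–0.9 mm) |
| TB (intermediate) | 4–5 | > 20 mm (20.5–30 mm) | intermediate (0.7–1.5 mm) |

The pipeline's stages are independent modules with one data contract
(`BinaryRootImage` → `TraitVector` → `LabeledDataset` →
`PredictionResult` → `MetricReport`), so real segmented images can replace
the synthetic generator at any point (`pipeline.ingest_external`).

## Synthetic root-crown generator

The generator renders what the classifier sees in practice, not a
botanical growth model.  Each root is drawn on a black canvas as:

* a **taproot**: a vertically descending centerline with gentle sinusoidal
  wobble (amplitude 0.5–2 mm), stroked with a quadratically tapering
  diameter from a class-dependent crown diameter down to 0.5 mm at the
  tip; default taproot length 105 mm;
* **laterals**: straight strokes with a slight droop, emerging from the
  taproot centerline at angles of 20–70° below horizontal, alternating
  sides, 15–35 mm long, linearly tapering to 0.3 mm.  The number of
  laterals and the arc-length gaps between consecutive origins are drawn
  from the class rules above; each gap's upper bound is clamped so the
  remaining gaps still fit on the taproot, which keeps every realized gap
  inside its class interval.  The TB count range is capped at 5 because a
  sixth lateral spaced >20 mm rarely fits a 105 mm taproot;
* **fine rootlets**: hair-thin (≈1 px) strokes 3–8 mm long scattered along
  the taproot at a class-dependent density (`fine_root_density`, rootlets
  per mm), feeding the smallest diameter range and the tip count;
* **holes**: small disks (radius 1–2.5 px) punched into thick interior
  regions at a rate proportional to `fine_root_density`, emulating root
  crossings and segmentation artifacts; placement requires a distance-
  transform margin so the mask stays one connected component.

Class overlap is deliberate: TB's thickness and taproot-diameter ranges
straddle both extremes, and its spacing and count ranges abut B's and T's,
so TB is the hardest class — the regime in which comparing classifiers is
informative.  Per-image pixel scale is drawn uniformly (default 8–12
px/mm; 4–6 in the quick configuration), emulating a camera whose working
distance varies between shots.

All geometry derives from `numpy.random.default_rng(seed)`, so identical
arguments give bit-identical images.  `generate_dataset` shuffles the
class sequence and draws one sub-seed per image from the dataset seed.

What the generator does **not** emulate: soil occlusion, touching/crossing
roots of neighbouring plants, segmentation errors beyond punched holes,
perspective distortion, and biological covariance between traits beyond
what the geometry induces.  Tests passing on synthetic data therefore
validate the pipeline's mechanics and orderings, not field-data accuracy
values.

## Trait extraction

Traits are computed on the binary mask and its medial-axis skeleton
(scikit-image `skeletonize`), with the local radius taken from the
Euclidean distance transform at each skeleton pixel (local diameter = 2 ×
radius).  Spur branches of skeleton length ≤ 2 px (configurable) are
pruned iteratively before measuring.  The 38 traits are 26 whole-root
traits — median/max roots per row, tip count, merged branch-point
clusters, branching density (branch points per mm), total skeleton length
(diagonal steps = √2 px), depth, max width, width/depth, network area,
convex hull area, solidity, lower root area (below ⅓ of depth), perimeter,
surface area (Σ π·d·step), volume (Σ π(d/2)²·step), hole count/total/mean
area, average orientation, shallow/medium/steep angle frequencies
([0,30)/[30,60)/[60,90]° from horizontal), and average/median/max diameter
— plus length, projected area, surface area and volume within each of
three diameter ranges.

Numerical choices worth knowing:

* **Diameter-range bounds are in pixels** (≤10, 11–20, ≥21 px by default),
  applied *before* mm conversion, because range settings are configured on
  pixel images whose scale varies image to image.  Since the per-image
  scale varies, the same physical diameter can fall in different ranges in
  different images — intentional, matching how the ranges were set in the
  original batch analysis.
* Skeleton orientation at a pixel is the principal axis of skeleton
  pixels within a 7 px window (configurable); absolute components make
  angles mirror-invariant.  Angle frequencies are weighted per skeleton
  pixel (≈ per unit length).
* 8-connectivity for foreground and skeleton, 4-connectivity for holes
  (complementary-connectivity convention).  Branch clusters of adjacent
  ≥3-neighbor pixels count once.
* Bounding-box extents use inclusive pixel counts (a 100-row mask at 10
  px/mm has depth 10.0 mm).
* A skeleton with fewer than two pixels yields zero lengths and
  frequencies and a `degenerate` flag plus a warning.
* Per-range additivity (lengths/surfaces/volumes summing to the totals) is
  exact by construction: every skeleton edge lands in exactly one range.
* Binarization auto-detects polarity: the side of the threshold with
  fewer pixels is foreground.

The extractor is our own implementation of the standard root-crown trait
repertoire; it does not claim numeric identity with any specific GUI
tool's output.

## Augmentation

Each source image receives `n_aug` (default 10) independent transforms:
rotation ~ U(−20°, 20°) about the image center and isotropic scale ~
U(0.8, 1.2), composed in one nearest-neighbor affine warp onto a canvas
padded so no foreground is clipped.  Bounds are hard: forced parameters
outside them raise.  The pixel scale of an augmented image is inherited
unchanged, so the scale factor deliberately changes measured mm sizes —
the same effect as a change in camera working distance.  Augmented images
are re-extracted with the trait module (there is no trait-space
augmentation).  Every transform is logged (source id, replicate 1..n,
angle, scale, seed).

## Models

All six classifiers sit behind one interface (`fit`, `predict_proba`,
`predict` → `PredictionResult`).  Traits are min-max normalized to [0, 1]
(y_nor = (y − y_min)/(y_max − y_min); constant columns → 0; test values
extrapolate unclipped).  For supervised models the normalization is fit on
each training fold only; for clustering it is fit on the full matrix,
since clustering is applied to the whole dataset at once.

* **k-means** (k = 3, ≤100 iterations, best of 10 restarts) uses Lloyd's
  algorithm via scikit-learn.  The classical alternative update scheme
  (Hartigan–Wong) optimizes the same objective; at these data sizes the
  partitions are equivalent for our purposes, and no Python implementation
  of it is available in the stack.
* **PAM** (k-medoids, Euclidean) is implemented here directly: greedy
  BUILD initialisation plus full SWAP descent, best of 10 inits (BUILD +
  9 random).  Medoids are always data points; the objective never
  increases.
* Cluster→class assignment maximizes total agreement over one-to-one
  assignments (Hungarian algorithm) — the most favorable deterministic
  convention.  The clustering itself never sees labels.
* **Random forest**: 500 trees, mtry = ⌊√p⌋ = 6 candidate variables per
  split.  Class probability is computed explicitly as the fraction of
  trees voting each class, so e.g. votes (400, 80, 20) of 500 give
  (0.80, 0.16, 0.04).
* **Naive Bayes**: Gaussian class-conditional densities under the
  independence assumption.  A Laplace smoothing parameter (default 1) is
  accepted and recorded, but it only affects categorical likelihoods and
  is therefore inert for these continuous traits.
* **Classic MLP**: 38-15-10-5-3, logistic activations throughout,
  per-output cross-entropy, trained full-batch by resilient
  backpropagation with weight backtracking (Rprop+; η⁺ = 1.2, η⁻ = 0.5,
  Δ₀ = 0.1, Δmax = 50 — the standard constants).  Training stops when the
  largest absolute gradient drops below 0.01 or at the step limit
  (default 100 000; the quick configuration caps it at 3 000 since the
  loss plateau is reached far earlier at that data size); hitting the
  limit warns and returns the model as-is.  Output probabilities are the
  logistic outputs normalized to sum to 1.
* **Modern MLP**: same 15-10-5 hidden sizes, relu hidden layers, softmax
  output with categorical cross-entropy, Adam, batch size 32, up to 200
  epochs with plateau-based early stopping (scikit-learn).

Ties in the probability triple resolve to the first class in (B, T, TB)
order.  Every model is deterministic under a fixed seed.

## Evaluation protocol

Default scheme: stratified 5-fold cross-validation repeated 3 times
(15 fold-reports per model); a stratified 70/30 holdout is available.
When a dataset contains augmented replicates, folds are **grouped by
source image** by default, so no descendant of a test root appears in
training.  The pipeline's augmented arm, however, follows the literal
study protocol — ungrouped folds — because that is the protocol whose
improvement-from-augmentation finding the package reproduces; under
grouped folds the modern MLP retains most of its augmentation benefit
while the random forest's largely disappears (nearly-duplicate training
rows add little to a bagged ensemble).  Both modes are one flag apart
(`augmented_cv_grouped` in the run config, `--ungrouped` in the CLI).

Metrics come from the pooled 3×3 confusion matrix (and per fold): for
each class one-vs-rest TP/FP/TN/FN give sensitivity, specificity,
precision = PPV, NPV, predicted prevalence (TP+FP)/total, true prevalence
(TP+FN)/total, and balanced accuracy = (sensitivity + specificity)/2.
"Prevalence" in the headline tables is the *predicted* proportion; both
are carried, unambiguously named.  Plain overall accuracy (trace/total) is
exposed separately as `overall_accuracy`.  Classes with a zero denominator
report NaN and are excluded from the macro mean with a warning.  Fold
summaries report mean and sample SD (n−1); model pairs are compared with
a two-sided paired t-test on per-fold macro balanced accuracies (identical
vectors return t = 0, p = 1 rather than 0/0).

Unsupervised models are evaluated by clustering the full normalized
matrix once, aligning clusters to classes, then scoring within each test
fold (a per-fold clustering mode exists for methodological hygiene).

## Confidence tiers

A prediction's maximum class probability (argmax of 3 ⇒ ≥ 1/3) is banded
into seven right-closed tiers: (0, 0.4] LLL, (0.4, 0.5] LL, (0.5, 0.6] L,
(0.6, 0.7] M, (0.7, 0.8] H, (0.8, 0.9] HH, (0.9, 1.0] HHH.  A
"table-compatible" mode moves the LL/L edge to 0.510 to match the worked
decision-example table, which grades 0.502–0.508 as LL; canonical bounds
are the default.  `select_high_confidence` retains calls strictly above a
threshold (default 0.9) and reports retention rate and, given truths,
subset accuracy; on calibrated probabilities raising the threshold never
lowers subset accuracy in expectation.

## Problem sizes and reproducibility

The default dataset plan is 237/245/135 roots per class (B/T/TB, 617
total, the study-scale imbalance).  The package's *quick* configuration —
used by the test suite and the acceptance script — scales this 5× down
(47/49/27 at 4–6 px/mm) and caps the classic MLP's step limit at 3 000;
it preserves the protocol, the class imbalance and all qualitative
orderings.  Every stage takes an explicit seed derived from the run seed;
reruns with the same config are bit-identical for the deterministic stages
and the run directory is stamped with a config hash.

## Known limitations

* Synthetic geometry is stylised; absolute metric values on real archives
  will differ, and only orderings/mechanics transfer.
* The 38-trait layout is one defensible composition of the standard
  repertoire (26 whole-root + 12 per-diameter-range); other tools order
  and name the set differently.
* PAM's full SWAP descent is O(k·n²) per pass; for n beyond ~5 000 roots
  a faster k-medoids variant would be needed.
* The classic MLP regularly overfits (that is part of what the benchmark
  shows); no weight decay or early stopping is applied to it.
* No probability calibration is performed; confidence tiers band the raw
  model probabilities.
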