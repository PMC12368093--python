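# Methods

This note records the evaluation procedures, their assumptions, the
numerical conventions, and the design choices made where the design was
genuinely open.  It states no empirical result the test suite or
`scripts/acceptance.py` does not itself compute.

## Setting and data model

A *session* is one time-lapse recording above a single target flower
(~1 frame / 1.6 s, roughly an hour).  Ground truth consists of per-frame
axis-aligned boxes, each with a fine taxon label (taxonomic order, plus
Formicidae split out of Hymenoptera) and an individual identifier that is
kept across consecutive frames and across short occlusions.  Each annotated
frame also carries exactly one region-of-interest (ROI) box around the
target flower.  Boxes follow the VIA convention: top-left origin, 0-based
continuous pixel coordinates, `(x, y, width, height)`, area = width×height.

Dataset construction mirrors common practice for such studies: frames are
cropped to the union of the ROI box and all arthropod boxes (so visitors at
the ROI edge are never cut), boxes of taxa too small to be detectable
(thrips) and boxes with unidentifiable taxa are excluded, and co-occurring
arthropods that did not interact with the target flower are removed via an
explicit boolean attribute — not inferred geometrically, because such
removals are a judgement call made by the annotator.  Individuals are scoped
per session: the same identifier in two sessions denotes two individuals.

## Matching and frame metrics

Predictions are first confidence-filtered and then greedily
non-maximum-suppressed (class-agnostic by default; suppression at
IoU > `nms_iou`, strict, ties in confidence broken by input order).
Matching at eval-IoU is the standard detection protocol: predictions in
descending confidence each claim the unmatched ground truth of maximal
IoU ≥ eval-IoU (ties: lowest ground-truth index); duplicates of an
already-claimed ground truth are false positives.  Localisation is evaluated
class-agnostically; a class-aware mode exists for confusion analyses.

The F1–confidence curve evaluates every unique observed confidence as a
threshold.  Because matching is greedy in descending confidence, a
prediction's TP/FP status is independent of lower-confidence predictions,
so one matching pass plus cumulative sums reproduces the per-threshold
re-evaluation exactly; the test suite checks this against a naive
re-matching oracle.  Conventions: precision is defined as 0 when no
prediction is retained; PR-AUC is the raw trapezoid over points sorted by
recall with an anchor at (recall 0, precision of the highest-threshold
point), with no precision-envelope interpolation and no extrapolation past
the maximum recall.  FPPI is ΣFP / #images; on background-only frames every
retained prediction is an FP.

The NMS grid search sweeps `nms_iou` ∈ {0.1, …, 0.9} on un-suppressed
predictions, recording max F1 (with its confidence) and PR-AUC per cell;
the argmax is by F1, ties to the lower `nms_iou`.  A caveat uncovered by
property testing: for *arbitrary* overlap graphs the number of boxes kept
by greedy NMS is **not** monotone in `nms_iou` — raising the threshold can
free a mid-confidence box that then suppresses several others.  Count
monotonicity does hold for disjoint clusters of near-duplicates, the regime
detector duplicates actually create, and that is the regime in which the
property is asserted.

## Sequence metrics

An individual is localised (an *arthropod-TP*) iff ≥ 1 of its boxes is a
box-TP, regardless of labels: one good frame suffices to register a visit.
Labels use the max-confidence rule over the *fine* labels of the
individual's box-TPs (ties at equal confidence: earliest frame), and the
winning fine label is collapsed to Hymenoptera / Diptera / OtherT
afterwards — the detector emits fine labels, so selection must run before
pooling.  Unlocalised individuals occupy a background/FN column.

Metric conventions were chosen so that a published confusion matrix and its
printed metric columns are mutually consistent, and they are the
package's primary regression surface (reconciled at 4 decimals in the
acceptance tests): recall = diag/rowsum; precision = diag/colsum with the
background column never counted as a predicted class; per-class accuracy
= (N − FP_c − FN_c)/N with FN_c including background misses; the overall
row weights precision and accuracy by class size, pools recall as
Σdiag/N, and takes overall F1 as the harmonic mean of the weighted overall
precision and recall — a size-weighted mean of per-class F1s does *not*
reconcile the published overall row, the harmonic mean does (to within
truncation of the printed last digit).

## Covariates and tests

Sharpness inside a box is proxied by the Tenengrad focus measure: the mean
over interior pixels of Gx² + Gy² for 3×3 Sobel kernels, colour converted
by Rec. 601 luma first.  The mean (not the sum) makes values independent of
patch size before the dataset-max normalisation to [0, 1]; the maximum is
taken over the whole analysed dataset, not per session.  Border pixels are
excluded rather than padded.

The permutation test reports |Δ| of means and of medians from one shared
set of label shuffles (n_perm = 1000 by default), with
p = (1 + #{|Δ*| ≥ |Δobs|}) / (1 + n_perm).  The add-one correction counts
the observed labelling among the resamples so p is never exactly 0 — a
deliberate, documented deviation from the literal "proportion of permuted
differences", justified by finite sampling; type-I error at α = 0.05 is
verified by a 300-replicate null simulation against the binomial interval.
No multiple-testing correction is applied across the group contrasts (a
config flag exists); a single α = 0.05 is reported against each p-value.

Misclassification asymmetries use the exact upper-tail binomial
p = Σ_{i≥k} C(n,i)p₀ⁱ(1−p₀)ⁿ⁻ⁱ with chance shares p₀ = 1/7 (one of seven
wrong fine labels) at box level and p₀ = 1/2 (two wrong coarse groups) at
sequence level.  The area–sharpness association is Spearman's ρ (mid-ranks;
undefined for constant input, reported as None).

## Synthetic generator: what it emulates, and what it does not

Defaults are the study conditions: 200 sessions × 2220 frames (~1 h at
1.6 s/frame), ~6 visitor arrivals per session, class mix 79/11/10 %
(OtherT subdivided by the observed shares: ants 67 %, beetles 16 %, bugs
9 %, spiders 8 %).

* **Visit lengths**: geometric, truncated at the session end, with
  p = 1 − 2^(−1/(m−½)) so the *sample* median of boxes-per-individual is
  m = 7 (placing the CDF crossing exactly at m would leave the empirical
  median straddling m and m+1).  Occlusion gaps of 1–3 frames are inserted
  with probability 0.05 per step, identifier retained.
* **Box areas**: log-normal with μ = ln 0.028 (median target) and
  σ = √(2 ln(0.075/0.028)) ≈ 1.404 (mean target), truncated at 0.9 of the
  frame and clipped to pixel bounds; truncation pulls the realised mean a
  few percent under 0.075 while leaving the median at target.
* **Sharpness**: latent s = logistic(z + ε) with z the standardised
  log-area and ε ~ N(0, τ²), τ = √(1/r² − 1) where r = 2 sin(πρ/6) inverts
  the bivariate-normal Spearman relation; ρ defaults to 0.79.  The logistic
  form is a modelling choice, stated openly — any monotone transform
  preserves the rank correlation.
* **Detector**: per-box detection via a logistic in log-area and sharpness
  (bigger/sharper found more often), or injected per-group sequence-level
  rates for parameter-recovery studies (each localised sequence then gets a
  Binomial subset of box hits, minimum one).  Labels are drawn from a
  row-stochastic 8×8 confusion matrix with elevated Hymenoptera↔Diptera
  mass (mimicry); confidence is Beta-distributed, higher for correct
  labels; boxes are jittered (log-size and centre); background FPs are a
  per-image Poisson process.

What the generator does **not** emulate: real image content (sharpness is
latent, not measured from pixels, except in the dedicated blur-patch
fixtures), per-session heterogeneity in arrival rates, within-frame
interactions between individuals, plant-species backgrounds, and the
extreme visit-length tail (a real dataset's maximum of ~1,700 frames is
far beyond a geometric tail).  Passing tests therefore certify the
*pipeline arithmetic and statistical procedures*, not detector behaviour on
real imagery.

## Problem sizes used in tests and the acceptance script

Unit and property tests run on scenes of ≤ 50 images and oracle checks on
≤ 10-box instances (1,000 random NMS cases, 300 matching cases).
Calibration tests use 10,000 generated individuals; the parameter-recovery
run uses the study's group sizes (1,013 / 145 / 123) with injected
localisation rates 0.91 / 0.81 / 0.56 and checks recovery within the
binomial 95 % interval at those sizes.  These sizes keep the full suite
around ten seconds while leaving every statistical check adequately
powered.

## Known limitations

* The published headline detector scores (max F1 0.70-class, PR-AUC, the
  NMS optimum) require the trained detector weights and the raw image set;
  they are out of scope here, and the grid-search procedure is validated by
  its limiting properties instead (perfect-detector limits, duplicate
  suppression, cluster monotonicity).
* PR-AUC values are comparable only under the same interpolation
  convention; this package's raw trapezoid is documented above.
* The VIA importer's filename convention (`<session>_<frame>.<ext>`) is a
  configurable guess; the canonical CSV sidesteps it entirely.
* Greedy matching can be suboptimal when several predictions contest one
  ground truth; the test suite bounds it by the brute-force optimal
  assignment and verifies equality in uncontested scenes.
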