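# Methods

## Problem setting

Ultrasound lesion screening favors sensitivity: detectors are run at a
deliberately low confidence threshold so that small or atypical lesions are
not missed, at the cost of many redundant and spurious boxes. `smwbf`
consolidates the output of an ensemble of such detectors — each trained on a
differently filtered rendition of the same images, each with its own global
mAP@0.5 — into one box per suspected lesion, then evaluates detection and
aggregates per-box class calls into an image-level decision.

## Pipeline model and assumptions

**Clustering.** Detections are grouped by DBSCAN on normalized box centers
with Euclidean distance, `eps = 0.1`, `min_samples = 1`. The distance is
computed on raw normalized coordinates; for non-square images this makes
`eps` anisotropic in physical pixels, which we accept because annotations
are normalized per axis. Points labeled noise are reassigned as singleton
clusters (with `min_samples = 1` none arise, but the branch is implemented
and tested for larger `min_samples`): a solitary box is treated as a lesion
hypothesis, not discarded. Determinism: inputs are pre-sorted by
`(cx, cy, detector_id)` — this fixes which cluster claims a border point
reachable from two clusters — and cluster ids are assigned by ascending
`(min member cx, min member cy)`.

**Outlier filter.** Per cluster, means `(w̄, h̄)` are computed once over all
members (single pass, not iterated — the exclusion is described as one
step), and a member survives iff
`(1−t)·w̄ ≤ w < (1+t)·w̄` and `(1−t)·h̄ ≤ h < (1+t)·h̄`, `t = 0.5`. The
bounds are inclusive below and exclusive above, exactly as specified, despite
the asymmetry. Degenerate case: if every member fails (possible in a
two-box cluster with very different sizes), the member nearest `(w̄, h̄)` in
Euclidean distance is kept, ties broken toward the smaller box. Emitting
nothing would silently drop a lesion hypothesis, which contradicts the
noise-retention principle above; this fallback is our design decision — the
underlying scheme does not address the case.

**Fusion.** Ensemble weights are a SoftMax over global mAP@0.5 scores,
computed once and reused for every cluster; within a cluster the weights of
the members present are renormalized by dividing by their sum. When one
detector contributes several boxes to a cluster, each box carries that
detector's weight independently (the fusion sum runs over boxes, not
detectors). Confidences are ignored by design. Since mAP ∈ [0, 1], the
SoftMax spreads weights mildly (extreme-weight ratio ≤ e); no temperature
or rescaling is applied — the transform is implemented exactly as defined.

**Padding.** Padding is defined in integer pixels: the fused box is
converted to pixel corners, each side grown by `p = 5`, and converted back.
No clipping to the image frame is applied, and evaluation pads ground truth
identically, so boxes near borders compare symmetrically.

**Decision rule.** Per-box three-class predictions (benign / malignant /
error — the error class absorbs spurious boxes admitted by the low
threshold) aggregate by: drop error; any malignant ⇒ malignant; else any
benign ⇒ benign. An image left with nothing aggregates to `none`, surfaced
so callers can route it to manual review; the rule itself does not define
this case. Sensitivity (malignant recall) and specificity (benign recall)
exclude the error class from their denominators; accuracy runs over all
three classes.

## Numerical choices

- **Pixel rounding.** YOLO↔pixel conversion rounds half away from zero.
  No convention is canonical here; this one is symmetric, documented, and
  fixed. Round-tripping perturbs each coordinate by at most half a pixel.
- **Exact identities.** `pad_box` with `p = 0` returns its input unchanged
  (skipping the pixel round trip), and fusing a cluster whose members all
  carry the identical box returns that box exactly. Both avoid spurious
  last-ulp drift in the noiseless limit, where the pipeline is provably the
  identity.
- **IoU** is computed in continuous normalized coordinates from box
  corners, with areas derived from the same corner differences as the
  intersection so that `iou(x, x) == 1.0` holds exactly in floating point.
- **Annotation format.** Writers emit six significant digits; parsing and
  re-emitting a file is byte-stable at that precision.
- **Metric arithmetic** uses exact rationals (`fractions.Fraction`) before
  conversion to float; zero-denominator metrics are reported as `None`
  (undefined), never as silent NaN.

## The synthetic-data generator

`smwbf.simulate` stands in for trained detectors applied to real frames.
Reference conditions (defaults): 10 detectors; 1–2 lesions per image with
sizes uniform in [0.05, 0.3] of the frame and centers uniform subject to
the box fitting inside; per detector and lesion, a miss probability of 0.1,
Gaussian center jitter (σ = 0.01, normalized units), relative size jitter
(σ = 0.1), a 5% chance of a grossly mis-sized box (×3 or ×1/3), and
Poisson false positives at 0.3 per detector-image; at most five boxes per
detector per image, lesion detections kept in preference to false positives
when truncating. Two defaults are package choices documented here: the
malignant fraction 0.3 (typical of a screening case mix of roughly 30%
malignant), and a minimum lesion center separation of 0.25 so that distinct
lesions are resolvable by center clustering at `eps = 0.1`. Detector
mAP@0.5 scores default to an even spread over [0.55, 0.75], a plausible
band for single-class ultrasound lesion detectors.

All draws come from one seeded NumPy generator; scenes are bit-identical
for identical seed and parameters.

What the generator does **not** emulate: speckle texture and any
image-appearance statistics (it produces geometry only), correlated errors
between detectors trained on overlapping data, systematic per-detector bias
(e.g. one network always oversizing), and lesion-morphology effects on
detectability. Passing tests therefore demonstrate the algebra and the
ensemble mechanics of the pipeline, not clinical performance on real
ultrasound.

On these reference conditions (200 images), the fused pipeline's image
detection rate at IoU ≥ 0.9 is about 0.8 — far above the best single
simulated detector (≈ 0.14), the gap the fusion exists to create, though
not near-perfect: with σ = 0.01 center jitter on lesions as small as 0.05,
even a 9-box average sometimes falls just short of the strict 0.9 overlap.
`scripts/acceptance.py` recomputes these numbers at run time.

The classifier stand-in (`gen_classifications`) samples predicted labels
from a user-given true→predicted confusion distribution; a box's true class
is its best-IoU ground-truth label when that IoU ≥ 0.5 (a conventional
matching threshold, chosen here), else `error`.

## The filter bank

The augmentation module expands one grayscale frame into ten variants from
four filter families: intensity adjustment (1st/99th-percentile contrast
stretch), CLAHE (clip limit 0.01, default tiling), Gaussian low-pass
blended as `c·blur + (1−c)·img`, and unsharp-mask high-pass
`img + c·(img − blur)`, with blend coefficients `α = 1.5` and `β = 0.5` and
blur σ = 2 px. The concrete 2×5 wiring — each contrast-enhanced base passed
through {identity, LP(α), LP(β), HP(α), HP(β)} — is this package's
reconstruction: the ingredients, the α/β pair and the count of ten are
fixed requirements, but their exact composition is under-specified, and
other wirings yielding ten images exist. The Gaussian σ and CLAHE clip
limit are likewise package defaults, exposed as parameters.

## Problem sizes

Default test and benchmark sizes — 200 simulated images for the stochastic
improvement benchmark, 1000 random instances for the clustering and IoU
oracle comparisons, ~10⁴ sampled boxes for the classifier-rate convergence
check — were chosen so the whole suite runs in seconds while keeping
Monte-Carlo noise well inside the asserted margins.

## Known limitations

- `eps` and the outlier threshold are global constants; crowded frames with
  adjacent lesions closer than `eps` will merge hypotheses (the simulator's
  separation default sidesteps this deliberately).
- mAP@0.5 is an input, taken on trust from the detector framework; the
  package does not recompute PR curves.
- The IoU ≥ 0.9 success criterion is meaningful only for lesion-bearing
  images; images without ground truth are excluded from rates and listed
  separately in evaluation reports.
- Rotated boxes, segmentation masks and 3-D volumes are out of scope.
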