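# smwbf — SoftMax-weighted box fusion for ensemble lesion detection

`smwbf` merges the bounding boxes produced by an *ensemble* of object
detectors into one representative box per lesion hypothesis. It targets the
ultrasound screening setting — e.g. hepatocellular-carcinoma surveillance —
where detectors are deliberately run at a low confidence threshold so that
no suspicious region is missed, and the resulting flood of overlapping boxes
must be consolidated before a downstream classifier makes the
benign / malignant call.

## The method

Given per-image detections from `N` detectors (YOLO-format normalized boxes)
and each detector's global mAP@0.5 score, the pipeline runs four stages per
image:

1. **Clustering.** DBSCAN on box centers `(cx, cy)` with `eps = 0.1`,
   `min_samples = 1`, Euclidean distance. Points DBSCAN would call noise are
   kept as singleton clusters — a lone box may be the only evidence of a
   lesion.
2. **Outlier filtering.** Within each cluster, with mean width/height
   `(w̄, h̄)` and deviation ratio `t = 0.5`, a box survives iff
   `(1−t)·w̄ ≤ w < (1+t)·w̄` and `(1−t)·h̄ ≤ h < (1+t)·h̄`.
3. **SoftMax-weighted fusion (SM-WBF).** Detector weights
   `w_i = exp(mAP_i) / Σ_j exp(mAP_j)` are computed once per ensemble; each
   fused coordinate is the weight-renormalized average over cluster members,
   `x̂ = Σ w_i·x_i / Σ w_i` (likewise `ŷ`, `ŵ`, `ĥ`). Confidence scores are
   deliberately ignored — unlike classical weighted box fusion, every
   retained box counts as equally valid evidence.
4. **Padding.** The fused box is converted to pixel corners, grown by
   `p = 5` pixels per side (`x_min−p`, `x_max+p`, `y_min−p`, `y_max+p`), and
   converted back, preserving the lesion contour and a rim of surrounding
   tissue for the classifier.

Evaluation counts an image as detected when any fused box reaches
**IoU ≥ 0.9** against a ground-truth box padded with the same `p`. Per-box
benign / malignant / error predictions aggregate sensitivity-first: error
boxes are dropped, and a single malignant box makes the whole image
malignant.

A seeded simulator (`smwbf.simulate`) generates ground truth plus
multi-detector detections with center jitter, size jitter, misses, false
positives and grossly mis-sized outliers, so the full pipeline is testable
without clinical data. An image filter bank (`smwbf.preprocessing`) produces
the ten contrast/sharpness variants used to diversify detector training.

## Worked example

```python
from smwbf import (DetectorProfile, Detection, NormBox, PaddingParams,
                   optimize_image, softmax_weights)

profiles = [DetectorProfile("net00", 0.9), DetectorProfile("net01", 0.8)]
print(softmax_weights(profiles).weights)
# {'net00': 0.5249791874789399, 'net01': 0.47502081252106}

dets = [
    Detection(NormBox(0.50, 0.50, 0.20, 0.20), "net00"),
    Detection(NormBox(0.52, 0.50, 0.22, 0.20), "net01"),
    Detection(NormBox(0.51, 0.49, 0.60, 0.60), "net00"),  # oversized outlier
]
fused = optimize_image(dets, profiles,
                       padding_params=PaddingParams(p=5, image_w=512, image_h=512))
print(fused)
# [NormBox(cx=0.5087890625, cy=0.5, w=0.228515625, h=0.21875)]
```

The three boxes share one cluster; the oversized box is rejected by the
size filter (its width 0.60 falls outside `[0.17, 0.51)`, the ±50% band
around the cluster mean 0.34); the two survivors are averaged with weights
0.52498 / 0.47502 and the result is padded by 5 px on a 512×512 frame —
one representative box per lesion hypothesis.

The same flow is available from a shell:

```
smwbf --seed 42 simulate --out scene --n-images 200
smwbf fuse --det-dir scene/det --profiles scene/profiles.csv --out fused
smwbf evaluate --fused-dir fused --gt-dir scene/gt --out report
```

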