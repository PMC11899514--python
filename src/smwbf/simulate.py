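"""Seeded synthetic scenes: ground-truth lesions plus multi-detector boxes.

The generator stands in for an ensemble of trained lesion detectors run
on real ultrasound frames, so every pipeline stage is testable without
clinical data.  It emulates the statistical structure the fusion stage
assumes:

* one or two lesions per image, uniformly placed, sizes 0.05–0.3 of the
  frame, with a minimum center separation so distinct lesions are
  resolvable by center-distance clustering;
* an ensemble of detectors of varying quality (each with a nominal
  mAP@0.5 used for weighting); each detector independently finds each
  lesion with probability ``1 - miss_rate``, reporting a box with
  Gaussian center jitter and relative size jitter;
* occasional grossly mis-sized boxes (x3 or x1/3) at ``outlier_rate``;
* Poisson-distributed false-positive boxes at random locations;
* at most five boxes per detector per image (lesion detections are kept
  in preference to false positives when truncating).

All draws come from one ``numpy`` generator seeded from ``SimParams.seed``,
so scenes are bit-identical across runs.  The distributions are test
scaffolding — uniform placement, Gaussian jitter and Poisson false
positives are modeling choices, not claims about ultrasound statistics.
"""

from __future__ import annotations

import json
from dataclasses import asdict, dataclass
from pathlib import Path

import numpy as np

from .aggregation import BENIGN, CLASSES, ClassifiedBox, GroundTruthBox, MALIGNANT
from .clustering import Detection
from .geometry import NormBox, iou
from .io import LABEL_TO_CLASS, write_ground_truth, write_yolo, YoloLine
from .weighting import DetectorProfile

__all__ = [
    "SimParams",
    "Scene",
    "gen_scene",
    "write_scene",
    "true_box_labels",
    "gen_classifications",
]

_LESION_SIZE_RANGE = (0.05, 0.3)


@dataclass(frozen=True)
class SimParams:
    """Generator knobs; defaults are the package's reference conditions."""

    n_images: int
    n_detectors: int = 10
    lesions_min: int = 1
    lesions_max: int = 2
    center_jitter_sd: float = 0.01
    size_jitter_sd: float = 0.1
    miss_rate: float = 0.1
    false_positive_rate: float = 0.3
    outlier_rate: float = 0.05
    detector_map50s: tuple[float, ...] | None = None
    malignant_fraction: float = 0.3
    min_center_separation: float = 0.25
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_images < 0 or self.n_detectors < 1:
            raise ValueError("need n_images >= 0 and n_detectors >= 1")
        if not (1 <= self.lesions_min <= self.lesions_max):
            raise ValueError("lesion count range must satisfy 1 <= min <= max")
        for name in ("miss_rate", "outlier_rate", "malignant_fraction"):
            v = getattr(self, name)
            if not (0.0 <= v <= 1.0):
                raise ValueError(f"{name}={v} outside [0, 1]")
        if self.center_jitter_sd < 0 or self.size_jitter_sd < 0:
            raise ValueError("jitter standard deviations must be non-negative")
        if self.false_positive_rate < 0:
            raise ValueError("false_positive_rate must be non-negative")
        if self.detector_map50s is not None and len(self.detector_map50s) != self.n_detectors:
            raise ValueError(
                f"detector_map50s has {len(self.detector_map50s)} entries "
                f"for {self.n_detectors} detectors"
            )
        if _LESION_SIZE_RANGE[1] >= 1.0:
            raise ValueError("lesion size range must fit inside the frame")

    def map50s(self) -> tuple[float, ...]:
        if self.detector_map50s is not None:
            return self.detector_map50s
        # Evenly spread ensemble quality over a plausible mAP@0.5 band.
        return tuple(np.linspace(0.55, 0.75, self.n_detectors).round(4))


@dataclass
class Scene:
    """Ground truth plus per-detector detections, keyed by image stem."""

    truth: dict[str, list[GroundTruthBox]]
    detections: dict[str, dict[str, list[Detection]]]
    profiles: list[DetectorProfile]
    params: SimParams

    def all_detections(self, stem: str) -> list[Detection]:
        return [d for dets in self.detections[stem].values() for d in dets]


def _draw_lesions(rng: np.random.Generator, params: SimParams) -> list[GroundTruthBox]:
    k = int(rng.integers(params.lesions_min, params.lesions_max + 1))
    lo, hi = _LESION_SIZE_RANGE
    boxes: list[GroundTruthBox] = []
    for _ in range(k):
        for _attempt in range(100):
            w = float(rng.uniform(lo, hi))
            h = float(rng.uniform(lo, hi))
            cx = float(rng.uniform(w / 2, 1 - w / 2))
            cy = float(rng.uniform(h / 2, 1 - h / 2))
            if all(
                np.hypot(cx - b.box.cx, cy - b.box.cy) >= params.min_center_separation
                for b in boxes
            ):
                label = MALIGNANT if rng.random() < params.malignant_fraction else BENIGN
                boxes.append(GroundTruthBox(NormBox(cx, cy, w, h), label))
                break
        # after 100 rejections the frame is crowded; emit fewer lesions
    return boxes


def _jittered_box(
    rng: np.random.Generator, truth: NormBox, params: SimParams
) -> NormBox:
    cx = float(np.clip(truth.cx + rng.normal(0.0, params.center_jitter_sd), 0.0, 1.0))
    cy = float(np.clip(truth.cy + rng.normal(0.0, params.center_jitter_sd), 0.0, 1.0))
    w_factor = max(0.2, 1.0 + float(rng.normal(0.0, params.size_jitter_sd)))
    h_factor = max(0.2, 1.0 + float(rng.normal(0.0, params.size_jitter_sd)))
    if rng.random() < params.outlier_rate:
        scale = 3.0 if rng.random() < 0.5 else 1.0 / 3.0
        w_factor *= scale
        h_factor *= scale
    w = float(np.clip(truth.w * w_factor, 1e-3, 1.0))
    h = float(np.clip(truth.h * h_factor, 1e-3, 1.0))
    return NormBox(cx, cy, w, h)


def gen_scene(params: SimParams) -> Scene:
    """Generate a reproducible synthetic scene from ``params.seed``."""
    rng = np.random.default_rng(params.seed)
    map50s = params.map50s()
    detector_ids = [f"net{i:02d}" for i in range(params.n_detectors)]
    profiles = [DetectorProfile(d, m) for d, m in zip(detector_ids, map50s)]

    truth: dict[str, list[GroundTruthBox]] = {}
    detections: dict[str, dict[str, list[Detection]]] = {}
    lo, hi = _LESION_SIZE_RANGE
    for i in range(params.n_images):
        stem = f"img_{i:04d}"
        lesions = _draw_lesions(rng, params)
        truth[stem] = lesions
        per_det: dict[str, list[Detection]] = {}
        for det_id in detector_ids:
            hits: list[Detection] = []
            for lesion in lesions:
                if rng.random() < params.miss_rate:
                    continue
                box = _jittered_box(rng, lesion.box, params)
                hits.append(
                    Detection(
                        box=box,
                        detector_id=det_id,
                        confidence=float(rng.uniform(0.25, 0.95)),
                        class_id=LABEL_TO_CLASS[lesion.label],
                    )
                )
            n_fp = int(rng.poisson(params.false_positive_rate))
            for _ in range(n_fp):
                w = float(rng.uniform(lo, hi))
                h = float(rng.uniform(lo, hi))
                fp_box = NormBox(
                    float(rng.uniform(w / 2, 1 - w / 2)),
                    float(rng.uniform(h / 2, 1 - h / 2)),
                    w,
                    h,
                )
                hits.append(
                    Detection(
                        box=fp_box,
                        detector_id=det_id,
                        confidence=float(rng.uniform(0.1, 0.5)),
                        class_id=0,
                    )
                )
            # Detectors emit at most five boxes; lesion hits take priority.
            per_det[det_id] = hits[:5]
        detections[stem] = per_det
    return Scene(truth=truth, detections=detections, profiles=profiles, params=params)


def write_scene(scene: Scene, out_dir: str | Path) -> None:
    """Emit gt/*.txt, det/<id>/*.txt, profiles.csv and sim_manifest.json."""
    import pandas as pd

    out = Path(out_dir)
    write_ground_truth(out / "gt", scene.truth)
    for stem, per_det in scene.detections.items():
        for det_id, dets in per_det.items():
            d = out / "det" / det_id
            d.mkdir(parents=True, exist_ok=True)
            write_yolo(
                d / f"{stem}.txt",
                [
                    YoloLine(d0.class_id if d0.class_id is not None else 0, d0.box, d0.confidence)
                    for d0 in dets
                ],
            )
    pd.DataFrame(
        [{"detector_id": p.detector_id, "map50": p.map50} for p in scene.profiles]
    ).to_csv(out / "profiles.csv", index=False)
    manifest = {"params": asdict(scene.params), "n_images": scene.params.n_images}
    (out / "sim_manifest.json").write_text(json.dumps(manifest, indent=2) + "\n")


def true_box_labels(
    fused: list[NormBox],
    truth: list[GroundTruthBox],
    match_iou: float = 0.5,
) -> list[str]:
    """Assign each fused box its true class: the best-matching lesion's
    label when best IoU >= ``match_iou``, else the error class."""
    labels = []
    for f in fused:
        best, best_label = 0.0, "error"
        for t in truth:
            v = iou(f, t.box)
            if v > best:
                best, best_label = v, t.label
        labels.append(best_label if best >= match_iou else "error")
    return labels


def gen_classifications(
    fused: list[NormBox],
    truth: list[GroundTruthBox],
    confusion_spec: dict[str, dict[str, float]],
    rng: np.random.Generator,
    match_iou: float = 0.5,
) -> list[ClassifiedBox]:
    """Sample per-box predicted labels from a true->predicted distribution.

    Stands in for a downstream CNN classifier: each fused box's true
    class comes from :func:`true_box_labels`, and its predicted class is
    drawn from ``confusion_spec[true_class]`` (rows must sum to one).
    """
    for cls in CLASSES:
        if cls not in confusion_spec:
            raise ValueError(f"confusion_spec missing row for {cls!r}")
        row = confusion_spec[cls]
        if any(p < 0 for p in row.values()) or abs(sum(row.values()) - 1.0) > 1e-9:
            raise ValueError(f"confusion_spec row for {cls!r} is not a distribution")
        if set(row) - set(CLASSES):
            raise ValueError(f"unknown predicted classes in row {cls!r}")
    out = []
    for box, true_cls in zip(fused, true_box_labels(fused, truth, match_iou)):
        row = confusion_spec[true_cls]
        preds = sorted(row)
        probs = np.array([row[p] for p in preds])
        predicted = str(rng.choice(preds, p=probs / probs.sum()))
        out.append(ClassifiedBox(box, predicted))
    return out
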