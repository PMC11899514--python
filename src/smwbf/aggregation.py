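"""Detection-success evaluation and image-level decision aggregation.

Detection evaluation: an image counts as successfully detected if at
least one fused box overlaps a ground-truth box at IoU >= 0.9, where the
ground truth receives the *same* pixel padding as the detections.  The
high threshold reflects the screening design: the fused, padded box must
localize the lesion almost exactly for the downstream classifier crop to
contain the contour and its surrounding tissue.

Image-level decision: each fused box is classified benign / malignant /
error (the error class absorbs spurious boxes produced by the
deliberately low detection threshold).  Error boxes are discarded; if
any remaining box is malignant the image is malignant; otherwise if any
is benign the image is benign.  This any-malignant rule is
sensitivity-first — one malignant box can never be outvoted — which is
the clinically appropriate bias for a screening tool.  An image whose
boxes are all error (or that has no boxes) aggregates to ``"none"`` so
callers can route it to manual review; the underlying rule does not
define this case.
"""

from __future__ import annotations

from dataclasses import dataclass
from fractions import Fraction

from .fusion import PaddingParams, pad_box
from .geometry import NormBox, iou

__all__ = [
    "BENIGN",
    "MALIGNANT",
    "ERROR",
    "CLASSES",
    "GroundTruthBox",
    "ClassifiedBox",
    "ConfusionCounts",
    "ClassificationMetrics",
    "image_detected",
    "detection_accuracy",
    "aggregate_image_label",
    "confusion_metrics",
]

BENIGN = "benign"
MALIGNANT = "malignant"
ERROR = "error"
CLASSES = (BENIGN, MALIGNANT, ERROR)


@dataclass(frozen=True)
class GroundTruthBox:
    """An annotated lesion box with its clinical label."""

    box: NormBox
    label: str

    def __post_init__(self) -> None:
        if self.label not in (BENIGN, MALIGNANT):
            raise ValueError(f"ground-truth label must be benign/malignant, got {self.label!r}")


@dataclass(frozen=True)
class ClassifiedBox:
    """A fused box with its three-class prediction."""

    box: NormBox
    predicted: str

    def __post_init__(self) -> None:
        if self.predicted not in CLASSES:
            raise ValueError(f"predicted class {self.predicted!r} not in {CLASSES}")


@dataclass(frozen=True)
class ConfusionCounts:
    """Counts over (true_class, predicted_class) pairs in the three-class set."""

    counts: dict[tuple[str, str], int]

    def __post_init__(self) -> None:
        for (t, p), n in self.counts.items():
            if t not in CLASSES or p not in CLASSES:
                raise ValueError(f"unknown class pair ({t!r}, {p!r})")
            if n < 0:
                raise ValueError(f"negative count for ({t!r}, {p!r})")

    def get(self, true_class: str, predicted: str) -> int:
        return self.counts.get((true_class, predicted), 0)

    def row_total(self, true_class: str) -> int:
        return sum(self.get(true_class, p) for p in CLASSES)

    @property
    def total(self) -> int:
        return sum(self.counts.values())

    @classmethod
    def from_pairs(cls, pairs: list[tuple[str, str]]) -> "ConfusionCounts":
        counts: dict[tuple[str, str], int] = {}
        for t, p in pairs:
            counts[(t, p)] = counts.get((t, p), 0) + 1
        return cls(counts)


@dataclass(frozen=True)
class ClassificationMetrics:
    """Accuracy / sensitivity / specificity; a metric whose denominator is
    zero is reported as ``None`` (undefined) rather than NaN."""

    accuracy: float | None
    sensitivity: float | None
    specificity: float | None

    def as_dict(self) -> dict[str, float | None]:
        return {
            "accuracy": self.accuracy,
            "sensitivity": self.sensitivity,
            "specificity": self.specificity,
        }


def image_detected(
    fused: list[NormBox],
    truth: list[GroundTruthBox],
    padding: PaddingParams,
    iou_threshold: float = 0.9,
) -> bool:
    """True iff any fused box matches any *padded* ground-truth box.

    Ground truth is padded with the same pixel budget as the detections
    so the comparison is symmetric; fused boxes are assumed already
    padded by the pipeline.
    """
    padded_truth = [pad_box(t.box, padding) for t in truth]
    return any(
        iou(f, t) >= iou_threshold for f in fused for t in padded_truth
    )


def detection_accuracy(flags: list[bool]) -> float:
    """Fraction of successfully detected images (exact rational, then float)."""
    if not flags:
        raise ValueError("detection_accuracy needs at least one image flag")
    return float(Fraction(sum(bool(f) for f in flags), len(flags)))


def aggregate_image_label(boxes: list[ClassifiedBox]) -> str:
    """Collapse per-box predictions into one image-level label.

    Error boxes are discarded; any malignant box makes the image
    malignant; otherwise any benign box makes it benign; an empty or
    all-error set yields ``"none"``.
    """
    informative = [b.predicted for b in boxes if b.predicted != ERROR]
    if MALIGNANT in informative:
        return MALIGNANT
    if BENIGN in informative:
        return BENIGN
    return "none"


def confusion_metrics(
    c: ConfusionCounts, positive_class: str = MALIGNANT
) -> ClassificationMetrics:
    """Accuracy, sensitivity and specificity from three-class counts.

    Accuracy runs over all three classes (diagonal / total).  Sensitivity
    is recall of the positive (malignant) class and specificity is recall
    of the benign class; the error class contributes to neither
    denominator.  Requires a non-empty table.
    """
    if c.total == 0:
        raise ValueError("confusion table is empty")
    negative_class = BENIGN if positive_class == MALIGNANT else MALIGNANT

    diagonal = sum(c.get(k, k) for k in CLASSES)
    accuracy = float(Fraction(diagonal, c.total))

    pos_total = c.row_total(positive_class)
    sensitivity = (
        float(Fraction(c.get(positive_class, positive_class), pos_total))
        if pos_total
        else None
    )
    neg_total = c.row_total(negative_class)
    specificity = (
        float(Fraction(c.get(negative_class, negative_class), neg_total))
        if neg_total
        else None
    )
    return ClassificationMetrics(accuracy, sensitivity, specificity)
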