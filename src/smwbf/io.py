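"""YOLO-format annotation I/O and directory conventions.

One ``.txt`` file per image, one box per line:

    class cx cy w h [conf]

whitespace-separated, coordinates normalized to image dimensions.  The
reader tolerates a trailing confidence field and blank lines; the writer
emits six significant digits, which is stable under a read/write round
trip (parsing a 6-digit decimal and reformatting reproduces the string).

Detection trees follow the de-facto YOLO layout: ``det/<detector_id>/``
holds one annotation file per image, and images are associated across
detectors and ground truth by filename stem.
"""

from __future__ import annotations

from pathlib import Path

from .aggregation import BENIGN, MALIGNANT, GroundTruthBox
from .clustering import Detection
from .geometry import NormBox

__all__ = [
    "YoloLine",
    "read_yolo",
    "write_yolo",
    "read_detections",
    "read_ground_truth",
    "write_ground_truth",
    "format_coord",
    "CLASS_TO_LABEL",
    "LABEL_TO_CLASS",
]

# Class-index convention for ground-truth files: 0 = benign, 1 = malignant.
CLASS_TO_LABEL = {0: BENIGN, 1: MALIGNANT}
LABEL_TO_CLASS = {v: k for k, v in CLASS_TO_LABEL.items()}


def format_coord(v: float) -> str:
    return f"{v:.6g}"


class YoloLine:
    """One parsed annotation line: class index, box, optional confidence."""

    __slots__ = ("class_id", "box", "confidence")

    def __init__(self, class_id: int, box: NormBox, confidence: float | None = None):
        self.class_id = class_id
        self.box = box
        self.confidence = confidence


def read_yolo(path: str | Path) -> list[YoloLine]:
    """Parse a per-image YOLO annotation file.

    Raises ``ValueError`` naming the file and line on malformed input.
    """
    path = Path(path)
    lines: list[YoloLine] = []
    for lineno, raw in enumerate(path.read_text().splitlines(), start=1):
        fields = raw.split()
        if not fields:
            continue
        if len(fields) not in (5, 6):
            raise ValueError(
                f"{path}:{lineno}: expected 'class cx cy w h [conf]', got {raw!r}"
            )
        try:
            class_id = int(fields[0])
            cx, cy, w, h = (float(f) for f in fields[1:5])
            conf = float(fields[5]) if len(fields) == 6 else None
        except ValueError as exc:
            raise ValueError(f"{path}:{lineno}: {exc}") from None
        if not (w <= 1.0 and h <= 1.0):
            raise ValueError(f"{path}:{lineno}: box size ({w}, {h}) exceeds 1")
        lines.append(YoloLine(class_id, NormBox(cx, cy, w, h), conf))
    return lines


def write_yolo(
    path: str | Path,
    lines: list[YoloLine],
) -> None:
    """Write annotation lines with 6-significant-digit coordinates."""
    out = []
    for ln in lines:
        b = ln.box
        fields = [str(ln.class_id)] + [
            format_coord(v) for v in (b.cx, b.cy, b.w, b.h)
        ]
        if ln.confidence is not None:
            fields.append(format_coord(ln.confidence))
        out.append(" ".join(fields))
    Path(path).write_text("\n".join(out) + ("\n" if out else ""))


def read_detections(det_dir: str | Path) -> dict[str, dict[str, list[Detection]]]:
    """Read a ``det/<detector_id>/*.txt`` tree.

    Returns ``{image_stem: {detector_id: [Detection, ...]}}``; images
    appear even if only some detectors fired on them.
    """
    det_dir = Path(det_dir)
    per_image: dict[str, dict[str, list[Detection]]] = {}
    for sub in sorted(p for p in det_dir.iterdir() if p.is_dir()):
        detector_id = sub.name
        for f in sorted(sub.glob("*.txt")):
            dets = [
                Detection(
                    box=ln.box,
                    detector_id=detector_id,
                    confidence=ln.confidence,
                    class_id=ln.class_id,
                )
                for ln in read_yolo(f)
            ]
            per_image.setdefault(f.stem, {})[detector_id] = dets
    return per_image


def read_ground_truth(gt_dir: str | Path) -> dict[str, list[GroundTruthBox]]:
    """Read ``gt/*.txt`` into per-image ground-truth boxes."""
    gt_dir = Path(gt_dir)
    out: dict[str, list[GroundTruthBox]] = {}
    for f in sorted(gt_dir.glob("*.txt")):
        boxes = []
        for ln in read_yolo(f):
            if ln.class_id not in CLASS_TO_LABEL:
                raise ValueError(
                    f"{f}: ground-truth class {ln.class_id} must be 0 (benign) or 1 (malignant)"
                )
            boxes.append(GroundTruthBox(ln.box, CLASS_TO_LABEL[ln.class_id]))
        out[f.stem] = boxes
    return out


def write_ground_truth(gt_dir: str | Path, per_image: dict[str, list[GroundTruthBox]]) -> None:
    gt_dir = Path(gt_dir)
    gt_dir.mkdir(parents=True, exist_ok=True)
    for stem, boxes in per_image.items():
        # positional order matches the fuser's cluster-id convention
        ordered = sorted(boxes, key=lambda b: (b.box.cx, b.box.cy, b.box.w, b.box.h))
        write_yolo(
            gt_dir / f"{stem}.txt",
            [YoloLine(LABEL_TO_CLASS[b.label], b.box) for b in ordered],
        )
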