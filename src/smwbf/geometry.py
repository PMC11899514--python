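"""Bounding-box representations, coordinate conversions, and IoU.

Two box representations are used throughout the package:

* :class:`NormBox` — YOLO-style normalized center format ``(cx, cy, w, h)``
  on the unit square.  All fusion arithmetic (clustering, weighted
  averaging, outlier filtering) happens in this continuous space.
* :class:`PixelBox` — integer corner format ``(xmin, ymin, xmax, ymax)``
  tied to a concrete image size.  Padding is defined in pixel units, so
  boxes round-trip through this representation when padded.

Conversions round half away from zero; the rule is fixed and documented
because integer pixel arithmetic must be reproducible.  IoU is computed in
continuous normalized coordinates and is never clipped to the image frame:
padded boxes are compared against padded ground truth symmetrically, and
clipping would bias matches near the image border.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

__all__ = ["NormBox", "PixelBox", "to_pixel", "to_norm", "iou"]


def _round_half_away(x: float) -> int:
    """Round to the nearest integer, halves away from zero."""
    return int(math.floor(abs(x) + 0.5)) * (1 if x >= 0 else -1)


@dataclass(frozen=True)
class NormBox:
    """Normalized center-format box.

    ``cx``/``cy`` lie in [0, 1]; ``w``/``h`` are strictly positive.  On
    construction from an annotation the implied corners lie inside the
    unit square; padding may later push corners (and hence ``w``/``h``)
    beyond it, which is permitted and deliberate.
    """

    cx: float
    cy: float
    w: float
    h: float

    def __post_init__(self) -> None:
        if not (0.0 <= self.cx <= 1.0 and 0.0 <= self.cy <= 1.0):
            raise ValueError(f"center ({self.cx}, {self.cy}) outside [0, 1]")
        if not (self.w > 0.0 and self.h > 0.0):
            raise ValueError(f"non-positive box size ({self.w}, {self.h})")

    @property
    def corners(self) -> tuple[float, float, float, float]:
        """Continuous ``(xmin, ymin, xmax, ymax)`` in normalized units."""
        return (
            self.cx - self.w / 2.0,
            self.cy - self.h / 2.0,
            self.cx + self.w / 2.0,
            self.cy + self.h / 2.0,
        )

    @property
    def area(self) -> float:
        return self.w * self.h


@dataclass(frozen=True)
class PixelBox:
    """Integer corner-format box within a ``image_w`` x ``image_h`` frame.

    Coordinates may lie outside the frame when produced by padding; use
    :meth:`clipped` for a view guaranteed to be inside the image.
    """

    xmin: int
    ymin: int
    xmax: int
    ymax: int
    image_w: int
    image_h: int

    def __post_init__(self) -> None:
        if self.image_w <= 0 or self.image_h <= 0:
            raise ValueError(
                f"non-positive image dimensions ({self.image_w}, {self.image_h})"
            )
        if self.xmin >= self.xmax or self.ymin >= self.ymax:
            raise ValueError(
                f"degenerate pixel box ({self.xmin}, {self.ymin}, "
                f"{self.xmax}, {self.ymax})"
            )

    def clipped(self) -> "PixelBox":
        """View clipped to the image frame (for cropping, never for IoU)."""
        return PixelBox(
            max(self.xmin, 0),
            max(self.ymin, 0),
            min(self.xmax, self.image_w),
            min(self.ymax, self.image_h),
            self.image_w,
            self.image_h,
        )


def to_pixel(box: NormBox, image_w: int, image_h: int) -> PixelBox:
    """Convert a normalized box to integer pixel corners.

    Each corner is scaled by the image dimension and rounded half away
    from zero.  Raises ``ValueError`` for non-positive image dimensions.
    """
    if image_w <= 0 or image_h <= 0:
        raise ValueError(f"non-positive image dimensions ({image_w}, {image_h})")
    x0, y0, x1, y1 = box.corners
    return PixelBox(
        _round_half_away(x0 * image_w),
        _round_half_away(y0 * image_h),
        _round_half_away(x1 * image_w),
        _round_half_away(y1 * image_h),
        image_w,
        image_h,
    )


def to_norm(box: PixelBox) -> NormBox:
    """Convert a pixel box back to normalized center format.

    Exact inverse of :func:`to_pixel` up to rounding: the round trip
    perturbs each coordinate by at most ``1/(2 * image_dim)``.
    """
    return NormBox(
        cx=(box.xmin + box.xmax) / (2.0 * box.image_w),
        cy=(box.ymin + box.ymax) / (2.0 * box.image_h),
        w=(box.xmax - box.xmin) / box.image_w,
        h=(box.ymax - box.ymin) / box.image_h,
    )


def iou(a: NormBox, b: NormBox) -> float:
    """Intersection-over-union of two boxes in continuous normalized space.

    Symmetric, bounded in [0, 1], and zero for disjoint boxes.  No
    clipping to the unit square is applied, so padded boxes compare
    consistently near image borders.
    """
    ax0, ay0, ax1, ay1 = a.corners
    bx0, by0, bx1, by1 = b.corners
    iw = min(ax1, bx1) - max(ax0, bx0)
    ih = min(ay1, by1) - max(ay0, by0)
    if iw <= 0.0 or ih <= 0.0:
        return 0.0
    inter = iw * ih
    # areas from the same corner differences as the intersection, so that
    # identical boxes yield exactly 1.0 in floating point
    area_a = (ax1 - ax0) * (ay1 - ay0)
    area_b = (bx1 - bx0) * (by1 - by0)
    union = area_a + area_b - inter
    return inter / union
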