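"""Per-cluster size-outlier filtering, weighted box fusion, and padding.

Within each cluster the pipeline (1) drops boxes whose width or height
deviates from the cluster mean by more than an allowable ratio, (2) fuses
the survivors into a single representative box as a SoftMax-weighted
average of centers and dimensions, and (3) pads the fused box by a fixed
number of pixels on each side so the lesion contour and a rim of
surrounding tissue are retained for downstream classification.

Outlier rule: with cluster means (w̄, h̄) and threshold t, a box of size
(w, h) is kept iff

    (1 - t)·w̄ <= w < (1 + t)·w̄   and   (1 - t)·h̄ <= h < (1 + t)·h̄.

The bounds are inclusive below and exclusive above; means are computed
once over the original cluster (single pass, not iterated).  Should the
rule reject every member — possible in a two-box cluster with very
different sizes — the member closest to the mean size is retained
instead, because discarding a whole lesion hypothesis would defeat the
screening purpose.

Fusion rule: each fused coordinate is sum(w_i · v_i) / sum(w_i) over
cluster members, where w_i is the *global* SoftMax weight of the member's
source detector (renormalized over the members present).  Confidence
scores play no role: every retained box is treated as equally valid
evidence, which is what distinguishes this scheme from confidence-driven
weighted box fusion.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

from .clustering import Cluster, ClusterParams, Detection, cluster_detections
from .geometry import NormBox, to_norm, to_pixel
from .weighting import DetectorProfile, WeightVector, softmax_weights

__all__ = [
    "OutlierParams",
    "PaddingParams",
    "filter_outliers",
    "fuse_cluster",
    "pad_box",
    "optimize_image",
    "optimize_image_detailed",
    "ClusterAudit",
]


@dataclass(frozen=True)
class OutlierParams:
    """Allowable relative deviation of box size from the cluster mean."""

    threshold: float = 0.5

    def __post_init__(self) -> None:
        if not (0.0 < self.threshold < 1.0):
            raise ValueError(f"threshold must be in (0, 1), got {self.threshold}")


@dataclass(frozen=True)
class PaddingParams:
    """Symmetric padding in pixels, tied to a concrete image size."""

    p: int = 5
    image_w: int = 512
    image_h: int = 512

    def __post_init__(self) -> None:
        if self.p < 0:
            raise ValueError(f"padding must be non-negative, got {self.p}")
        if self.image_w <= 0 or self.image_h <= 0:
            raise ValueError(
                f"non-positive image dimensions ({self.image_w}, {self.image_h})"
            )


def filter_outliers(cluster: Cluster, params: OutlierParams = OutlierParams()) -> Cluster:
    """Remove size outliers from a cluster (single-pass means).

    Keeps members within the half-open band around the mean width *and*
    height.  If no member survives, the one nearest the mean size in
    Euclidean (w, h) distance is kept (ties broken by smaller size).
    """
    if not cluster.members:  # Cluster forbids this, but guard the API
        raise ValueError("cannot filter an empty cluster")
    t = params.threshold
    n = len(cluster.members)
    w_mean = sum(d.box.w for d in cluster.members) / n
    h_mean = sum(d.box.h for d in cluster.members) / n

    kept = tuple(
        d
        for d in cluster.members
        if (1 - t) * w_mean <= d.box.w < (1 + t) * w_mean
        and (1 - t) * h_mean <= d.box.h < (1 + t) * h_mean
    )
    if not kept:
        fallback = min(
            cluster.members,
            key=lambda d: (
                math.hypot(d.box.w - w_mean, d.box.h - h_mean),
                d.box.w,
                d.box.h,
            ),
        )
        kept = (fallback,)
    return Cluster(cluster_id=cluster.cluster_id, members=kept)


def fuse_cluster(cluster: Cluster, weights: WeightVector) -> NormBox:
    """Fuse cluster members into one box by detector-weighted averaging.

    When one detector contributes several boxes to a cluster, each box
    independently carries that detector's weight.  A singleton cluster
    returns its member's box unchanged.  Raises ``KeyError`` if a member's
    detector has no weight.
    """
    members = cluster.members
    for d in members:
        if d.detector_id not in weights:
            raise KeyError(
                f"detector {d.detector_id!r} has no fusion weight configured"
            )
    if len(members) == 1 or all(d.box == members[0].box for d in members):
        # exact in the singleton and unanimous cases (no summation drift)
        return members[0].box
    ws = [weights[d.detector_id] for d in members]
    total = sum(ws)
    return NormBox(
        cx=sum(w * d.box.cx for w, d in zip(ws, members)) / total,
        cy=sum(w * d.box.cy for w, d in zip(ws, members)) / total,
        w=sum(w * d.box.w for w, d in zip(ws, members)) / total,
        h=sum(w * d.box.h for w, d in zip(ws, members)) / total,
    )


def pad_box(box: NormBox, params: PaddingParams) -> NormBox:
    """Extend each box boundary by ``p`` pixels and return to normalized form.

    The box is converted to pixel corners, grown by p on every side, and
    converted back; the result may extend beyond the unit square (no
    clipping).  With ``p=0`` the box is returned unchanged, bypassing
    pixel rounding entirely.
    """
    if params.p == 0:
        return box
    pix = to_pixel(box, params.image_w, params.image_h)
    from .geometry import PixelBox

    padded = PixelBox(
        pix.xmin - params.p,
        pix.ymin - params.p,
        pix.xmax + params.p,
        pix.ymax + params.p,
        pix.image_w,
        pix.image_h,
    )
    assert padded.xmin < padded.xmax and padded.ymin < padded.ymax
    return to_norm(padded)


@dataclass(frozen=True)
class ClusterAudit:
    """Record of what happened to one cluster during fusion."""

    cluster_id: int
    members: tuple[Detection, ...]
    removed: tuple[Detection, ...]
    applied_weights: dict[str, float]
    fused: NormBox
    padded: NormBox


def optimize_image_detailed(
    dets: list[Detection],
    profiles: list[DetectorProfile],
    cluster_params: ClusterParams = ClusterParams(),
    outlier_params: OutlierParams = OutlierParams(),
    padding_params: PaddingParams = PaddingParams(),
) -> list[ClusterAudit]:
    """Full per-image pipeline with an audit trail per cluster.

    Runs cluster -> filter outliers -> fuse -> pad and records, for each
    cluster, the surviving and removed members and the per-detector
    weights that entered the fusion.
    """
    weights = softmax_weights(profiles)
    audits: list[ClusterAudit] = []
    for cluster in cluster_detections(dets, cluster_params):
        refined = filter_outliers(cluster, outlier_params)
        removed = tuple(d for d in cluster.members if d not in refined.members)
        fused = fuse_cluster(refined, weights)
        padded = pad_box(fused, padding_params)
        audits.append(
            ClusterAudit(
                cluster_id=cluster.cluster_id,
                members=refined.members,
                removed=removed,
                applied_weights={
                    d.detector_id: weights[d.detector_id] for d in refined.members
                },
                fused=fused,
                padded=padded,
            )
        )
    return audits


def optimize_image(
    dets: list[Detection],
    profiles: list[DetectorProfile],
    cluster_params: ClusterParams = ClusterParams(),
    outlier_params: OutlierParams = OutlierParams(),
    padding_params: PaddingParams = PaddingParams(),
) -> list[NormBox]:
    """One padded representative box per cluster, ordered by cluster id."""
    return [
        a.padded
        for a in optimize_image_detailed(
            dets, profiles, cluster_params, outlier_params, padding_params
        )
    ]
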