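"""Group multi-detector detections into lesion-hypothesis clusters.

Detections from all detectors of the ensemble are clustered with DBSCAN
on their normalized box centers ``(cx, cy)`` under Euclidean distance.
Defaults (``eps=0.1``, ``min_samples=1``) are tuned so that boxes fired at
the same lesion by different detectors land in one cluster while isolated
boxes survive as their own cluster.

A deliberate departure from textbook DBSCAN: points DBSCAN would label as
noise are *retained* as singleton clusters rather than discarded.  In a
screening setting a lone detection may be the only evidence of a lesion,
so sparse boxes are treated as important data.  With ``min_samples=1``
DBSCAN produces no noise by construction, but the reassignment branch is
implemented so the behavior holds for any configuration.

Output is fully deterministic: detections are pre-sorted by
``(cx, cy, detector_id)`` before clustering (fixing border-point
tie-breaks), and cluster ids are assigned by ascending
``(min member cx, min member cy)``.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from sklearn.cluster import DBSCAN

from .geometry import NormBox

__all__ = ["Detection", "Cluster", "ClusterParams", "cluster_detections"]


@dataclass(frozen=True)
class Detection:
    """One box emitted by one detector, with optional confidence and class.

    ``class_id`` carries the detector's raw class prediction when the
    annotation format provides one; fusion ignores it except to propagate
    a majority label into fused output files.
    """

    box: NormBox
    detector_id: str
    confidence: float | None = None
    class_id: int | None = None

    def __post_init__(self) -> None:
        if self.confidence is not None and not (0.0 <= self.confidence <= 1.0):
            raise ValueError(f"confidence {self.confidence} outside [0, 1]")


@dataclass(frozen=True)
class Cluster:
    """A non-empty group of detections treated as one lesion hypothesis."""

    cluster_id: int
    members: tuple[Detection, ...]

    def __post_init__(self) -> None:
        if not self.members:
            raise ValueError("cluster must have at least one member")


@dataclass(frozen=True)
class ClusterParams:
    """DBSCAN parameters on normalized center coordinates."""

    eps: float = 0.1
    min_samples: int = 1

    def __post_init__(self) -> None:
        if self.eps <= 0.0:
            raise ValueError(f"eps must be positive, got {self.eps}")
        if self.min_samples < 1:
            raise ValueError(f"min_samples must be >= 1, got {self.min_samples}")


def cluster_detections(
    dets: list[Detection], params: ClusterParams = ClusterParams()
) -> list[Cluster]:
    """Partition detections into clusters by DBSCAN on box centers.

    Every input detection lands in exactly one output cluster; noise
    points become singleton clusters.  Empty input yields an empty list.
    """
    if not dets:
        return []
    ordered = sorted(dets, key=lambda d: (d.box.cx, d.box.cy, str(d.detector_id)))
    centers = np.array([[d.box.cx, d.box.cy] for d in ordered], dtype=float)
    labels = DBSCAN(eps=params.eps, min_samples=params.min_samples).fit_predict(
        centers
    )

    # Noise points (-1) are reassigned to fresh singleton clusters.
    next_label = int(labels.max()) + 1 if (labels >= 0).any() else 0
    groups: dict[int, list[Detection]] = {}
    for det, lab in zip(ordered, labels):
        lab = int(lab)
        if lab < 0:
            lab = next_label
            next_label += 1
        groups.setdefault(lab, []).append(det)

    def sort_key(members: list[Detection]) -> tuple[float, float]:
        return (min(d.box.cx for d in members), min(d.box.cy for d in members))

    clusters = sorted(groups.values(), key=sort_key)
    return [
        Cluster(cluster_id=i, members=tuple(members))
        for i, members in enumerate(clusters)
    ]
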