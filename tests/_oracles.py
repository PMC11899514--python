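"""Independent reference implementations used to cross-check the package.

These stay deliberately naive — rasterized area counting and O(n²)
neighborhood-expansion DBSCAN — so they share no code path with the
implementations they verify.
"""

from __future__ import annotations

import numpy as np

from smwbf.geometry import NormBox


def rasterized_iou(a: NormBox, b: NormBox, grid: int = 1000) -> float:
    """IoU by antialiased rasterization on a grid x grid pixel lattice.

    Each pixel holds its fractional coverage by the box (separable per
    axis); intersections take the per-pixel minimum of coverages.
    """
    edges = np.arange(grid + 1) / grid

    def coverage(lo: float, hi: float) -> np.ndarray:
        return np.clip(np.minimum(edges[1:], hi) - np.maximum(edges[:-1], lo), 0.0, None)

    ax0, ay0, ax1, ay1 = a.corners
    bx0, by0, bx1, by1 = b.corners
    ax, ay = coverage(ax0, ax1), coverage(ay0, ay1)
    bx, by = coverage(bx0, bx1), coverage(by0, by1)
    inter = np.minimum(ax, bx).sum() * np.minimum(ay, by).sum()
    area_a = ax.sum() * ay.sum()
    area_b = bx.sum() * by.sum()
    union = area_a + area_b - inter
    return float(inter / union) if union else 0.0


def brute_force_dbscan(
    points: np.ndarray, eps: float, min_samples: int
) -> tuple[list[set[int]], set[int], set[int]]:
    """Textbook DBSCAN by explicit neighborhood expansion.

    Returns (clusters as index sets, core point indices, noise indices).
    Border points reachable from several clusters are assigned to the
    first cluster (by scan order) that reaches them.
    """
    n = len(points)
    d = np.sqrt(((points[:, None, :] - points[None, :, :]) ** 2).sum(-1))
    neighbors = [set(np.flatnonzero(d[i] <= eps)) for i in range(n)]
    core = {i for i in range(n) if len(neighbors[i]) >= min_samples}

    labels = [None] * n
    clusters: list[set[int]] = []
    for i in range(n):
        if labels[i] is not None or i not in core:
            continue
        cluster = {i}
        labels[i] = len(clusters)
        frontier = [i]
        while frontier:
            j = frontier.pop()
            for k in neighbors[j]:
                if labels[k] is None:
                    labels[k] = len(clusters)
                    cluster.add(k)
                    if k in core:
                        frontier.append(k)
        clusters.append(cluster)
    noise = {i for i in range(n) if labels[i] is None}
    return clusters, core, noise
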