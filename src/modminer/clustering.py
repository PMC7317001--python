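"""Compactness (density) clustering of key genes over the CCRS distance matrix.

A DBSCAN-style procedure: a gene is a *core point* when strictly more than
``min_pts`` other genes lie within radius ``eps`` of it; clusters are the
density-reachability components grown from core points by stack expansion;
non-core genes within ``eps`` of a core point become *border points* of that
core's cluster; everything else is *noise*. Masked (path-less) distances are
treated as infinite, so key genes disconnected from the rest become noise.

Both parameters can be determined automatically from the data: ``min_pts``
from the sample-size rule max(2, ceil(ln n)) and ``eps`` from the knee of
the sorted min_pts-nearest-neighbor distance curve.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .ccrs import DistanceMatrix

logger = logging.getLogger(__name__)

__all__ = ["ClusteringParams", "ModuleAssignment", "auto_parameters", "cluster_modules"]

NOISE = -1


@dataclass(frozen=True)
class ClusteringParams:
    eps: float
    min_pts: int

    def __post_init__(self) -> None:
        if self.eps <= 0:
            raise ValueError("eps must be positive")
        if self.min_pts < 1:
            raise ValueError("min_pts must be >= 1")


@dataclass(frozen=True, eq=False)
class ModuleAssignment:
    """Cluster labels per key gene; label -1 marks noise."""

    key_gene_ids: list
    labels: np.ndarray
    point_types: list  # "core" | "border" | "noise" per gene

    def modules(self) -> dict[int, list]:
        out: dict[int, list] = {}
        for gene, label in zip(self.key_gene_ids, self.labels):
            if label != NOISE:
                out.setdefault(int(label), []).append(gene)
        return out

    @property
    def n_modules(self) -> int:
        return len(set(self.labels[self.labels != NOISE]))

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {"gene_id": self.key_gene_ids, "cluster": self.labels, "point_type": self.point_types}
        )


def _dense_distances(D: DistanceMatrix) -> np.ndarray:
    values = D.values.copy().astype(float)
    values[D.mask] = np.inf
    np.fill_diagonal(values, 0.0)
    return values


def auto_parameters(D: DistanceMatrix) -> ClusteringParams:
    """Data-driven scan radius and compactness threshold.

    ``min_pts = max(2, ceil(ln n))``; ``eps`` comes from the ascending
    min_pts-nearest-neighbor distance curve: the knee is the point of maximum
    distance to the chord joining the curve's endpoints (ties resolved toward
    the largest index), and eps is the midpoint between the knee value and
    the next strictly larger curve value, which places the radius between two
    separated distance scales. Infinite (masked) neighbor distances are
    excluded from the curve.
    """
    n = len(D.key_gene_ids)
    if n < 5:
        raise ValueError("automatic parameter selection needs at least 5 key genes")
    dist = _dense_distances(D)
    min_pts = max(2, int(np.ceil(np.log(n))))

    kdist = []
    for i in range(n):
        others = np.sort(np.delete(dist[i], i))
        if min_pts <= len(others):
            kdist.append(others[min_pts - 1])
    curve = np.sort([d for d in kdist if np.isfinite(d)])
    if curve.size == 0:
        raise ValueError("all key-gene distances are masked; cannot choose eps")

    if curve.size == 1 or curve[0] == curve[-1]:
        eps = float(curve[-1])
    else:
        x = np.arange(curve.size, dtype=float)
        # distance from each curve point to the chord (first -> last point)
        dx, dy = x[-1] - x[0], curve[-1] - curve[0]
        norm = np.hypot(dx, dy)
        dev = np.abs(dy * (x - x[0]) - dx * (curve - curve[0])) / norm
        knee = int(np.flatnonzero(dev == dev.max())[-1])
        larger = curve[curve > curve[knee]]
        eps = float((curve[knee] + larger[0]) / 2.0) if larger.size else float(curve[knee])
    logger.info("auto_parameters: n=%d, min_pts=%d, eps=%.4g", n, min_pts, eps)
    return ClusteringParams(eps=eps, min_pts=min_pts)


def cluster_modules(D: DistanceMatrix, params: ClusteringParams) -> ModuleAssignment:
    """Density clustering of the key-gene distance matrix.

    Core points have strictly more than ``min_pts`` neighbors within ``eps``
    (the point itself not counted). Clusters grow from unvisited core points
    by stack expansion through core neighbors; border points attach to the
    cluster of their nearest core point, ties broken toward the smallest
    cluster id. Cluster ids are canonicalized by each cluster's
    lexicographically smallest member, so the output is invariant to input
    ordering.
    """
    values = D.values
    finite = ~D.mask
    if not np.allclose(values[finite & finite.T], values.T[finite & finite.T]):
        raise ValueError("distance matrix must be symmetric")
    if not np.array_equal(D.mask, D.mask.T):
        raise ValueError("distance mask must be symmetric")
    dist = _dense_distances(D)
    n = len(D.key_gene_ids)
    eps, m = params.eps, params.min_pts

    neighbors = [np.flatnonzero((dist[i] <= eps) & (np.arange(n) != i)) for i in range(n)]
    is_core = np.array([len(nb) > m for nb in neighbors])

    labels = np.full(n, NOISE, dtype=int)
    visited = np.zeros(n, dtype=bool)
    cluster_id = 0
    for p in range(n):
        if not is_core[p] or visited[p]:
            continue
        visited[p] = True
        labels[p] = cluster_id
        stack = [p]
        while stack:
            v = stack.pop()
            for q in neighbors[v]:
                if is_core[q] and not visited[q]:
                    visited[q] = True
                    labels[q] = cluster_id
                    stack.append(q)
        cluster_id += 1

    # canonical ids: clusters ordered by their smallest member gene id
    if cluster_id > 0:
        order = sorted(
            range(cluster_id),
            key=lambda c: min(D.key_gene_ids[i] for i in np.flatnonzero(labels == c)),
        )
        remap = {old: new for new, old in enumerate(order)}
        labels = np.array([remap[l] if l != NOISE else NOISE for l in labels])

    point_types = ["core" if is_core[i] else "noise" for i in range(n)]
    for b in range(n):
        if is_core[b]:
            continue
        core_nb = [q for q in neighbors[b] if is_core[q]]
        if not core_nb:
            continue
        best = min(core_nb, key=lambda q: (dist[b, q], labels[q]))
        labels[b] = labels[best]
        point_types[b] = "border"

    return ModuleAssignment(list(D.key_gene_ids), labels, point_types)
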