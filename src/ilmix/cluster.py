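"""Cutoff clustering with periodic boundaries, percolation and shape.

Molecules are "clustered" when their center-center minimum-image distance
is strictly below the cutoff (the radius of the first solvation shell:
9.1 A for TBPH cation pairs, 9.3 A for TBPCl; the water-water cutoff
defaults to the 3.5 A hydrogen-bond donor-acceptor distance and can be
derived from the first minimum of the water O-O RDF instead).

A cluster "spans" a dimension — a water vein — when a cycle in its
contact graph accumulates a nonzero net periodic image shift along that
dimension (the standard wrapping-cluster test).
"""

from __future__ import annotations

from collections import deque
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.sparse import coo_matrix
from scipy.sparse.csgraph import connected_components
from scipy.spatial import cKDTree

from .trajectory import minimum_image, wrap_positions

__all__ = [
    "ClusterResult",
    "cluster",
    "mean_neighbors",
    "spanning",
    "shape_metrics",
    "classify_cluster",
    "percolation_curve",
]


@dataclass
class ClusterResult:
    labels: np.ndarray  # per-particle cluster label
    sizes: np.ndarray  # per-cluster member count
    largest_label: int
    largest_fraction: float
    neighbor_counts: np.ndarray  # per-particle degree in the contact graph
    mean_neighbors_largest: float
    spanning: np.ndarray  # (n_clusters, 3) bool
    asphericity: np.ndarray  # per cluster, in [0, 1]
    radius_of_gyration: np.ndarray  # per cluster, A
    cutoff: float

    @property
    def n_clusters(self) -> int:
        return len(self.sizes)

    @property
    def spanning_largest(self) -> tuple[bool, bool, bool]:
        return tuple(bool(v) for v in self.spanning[self.largest_label])


def _contact_pairs(
    points: np.ndarray, box: np.ndarray, cutoff: float
) -> tuple[np.ndarray, np.ndarray]:
    """Unordered index pairs at minimum-image distance strictly < cutoff."""
    wrapped = wrap_positions(points, box)
    tree = cKDTree(wrapped, boxsize=box)
    pairs = tree.query_pairs(cutoff, output_type="ndarray")
    if len(pairs) == 0:
        return pairs.reshape(0, 2), np.empty(0)
    d = minimum_image(points[pairs[:, 0]] - points[pairs[:, 1]], box)
    dist = np.linalg.norm(d, axis=1)
    keep = dist < cutoff  # strict inequality per the clustering definition
    return pairs[keep], dist[keep]


def cluster(points: np.ndarray, box: np.ndarray, cutoff: float) -> ClusterResult:
    """Connected components of the cutoff contact graph under PBC."""
    points = np.asarray(points, dtype=float).reshape(-1, 3)
    box = np.asarray(box, dtype=float).reshape(3)
    if cutoff >= box.min() / 2.0:
        raise ValueError(
            f"cutoff {cutoff} >= half the smallest box edge {box.min() / 2.0}"
        )
    n = len(points)
    if n == 0:
        raise ValueError("no points to cluster")
    pairs, _ = _contact_pairs(points, box, cutoff)
    i = pairs[:, 0]
    j = pairs[:, 1]
    adj = coo_matrix(
        (np.ones(2 * len(pairs)), (np.r_[i, j], np.r_[j, i])), shape=(n, n)
    )
    n_clusters, labels = connected_components(adj, directed=False)
    sizes = np.bincount(labels, minlength=n_clusters)
    largest = int(np.argmax(sizes))
    degree = np.zeros(n, dtype=int)
    np.add.at(degree, i, 1)
    np.add.at(degree, j, 1)
    mean_nn = float(degree[labels == largest].mean())
    adjacency = [[] for _ in range(n)]
    for a, b in pairs:
        adjacency[a].append(b)
        adjacency[b].append(a)
    span = np.zeros((n_clusters, 3), dtype=bool)
    asph = np.zeros(n_clusters)
    rg = np.zeros(n_clusters)
    unwrapped = _unwrap_clusters(points, box, labels, adjacency, span)
    for c in range(n_clusters):
        members = np.where(labels == c)[0]
        a, r = _gyration(unwrapped[members])
        asph[c] = a
        rg[c] = r
    return ClusterResult(
        labels=labels,
        sizes=sizes,
        largest_label=largest,
        largest_fraction=float(sizes[largest] / n),
        neighbor_counts=degree,
        mean_neighbors_largest=mean_nn,
        spanning=span,
        asphericity=asph,
        radius_of_gyration=rg,
        cutoff=float(cutoff),
    )


def _unwrap_clusters(
    points: np.ndarray,
    box: np.ndarray,
    labels: np.ndarray,
    adjacency: list[list[int]],
    span_out: np.ndarray,
) -> np.ndarray:
    """BFS over each cluster's contact graph, assigning continuous
    coordinates via minimum-image steps; a revisited node whose assigned
    coordinate disagrees by a box multiple marks a wrapping cluster."""
    n = len(points)
    unwrapped = points.copy()
    visited = np.zeros(n, dtype=bool)
    for start in range(n):
        if visited[start]:
            continue
        c = labels[start]
        visited[start] = True
        queue = deque([start])
        while queue:
            a = queue.popleft()
            for b in adjacency[a]:
                step = minimum_image(points[b] - points[a], box)
                expected = unwrapped[a] + step
                if visited[b]:
                    diff = expected - unwrapped[b]
                    wraps = np.abs(diff) > box / 2.0
                    span_out[c] |= wraps
                else:
                    unwrapped[b] = expected
                    visited[b] = True
                    queue.append(b)
    return unwrapped


def _gyration(coords: np.ndarray) -> tuple[float, float]:
    """(asphericity, radius of gyration) from the gyration tensor.

    Asphericity b = lambda1 - (lambda2 + lambda3)/2 normalized by the
    trace: 1 for collinear points, 0 for spherical symmetry (and for a
    single point, by convention).
    """
    if len(coords) < 2:
        return 0.0, 0.0
    centered = coords - coords.mean(axis=0)
    tensor = centered.T @ centered / len(coords)
    lam = np.sort(np.linalg.eigvalsh(tensor))[::-1]
    trace = lam.sum()
    if trace <= 0:
        return 0.0, 0.0
    b = lam[0] - 0.5 * (lam[1] + lam[2])
    return float(b / trace), float(np.sqrt(trace))


def shape_metrics(
    points: np.ndarray, box: np.ndarray, cutoff: float | None = None
) -> tuple[float, float]:
    """Asphericity and radius of gyration of one cluster's points.

    When ``cutoff`` is given the points are first made continuous along
    the cluster's contact graph (minimum-image unwrapping); otherwise
    they are taken as already continuous.
    """
    points = np.asarray(points, dtype=float).reshape(-1, 3)
    if cutoff is not None:
        box = np.asarray(box, dtype=float).reshape(3)
        pairs, _ = _contact_pairs(points, box, cutoff)
        adjacency: list[list[int]] = [[] for _ in range(len(points))]
        for a, b in pairs:
            adjacency[a].append(b)
            adjacency[b].append(a)
        span = np.zeros((len(points), 3), dtype=bool)
        labels = np.zeros(len(points), dtype=int)
        points = _unwrap_clusters(points, box, labels, adjacency, span)
    return _gyration(points)


def mean_neighbors(
    points: np.ndarray,
    box: np.ndarray,
    cutoff: float,
    restrict_to_largest: bool = True,
) -> float:
    """Average contact-graph degree, over the largest cluster's members
    (the reported "neighbors in the largest cluster") or over all points."""
    result = cluster(points, box, cutoff)
    if restrict_to_largest:
        return result.mean_neighbors_largest
    return float(result.neighbor_counts.mean())


def spanning(points: np.ndarray, box: np.ndarray, cutoff: float) -> np.ndarray:
    """Per-cluster (x, y, z) wrapping flags."""
    return cluster(points, box, cutoff).spanning


def classify_cluster(
    result: ClusterResult,
    label: int | None = None,
    vein_asphericity: float = 0.5,
    globule_asphericity: float = 0.3,
) -> str:
    """Label a cluster "vein", "globule" or "intermediate".

    A vein spans at least one dimension and is elongated (asphericity
    above ``vein_asphericity``); a globule is non-spanning and compact
    (asphericity below ``globule_asphericity``).
    """
    c = result.largest_label if label is None else label
    spans = bool(result.spanning[c].any())
    a = result.asphericity[c]
    if spans and a > vein_asphericity:
        return "vein"
    if not spans and a < globule_asphericity:
        return "globule"
    return "intermediate"


def percolation_curve(
    configs: list[tuple[float, np.ndarray, np.ndarray]], cutoff: float
) -> pd.DataFrame:
    """Clustering summary across a composition sweep.

    ``configs`` is a list of (mol% water, points, box).  Returns a tidy
    table with the largest-cluster fraction, mean neighbor count in the
    largest cluster, and whether any cluster spans any dimension.
    """
    rows = []
    for mol_pct, points, box in configs:
        res = cluster(points, box, cutoff)
        rows.append(
            {
                "mol_pct_water": mol_pct,
                "largest_fraction": res.largest_fraction,
                "mean_neighbors": res.mean_neighbors_largest,
                "spanning_fraction": float(res.spanning.any(axis=1).mean()),
                "spans_any": bool(res.spanning.any()),
                "n_clusters": res.n_clusters,
            }
        )
    return pd.DataFrame(rows)
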