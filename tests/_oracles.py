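"""Independent brute-force reference implementations used only by tests.

Deliberately naive (double/triple loops, explicit minimum imaging) so
they share no code path with the package's KD-tree / FFT / sparse-graph
implementations.
"""

from __future__ import annotations

import numpy as np


def min_image(d: np.ndarray, box: np.ndarray) -> np.ndarray:
    return d - box * np.round(d / box)


def brute_pair_distances(points_a, points_b, box, same: bool) -> np.ndarray:
    """All unordered pair distances (minimum image)."""
    out = []
    na, nb = len(points_a), len(points_b)
    for i in range(na):
        for j in range((i + 1) if same else 0, nb):
            d = min_image(points_a[i] - points_b[j], box)
            out.append(np.sqrt(float(d @ d)))
    return np.array(out)


def brute_cluster_labels(points, box, cutoff) -> np.ndarray:
    """Union-find over every pair with distance strictly below cutoff."""
    n = len(points)
    parent = list(range(n))

    def find(a):
        while parent[a] != a:
            parent[a] = parent[parent[a]]
            a = parent[a]
        return a

    for i in range(n):
        for j in range(i + 1, n):
            d = min_image(points[i] - points[j], box)
            if float(d @ d) < cutoff**2:
                ri, rj = find(i), find(j)
                if ri != rj:
                    parent[ri] = rj
    roots = np.array([find(i) for i in range(n)])
    return np.unique(roots, return_inverse=True)[1]


def same_partition(labels_a: np.ndarray, labels_b: np.ndarray) -> bool:
    """True when two labelings induce the same partition."""
    a = np.unique(labels_a, return_inverse=True)[1]
    b = np.unique(labels_b, return_inverse=True)[1]
    pairs = set(zip(a.tolist(), b.tolist()))
    return len(pairs) == len(np.unique(a)) == len(np.unique(b))


def brute_hbonds(frame, topology, d_ha=2.45, angle_deg=30.0, d_da=3.5):
    """Triple-loop geometric hydrogen-bond detection (donor-vertex angle)."""
    pos = frame.positions
    box = frame.box
    found = []
    for d, h in topology.donors:
        for a in topology.acceptors:
            a = int(a)
            if a in (int(d), int(h)):
                continue
            if topology.molecule_id[a] == topology.molecule_id[d]:
                continue
            v_da = min_image(pos[a] - pos[d], box)
            if np.linalg.norm(v_da) > d_da:
                continue
            v_ha = min_image(pos[a] - pos[h], box)
            if np.linalg.norm(v_ha) > d_ha:
                continue
            v_dh = min_image(pos[h] - pos[d], box)
            cosang = v_dh @ v_da / (np.linalg.norm(v_dh) * np.linalg.norm(v_da))
            if np.degrees(np.arccos(np.clip(cosang, -1, 1))) <= angle_deg + 1e-9:
                found.append((int(d), int(h), int(a)))
    return found


def brute_tamsd(track: np.ndarray, lags: np.ndarray) -> np.ndarray:
    """Window-by-window TAMSD for one track."""
    f = len(track)
    out = np.zeros(len(lags))
    for k, m in enumerate(lags):
        if m == 0:
            continue
        acc = 0.0
        for start in range(f - m):
            d = track[start + m] - track[start]
            acc += float(d @ d)
        out[k] = acc / (f - m)
    return out


def brute_neighbor_counts(points, box, cutoff) -> np.ndarray:
    n = len(points)
    counts = np.zeros(n, dtype=int)
    for i in range(n):
        for j in range(i + 1, n):
            d = min_image(points[i] - points[j], box)
            if float(d @ d) < cutoff**2:
                counts[i] += 1
                counts[j] += 1
    return counts
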