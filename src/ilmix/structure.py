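"""Radial distribution functions under periodic boundaries.

RDFs are computed between per-molecule "center" atoms (P for the cation,
O for hydroxide and water, terminal butyl carbons for chain-conformation
analysis), histogramming minimum-image pair distances and normalizing by
the ideal-gas shell count 4 pi r^2 dr rho_B per center of the first
species per frame.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.signal import find_peaks, savgol_filter
from scipy.spatial import cKDTree

from .trajectory import CENTER_ROLES, Topology, Trajectory, wrap_positions

__all__ = [
    "RDFResult",
    "rdf",
    "rdf_c4c4",
    "first_shell_minimum",
    "coordination_number",
]


@dataclass
class RDFResult:
    r: np.ndarray  # bin centers, A
    g: np.ndarray
    pair: tuple[str, str]
    r_max: float
    dr: float
    n_frames: int
    includes_intramolecular: bool
    rho_b: float  # mean number density of the second species, A^-3
    n_a: int
    n_b: int

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame({"r": self.r, "g": self.g})


def _select(topology: Topology, species: str) -> np.ndarray:
    """Atom indices for a species center role or an explicit role tag."""
    if species in CENTER_ROLES:
        return topology.center_indices(species)
    idx = np.where(topology.role == species)[0]
    if len(idx) == 0:
        raise ValueError(f"no atoms with role or species {species!r}")
    return idx


def rdf(
    traj: Trajectory,
    topology: Topology,
    species_a: str,
    species_b: str,
    r_max: float | None = None,
    dr: float = 0.1,
    exclude_same_molecule: bool = True,
) -> RDFResult:
    """g(r) between the centers of two species.

    ``species_a``/``species_b`` are either species names with a defined
    center role ("cation", "anion", "water") or explicit role tags (e.g.
    "terminal_carbon").  Same-species pairs are counted once with the
    N(N-1) normalization; the self pair is always excluded.
    """
    idx_a = _select(topology, species_a)
    idx_b = _select(topology, species_b)
    same = species_a == species_b
    min_edge = min(float(f.box.min()) for f in traj.frames)
    if r_max is None:
        r_max = min_edge / 2.0 - 1e-9
    if r_max > min_edge / 2.0:
        raise ValueError(
            f"r_max={r_max} exceeds half the smallest box edge ({min_edge / 2.0}); "
            "minimum-image distances are undefined beyond it"
        )
    nbins = int(np.floor(r_max / dr))
    edges = np.arange(nbins + 1) * dr
    hist = np.zeros(nbins)
    rho_sum = 0.0
    mol_a = topology.molecule_id[idx_a]
    mol_b = topology.molecule_id[idx_b]
    for f in traj.frames:
        box = f.box
        pa = wrap_positions(f.positions[idx_a], box)
        pb = wrap_positions(f.positions[idx_b], box)
        if same:
            tree = cKDTree(pa, boxsize=box)
            pairs = tree.query_pairs(r_max, output_type="ndarray")
            if len(pairs):
                i, j = pairs[:, 0], pairs[:, 1]
                if exclude_same_molecule:
                    keep = mol_a[i] != mol_a[j]
                    i, j = i[keep], j[keep]
                d = pa[i] - pb[j]
                d -= box * np.round(d / box)
                dist = np.linalg.norm(d, axis=1)
                hist += np.histogram(dist, bins=edges)[0]
        else:
            tree_a = cKDTree(pa, boxsize=box)
            tree_b = cKDTree(pb, boxsize=box)
            sdm = tree_a.sparse_distance_matrix(
                tree_b, r_max, output_type="ndarray"
            )
            i, j, dist = sdm["i"], sdm["j"], sdm["v"]
            if exclude_same_molecule:
                keep = mol_a[i] != mol_b[j]
                dist = dist[keep]
            hist += np.histogram(dist, bins=edges)[0]
        vol = float(np.prod(box))
        rho_sum += (len(idx_b) - (1 if same else 0)) / vol
    rho_b = rho_sum / len(traj)
    shell = 4.0 / 3.0 * np.pi * (edges[1:] ** 3 - edges[:-1] ** 3)
    # per-A ideal count; same-species unordered pairs carry a factor 1/2
    norm = len(idx_a) * shell * rho_b * len(traj)
    if same:
        norm = norm / 2.0
    with np.errstate(invalid="ignore", divide="ignore"):
        g = np.where(norm > 0, hist / norm, 0.0)
    centers_r = 0.5 * (edges[1:] + edges[:-1])
    return RDFResult(
        r=centers_r,
        g=g,
        pair=(species_a, species_b),
        r_max=float(r_max),
        dr=dr,
        n_frames=len(traj),
        includes_intramolecular=not exclude_same_molecule,
        rho_b=rho_b,
        n_a=len(idx_a),
        n_b=len(idx_b),
    )


def rdf_c4c4(
    traj: Trajectory,
    topology: Topology,
    r_max: float | None = None,
    dr: float = 0.1,
) -> RDFResult:
    """Terminal-carbon (C4-C4) RDF of the cation's butyl arms.

    The intramolecular distribution of the four arms is included (the
    within-molecule pairs are the signal: an isolated cation's end-to-end
    arm distance approaches 8.2 A when the arms spread out).
    """
    return rdf(
        traj,
        topology,
        "terminal_carbon",
        "terminal_carbon",
        r_max=r_max,
        dr=dr,
        exclude_same_molecule=False,
    )


def first_shell_minimum(
    result: RDFResult, smooth_window: int = 5, polyorder: int = 2
) -> float:
    """Radius of the first solvation shell: the first local minimum of
    g(r) after its first local maximum, on a lightly smoothed curve.

    Raises ``ValueError("no shell structure")`` when g(r) has no interior
    maximum followed by a minimum (e.g. an ideal gas).
    """
    g = np.asarray(result.g, dtype=float)
    if smooth_window > 1 and len(g) > smooth_window:
        g = savgol_filter(g, smooth_window, min(polyorder, smooth_window - 1))
    span = float(g.max() - g.min())
    if span <= 1e-9:
        raise ValueError("no shell structure")
    prominence = 0.05 * span
    peaks, _ = find_peaks(g, prominence=prominence)
    if len(peaks) == 0:
        raise ValueError("no shell structure")
    p = int(peaks[0])
    minima, _ = find_peaks(-g[p:], prominence=prominence)
    if len(minima) == 0:
        raise ValueError("no shell structure")
    return float(result.r[p + int(minima[0])])


def coordination_number(result: RDFResult, rho_b: float, r_cut: float) -> float:
    """Average neighbor count within r_cut: 4 pi rho_B int_0^rcut g r^2 dr
    (trapezoid rule on the binned curve)."""
    mask = result.r <= r_cut
    r = result.r[mask]
    g = result.g[mask]
    if len(r) < 2:
        return 0.0
    # close the integration range: g r^2 -> 0 at r = 0, interpolate at r_cut
    if r[0] > 0:
        r = np.concatenate([[0.0], r])
        g = np.concatenate([[0.0], g])
    if r_cut > r[-1] and r_cut <= result.r[-1] + result.dr / 2:
        g_cut = float(np.interp(r_cut, result.r, result.g))
        r = np.concatenate([r, [r_cut]])
        g = np.concatenate([g, [g_cut]])
    return float(4.0 * np.pi * rho_b * np.trapezoid(g * r**2, r))
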