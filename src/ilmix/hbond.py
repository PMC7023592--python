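"""Geometric hydrogen-bond detection and per-pair-type counting.

A hydrogen bond D-H...A exists when all three criteria hold
(minimum-image distances):

* H...A distance <= 2.45 A,
* the angle at the donor between D->H and D->A <= 30 degrees,
* donor-acceptor distance D...A <= 3.5 A.

The donor-vertex angle convention matches the VMD-style criterion; the
hydrogen-vertex alternative is available as a switch.  A donor-acceptor
pair with two qualifying hydrogens contributes two bonds (per-H triplet
enumeration).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.spatial import cKDTree

from .trajectory import Frame, Topology, Trajectory, minimum_image, wrap_positions

__all__ = ["HBondCriteria", "HBondCount", "find_hbonds", "hbond_counts"]


@dataclass(frozen=True)
class HBondCriteria:
    d_ha_max: float = 2.45  # A, hydrogen...acceptor
    angle_max: float = 30.0  # degrees at the chosen vertex
    d_da_max: float = 3.5  # A, donor...acceptor
    angle_vertex: str = "donor"  # "donor" | "hydrogen"

    def __post_init__(self) -> None:
        if min(self.d_ha_max, self.angle_max, self.d_da_max) <= 0:
            raise ValueError("criteria must be positive")
        if self.d_ha_max >= self.d_da_max:
            raise ValueError("d_ha_max must be below d_da_max")
        if self.angle_vertex not in ("donor", "hydrogen"):
            raise ValueError("angle_vertex must be 'donor' or 'hydrogen'")


@dataclass
class HBondCount:
    pair: tuple[str, str]
    mean_per_molecule: float  # bonds per molecule of the first species
    per_frame: np.ndarray
    n_first_species: int


def find_hbonds(
    frame: Frame,
    topology: Topology,
    criteria: HBondCriteria | None = None,
) -> list[tuple[int, int, int]]:
    """All (donor, hydrogen, acceptor) triplets satisfying the criteria.

    Donor-hydrogen covalent pairs and acceptor atoms come from the
    topology; donor and acceptor must belong to different molecules.
    """
    if criteria is None:
        criteria = HBondCriteria()
    if topology.donors is None or len(topology.donors) == 0:
        raise ValueError("topology declares no donor-hydrogen pairs")
    if topology.acceptors is None or len(topology.acceptors) == 0:
        return []
    box = frame.box
    pos = frame.positions
    acceptors = topology.acceptors
    acc_tree = cKDTree(wrap_positions(pos[acceptors], box), boxsize=box)
    cos_max = np.cos(np.radians(criteria.angle_max))
    out: list[tuple[int, int, int]] = []
    donor_pos = wrap_positions(pos[topology.donors[:, 0]], box)
    cand = acc_tree.query_ball_point(donor_pos, criteria.d_da_max)
    for (d, h), nearby in zip(topology.donors, cand):
        for ai in nearby:
            a = int(acceptors[ai])
            if a == d or a == h:
                continue
            if topology.molecule_id[a] == topology.molecule_id[d]:
                continue
            v_da = minimum_image(pos[a] - pos[d], box)
            d_da = float(np.linalg.norm(v_da))
            if d_da > criteria.d_da_max:
                continue
            v_ha = minimum_image(pos[a] - pos[h], box)
            if float(np.linalg.norm(v_ha)) > criteria.d_ha_max:
                continue
            v_dh = minimum_image(pos[h] - pos[d], box)
            if criteria.angle_vertex == "donor":
                cosang = float(v_dh @ v_da) / (
                    np.linalg.norm(v_dh) * d_da
                )
            else:  # vertex at H, between H->D and H->A
                v_hd = -v_dh
                cosang = float(v_hd @ v_ha) / (
                    np.linalg.norm(v_hd) * np.linalg.norm(v_ha)
                )
            if cosang >= cos_max - 1e-12:
                out.append((int(d), int(h), a))
    return out


def hbond_counts(
    traj: Trajectory,
    topology: Topology,
    pairs: list[tuple[str, str]],
    criteria: HBondCriteria | None = None,
) -> list[HBondCount]:
    """Time-averaged bond counts per species pair.

    A pair (x, y) counts every detected bond joining a molecule of
    species x and one of species y, in either donor/acceptor direction,
    normalized by the number of x molecules ("bonds between x and y per
    molecule of x").
    """
    species = topology.species
    mol = topology.molecule_id
    n_frames = len(traj)
    per_frame = {p: np.zeros(n_frames) for p in pairs}
    n_first = {}
    for p in pairs:
        n_first[p] = len(np.unique(mol[species == p[0]]))
    for k, frame in enumerate(traj.frames):
        bonds = find_hbonds(frame, topology, criteria)
        for d, _h, a in bonds:
            sd, sa = species[d], species[a]
            for p in pairs:
                x, y = p
                if (sd == x and sa == y) or (sd == y and sa == x):
                    per_frame[p][k] += 1
    out = []
    for p in pairs:
        nx = n_first[p]
        mean = float(per_frame[p].mean() / nx) if nx else 0.0
        out.append(HBondCount(p, mean, per_frame[p], nx))
    return out


def counts_frame(counts: list[HBondCount]) -> pd.DataFrame:
    """Tidy (pair, frame, count) table for CSV export."""
    rows = []
    for c in counts:
        for k, v in enumerate(c.per_frame):
            rows.append({"pair": f"{c.pair[0]}-{c.pair[1]}", "frame": k, "count": v})
    return pd.DataFrame(rows)
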