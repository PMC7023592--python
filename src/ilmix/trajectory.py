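"""In-memory containers for trajectories, topology and thermodynamic series.

Conventions (fixed once, converted at the boundary):

* coordinates and box edges in angstrom, time in ps, density in g/cm^3;
* orthorhombic boxes only — the three edge lengths; triclinic cells are
  rejected loudly by the readers;
* wrapped coordinates live on the half-open interval [0, L) per axis;
* all distance computations downstream use the minimum-image convention.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field, replace
from typing import Iterator, Sequence

import numpy as np
import pandas as pd

__all__ = [
    "Frame",
    "Trajectory",
    "Topology",
    "ThermoSeries",
    "minimum_image",
    "wrap_positions",
    "unwrap",
    "wrap",
    "centers",
]

CENTER_ROLES = {
    "cation": "cation_center",
    "anion": "anion_center",
    "water": "water_center",
}


def minimum_image(delta: np.ndarray, box: np.ndarray) -> np.ndarray:
    """Minimum-image displacement(s) for an orthorhombic box."""
    box = np.asarray(box, dtype=float)
    return delta - box * np.round(delta / box)


def wrap_positions(positions: np.ndarray, box: np.ndarray) -> np.ndarray:
    """Wrap coordinates into [0, L) per axis."""
    box = np.asarray(box, dtype=float)
    wrapped = np.mod(positions, box)
    # np.mod can return L for tiny negative inputs due to rounding
    return np.where(wrapped >= box, wrapped - box, wrapped)


@dataclass
class Topology:
    """Per-atom molecular metadata.

    roles name the per-molecule "center" atoms used as center-of-mass
    proxies: the central P of the tetrabutylphosphonium cation, the O of
    hydroxide and of water.  ``donors`` lists covalent (donor, hydrogen)
    atom-index pairs for hydrogen-bond detection; ``acceptors`` lists
    acceptor atom indices.
    """

    molecule_id: np.ndarray  # (N,) int
    species: np.ndarray  # (N,) str, e.g. "cation" | "anion" | "water"
    role: np.ndarray  # (N,) str: *_center | "terminal_carbon" | "other"
    donors: np.ndarray | None = None  # (M, 2) int: (donor atom, attached H)
    acceptors: np.ndarray | None = None  # (K,) int

    def __post_init__(self) -> None:
        self.molecule_id = np.asarray(self.molecule_id, dtype=int)
        self.species = np.asarray(self.species, dtype=object)
        self.role = np.asarray(self.role, dtype=object)
        n = len(self.molecule_id)
        if len(self.species) != n or len(self.role) != n:
            raise ValueError("topology arrays must have equal length")
        if self.donors is not None:
            self.donors = np.asarray(self.donors, dtype=int).reshape(-1, 2)
        if self.acceptors is not None:
            self.acceptors = np.asarray(self.acceptors, dtype=int)
        # at most one center atom per molecule and role
        for role in CENTER_ROLES.values():
            mask = self.role == role
            mols = self.molecule_id[mask]
            if len(mols) != len(np.unique(mols)):
                raise ValueError(f"molecule with more than one {role} atom")

    @property
    def n_atoms(self) -> int:
        return len(self.molecule_id)

    def center_indices(self, species: str) -> np.ndarray:
        """Atom indices of the center atoms of a species, molecule-sorted."""
        role = CENTER_ROLES.get(species, species)
        idx = np.where(self.role == role)[0]
        if len(idx) == 0:
            raise ValueError(f"no atoms with center role for species {species!r}")
        return idx[np.argsort(self.molecule_id[idx], kind="stable")]


@dataclass
class Frame:
    """One snapshot: time (ps), box edges (A), positions (N, 3) (A)."""

    time: float
    box: np.ndarray
    positions: np.ndarray
    image_flags: np.ndarray | None = None

    def __post_init__(self) -> None:
        self.box = np.asarray(self.box, dtype=float).reshape(3)
        self.positions = np.asarray(self.positions, dtype=float)
        if self.positions.ndim != 2 or self.positions.shape[1] != 3:
            raise ValueError("positions must be (N, 3)")
        if not np.all(self.box > 0):
            raise ValueError("box edge lengths must be positive")
        if not np.all(np.isfinite(self.positions)):
            raise ValueError("non-finite coordinates")
        if self.image_flags is not None:
            self.image_flags = np.asarray(self.image_flags, dtype=int)
            if self.image_flags.shape != self.positions.shape:
                raise ValueError("image_flags must match positions shape")

    @property
    def n_atoms(self) -> int:
        return self.positions.shape[0]


@dataclass
class Trajectory:
    """Ordered frames with constant particle count and increasing times."""

    frames: list[Frame]
    topology: Topology | None = None
    wrapped: bool = True

    def __post_init__(self) -> None:
        if not self.frames:
            raise ValueError("empty trajectory")
        n = self.frames[0].n_atoms
        times = [f.time for f in self.frames]
        for f in self.frames:
            if f.n_atoms != n:
                raise ValueError("particle count varies across frames")
        if np.any(np.diff(times) <= 0):
            raise ValueError("frame times must be strictly increasing")
        if self.topology is not None and self.topology.n_atoms != n:
            raise ValueError("topology size does not match trajectory")

    def __len__(self) -> int:
        return len(self.frames)

    def __iter__(self) -> Iterator[Frame]:
        return iter(self.frames)

    @property
    def n_atoms(self) -> int:
        return self.frames[0].n_atoms

    @property
    def times(self) -> np.ndarray:
        return np.array([f.time for f in self.frames])

    @property
    def boxes(self) -> np.ndarray:
        return np.array([f.box for f in self.frames])

    @property
    def coordinates(self) -> np.ndarray:
        """(n_frames, n_atoms, 3) coordinate array."""
        return np.array([f.positions for f in self.frames])

    @classmethod
    def from_arrays(
        cls,
        times: Sequence[float],
        box: np.ndarray,
        coords: np.ndarray,
        topology: Topology | None = None,
        wrapped: bool = True,
    ) -> "Trajectory":
        """Build from a (F, N, 3) array and a shared or per-frame box."""
        coords = np.asarray(coords, dtype=float)
        box = np.asarray(box, dtype=float)
        boxes = np.tile(box, (len(times), 1)) if box.ndim == 1 else box
        frames = [Frame(float(t), boxes[i], coords[i]) for i, t in enumerate(times)]
        return cls(frames, topology=topology, wrapped=wrapped)


def unwrap(traj: Trajectory) -> Trajectory:
    """Remove periodic jumps, producing continuous coordinates.

    Uses image flags when present; otherwise accumulates minimum-image
    frame-to-frame displacements (valid when true per-step displacements
    are below half a box edge).  The first frame's coordinates are kept.
    """
    if not traj.wrapped:
        return traj
    frames: list[Frame] = []
    prev_wrapped = None
    current = None
    for k, f in enumerate(traj.frames):
        if f.image_flags is not None:
            pos = f.positions + f.image_flags * f.box
            current = pos if current is None else pos
            prev_wrapped = f.positions
        else:
            if current is None:
                current = f.positions.copy()
                prev_wrapped = f.positions
            else:
                delta = f.positions - prev_wrapped
                step = minimum_image(delta, f.box)
                big = np.abs(step) >= f.box / 2.0
                if np.any(big):
                    atom, dim = np.argwhere(big)[0]
                    warnings.warn(
                        f"frame {k}, atom {atom}: step displacement "
                        f">= box/2 along axis {dim}; unwrapping is ambiguous "
                        "without image flags",
                        stacklevel=2,
                    )
                current = current + step
                prev_wrapped = f.positions
        frames.append(Frame(f.time, f.box.copy(), np.array(current)))
    return Trajectory(frames, topology=traj.topology, wrapped=False)


def wrap(traj: Trajectory) -> Trajectory:
    """Wrap all coordinates into [0, L)."""
    frames = [
        Frame(f.time, f.box.copy(), wrap_positions(f.positions, f.box))
        for f in traj.frames
    ]
    return Trajectory(frames, topology=traj.topology, wrapped=True)


def centers(traj: Trajectory, topology: Topology, species: str) -> Trajectory:
    """Per-molecule center trajectory for a species.

    Molecular centers of mass are approximated by a single representative
    atom: the central P for the cation and the O for hydroxide and water.
    Returns one pseudo-particle per molecule of the species, carrying the
    coordinates of its center-role atom.
    """
    idx = topology.center_indices(species)
    frames = [
        Frame(f.time, f.box.copy(), f.positions[idx]) for f in traj.frames
    ]
    mol_ids = topology.molecule_id[idx]
    sub_top = Topology(
        molecule_id=mol_ids,
        species=np.array([species] * len(idx), dtype=object),
        role=np.array([CENTER_ROLES.get(species, species)] * len(idx), dtype=object),
    )
    return Trajectory(frames, topology=sub_top, wrapped=traj.wrapped)


@dataclass
class ThermoSeries:
    """Tabular thermodynamic time series from an MD log.

    Enthalpy basis (total vs per-mole-of-system) is whatever the producer
    declared; this container only enforces shape and finiteness.
    """

    time: np.ndarray
    enthalpy: np.ndarray | None = None
    volume: np.ndarray | None = None
    density: np.ndarray | None = None
    temperature: np.ndarray | None = None
    pressure: np.ndarray | None = None

    _COLUMNS = ("time", "enthalpy", "volume", "density", "temperature", "pressure")

    def __post_init__(self) -> None:
        self.time = np.asarray(self.time, dtype=float)
        n = len(self.time)
        for name in self._COLUMNS[1:]:
            v = getattr(self, name)
            if v is None:
                continue
            v = np.asarray(v, dtype=float)
            if len(v) != n:
                raise ValueError(f"column {name!r} length {len(v)} != {n}")
            if not np.all(np.isfinite(v)):
                raise ValueError(f"non-finite values in column {name!r}")
            setattr(self, name, v)

    def __len__(self) -> int:
        return len(self.time)

    def to_frame(self) -> pd.DataFrame:
        data = {}
        for name in self._COLUMNS:
            v = getattr(self, name)
            if v is not None:
                data[name] = v
        return pd.DataFrame(data)

    @classmethod
    def from_frame(cls, df: pd.DataFrame) -> "ThermoSeries":
        kwargs = {}
        for name in cls._COLUMNS:
            if name in df.columns:
                kwargs[name] = df[name].to_numpy(dtype=float)
        if "time" not in kwargs:
            raise ValueError("thermo table must have a 'time' column")
        return cls(**kwargs)
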