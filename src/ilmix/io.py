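"""Text readers/writers: LAMMPS dump, XYZ, and thermodynamic-log CSV.

Only orthorhombic cells are supported; a dump carrying triclinic tilt
factors is rejected with an explicit error.  Scaled ("xs ys zs")
coordinates are converted to absolute angstrom on read.
"""

from __future__ import annotations

from pathlib import Path

import numpy as np
import pandas as pd

from .trajectory import Frame, ThermoSeries, Topology, Trajectory

__all__ = [
    "read_lammps_dump",
    "write_lammps_dump",
    "read_xyz",
    "write_xyz",
    "read_thermo_csv",
    "write_thermo_csv",
    "read_topology_csv",
    "write_topology_csv",
]


def _read_section_line(lines: list[str], i: int, prefix: str) -> int:
    if i >= len(lines) or not lines[i].startswith(prefix):
        got = lines[i].strip() if i < len(lines) else "<EOF>"
        raise ValueError(f"expected {prefix!r}, got {got!r}")
    return i


def read_lammps_dump(path: str | Path, timestep_ps: float = 1.0) -> Trajectory:
    """Read a LAMMPS text dump into a :class:`Trajectory`.

    Requires ``id`` and one coordinate triple among (x y z), (xs ys zs) or
    (xu yu zu); optional image flags (ix iy iz).  Atoms are sorted by id.
    ``timestep_ps`` converts the integer TIMESTEP to picoseconds.
    """
    lines = Path(path).read_text().splitlines()
    frames: list[Frame] = []
    wrapped = True
    i = 0
    n_atoms_ref: int | None = None
    while i < len(lines):
        if not lines[i].strip():
            i += 1
            continue
        _read_section_line(lines, i, "ITEM: TIMESTEP")
        step = int(lines[i + 1].split()[0])
        i += 2
        _read_section_line(lines, i, "ITEM: NUMBER OF ATOMS")
        n_atoms = int(lines[i + 1])
        i += 2
        _read_section_line(lines, i, "ITEM: BOX BOUNDS")
        bounds_header = lines[i]
        if any(t in bounds_header.split() for t in ("xy", "xz", "yz")):
            raise ValueError("triclinic box (tilt factors present) is not supported")
        lo = np.empty(3)
        hi = np.empty(3)
        for k in range(3):
            parts = lines[i + 1 + k].split()
            if len(parts) > 2:
                raise ValueError("triclinic box (tilt factors present) is not supported")
            lo[k], hi[k] = float(parts[0]), float(parts[1])
        box = hi - lo
        i += 4
        _read_section_line(lines, i, "ITEM: ATOMS")
        columns = lines[i].split()[2:]
        col = {name: j for j, name in enumerate(columns)}
        if "id" not in col:
            raise ValueError("dump is missing the 'id' column")
        if {"x", "y", "z"} <= col.keys():
            xyz_cols, scaled, unwrapped_cols = ("x", "y", "z"), False, False
        elif {"xs", "ys", "zs"} <= col.keys():
            xyz_cols, scaled, unwrapped_cols = ("xs", "ys", "zs"), True, False
        elif {"xu", "yu", "zu"} <= col.keys():
            xyz_cols, scaled, unwrapped_cols = ("xu", "yu", "zu"), False, True
        else:
            raise ValueError(
                "dump is missing coordinate columns (x y z | xs ys zs | xu yu zu)"
            )
        has_flags = {"ix", "iy", "iz"} <= col.keys()
        i += 1
        if n_atoms_ref is None:
            n_atoms_ref = n_atoms
        elif n_atoms != n_atoms_ref:
            raise ValueError(
                f"atom count varies across frames ({n_atoms_ref} then {n_atoms})"
            )
        data = np.array(
            [lines[i + k].split() for k in range(n_atoms)], dtype=float
        )
        i += n_atoms
        order = np.argsort(data[:, col["id"]], kind="stable")
        data = data[order]
        pos = data[:, [col[c] for c in xyz_cols]]
        if scaled:
            pos = pos * box
        else:
            pos = pos - lo
        flags = None
        if has_flags:
            flags = data[:, [col["ix"], col["iy"], col["iz"]]].astype(int)
        if unwrapped_cols:
            wrapped = False
        frames.append(Frame(step * timestep_ps, box, pos, image_flags=flags))
    if not frames:
        raise ValueError(f"no frames found in {path}")
    return Trajectory(frames, wrapped=wrapped)


def write_lammps_dump(traj: Trajectory, path: str | Path, timestep_ps: float = 1.0) -> None:
    """Write a trajectory as a LAMMPS text dump (id x y z [ix iy iz])."""
    with open(path, "w") as fh:
        for f in traj.frames:
            fh.write("ITEM: TIMESTEP\n")
            fh.write(f"{int(round(f.time / timestep_ps))}\n")
            fh.write("ITEM: NUMBER OF ATOMS\n")
            fh.write(f"{f.n_atoms}\n")
            fh.write("ITEM: BOX BOUNDS pp pp pp\n")
            for k in range(3):
                fh.write(f"0.0 {f.box[k]:.10g}\n")
            cols = "id x y z" + (" ix iy iz" if f.image_flags is not None else "")
            fh.write(f"ITEM: ATOMS {cols}\n")
            for a in range(f.n_atoms):
                x, y, z = f.positions[a]
                line = f"{a + 1} {x:.8f} {y:.8f} {z:.8f}"
                if f.image_flags is not None:
                    ix, iy, iz = f.image_flags[a]
                    line += f" {ix} {iy} {iz}"
                fh.write(line + "\n")


def read_xyz(path: str | Path) -> Trajectory:
    """Read an (extended-comment) XYZ trajectory.

    The comment line is expected to carry ``time=<ps> box=<Lx>,<Ly>,<Lz>``
    as written by :func:`write_xyz`; both fields are required because a
    bare XYZ has no cell.
    """
    lines = Path(path).read_text().splitlines()
    frames: list[Frame] = []
    species: list[str] | None = None
    i = 0
    while i < len(lines):
        if not lines[i].strip():
            i += 1
            continue
        n = int(lines[i])
        comment = lines[i + 1]
        fields = dict(
            token.split("=", 1) for token in comment.split() if "=" in token
        )
        if "time" not in fields or "box" not in fields:
            raise ValueError("XYZ comment line must carry time=... box=Lx,Ly,Lz")
        time = float(fields["time"])
        box = np.array([float(v) for v in fields["box"].split(",")])
        syms: list[str] = []
        pos = np.empty((n, 3))
        for k in range(n):
            parts = lines[i + 2 + k].split()
            syms.append(parts[0])
            pos[k] = [float(v) for v in parts[1:4]]
        if species is None:
            species = syms
        frames.append(Frame(time, box, pos))
        i += 2 + n
    if not frames:
        raise ValueError(f"no frames found in {path}")
    return Trajectory(frames)


def write_xyz(traj: Trajectory, path: str | Path, symbols: list[str] | None = None) -> None:
    """Write standard XYZ; comment line carries time and box."""
    n = traj.n_atoms
    if symbols is None:
        symbols = ["X"] * n
    with open(path, "w") as fh:
        for f in traj.frames:
            fh.write(f"{n}\n")
            bx = ",".join(f"{v:.10g}" for v in f.box)
            fh.write(f"time={f.time:.10g} box={bx}\n")
            for a in range(n):
                x, y, z = f.positions[a]
                fh.write(f"{symbols[a]} {x:.8f} {y:.8f} {z:.8f}\n")


def read_topology_csv(path: str | Path) -> Topology:
    """Read per-atom topology from CSV.

    Required columns: ``molecule_id``, ``species``, ``role``.  Optional:
    ``donor_h`` (row index of the covalently attached H for donor atoms,
    -1 otherwise) and ``acceptor`` (0/1 flag).
    """
    df = pd.read_csv(path)
    for col in ("molecule_id", "species", "role"):
        if col not in df.columns:
            raise ValueError(f"topology CSV is missing column {col!r}")
    donors = None
    if "donor_h" in df.columns:
        d = df.index[df["donor_h"] >= 0].to_numpy()
        donors = np.column_stack([d, df.loc[d, "donor_h"].to_numpy(dtype=int)])
    acceptors = None
    if "acceptor" in df.columns:
        acceptors = df.index[df["acceptor"] > 0].to_numpy()
    return Topology(
        molecule_id=df["molecule_id"].to_numpy(dtype=int),
        species=df["species"].to_numpy(dtype=object),
        role=df["role"].to_numpy(dtype=object),
        donors=donors if donors is not None and len(donors) else None,
        acceptors=acceptors if acceptors is not None and len(acceptors) else None,
    )


def write_topology_csv(topology: Topology, path: str | Path) -> None:
    n = topology.n_atoms
    donor_h = np.full(n, -1, dtype=int)
    if topology.donors is not None:
        donor_h[topology.donors[:, 0]] = topology.donors[:, 1]
    acceptor = np.zeros(n, dtype=int)
    if topology.acceptors is not None:
        acceptor[topology.acceptors] = 1
    pd.DataFrame(
        {
            "molecule_id": topology.molecule_id,
            "species": topology.species,
            "role": topology.role,
            "donor_h": donor_h,
            "acceptor": acceptor,
        }
    ).to_csv(path, index=False)


def read_thermo_csv(path: str | Path) -> ThermoSeries:
    """Read a thermodynamic log CSV (time plus any of enthalpy, volume,
    density, temperature, pressure)."""
    return ThermoSeries.from_frame(pd.read_csv(path))


def write_thermo_csv(series: ThermoSeries, path: str | Path) -> None:
    series.to_frame().to_csv(path, index=False)
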