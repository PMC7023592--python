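"""Trajectory containers, LAMMPS dump / XYZ round trips, unwrapping."""

import numpy as np
import pytest

from ilmix.io import (
    read_lammps_dump,
    read_thermo_csv,
    read_topology_csv,
    read_xyz,
    write_lammps_dump,
    write_thermo_csv,
    write_topology_csv,
    write_xyz,
)
from ilmix.synthetic import WalkerSpec, gen_walkers
from ilmix.trajectory import (
    Frame,
    ThermoSeries,
    Topology,
    Trajectory,
    centers,
    minimum_image,
    unwrap,
    wrap,
)

DUMP_2F3A = """ITEM: TIMESTEP
0
ITEM: NUMBER OF ATOMS
3
ITEM: BOX BOUNDS pp pp pp
0.0 10.0
0.0 10.0
0.0 10.0
ITEM: ATOMS id x y z
1 1.0 2.0 3.0
3 7.0 8.0 9.0
2 4.0 5.0 6.0
ITEM: TIMESTEP
10
ITEM: NUMBER OF ATOMS
3
ITEM: BOX BOUNDS pp pp pp
0.0 10.0
0.0 10.0
0.0 10.0
ITEM: ATOMS id x y z
1 1.5 2.0 3.0
2 4.0 5.5 6.0
3 7.0 8.0 9.5
"""


class TestLammpsDump:
    def test_handcrafted_two_frames(self, tmp_path):
        p = tmp_path / "t.dump"
        p.write_text(DUMP_2F3A)
        traj = read_lammps_dump(p)
        assert traj.coordinates.shape == (2, 3, 3)
        # atoms sorted by id despite shuffled file order
        np.testing.assert_allclose(traj.frames[0].positions[1], [4.0, 5.0, 6.0])
        np.testing.assert_allclose(traj.frames[0].box, [10, 10, 10])
        assert traj.times[1] == 10.0

    def test_image_flag_unwrap(self, tmp_path):
        text = DUMP_2F3A.replace(
            "ITEM: ATOMS id x y z\n1 1.0 2.0 3.0",
            "ITEM: ATOMS id x y z ix iy iz\n1 1.0 2.0 3.0 1 0 0",
        ).split("ITEM: TIMESTEP\n10")[0]
        p = tmp_path / "flag.dump"
        p.write_text(text + "")
        # remaining atoms in the frame lack flag columns -> keep them too
        p.write_text(
            "ITEM: TIMESTEP\n0\nITEM: NUMBER OF ATOMS\n1\n"
            "ITEM: BOX BOUNDS pp pp pp\n0.0 10.0\n0.0 10.0\n0.0 10.0\n"
            "ITEM: ATOMS id x y z ix iy iz\n1 1.0 2.0 3.0 1 0 0\n"
        )
        traj = read_lammps_dump(p)
        out = unwrap(traj)
        np.testing.assert_allclose(out.frames[0].positions[0], [11.0, 2.0, 3.0])

    def test_scaled_coordinates(self, tmp_path):
        p = tmp_path / "s.dump"
        p.write_text(
            "ITEM: TIMESTEP\n0\nITEM: NUMBER OF ATOMS\n1\n"
            "ITEM: BOX BOUNDS pp pp pp\n0.0 20.0\n0.0 20.0\n0.0 20.0\n"
            "ITEM: ATOMS id xs ys zs\n1 0.25 0.5 0.75\n"
        )
        traj = read_lammps_dump(p)
        np.testing.assert_allclose(traj.frames[0].positions[0], [5.0, 10.0, 15.0])

    def test_triclinic_rejected(self, tmp_path):
        p = tmp_path / "tri.dump"
        p.write_text(
            "ITEM: TIMESTEP\n0\nITEM: NUMBER OF ATOMS\n1\n"
            "ITEM: BOX BOUNDS xy xz yz pp pp pp\n0.0 10.0 1.0\n0.0 10.0 0.0\n0.0 10.0 0.0\n"
            "ITEM: ATOMS id x y z\n1 1.0 2.0 3.0\n"
        )
        with pytest.raises(ValueError, match="triclinic"):
            read_lammps_dump(p)

    def test_missing_coordinates_rejected(self, tmp_path):
        p = tmp_path / "bad.dump"
        p.write_text(
            "ITEM: TIMESTEP\n0\nITEM: NUMBER OF ATOMS\n1\n"
            "ITEM: BOX BOUNDS pp pp pp\n0.0 10.0\n0.0 10.0\n0.0 10.0\n"
            "ITEM: ATOMS id x y\n1 1.0 2.0\n"
        )
        with pytest.raises(ValueError, match="coordinate"):
            read_lammps_dump(p)

    def test_varying_atom_count_rejected(self, tmp_path):
        text = DUMP_2F3A.replace(
            "ITEM: TIMESTEP\n10\nITEM: NUMBER OF ATOMS\n3",
            "ITEM: TIMESTEP\n10\nITEM: NUMBER OF ATOMS\n2",
        ).rsplit("3 7.0 8.0 9.5\n", 1)[0]
        p = tmp_path / "vary.dump"
        p.write_text(text)
        with pytest.raises(ValueError, match="varies"):
            read_lammps_dump(p)

    def test_round_trip(self, tmp_path, rng):
        coords = rng.random((3, 5, 3)) * 12.0
        traj = Trajectory.from_arrays([0.0, 1.0, 2.0], np.array([12.0, 12, 12]), coords)
        p = tmp_path / "rt.dump"
        write_lammps_dump(traj, p)
        back = read_lammps_dump(p)
        np.testing.assert_allclose(back.coordinates, coords, atol=1e-6)

    def test_against_mdanalysis_reader(self, tmp_path, rng):
        """Independent cross-check of the dump parser."""
        mda = pytest.importorskip("MDAnalysis")
        coords = rng.random((2, 4, 3)) * 10.0
        traj = Trajectory.from_arrays([0.0, 1.0], np.array([10.0, 10, 10]), coords)
        p = tmp_path / "x.dump"
        write_lammps_dump(traj, p)
        u = mda.Universe(str(p), format="LAMMPSDUMP")
        mine = read_lammps_dump(p)
        for k, _ts in enumerate(u.trajectory):
            np.testing.assert_allclose(
                u.atoms.positions, mine.frames[k].positions, atol=1e-5
            )


class TestXYZ:
    def test_round_trip(self, tmp_path, rng):
        coords = rng.random((2, 4, 3)) * 9.0
        traj = Trajectory.from_arrays([0.0, 5.0], np.array([9.0, 9, 9]), coords)
        p = tmp_path / "t.xyz"
        write_xyz(traj, p, symbols=["O", "H", "H", "P"])
        back = read_xyz(p)
        np.testing.assert_allclose(back.coordinates, coords, atol=1e-6)
        np.testing.assert_allclose(back.times, [0.0, 5.0])
        np.testing.assert_allclose(back.frames[0].box, [9, 9, 9])

    def test_missing_box_rejected(self, tmp_path):
        p = tmp_path / "bare.xyz"
        p.write_text("1\nplain comment\nO 1.0 2.0 3.0\n")
        with pytest.raises(ValueError, match="box"):
            read_xyz(p)


class TestUnwrap:
    def test_single_boundary_crossing(self):
        box = np.array([10.0, 10, 10])
        coords = np.array([[[9.5, 5, 5]], [[0.2, 5, 5]]])  # crosses +x
        traj = Trajectory.from_arrays([0.0, 1.0], box, coords)
        out = unwrap(traj)
        assert out.frames[1].positions[0, 0] > 10.0 - 0.5
        assert out.frames[1].positions[0, 0] == pytest.approx(10.2)

    def test_wrap_unwrap_inverse(self, rng):
        box = np.array([7.0, 8.0, 9.0])
        steps = rng.normal(0, 0.8, (20, 6, 3))
        pos = 3.0 + np.cumsum(steps, axis=0)
        traj_true = Trajectory.from_arrays(np.arange(20.0), box, pos, wrapped=False)
        wrapped = wrap(traj_true)
        back = unwrap(wrapped)
        np.testing.assert_allclose(
            np.mod(back.coordinates, box), wrapped.coordinates, atol=1e-9
        )
        # inter-frame displacements identical to the truth
        np.testing.assert_allclose(
            np.diff(back.coordinates, axis=0), np.diff(pos, axis=0), atol=1e-9
        )

    def test_walker_displacements_match_generator_truth(self):
        traj, truth = gen_walkers(
            WalkerSpec(n_particles=4, n_steps=50, model="brownian", seed=7)
        )
        wrapped = wrap(traj)
        back = unwrap(wrapped)
        np.testing.assert_allclose(
            np.diff(back.coordinates, axis=0), truth.displacements, atol=1e-9
        )

    def test_first_frame_preserved(self, rng):
        box = np.array([10.0, 10, 10])
        coords = np.mod(rng.normal(5, 1, (3, 4, 3)), box)
        traj = Trajectory.from_arrays([0.0, 1, 2], box, coords)
        out = unwrap(traj)
        np.testing.assert_allclose(out.frames[0].positions, coords[0])


class TestCenters:
    def test_water_center_is_oxygen(self):
        # one water: O at origin-ish, two H nearby
        topo = Topology(
            molecule_id=[0, 0, 0],
            species=np.array(["water"] * 3, dtype=object),
            role=np.array(["water_center", "other", "other"], dtype=object),
        )
        pos = np.array([[[1.0, 1, 1], [1.5, 1, 1], [1, 1.5, 1]]])
        traj = Trajectory.from_arrays([0.0], np.array([10.0, 10, 10]), pos)
        c = centers(traj, topo, "water")
        assert c.n_atoms == 1
        np.testing.assert_allclose(c.frames[0].positions[0], [1.0, 1, 1])

    def test_known_phosphorus_positions(self, rng):
        n_mol = 5
        p_pos = rng.random((n_mol, 3)) * 10
        mol, species, role, allpos = [], [], [], []
        for m in range(n_mol):
            mol += [m, m]
            species += ["cation", "cation"]
            role += ["cation_center", "other"]
            allpos += [p_pos[m], p_pos[m] + 0.5]
        topo = Topology(mol, np.array(species, dtype=object), np.array(role, dtype=object))
        traj = Trajectory.from_arrays(
            [0.0], np.array([20.0, 20, 20]), np.array(allpos)[None]
        )
        c = centers(traj, topo, "cation")
        np.testing.assert_allclose(c.frames[0].positions, p_pos)

    def test_missing_role_errors(self, point_topology):
        topo = point_topology(3, "water")
        traj = Trajectory.from_arrays(
            [0.0], np.array([5.0, 5, 5]), np.zeros((1, 3, 3)) + 1.0
        )
        with pytest.raises(ValueError):
            centers(traj, topo, "anion")


class TestThermoSeriesIO:
    def test_csv_round_trip(self, tmp_path):
        s = ThermoSeries(
            time=np.arange(5.0),
            enthalpy=np.linspace(0, 1, 5),
            volume=np.full(5, 90.0),
            density=np.full(5, 1.0),
            temperature=np.full(5, 300.0),
        )
        p = tmp_path / "t.csv"
        write_thermo_csv(s, p)
        back = read_thermo_csv(p)
        np.testing.assert_allclose(back.enthalpy, s.enthalpy)
        np.testing.assert_allclose(back.volume, s.volume)

    def test_length_mismatch_rejected(self):
        with pytest.raises(ValueError):
            ThermoSeries(time=np.arange(5.0), enthalpy=np.arange(4.0))


class TestTopologyIO:
    def test_round_trip_with_donors(self, tmp_path):
        topo = Topology(
            molecule_id=[0, 0, 1],
            species=np.array(["water"] * 3, dtype=object),
            role=np.array(["water_center", "other", "water_center"], dtype=object),
            donors=np.array([[0, 1]]),
            acceptors=np.array([2]),
        )
        p = tmp_path / "topo.csv"
        write_topology_csv(topo, p)
        back = read_topology_csv(p)
        np.testing.assert_array_equal(back.molecule_id, topo.molecule_id)
        np.testing.assert_array_equal(back.donors, topo.donors)
        np.testing.assert_array_equal(back.acceptors, topo.acceptors)


class TestInvariants:
    def test_minimum_image_bounds(self, rng):
        box = np.array([6.0, 7.0, 8.0])
        d = rng.normal(0, 20, (100, 3))
        m = minimum_image(d, box)
        assert np.all(np.abs(m) <= box / 2 + 1e-12)

    def test_nonincreasing_times_rejected(self):
        with pytest.raises(ValueError):
            Trajectory.from_arrays([0.0, 0.0], np.array([5.0, 5, 5]), np.zeros((2, 1, 3)))

    def test_two_center_atoms_per_molecule_rejected(self):
        with pytest.raises(ValueError):
            Topology(
                molecule_id=[0, 0],
                species=np.array(["water", "water"], dtype=object),
                role=np.array(["water_center", "water_center"], dtype=object),
            )
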