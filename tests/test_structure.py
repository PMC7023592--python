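"""RDFs under periodic boundaries, shell minima, coordination numbers."""

import numpy as np
import pytest

from _oracles import brute_pair_distances
from ilmix.structure import (
    RDFResult,
    coordination_number,
    first_shell_minimum,
    rdf,
    rdf_c4c4,
)
from ilmix.trajectory import Topology, Trajectory


def _traj(points, box, times=(0.0,)):
    pts = np.asarray(points, dtype=float)
    if pts.ndim == 2:
        pts = pts[None]
    return Trajectory.from_arrays(list(times), np.asarray(box, dtype=float), pts)


class TestRdf:
    def test_two_fixed_particles_single_bin(self, point_topology):
        box = [20.0, 20, 20]
        d = 4.32
        pts = np.array([[1.0, 1, 1], [1.0 + d, 1, 1]])
        traj = _traj(pts, box)
        res = rdf(traj, point_topology(2), "water", "water", dr=0.1)
        nz = np.nonzero(res.g)[0]
        assert len(nz) == 1
        assert res.r[nz[0]] == pytest.approx(d, abs=0.05 + 1e-9)

    def test_minimum_image_pair_across_boundary(self, point_topology):
        box = [10.0, 10, 10]
        pts = np.array([[0.5, 5, 5], [9.7, 5, 5]])  # true distance 0.8
        traj = _traj(pts, box)
        res = rdf(traj, point_topology(2), "water", "water", dr=0.1)
        nz = np.nonzero(res.g)[0]
        assert res.r[nz[0]] == pytest.approx(0.8, abs=0.05 + 1e-9)

    def test_histogram_equals_bruteforce(self, rng, point_topology):
        box = np.array([15.0, 15, 15])
        pts = rng.random((100, 3)) * box
        traj = _traj(pts, box)
        dr, r_max = 0.25, 7.0
        res = rdf(traj, point_topology(100), "water", "water", r_max=r_max, dr=dr)
        dists = brute_pair_distances(pts, pts, box, same=True)
        edges = np.arange(int(r_max / dr) + 1) * dr
        hist = np.histogram(dists[dists < edges[-1]], bins=edges)[0]
        shell = 4.0 / 3.0 * np.pi * (edges[1:] ** 3 - edges[:-1] ** 3)
        rho = 99 / box.prod()
        expected = hist / (100 * shell * rho / 2.0)
        np.testing.assert_allclose(res.g, expected, atol=1e-10)

    def test_ideal_gas_flat(self, rng, point_topology):
        box = np.array([30.0, 30, 30])
        frames = rng.random((20, 1000, 3)) * box
        traj = _traj(frames, box, times=np.arange(20.0))
        res = rdf(traj, point_topology(1000), "water", "water", r_max=8.0, dr=0.1)
        mask = (res.r > 2.0) & (res.r < 7.5)
        assert np.abs(res.g[mask] - 1.0).max() < 0.05

    def test_cross_species_pair(self, rng, point_topology):
        box = np.array([12.0, 12, 12])
        n_a, n_b = 30, 50
        pts = rng.random((n_a + n_b, 3)) * box
        topo = Topology(
            molecule_id=np.arange(n_a + n_b),
            species=np.array(["cation"] * n_a + ["water"] * n_b, dtype=object),
            role=np.array(
                ["cation_center"] * n_a + ["water_center"] * n_b, dtype=object
            ),
        )
        traj = _traj(pts, box)
        dr, r_max = 0.3, 5.5
        res = rdf(traj, topo, "cation", "water", r_max=r_max, dr=dr)
        dists = brute_pair_distances(pts[:n_a], pts[n_a:], box, same=False)
        edges = np.arange(int(r_max / dr) + 1) * dr
        hist = np.histogram(dists[dists < edges[-1]], bins=edges)[0]
        shell = 4.0 / 3.0 * np.pi * (edges[1:] ** 3 - edges[:-1] ** 3)
        expected = hist / (n_a * shell * (n_b / box.prod()))
        np.testing.assert_allclose(res.g, expected, atol=1e-10)

    def test_rmax_beyond_half_box_rejected(self, point_topology):
        traj = _traj(np.ones((2, 3)), [10.0, 10, 10])
        with pytest.raises(ValueError, match="minimum-image"):
            rdf(traj, point_topology(2), "water", "water", r_max=6.0)

    def test_normalization_integral_matches_neighbor_count(self, rng, point_topology):
        box = np.array([20.0, 20, 20])
        pts = rng.random((200, 3)) * box
        traj = _traj(pts, box)
        res = rdf(traj, point_topology(200), "water", "water", r_max=9.0, dr=0.05)
        # rho * int 4 pi r^2 g dr == mean neighbors within r_max
        integral = 4 * np.pi * res.rho_b * np.trapezoid(res.g * res.r**2, res.r)
        dists = brute_pair_distances(pts, pts, box, same=True)
        mean_neighbors = 2 * np.sum(dists < 9.0) / 200
        assert integral == pytest.approx(mean_neighbors, rel=0.01)


class TestRdfC4C4:
    @staticmethod
    def _tbp_like(n_mol, rng, box, arm=4.1):
        """Molecules with 4 terminal carbons at +-arm along two axes, so
        opposite arms sit 2*arm apart end to end."""
        pos, mol, species, role = [], [], [], []
        centers = rng.random((n_mol, 3)) * (box - 2 * arm - 1) + arm + 0.5
        offsets = np.array(
            [[arm, 0, 0], [-arm, 0, 0], [0, arm, 0], [0, -arm, 0]]
        )
        for m in range(n_mol):
            pos.append(centers[m])
            mol.append(m)
            species.append("cation")
            role.append("cation_center")
            for off in offsets:
                pos.append(centers[m] + off)
                mol.append(m)
                species.append("cation")
                role.append("terminal_carbon")
        topo = Topology(
            molecule_id=mol,
            species=np.array(species, dtype=object),
            role=np.array(role, dtype=object),
        )
        return np.array(pos), topo

    def test_isolated_cation_intramolecular_peak(self, rng):
        box = np.array([40.0, 40, 40])
        pts, topo = self._tbp_like(1, rng, box)
        res = rdf_c4c4(_traj(pts, box), topo, dr=0.1)
        # the 8.2 A end-to-end arm distance must appear as an
        # intramolecular peak (the only feature beyond the 5.8 A
        # adjacent-arm distance)
        far = res.r > 7.0
        peak_r = res.r[far][np.argmax(res.g[far])]
        assert peak_r == pytest.approx(8.2, abs=0.05 + 1e-9)
        assert res.g[far].max() > 0
        assert res.includes_intramolecular

    def test_exclude_flag_removes_within_molecule_pairs(self, rng, point_topology):
        box = np.array([40.0, 40, 40])
        pts, topo = self._tbp_like(3, rng, box)
        traj = _traj(pts, box)
        with_intra = rdf(traj, topo, "terminal_carbon", "terminal_carbon",
                         dr=0.1, exclude_same_molecule=False)
        without = rdf(traj, topo, "terminal_carbon", "terminal_carbon",
                      dr=0.1, exclude_same_molecule=True)
        shell = 4.0 / 3.0 * np.pi
        # back out raw pair counts from the normalized curves
        edges = np.arange(len(with_intra.g) + 1) * 0.1
        shells = shell * (edges[1:] ** 3 - edges[:-1] ** 3)
        norm = 12 * shells * with_intra.rho_b / 2.0
        diff_counts = (with_intra.g - without.g) * norm
        # 4*3/2 = 6 intramolecular pairs per molecule, 3 molecules
        assert np.sum(diff_counts) == pytest.approx(18, abs=1e-6)

    def test_two_molecules_match_bruteforce(self, rng):
        box = np.array([30.0, 30, 30])
        pts, topo = self._tbp_like(2, rng, box)
        res = rdf_c4c4(_traj(pts, box), topo, r_max=14.0, dr=0.2)
        c4 = pts[topo.role == "terminal_carbon"]
        dists = brute_pair_distances(c4, c4, box, same=True)
        edges = np.arange(int(14.0 / 0.2) + 1) * 0.2
        hist = np.histogram(dists[dists < edges[-1]], bins=edges)[0]
        shells = 4.0 / 3.0 * np.pi * (edges[1:] ** 3 - edges[:-1] ** 3)
        expected = hist / (8 * shells * (7 / box.prod()) / 2.0)
        np.testing.assert_allclose(res.g, expected, atol=1e-10)


class TestFirstShellMinimum:
    @staticmethod
    def _curve(r, g):
        return RDFResult(
            r=r, g=g, pair=("a", "b"), r_max=float(r[-1]), dr=float(r[1] - r[0]),
            n_frames=1, includes_intramolecular=False, rho_b=0.01,
            n_a=1, n_b=1,
        )

    def test_constructed_bump_and_dip(self):
        r = np.arange(0.05, 12, 0.1)
        g = 1 + 1.5 * np.exp(-((r - 4) ** 2) / 0.3) - 0.6 * np.exp(-((r - 6) ** 2) / 0.3)
        assert first_shell_minimum(self._curve(r, g)) == pytest.approx(6.0, abs=0.1)

    def test_flat_ideal_gas_errors(self):
        r = np.arange(0.05, 12, 0.1)
        with pytest.raises(ValueError, match="no shell structure"):
            first_shell_minimum(self._curve(r, np.ones_like(r)))

    def test_noisy_curve_matches_smoothed_argmin(self, rng):
        from scipy.signal import savgol_filter

        r = np.arange(0.05, 12, 0.1)
        g = 1 + 1.5 * np.exp(-((r - 4) ** 2) / 0.5) - 0.6 * np.exp(-((r - 6.5) ** 2) / 0.5)
        g = g + rng.normal(0, 0.01, len(g))
        found = first_shell_minimum(self._curve(r, g))
        sm = savgol_filter(g, 5, 2)
        lo, hi = np.searchsorted(r, [5.0, 8.0])
        assert found == pytest.approx(r[lo + np.argmin(sm[lo:hi])], abs=0.15)


class TestCoordinationNumber:
    def test_ideal_gas_closed_form(self):
        r = np.arange(0.05, 10, 0.1)
        res = TestFirstShellMinimum._curve(r, np.ones_like(r))
        rho, rc = 0.02, 6.0
        expected = 4.0 / 3.0 * np.pi * rho * rc**3
        assert coordination_number(res, rho, rc) == pytest.approx(expected, rel=0.01)

    def test_delta_peak_counts_neighbors(self, point_topology):
        # k = 6 neighbors in an octahedron at distance d
        box = np.array([30.0, 30, 30])
        d = 3.0
        center = np.array([15.0, 15, 15])
        neigh = center + d * np.array(
            [[1, 0, 0], [-1, 0, 0], [0, 1, 0], [0, -1, 0], [0, 0, 1], [0, 0, -1]]
        )
        pts = np.vstack([center, neigh])
        topo = Topology(
            molecule_id=np.arange(7),
            species=np.array(["cation"] + ["water"] * 6, dtype=object),
            role=np.array(["cation_center"] + ["water_center"] * 6, dtype=object),
        )
        res = rdf(_traj(pts, box), topo, "cation", "water", r_max=8.0, dr=0.1)
        cn = coordination_number(res, res.rho_b, 5.0)
        assert cn == pytest.approx(6.0, rel=0.02)

    def test_random_config_matches_direct_count(self, rng, point_topology):
        box = np.array([18.0, 18, 18])
        pts = rng.random((150, 3)) * box
        res = rdf(_traj(pts, box), point_topology(150), "water", "water",
                  r_max=8.0, dr=0.02)
        rc = 6.0
        cn = coordination_number(res, res.rho_b, rc)
        dists = brute_pair_distances(pts, pts, box, same=True)
        direct = 2 * np.sum(dists < rc) / 150
        assert cn == pytest.approx(direct, rel=0.02)
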