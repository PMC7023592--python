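"""Synthetic inputs with known ground truth for every analysis stage.

The study's MD trajectories are not deposited, so each analysis is
exercised on generated data that emulates the relevant physics:

* random walkers with a prescribed anomalous exponent alpha and
  generalized diffusion coefficient K_alpha (fractional Brownian motion
  by exact-covariance construction, Brownian motion as its alpha = 1
  limit, and continuous-time random walks with heavy-tailed waits for
  the weakly non-ergodic case);
* particle configurations with prescribed cluster topology (dispersed,
  chain, box-spanning vein, compact globule, interlocked lattice);
* donor-H-acceptor triplets that satisfy all three geometric
  hydrogen-bond criteria, plus decoys violating exactly one each;
* linear-in-temperature enthalpy and volume series with additive noise.

Every generator is deterministic under a fixed seed and emits its ground
truth alongside the data; analysis modules never read the truth.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np

from .trajectory import Frame, ThermoSeries, Topology, Trajectory

__all__ = [
    "WalkerSpec",
    "WalkerTruth",
    "ConfigSpec",
    "ConfigTruth",
    "HBondTruth",
    "ThermoTruth",
    "gen_walkers",
    "gen_config",
    "gen_hbond_config",
    "gen_thermo_series",
    "fgn_increments",
]

# ---------------------------------------------------------------------------
# anomalous random walkers


@dataclass(frozen=True)
class WalkerSpec:
    """Specification of an ensemble of 3-D random walkers.

    ``alpha_true`` is the anomalous diffusion exponent (ensemble MSD =
    2 d K t^alpha with d = 3); ``k_true`` the generalized diffusion
    coefficient in A^2/ps^alpha.  For fBm the Hurst exponent is
    H = alpha/2, restricted here to the (sub)diffusive range (0, 0.5].
    """

    n_particles: int
    n_steps: int
    dt: float = 1.0
    model: str = "brownian"  # brownian | fbm | ctrw
    alpha_true: float = 1.0
    k_true: float = 1.0
    seed: int = 0

    def __post_init__(self) -> None:
        if self.model not in ("brownian", "fbm", "ctrw"):
            raise ValueError(f"unknown walker model {self.model!r}")
        if not 0.0 < self.alpha_true <= 1.0:
            raise ValueError("alpha_true must be in (0, 1]")
        if self.dt <= 0:
            raise ValueError("dt must be positive")
        if self.k_true <= 0:
            raise ValueError("k_true must be positive")


@dataclass
class WalkerTruth:
    alpha: float
    k: float
    model: str
    displacements: np.ndarray  # (n_steps, n_particles, 3) true step vectors


def _fgn_covariance(n: int, hurst: float, sigma2: float) -> np.ndarray:
    """Autocovariance gamma(0..n-1) of fractional Gaussian noise with
    one-step variance sigma2."""
    k = np.arange(n, dtype=float)
    h2 = 2.0 * hurst
    return 0.5 * sigma2 * (
        np.abs(k + 1) ** h2 - 2.0 * np.abs(k) ** h2 + np.abs(k - 1) ** h2
    )


def fgn_increments(
    n_steps: int,
    hurst: float,
    sigma2: float,
    size: int,
    rng: np.random.Generator,
    method: str = "auto",
) -> np.ndarray:
    """Exact-covariance fractional Gaussian noise, shape (size, n_steps).

    ``method``: "cholesky" (dense, exact, O(n^2) memory), "circulant"
    (Davies-Harte embedding, exact when the embedding is nonnegative —
    always the case for fGn), or "auto" (cholesky for short series).
    """
    if not 0.0 < hurst <= 0.5 + 1e-12:
        raise ValueError("hurst must be in (0, 0.5] for (sub)diffusive fGn")
    if method == "auto":
        method = "cholesky" if n_steps <= 64 else "circulant"
    gamma = _fgn_covariance(n_steps, hurst, sigma2)
    if method == "cholesky":
        cov = gamma[np.abs(np.subtract.outer(np.arange(n_steps), np.arange(n_steps)))]
        chol = np.linalg.cholesky(cov + 1e-14 * sigma2 * np.eye(n_steps))
        z = rng.standard_normal((size, n_steps))
        return z @ chol.T
    if method != "circulant":
        raise ValueError(f"unknown fGn method {method!r}")
    # circulant embedding of length 2n: [g0..g_{n-1}, g_n, g_{n-1}..g_1]
    m = 2 * n_steps
    circ = np.empty(m)
    circ[:n_steps] = gamma
    circ[n_steps] = _fgn_covariance(n_steps + 1, hurst, sigma2)[-1]
    circ[n_steps + 1 :] = gamma[-1:0:-1]
    lam = np.fft.fft(circ).real
    if lam.min() < -1e-8 * sigma2:
        # embedding failed (does not happen for fGn); fall back
        return fgn_increments(n_steps, hurst, sigma2, size, rng, "cholesky")
    lam = np.clip(lam, 0.0, None)
    z = np.zeros((size, m), dtype=complex)
    z[:, 0] = rng.standard_normal(size) * math.sqrt(m)
    z[:, n_steps] = rng.standard_normal(size) * math.sqrt(m)
    u = rng.standard_normal((size, n_steps - 1))
    w = rng.standard_normal((size, n_steps - 1))
    z[:, 1:n_steps] = (u + 1j * w) * math.sqrt(m / 2.0)
    z[:, n_steps + 1 :] = np.conj(z[:, 1:n_steps][:, ::-1])
    x = np.fft.ifft(np.sqrt(lam)[None, :] * z, axis=1)[:, :n_steps].real
    return x


def gen_walkers(spec: WalkerSpec) -> tuple[Trajectory, WalkerTruth]:
    """Generate walker trajectories plus ground truth.

    Brownian and fBm walkers have, per dimension, variance 2 K t^alpha so
    that the 3-D ensemble MSD is 6 K t^alpha.  CTRW walkers draw Pareto
    waiting times with tail exponent alpha and Gaussian jumps scaled so
    the ensemble MSD matches 6 K t^alpha on average.
    """
    rng = np.random.default_rng(spec.seed)
    n, t = spec.n_particles, spec.n_steps
    if spec.model in ("brownian", "fbm"):
        if spec.model == "brownian":
            sigma2 = 2.0 * spec.k_true * spec.dt  # alpha = 1
            steps = rng.standard_normal((t, n, 3)) * math.sqrt(sigma2)
        else:
            hurst = spec.alpha_true / 2.0
            sigma2 = 2.0 * spec.k_true * spec.dt**spec.alpha_true
            flat = fgn_increments(t, hurst, sigma2, n * 3, rng)
            steps = flat.reshape(n, 3, t).transpose(2, 0, 1)
        pos = np.concatenate(
            [np.zeros((1, n, 3)), np.cumsum(steps, axis=0)], axis=0
        )
    else:  # ctrw
        tau0 = spec.dt
        alpha = spec.alpha_true
        sigma_jump = math.sqrt(
            2.0 * spec.k_true * tau0**alpha * math.gamma(1.0 + alpha)
        )
        total_time = t * spec.dt
        pos = np.zeros((t + 1, n, 3))
        for i in range(n):
            # renewal times: heavy-tailed Pareto waits
            waits: list[float] = []
            acc = 0.0
            while acc < total_time:
                w = tau0 * rng.random() ** (-1.0 / alpha)
                waits.append(w)
                acc += w
            jump_times = np.cumsum(waits)
            jumps = rng.standard_normal((len(waits), 3)) * sigma_jump
            path = np.cumsum(jumps, axis=0)
            grid = np.arange(1, t + 1) * spec.dt
            k = np.searchsorted(jump_times, grid, side="right")
            traj_i = np.zeros((t + 1, 3))
            nonzero = k > 0
            traj_i[1:][nonzero] = path[k[nonzero] - 1]
            pos[:, i, :] = traj_i
        steps = np.diff(pos, axis=0)
    times = np.arange(t + 1) * spec.dt
    span = float(np.abs(pos).max()) if pos.size else 1.0
    box = np.full(3, max(4.0 * span, 1.0))
    traj = Trajectory.from_arrays(times, box, pos, wrapped=False)
    truth = WalkerTruth(
        alpha=1.0 if spec.model == "brownian" else spec.alpha_true,
        k=spec.k_true,
        model=spec.model,
        displacements=steps,
    )
    return traj, truth


# ---------------------------------------------------------------------------
# cluster-motif configurations


@dataclass(frozen=True)
class ConfigSpec:
    """A single-frame configuration with a prescribed water cluster motif."""

    box: tuple[float, float, float] = (44.0, 44.0, 44.0)
    n_tbp: int = 0
    n_water: int = 100
    motif: str = "dispersed"  # dispersed | chain | vein | globule | interlocked
    water_cutoff: float = 3.5  # A, clustering cutoff the truth refers to
    tbp_cutoff: float = 9.1
    spacing: float = 2.8  # A, nearest-neighbor spacing in built motifs
    min_separation: float = 1.5
    seed: int = 0

    def __post_init__(self) -> None:
        if self.motif not in ("dispersed", "chain", "vein", "globule", "interlocked"):
            raise ValueError(f"unknown motif {self.motif!r}")
        if self.n_water < 0 or self.n_tbp < 0:
            raise ValueError("counts must be non-negative")


@dataclass
class ConfigTruth:
    """Ground-truth clustering of the generated configuration.

    Computed inside the generator by an O(N^2) double loop plus a 3x3x3
    replicated-cell component test — deliberately naive and independent
    of the analysis module's KD-tree/cycle-shift algorithms.
    """

    labels: np.ndarray  # per-water cluster label
    neighbor_counts: np.ndarray  # per-water neighbors within cutoff
    largest_fraction: float
    mean_neighbors_largest: float
    spanning_largest: tuple[bool, bool, bool]
    cutoff: float
    tbp_labels: np.ndarray | None = None


def _brute_labels(points: np.ndarray, box: np.ndarray, cutoff: float) -> np.ndarray:
    """Union-find over all pairs at minimum-image distance < cutoff."""
    n = len(points)
    parent = np.arange(n)

    def find(a: int) -> int:
        while parent[a] != a:
            parent[a] = parent[parent[a]]
            a = parent[a]
        return a

    for i in range(n):
        for j in range(i + 1, n):
            d = points[i] - points[j]
            d -= box * np.round(d / box)
            if float(d @ d) < cutoff * cutoff:
                ri, rj = find(i), find(j)
                if ri != rj:
                    parent[ri] = rj
    roots = np.array([find(i) for i in range(n)])
    _, labels = np.unique(roots, return_inverse=True)
    return labels


def _brute_neighbor_counts(
    points: np.ndarray, box: np.ndarray, cutoff: float
) -> np.ndarray:
    n = len(points)
    counts = np.zeros(n, dtype=int)
    for i in range(n):
        for j in range(i + 1, n):
            d = points[i] - points[j]
            d -= box * np.round(d / box)
            if float(d @ d) < cutoff * cutoff:
                counts[i] += 1
                counts[j] += 1
    return counts


def _brute_spanning(
    points: np.ndarray, box: np.ndarray, cutoff: float, labels: np.ndarray, cluster: int
) -> tuple[bool, bool, bool]:
    """3x3x3 replicated-cell test: a cluster spans dimension k iff two
    replicas of one particle with different image index along k join the
    same non-periodic component."""
    members = np.where(labels == cluster)[0]
    pts = points[members]
    shifts = np.array(
        [[i, j, k] for i in (-1, 0, 1) for j in (-1, 0, 1) for k in (-1, 0, 1)]
    )
    rep = (pts[None, :, :] + shifts[:, None, :] * box[None, None, :]).reshape(-1, 3)
    rep_img = np.repeat(shifts, len(pts), axis=0)
    rep_orig = np.tile(np.arange(len(pts)), len(shifts))
    m = len(rep)
    parent = np.arange(m)

    def find(a: int) -> int:
        while parent[a] != a:
            parent[a] = parent[parent[a]]
            a = parent[a]
        return a

    c2 = cutoff * cutoff
    for i in range(m):
        for j in range(i + 1, m):
            d = rep[i] - rep[j]
            if float(d @ d) < c2:
                ri, rj = find(i), find(j)
                if ri != rj:
                    parent[ri] = rj
    roots = np.array([find(i) for i in range(m)])
    spans = [False, False, False]
    for orig in range(len(pts)):
        mask = rep_orig == orig
        comp = roots[mask]
        imgs = rep_img[mask]
        for dim in range(3):
            uniq, inv = np.unique(comp, return_inverse=True)
            for c in range(len(uniq)):
                vals = imgs[inv == c, dim]
                if len(np.unique(vals)) > 1:
                    spans[dim] = True
    return tuple(spans)  # type: ignore[return-value]


def _place_dispersed(
    n: int, box: np.ndarray, rng: np.random.Generator, min_sep: float,
    existing: np.ndarray | None = None, max_tries: int = 20000,
) -> np.ndarray:
    pts: list[np.ndarray] = []
    anchors = [] if existing is None else list(existing)
    tries = 0
    while len(pts) < n:
        cand = rng.random(3) * box
        ok = True
        for other in pts + anchors:
            d = cand - other
            d -= box * np.round(d / box)
            if float(d @ d) < min_sep * min_sep:
                ok = False
                break
        if ok:
            pts.append(cand)
        tries += 1
        if tries > max_tries:
            raise RuntimeError("could not place points at requested separation")
    return np.array(pts) if pts else np.zeros((0, 3))


def gen_config(spec: ConfigSpec) -> tuple[Frame, Topology, ConfigTruth]:
    """Generate one configuration with the requested water motif.

    Waters are represented by their O center pseudo-atoms and cations by
    their P center pseudo-atoms, matching the center conventions used by
    all downstream analyses.
    """
    rng = np.random.default_rng(spec.seed)
    box = np.asarray(spec.box, dtype=float)
    n = spec.n_water
    s = spec.spacing
    if spec.motif == "chain":
        length = (n - 1) * s
        if length >= box[0] - 2.0:
            raise ValueError("chain does not fit in the box without wrapping")
        x0 = 1.0
        water = np.zeros((n, 3))
        water[:, 0] = x0 + np.arange(n) * s
        water[:, 1] = box[1] / 2.0
        water[:, 2] = box[2] / 2.0
    elif spec.motif == "vein":
        if n == 0:
            raise ValueError("vein motif needs waters")
        pitch = box[0] / n
        if pitch >= spec.water_cutoff:
            raise ValueError(
                "too few waters to wrap the box at the clustering cutoff"
            )
        water = np.zeros((n, 3))
        water[:, 0] = np.arange(n) * pitch
        water[:, 1] = box[1] / 2.0 + rng.normal(0.0, 0.25, n)
        water[:, 2] = box[2] / 2.0 + rng.normal(0.0, 0.25, n)
    elif spec.motif == "globule":
        # jittered cubic lattice clipped to the smallest ball holding n points
        a = s
        side = int(np.ceil(n ** (1 / 3))) + 2
        grid = np.array(
            [
                [i, j, k]
                for i in range(-side, side + 1)
                for j in range(-side, side + 1)
                for k in range(-side, side + 1)
            ],
            dtype=float,
        ) * a
        order = np.argsort(np.einsum("ij,ij->i", grid, grid), kind="stable")
        pts = grid[order[:n]]
        pts = pts + rng.normal(0.0, 0.05 * a, pts.shape)
        water = pts + box / 2.0
        if np.any(water.min(axis=0) < 0) or np.any(water.max(axis=0) > box):
            raise ValueError("globule does not fit in the box")
    elif spec.motif == "interlocked":
        water = _place_dispersed(n, box, rng, spec.min_separation)
    else:  # dispersed
        water = _place_dispersed(n, box, rng, spec.min_separation)

    if spec.motif == "interlocked":
        # wrapped cubic lattice of cation centers spanning every dimension
        per_side = max(2, int(round(spec.n_tbp ** (1 / 3))))
        n_tbp = spec.n_tbp
        a_t = box / per_side
        if np.any(a_t >= spec.tbp_cutoff):
            raise ValueError("interlocked lattice pitch exceeds the TBP cutoff")
        sites = np.array(
            [
                [i, j, k]
                for i in range(per_side)
                for j in range(per_side)
                for k in range(per_side)
            ],
            dtype=float,
        ) * a_t
        if len(sites) < n_tbp:
            raise ValueError("interlocked motif needs a cubic cation count")
        tbp = sites[:n_tbp] + rng.normal(0.0, 0.05 * a_t.min(), (n_tbp, 3))
        tbp = np.mod(tbp, box)
    elif spec.n_tbp > 0:
        tbp = _place_dispersed(
            spec.n_tbp, box, rng, max(spec.min_separation, 4.0), existing=water
        )
    else:
        tbp = np.zeros((0, 3))

    positions = np.vstack([water, tbp]) if len(tbp) else water
    species = np.array(
        ["water"] * len(water) + ["cation"] * len(tbp), dtype=object
    )
    role = np.array(
        ["water_center"] * len(water) + ["cation_center"] * len(tbp), dtype=object
    )
    topo = Topology(
        molecule_id=np.arange(len(positions)),
        species=species,
        role=role,
    )
    frame = Frame(0.0, box, np.mod(positions, box))

    labels = _brute_labels(water, box, spec.water_cutoff)
    counts = _brute_neighbor_counts(water, box, spec.water_cutoff)
    sizes = np.bincount(labels) if len(labels) else np.array([0])
    largest = int(np.argmax(sizes))
    frac = sizes[largest] / max(len(water), 1)
    mean_nn = float(counts[labels == largest].mean()) if len(water) else 0.0
    if spec.motif == "vein":
        spanning = (True, False, False)
    elif spec.motif in ("chain", "globule"):
        spanning = (False, False, False)
    else:
        spanning = _brute_spanning(water, box, spec.water_cutoff, labels, largest)
    tbp_labels = _brute_labels(tbp, box, spec.tbp_cutoff) if len(tbp) else None
    truth = ConfigTruth(
        labels=labels,
        neighbor_counts=counts,
        largest_fraction=float(frac),
        mean_neighbors_largest=mean_nn,
        spanning_largest=spanning,
        cutoff=spec.water_cutoff,
        tbp_labels=tbp_labels,
    )
    return frame, topo, truth


# ---------------------------------------------------------------------------
# planted hydrogen-bond configurations


@dataclass
class HBondTruth:
    bonds: list[tuple[int, int, int]]  # (donor, hydrogen, acceptor) atom indices
    decoy_kinds: list[str] = field(default_factory=list)


def gen_hbond_config(
    n_true_bonds: int,
    n_decoys: int,
    seed: int = 0,
    box_edge: float | None = None,
) -> tuple[Frame, Topology, HBondTruth]:
    """Plant donor-H-acceptor triplets for detector validation.

    Each true triplet satisfies all three geometric criteria
    (H...A <= 2.45 A, donor-angle <= 30 deg, D...A <= 3.5 A); each decoy
    violates exactly one.  A decoy violating only the donor-acceptor
    cutoff uses a 1.09 A donor-H bond (a C-H donor): with the 0.96 A O-H
    bond, H...A >= D...A - 0.96 > 2.45 whenever D...A > 3.5, so the
    single-violation geometry would be impossible.

    Sites are laid on an 8 A lattice so triplets cannot cross-talk.
    """
    n_sites = n_true_bonds + n_decoys
    rng = np.random.default_rng(seed)
    per_side = max(2, int(np.ceil(n_sites ** (1 / 3))))
    pitch = 8.0
    if box_edge is None:
        box_edge = per_side * pitch
    box = np.full(3, float(box_edge))
    site_idx = np.array(
        [
            [i, j, k]
            for i in range(per_side)
            for j in range(per_side)
            for k in range(per_side)
        ],
        dtype=float,
    )
    if len(site_idx) < n_sites:
        raise ValueError("box too small for requested triplet count")
    sites = site_idx[:n_sites] * pitch + pitch / 2.0

    decoy_cycle = ("distance", "angle", "donor_acceptor")
    positions: list[np.ndarray] = []
    mol_id: list[int] = []
    species: list[str] = []
    role: list[str] = []
    donors: list[tuple[int, int]] = []
    acceptors: list[int] = []
    bonds: list[tuple[int, int, int]] = []
    decoy_kinds: list[str] = []

    def random_unit() -> np.ndarray:
        v = rng.standard_normal(3)
        return v / np.linalg.norm(v)

    def perpendicular(u: np.ndarray) -> np.ndarray:
        v = rng.standard_normal(3)
        v -= u * (v @ u)
        return v / np.linalg.norm(v)

    mol = 0
    for t in range(n_sites):
        d_pos = sites[t]
        u = random_unit()
        kind = "true" if t < n_true_bonds else decoy_cycle[(t - n_true_bonds) % 3]
        if kind == "true":
            d_da, d_dh, angle = 2.9, 0.96, 0.0
        elif kind == "distance":  # violates H...A only
            d_da, d_dh, angle = 3.45, 0.96, 0.0
        elif kind == "angle":  # violates the 30 deg donor angle only
            d_da, d_dh, angle = 2.6, 0.96, math.radians(35.0)
        else:  # donor_acceptor: violates the 3.5 A D...A cutoff only
            d_da, d_dh, angle = 3.52, 1.09, 0.0
        a_pos = d_pos + d_da * u
        if angle == 0.0:
            h_pos = d_pos + d_dh * u
        else:
            w = perpendicular(u)
            h_pos = d_pos + d_dh * (math.cos(angle) * u + math.sin(angle) * w)
        di = len(positions)
        positions.extend([d_pos, h_pos])
        mol_id.extend([mol, mol])
        species.extend(["water", "water"])
        role.extend(["water_center", "other"])
        donors.append((di, di + 1))
        mol += 1
        ai = len(positions)
        positions.append(a_pos)
        mol_id.append(mol)
        species.append("water")
        role.append("water_center")
        acceptors.append(ai)
        mol += 1
        if kind == "true":
            bonds.append((di, di + 1, ai))
        else:
            decoy_kinds.append(kind)

    pos = np.mod(np.array(positions).reshape(-1, 3), box)
    topo = Topology(
        molecule_id=np.array(mol_id),
        species=np.array(species, dtype=object),
        role=np.array(role, dtype=object),
        donors=np.array(donors, dtype=int).reshape(-1, 2),
        acceptors=np.array(acceptors, dtype=int),
    )
    frame = Frame(0.0, box, pos)
    return frame, topo, HBondTruth(bonds=bonds, decoy_kinds=decoy_kinds)


# ---------------------------------------------------------------------------
# linear-in-temperature thermodynamic series


@dataclass
class ThermoTruth:
    cp_true: float  # J g^-1 K^-1
    alpha_p_true: float  # K^-1
    h_means: dict[float, float]  # J at each temperature
    v_means: dict[float, float]  # A^3 at each temperature


def gen_thermo_series(
    cp_true: float,
    alpha_p_true: float,
    mass: float,
    temps: tuple[float, ...] = (280.0, 300.0, 320.0),
    noise_sd_enthalpy: float = 0.0,
    noise_sd_volume: float = 0.0,
    n_samples: int = 1000,
    dt: float = 5.0,
    v_ref: float = 90000.0,
    t_ref: float = 300.0,
    ar1_phi: float = 0.0,
    seed: int = 0,
) -> tuple[list[ThermoSeries], ThermoTruth]:
    """Enthalpy/volume series linear in temperature with additive noise.

    H(T) has slope ``cp_true * mass`` (J/K); v(T) has relative slope
    ``alpha_p_true`` about ``v_ref`` at ``t_ref``.  ``ar1_phi`` adds AR(1)
    correlation to the noise so blocking analysis has something to find.
    """
    rng = np.random.default_rng(seed)
    h0 = 0.0
    series: list[ThermoSeries] = []
    h_means: dict[float, float] = {}
    v_means: dict[float, float] = {}

    def noise(sd: float) -> np.ndarray:
        if sd == 0.0:
            return np.zeros(n_samples)
        eps = rng.standard_normal(n_samples) * sd
        if ar1_phi != 0.0:
            out = np.empty(n_samples)
            out[0] = eps[0] / math.sqrt(1.0 - ar1_phi**2)
            for i in range(1, n_samples):
                out[i] = ar1_phi * out[i - 1] + eps[i]
            return out
        return eps

    for temp in temps:
        h_mean = h0 + cp_true * mass * temp
        v_mean = v_ref * (1.0 + alpha_p_true * (temp - t_ref))
        h = h_mean + noise(noise_sd_enthalpy)
        v = v_mean + noise(noise_sd_volume)
        dens = mass / (v * 1e-24)  # g/cm^3 when mass is in grams
        series.append(
            ThermoSeries(
                time=np.arange(n_samples) * dt,
                enthalpy=h,
                volume=v,
                density=dens,
                temperature=np.full(n_samples, temp),
            )
        )
        h_means[temp] = h_mean
        v_means[temp] = v_mean
    return series, ThermoTruth(cp_true, alpha_p_true, h_means, v_means)
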