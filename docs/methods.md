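# Methods

This note documents the models implemented in `ilmix`, the defaults and
why they were chosen, what the synthetic-data generators do and do not
emulate, and the numerical decisions a user should know before trusting
a result.

## Conventions

Coordinates and box edges are in ångström, time in picoseconds,
densities in g/cm³. Boxes are orthorhombic; readers reject triclinic
cells explicitly rather than silently mis-imaging distances. Wrapped
coordinates live on [0, L) per axis and every distance downstream uses
the minimum-image convention, which restricts pair analyses to
r < min(L)/2. Molecular centers of mass are approximated by one
representative atom — the central P of the tetrabutylphosphonium
cation, the O of hydroxide and of water — a proxy that is accurate to a
few tenths of an ångström for these molecules because of their symmetry
and central mass weighting; all RDF, clustering and displacement
analyses operate on these center pseudo-particles.

## Composition

Molar masses come from an embedded table of IUPAC standard atomic
weights (conventional abridged values; two-decimal precision is ample
for one-decimal mole-percent outputs). Weight-to-mole percent uses
x = (w/M_w)/(w/M_w + (100−w)/M_IL); the inverse is exact and the pair
round-trips to 1e−10 relative. Percent outputs are rounded half-up to
one decimal for display only. Atom totals count TBP⁺ as 53 sites, OH⁻
as 2, Cl⁻ as 1, and water as 3 — water keeps 3 counted sites even under
4-site rigid models whose 4th site is massless, which is the only
convention consistent with the published per-system atom totals the
manifest reproduces. The built-in manifest covers the 17 TBPH–water
systems; the chloride systems' totals are not tabulated at the source
and are therefore not invented here.

## Trajectory handling

The LAMMPS text-dump reader accepts absolute (`x y z`), scaled
(`xs ys zs`) and pre-unwrapped (`xu yu zu`) coordinates with optional
image flags, sorts atoms by id, and errors on varying atom counts or
missing columns. Unwrapping uses image flags when present; otherwise it
accumulates minimum-image frame-to-frame displacements, which is exact
as long as no particle moves half a box edge between frames — a
condition that cannot be verified from wrapped data alone, so a
warning names the first frame/atom whenever a step sits on that
boundary. Unwrapping preserves first-frame coordinates and all
minimum-image inter-frame displacements; wrap∘unwrap is the identity
modulo the box.

## Radial distribution functions

Pair distances are histogrammed per frame (KD-tree with periodic box)
and normalized by the ideal-gas shell count 4πr²dr·ρ_B per center of
the first species; same-species pairs are counted once with the
N(N−1)/2 normalization and the self pair excluded. Per-frame density is
used (for constant-volume runs this coincides with the global mean).
Defaults: bin width 0.1 Å, r_max just under half the smallest box edge.
Intramolecular pairs are excluded by default except for the
terminal-carbon (C4–C4) analysis, where the intramolecular arm-to-arm
distribution is the signal. The first-shell radius is the first local
minimum after the first local maximum of g(r), found on a
Savitzky–Golay-smoothed curve (window 5 bins, order 2) with a
prominence threshold of 5% of the curve's range so numerical ripple on
flat curves is not mistaken for shell structure; featureless curves
raise "no shell structure". Coordination numbers integrate
4πρ_B g r² dr by the trapezoid rule with the range closed at r = 0 and
interpolated at r_cut, keeping the binning error second order.

## Clustering and percolation

Two centers are bonded when their minimum-image distance is strictly
below the cutoff: 9.1 Å (TBPH) and 9.3 Å (TBPCl) for cation–cation
contacts — the first-solvation-shell radii — and 3.5 Å by default for
water–water (the hydrogen-bond donor–acceptor cutoff; no water cutoff
is stated at the source, so it is configurable and can be derived from
the water O–O RDF's first minimum instead, with ±0.3 Å sensitivity
worth reporting). Clusters are connected components of that graph. A
cluster spans a dimension when a cycle in its contact graph accumulates
a nonzero net periodic image shift there — detected during
breadth-first unwrapping when a revisited member's coordinate disagrees
by a box multiple (the standard wrapping-cluster criterion, exact under
PBC, unlike largest-extent heuristics). Shape metrics come from the
gyration tensor of the unwrapped cluster: asphericity
b = λ₁ − (λ₂+λ₃)/2 normalized by the trace, 1 for a rod and 0 for a
sphere. Classification defaults — vein: spanning in ≥ 1 dimension and
asphericity > 0.5; globule: non-spanning and asphericity < 0.3; else
intermediate — quantify what the source literature classifies only
visually, and are exposed as configuration values.

## Hydrogen bonds

A bond D–H···A requires H···A ≤ 2.45 Å, donor-vertex angle between
D→H and D→A ≤ 30°, and D···A ≤ 3.5 Å (all inclusive, minimum-image).
The donor-vertex convention matches the VMD-style criterion used with
these thresholds; the hydrogen-vertex alternative is a switch. Donor–H
pairs and acceptors are topology roles, not hard-coded chemistry, so
water can donate and accept, hydroxide accepts (and its H may donate),
and cation C–H donors are expressible. A D–A pair with two qualifying
hydrogens counts twice (per-H triplet enumeration). Counts for a pair
(x, y) include bonds in either direction between the species and are
normalized by the number of x molecules.

## Thermodynamics

Blocking (Flyvbjerg–Petersen) halves the series by pairwise averaging;
the standard error per level is s/√n with one-sigma uncertainty
SE/√(2(n−1)), and the plateau is the first level whose SE agrees with
the next within that uncertainty. White noise plateaus at level ~0
(naive SE); AR(1) with φ = 0.9 reproduces the analytic √((1+φ)/(1−φ))
inflation within a few percent at n = 2¹⁴. If no plateau is reached the
largest SE is reported and the result flagged unconverged. Excess
properties are mixture minus mole-fraction-weighted pure values, on the
per-total-molecule basis (an IL pair counts as one molecule). The pure-
IL endpoint in practice is the water-infinite-dilution system, an
approximation inherited from the data. c_p and α_p use the least-squares
slope over the temperature grid (280/300/320 K by default; identical to
the central difference at three equispaced points), α_p normalized by
the volume at the middle temperature; the quoted uncertainty is half
the maximum change between adjacent two-point slopes — a worst-case
curvature measure, reported separately from (never merged with) the
blocking errors of the means. The heat-capacity correction factor is
computed as cp_exp/cp_sim from an explicitly supplied simulated
pure-water value (e.g. 4.184/5.10 = 0.820); no ratio is hard-coded
because published tables are ambiguous about which simulated value
anchors it.

## Transport

TAMSDs are computed for every particle by the FFT autocorrelation
algorithm (O(T log T) per particle and dimension, exactly equal to the
window-by-window double loop), then sampled on a lag grid with 25 ps
spacing (0.025 ns, the spacing the source analyses used) up to half the
measurement time by default — beyond t/2 too few windows remain and
the estimate degrades; full-window fitting is behind a flag. The
power-law fit is OLS of log⟨δ̄²⟩ on log Δ with approximately
log-uniform thinning of the lag grid (≤ 50 points) so the dense long-
lag end does not dominate; the raw prefactor and the 2d-normalized K_α
are both reported, with unit conversion to cm² s^−α stating the
exponent per value because the unit itself depends on α. χ uses the
population variance (the definitional form; sample variance behind a
flag). The ergodicity report compares MSD with the particle-averaged
TAMSD by relative sup-distance on the common lag window: below 15% is
"ergodic-overlap", else "aging/non-overlap"; regime labels are normal
(α ≥ 0.96), subdiffusive (α < 0.90), near-normal between. The MSD is a
single-time-origin average, so its sampling noise sets how many
particles the 15% discrimination needs: ~400+ walkers for a clean
separation at α = 0.5; at 300 the sup-distance straddles the threshold.

## Synthetic data: what it does and does not emulate

Walkers: fBm uses exact-covariance construction per dimension
(Cholesky for ≤ 64 steps, Davies–Harte circulant embedding beyond, with
a Cholesky fallback if an embedding were ever indefinite), scaled so
the 3-D ensemble MSD is 6K t^α with H = α/2 ∈ (0, 0.5]; Brownian is the
α = 1 limit; CTRW draws Pareto waits with tail exponent α and Gaussian
jumps scaled to match 6K t^α on ensemble average. CTRW exists solely to
exercise aging/non-overlap detection — the case distinguishing
percolation-like subdiffusion (ergodic, overlapping curves) from
trap-dominated subdiffusion. Configurations: the vein is a wrapped
channel along x with small lateral jitter, the globule a jittered
lattice ball, the chain a straight path with interior coordination 2,
dispersed a minimum-separation Poisson placement, interlocked a wrapped
lattice spanning all dimensions — minimal geometries realizing the
motif categories, with ground-truth labels computed inside the
generator by an O(N²) double loop and a 3×3×3 replicated-cell spanning
test, independent of the analysis algorithms. Planted hydrogen-bond
decoys each violate exactly one criterion; the donor–acceptor-only
decoy uses a 1.09 Å C–H donor bond because with a 0.96 Å O–H bond that
single violation is geometrically impossible (H···A ≥ D···A − 0.96).
Thermo series are exactly linear in T with additive (optionally AR(1))
noise.

None of these generators sample a force field: passing tests
demonstrates the estimators are correct and calibrated on processes
with known truth, not that any particular MD system is well described
by fBm, ideal mixing, or linear H(T). Quantities that require the real
MD ensembles (absolute heat capacities, per-system hydrogen-bond
counts, the published K_α/α tables) are schema-compatible outputs of
the pipeline but are not reproduced from first principles.

## Problem sizes and determinism

Default validation sizes — 200 walkers × 4000 steps for exponent
recovery (median over 10 seeds), 400 × 2000 for overlap classification,
≤ 300 points and ≤ 44 molecules for brute-force cross-checks over 50
seeds, 2¹⁴ samples for blocking calibration — were chosen so each
recovery's sampling error sits well inside its tolerance while the full
suite stays interactive. Every generator and the pipeline are
deterministic under a fixed seed; identical config + seed yields
byte-identical numeric outputs.

## Known limitations

- Orthorhombic cells only; no triclinic support by design.
- No binary trajectory formats (DCD/NetCDF); text dump and XYZ only.
- Cluster tracking over time, H-bond lifetimes, structure factors and
  Green–Kubo transport are out of scope.
- The spanning test labels a cluster, not a frame sequence: transient
  percolation requires analyzing frames independently.
- CTRW K has no clean stationary meaning (the process ages); only its
  short-time ensemble scaling is matched.
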