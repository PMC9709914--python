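# Methods

## Metric layer

Configurations are points in the `n = 3 n_a` (or `2 n_a` for planar toy
data) dimensional coordinate space of the `n_a` selected atoms, in nm.
The similarity metric is the mass-unweighted RMSD

    rmsd(a, b) = sqrt( (1/n_a) * Σ_atoms |a_i - b_i|² )

optionally minimized over rigid motions of one configuration.  The
minimizer is the Kabsch algorithm: center both configurations, take the
SVD of the covariance `H = Aᵀ B = U Σ Wᵀ`, and use the proper rotation
`(U diag(1, …, 1, det(UWᵀ)) W)ᵀ`, i.e. the smallest singular direction is
flipped whenever the unconstrained optimum would be a reflection.  The
minimized RMSD comes from the trace identity
`rmsd² = (|A|² + |B|² − 2 Σ σ̃_i)/n_a` with the last singular value negated
under reflection correction.  Degenerate inputs (single atom, collinear
atoms) have rank-deficient `H`; the SVD branch still returns a valid
proper-rotation minimizer.  Atoms are uniformly weighted throughout: no
mass or occupancy weighting, no periodic-boundary handling, no
internal-coordinate metrics.

The pairwise matrix is computed in two modes.  `pairwise_fit` (default)
superposes every pair independently (row-blocked batched 3×3 SVDs, so the
N = 6001 tau matrix is feasible on one CPU); `prealigned` measures raw
coordinate differences and is the appropriate mode when the trajectory has
already been fitted to a common reference, and the only defined mode for
the 2D single-atom representation.  Every pairwise-fit entry is bounded
above by its prealigned counterpart.  The matrix is stored exactly
symmetric with an exactly zero diagonal so strict threshold comparisons
can never disagree between `(i, j)` and `(j, i)`.

## Clustering algorithms

Both algorithms share the outer loop.  With `I_m` the indices still
available at iteration `m` (all indices at `m = 1`), every `k ∈ I_m`
proposes a tentative cluster; the largest proposal becomes cluster `C_m`,
its members leave the pool, and iteration continues until the pool is
empty or the winning cluster falls below `min_size` (the undersized winner
is *not* emitted; it and everything still unclustered are reported as
unassigned, with rank 0 in the output tables).

* **RTC** (radial threshold `θ_r`): the proposal of seed `k` is its strict
  radial neighbor set `A_k = {i ∈ I_m : rmsd(k, i) < θ_r}`, which always
  contains `k` itself.
* **QTC** (diametral threshold `θ_d`): the proposal is grown greedily from
  `{k}` — among remaining candidates, add the one whose inclusion
  minimizes the resulting diameter, subject to the diameter remaining
  strictly below `θ_d`; stop when no candidate qualifies.  The candidate
  pool is restricted to `A_k(θ_d)`: a point at `rmsd ≥ θ_d` from the seed
  can never enter, so the restriction is a pure optimization with
  provably identical output (cross-checked against an unrestricted-pool
  re-simulation in the tests).

Deterministic tie-breaking:

* equal-size tentative clusters: selection rule `f`, by default the lowest
  seed index; `f` is injectable for order-sensitivity experiments;
* equal resulting diameter during QTC growth: lowest frame index.
  Floating-point ties are compared exactly, with no epsilon — two
  candidates tie only when their resulting diameters are bit-identical
  (common on symmetric or duplicated configurations, vanishingly rare on
  generic data);
* all inequalities are strict (`rmsd < θ`, diameter `< θ`); values exactly
  equal to the threshold are excluded.

Seeds are evaluated in ascending index order, but the result is
independent of evaluation order except through `f` (asserted by shuffling
in the tests).  The full run caches each seed's grown QTC proposal across
iterations and invalidates it only when the removed members intersect the
seed's candidate pool, which leaves results bit-identical while making
full runs on thousands of configurations practical.

Guarantees (all enforced by tests): clusters plus unassigned always
partition the indices; every RTC member is strictly within `θ_r` of its
seed; every QTC cluster has diameter strictly below `θ_d`; RTC cluster
sizes never increase with rank.  QTC sizes may invert (`|C_m| <
|C_{m+1}|`): the greedy growth direction around a seed can be less
favorable in an earlier, denser pool than in a later one.  Inversions are
rare and only recorded, never forbidden, by the tests.

## Threshold selection

A threshold is physically meaningful when it separates a conformer's own
density shell from its neighbors'.  The implemented workflow: run a
tentative radial clustering, take the seeds of the most populated
clusters, and for each seed histogram its full matrix row (the RMSD from
that seed to every other configuration).  These profiles typically show a
first high-density shell, a trough ("deep") at or near zero density — the
conformational-transition region — and a later rise.  The deep is located
per profile on a fixed-width histogram (default bin width 0.005 nm)
smoothed with a 3-bin moving average: the first bin after the first local
maximum whose density falls below 5% of that mode's peak, or a strict
local minimum that is also below half the peak (the prominence condition
keeps histogram noise on a flat tail from triggering).  If the density
never recovers, the deep is the end of the support.  All three knobs
(bin width, smoothing window, drop fraction) are parameters.  The
consensus over profiles is the maximum of the per-profile deeps — a value
at which every profile has already collapsed or not yet recovered.  The
result is radial in nature: it bounds seed-to-member distances, so it is a
`θ_r`, not a `θ_d`.  This consensus rule is one defensible formalization
of what is ultimately a visual judgment across profiles.

## Cluster geometry diagnostics

* diameter: largest pairwise member RMSD (0 for singletons);
* centroid convention: members are least-squares fitted to the seed (the
  one frame every member already relates to) before coordinate averaging;
  prealigned ensembles are used as-is;
* radius of gyration: `rog = sqrt( (1/|C|) Σ_i rmsd(x_i, x_c)² )` with
  `x_c` the member centroid — the population form, divisor `|C|`;
* seed-to-centroid RMSD, quantifying how off-center seeds are (QTC seeds
  drift toward the cluster boundary because greedy growth runs away from
  the seed in eccentric layers; the majority-vote comparison against RTC
  seeds is a test);
* distance-sum/angle records: for non-seed member pairs `(j, k)` of a
  cluster with seed `i`, `rmsd_ij + rmsd_ik` against the angle between the
  full-coordinate difference vectors `x_j − x_i` and `x_k − x_i` (degrees;
  the arccos argument is clamped to [−1, 1]).  A pair only realizes a
  diameter near the sum when the angle approaches 180°, which is why RTC
  diameters stay well below `2 θ_r` on simulation-like data;
* intra-cluster RMSD distributions (split/bimodal shapes flag merged
  populations) and coverage tables (clusters above size cutoffs and the
  population percentage they hold).

Note that after per-pair fitting the RMSD is not a vector-space norm, so
norm-based identities (e.g. diameter ≤ 2·max member-to-centroid distance)
are deliberately not asserted; the diagnostics only use relations that
survive the fitted metric.

## Synthetic data

The planted generator emulates the statistical geometry the algorithms are
sensitive to, nothing more: `k` isotropic Gaussian clusters (per-coordinate
sigma, in nm) around centers rejection-sampled uniformly in a hypercube
scaled so that the pairwise center RMSD constraint (`min_separation`) is
comfortably feasible; optionally the first member of each cluster is
planted exactly at its center.  The expected member-to-center RMSD is
`σ√3`.  There is no bonded structure and no Boltzmann weighting, so
passing tests demonstrate correct algorithmic behavior on well- and
poorly-separated density regions, not fidelity to any force field.  The
default study conditions are 3 clusters × 100 members, σ = 0.02 nm,
separation ≥ 0.5 nm — a separation/spread ratio comfortably above 10, the
regime where both algorithms must recover the partition exactly.

2D fixtures are uniform disks (dense, structureless), Gaussian blobs, or
multimodal mixtures, treated as single-atom two-coordinate configurations
under the prealigned metric.  A trajectory-like ensemble can also be
reduced to 2D by fitting all frames to a reference and keeping one atom's
x, y — with 1-in-k subsampling to mimic the sparse sampling of real
clustering exercises.

All generators use numpy's PCG64 (`default_rng`) with explicit integer
seeds and are bit-reproducible.

## Radial/diametral comparability

With `θ_r = θ_d/2` both algorithms bound the cluster diameter by `θ_d`,
and on dense data with few voids they carve out clusters of closely
matching sizes; on sparse simulation-like data `θ_d/2 ≤ θ_r < θ_d` is
typically needed for size parity.  One caveat the test suite makes
explicit: on *continuum-random* structureless data (the uniform-disk
fixture) the first-cluster sizes agree only to within a few percent, not
exactly.  Both algorithms report the maximum proposal size over ~N seeds;
the radial maximum ranges over seed-centered balls of radius `θ_d/2`,
while the greedy diametral maximum effectively ranges over all
diameter-`θ_d` shapes at any position — an equal-area family by the
isodiametric inequality, but a strictly richer one, so its extreme value
is systematically a few boundary points larger.  Exact size equality
holds when cluster sizes are determined by the density structure rather
than by boundary fluctuations, i.e. on well-separated blobs, where both
algorithms return identical memberships (asserted on the planted
fixture).

## Problem sizes and numerical choices

The self-contained verification runs at desk scale: 200 random instances
with N ≤ 60 for the algebraic guarantees, 1000 instances with N ≤ 12
against the brute-force oracles, 1501 points for the 2D parity fixture,
300 configurations for the planted-recovery fixture, a 6° Euler grid
(all of SO(3)) for the superposition check.  The published-trajectory
reproduction (6001 configurations, 6001² pairwise-fit matrix) is a
separate script with a one-time download and a matrix cache.

Matrix entries are float64 end to end; the text cache writes `%.17g` (full
round-trip precision) and the binary cache is bit-exact.  Thresholds are
compared strictly with no epsilon.  Human-readable tables are 1-based
(frames and seeds), the API 0-based.

## Known limitations

* Only Heyer-style greedy growth is implemented for the diametral
  proposal; the growth procedure is injectable but time-sequence growth
  and maximal-subset search variants are out of scope.
* No hierarchical, density-based, or approximate/bit-packed accelerations.
* The deep-finding heuristic assumes a first shell followed by a trough;
  profiles without that structure are skipped with a warning, and the
  consensus rule (max over profiles) is a design choice, not the only
  reasonable one.
* PDB/DCD/XTC input only (via mdtraj); no GROMACS/AMBER topologies.
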