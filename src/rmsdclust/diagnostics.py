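"""Threshold-selection and cluster-geometry diagnostics.

The physically motivated way to pick a radial threshold is to query the
configuration space itself: take the seeds of the most populated clusters
from a first, tentative clustering and look at the distribution of RMSDs
from each seed to every other configuration.  These distributions typically
show a first high-density shell around the seed, then a trough ("deep")
where the density drops to (near) zero — the conformational-transition
region — and then a second rise.  The deep location is a natural radial
cutoff; a consensus over several seeds gives the final threshold.

The remaining diagnostics characterize cluster geometry: the generalized
diameter (largest pairwise RMSD among members), the cluster radius of
gyration (rms deviation of the members from their center of geometry), the
seed-to-centroid RMSD (seeds are not central elements, especially for
quality-threshold clusters), the pairwise distance-sum/angle records that
explain why radial clusters rarely reach the 2*theta_r diameter bound, and
coverage statistics over the cluster-size ranking.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from typing import Sequence

import numpy as np
import pandas as pd

from .clustering import Cluster, ClusteringResult
from .geometry import (
    ConfigurationEnsemble,
    MatrixMode,
    RmsdMatrix,
    rmsd_raw,
    superpose,
    apply_superposition,
)

__all__ = [
    "SeedProfile",
    "ClusterGeometry",
    "PairAngleRecord",
    "cluster_diameter",
    "seed_profile",
    "suggest_radial_threshold",
    "ThresholdSuggestion",
    "radius_of_gyration",
    "seed_centroid_rmsd",
    "cluster_geometry",
    "pair_sum_angle",
    "intra_cluster_distribution",
    "coverage_report",
]


@dataclass(frozen=True)
class SeedProfile:
    """RMSD distribution from one seed to every other configuration."""

    seed: int
    distances: np.ndarray
    bin_edges: np.ndarray
    densities: np.ndarray


@dataclass(frozen=True)
class ClusterGeometry:
    """Geometric summary of one cluster (all lengths in nm)."""

    rank: int
    diameter: float
    rog: float
    seed_centroid_rmsd: float
    centroid: np.ndarray


@dataclass(frozen=True)
class PairAngleRecord:
    """For one pair (j, k) of non-seed members with seed i:
    rmsd_ij + rmsd_ik and the angle between x_j - x_i and x_k - x_i."""

    pair: tuple[int, int]
    distance_sum: float
    angle: float


def cluster_diameter(matrix: RmsdMatrix, cluster: Cluster) -> float:
    """Largest pairwise RMSD among cluster members; 0 for singletons."""
    members = np.asarray(cluster.members, dtype=np.intp)
    if members.size == 0:
        raise ValueError("cluster has no members")
    if members.size == 1:
        return 0.0
    return float(matrix.values[np.ix_(members, members)].max())


def seed_profile(
    matrix: RmsdMatrix,
    seed: int,
    bins: int | Sequence[float] | str = "auto",
) -> SeedProfile:
    """Distances from one seed to all other configurations, as a density.

    The seed's full matrix row minus its (zero) diagonal entry, histogrammed
    as a probability density (the densities integrate to one over the binned
    range).
    """
    if matrix.n < 2:
        raise ValueError("a seed profile needs at least two configurations")
    row = matrix.values[seed]
    distances = np.delete(row, seed)
    densities, edges = np.histogram(distances, bins=bins, density=True)
    return SeedProfile(
        seed=int(seed), distances=distances, bin_edges=edges, densities=densities
    )


@dataclass(frozen=True)
class ThresholdSuggestion:
    """Consensus radial threshold plus the per-seed deep locations."""

    threshold: float
    per_profile: pd.DataFrame


def _find_deep(
    distances: np.ndarray,
    bin_width: float,
    smooth_window: int,
    drop_fraction: float,
) -> float | None:
    """Locate the first trough after the first mode of a smoothed density.

    Histogram at fixed ``bin_width``, smooth with a ``smooth_window``-bin
    moving average, find the first local maximum (the first shell), then the
    first subsequent bin whose density falls below ``drop_fraction`` of that
    mode's peak or is a strict local minimum.  Returns the bin-center
    location, or None when no mode/trough structure exists.
    """
    hi = float(distances.max())
    if hi <= 0:
        return None
    edges = np.arange(0.0, hi + 2 * bin_width, bin_width)
    dens, edges = np.histogram(distances, bins=edges, density=True)
    kernel = np.ones(smooth_window) / smooth_window
    smooth = np.convolve(dens, kernel, mode="same")
    centers = 0.5 * (edges[:-1] + edges[1:])
    # first local maximum of the smoothed density
    mode_idx = None
    for i in range(len(smooth)):
        left = smooth[i - 1] if i > 0 else -np.inf
        right = smooth[i + 1] if i + 1 < len(smooth) else -np.inf
        if smooth[i] > 0 and smooth[i] >= left and smooth[i] > right:
            mode_idx = i
            break
    if mode_idx is None:
        return None
    peak = smooth[mode_idx]
    for j in range(mode_idx + 1, len(smooth)):
        if smooth[j] < drop_fraction * peak:
            return float(centers[j])
        # a strict local minimum counts only when genuinely deep (below half
        # the mode peak), so histogram noise on a flat tail cannot trigger it
        if (
            0 < j < len(smooth) - 1
            and smooth[j - 1] > smooth[j] < smooth[j + 1]
            and smooth[j] < 0.5 * peak
        ):
            return float(centers[j])
    # density never recovers: unimodal profile — threshold at end of support
    return float(edges[np.nonzero(dens)[0][-1] + 1])


def suggest_radial_threshold(
    profiles: Sequence[SeedProfile],
    bin_width: float = 0.005,
    smooth_window: int = 3,
    drop_fraction: float = 0.05,
) -> ThresholdSuggestion:
    """Consensus radial threshold from seed RMSD distributions.

    For each profile the first trough ("deep") after the first density mode
    is located; the consensus is the maximum of the per-profile deep
    locations — a point where every profile's density has already collapsed
    or not yet recovered.  Profiles with fewer than two distinct distances
    are skipped with a warning.

    Parameters
    ----------
    bin_width : float
        Histogram bin width in nm (default 0.005 nm).
    smooth_window : int
        Moving-average window in bins (default 3).
    drop_fraction : float
        Density fraction of the first mode's peak below which a bin counts
        as the deep (default 0.05).
    """
    if len(profiles) == 0:
        raise ValueError("need at least one seed profile")
    rows = []
    for prof in profiles:
        if np.unique(prof.distances).size < 2:
            warnings.warn(
                f"seed {prof.seed}: fewer than two distinct distances; skipped",
                stacklevel=2,
            )
            continue
        deep = _find_deep(prof.distances, bin_width, smooth_window, drop_fraction)
        if deep is None:
            warnings.warn(f"seed {prof.seed}: no mode/trough structure; skipped",
                          stacklevel=2)
            continue
        rows.append({"seed": prof.seed, "deep": deep})
    if not rows:
        raise ValueError("no usable profile: cannot suggest a threshold")
    table = pd.DataFrame(rows)
    return ThresholdSuggestion(threshold=float(table["deep"].max()), per_profile=table)


def _fitted_member_coords(
    ensemble: ConfigurationEnsemble, cluster: Cluster, mode: MatrixMode
) -> np.ndarray:
    """Member coordinates in the seed's frame.

    For pairwise-fit matrices every member is least-squares fitted onto the
    seed (the one frame each member already relates to); prealigned
    ensembles are used as-is.
    """
    members = list(cluster.members)
    coords = ensemble.coords[members]
    if mode is MatrixMode.PREALIGNED:
        return coords
    seed_xyz = ensemble.coords[cluster.seed]
    out = np.empty_like(coords)
    for idx, m in enumerate(members):
        if m == cluster.seed:
            out[idx] = seed_xyz
        else:
            res = superpose(ensemble.coords[m], seed_xyz)
            out[idx] = apply_superposition(ensemble.coords[m], res)
    return out


def radius_of_gyration(
    ensemble: ConfigurationEnsemble,
    cluster: Cluster,
    mode: MatrixMode | str = MatrixMode.PAIRWISE_FIT,
) -> float:
    """Cluster radius of gyration in RMSD units.

    rog_m = sqrt( (1/|C_m|) * sum over members i of rmsd(x_i, x_c)^2 ) with
    x_c the coordinate-wise mean of the members after fitting each to the
    seed.  Population form (divisor |C_m|).  0 for singletons.
    """
    fitted = _fitted_member_coords(ensemble, cluster, MatrixMode(mode))
    centroid = fitted.mean(axis=0)
    msd = np.mean([rmsd_raw(x, centroid) ** 2 for x in fitted])
    return float(np.sqrt(msd))


def seed_centroid_rmsd(
    ensemble: ConfigurationEnsemble,
    cluster: Cluster,
    mode: MatrixMode | str = MatrixMode.PAIRWISE_FIT,
) -> float:
    """RMSD between the seed and the members' center of geometry."""
    fitted = _fitted_member_coords(ensemble, cluster, MatrixMode(mode))
    centroid = fitted.mean(axis=0)
    return rmsd_raw(ensemble.coords[cluster.seed], centroid)


def cluster_geometry(
    ensemble: ConfigurationEnsemble,
    matrix: RmsdMatrix,
    cluster: Cluster,
) -> ClusterGeometry:
    """Bundle diameter, radius of gyration and seed-centroid distance."""
    fitted = _fitted_member_coords(ensemble, cluster, matrix.mode)
    centroid = fitted.mean(axis=0)
    msd = np.mean([rmsd_raw(x, centroid) ** 2 for x in fitted])
    return ClusterGeometry(
        rank=cluster.rank,
        diameter=cluster_diameter(matrix, cluster),
        rog=float(np.sqrt(msd)),
        seed_centroid_rmsd=rmsd_raw(ensemble.coords[cluster.seed], centroid),
        centroid=centroid,
    )


def pair_sum_angle(
    ensemble: ConfigurationEnsemble,
    cluster: Cluster,
    mode: MatrixMode | str = MatrixMode.PAIRWISE_FIT,
) -> list[PairAngleRecord]:
    """Distance sums and angles for member pairs, seen from the seed.

    After fitting all members to the seed i, every unordered pair (j, k) of
    non-seed members yields rmsd_ij + rmsd_ik and the angle phi (degrees)
    between the full-coordinate difference vectors x_j - x_i and x_k - x_i.
    A pair can only realize a diameter near rmsd_ij + rmsd_ik when phi is
    near 180 degrees, which is why radial clusters rarely reach the
    2*theta_r bound.  Zero-norm difference vectors are skipped with a
    warning.
    """
    members = [m for m in cluster.members if m != cluster.seed]
    if len(members) < 2:
        raise ValueError("pair/angle records need a seed plus at least two members")
    fitted = _fitted_member_coords(ensemble, cluster, MatrixMode(mode))
    by_index = dict(zip(cluster.members, fitted))
    seed_xyz = by_index[cluster.seed]
    n_a = ensemble.n_atoms
    vecs: dict[int, np.ndarray] = {}
    dists: dict[int, float] = {}
    for m in members:
        v = (by_index[m] - seed_xyz).ravel()
        norm = np.linalg.norm(v)
        if norm == 0.0:
            warnings.warn(f"member {m} coincides with the seed; pairs skipped",
                          stacklevel=2)
            continue
        vecs[m] = v
        dists[m] = float(norm / np.sqrt(n_a))
    keep = sorted(vecs)
    records = []
    for a_pos, j in enumerate(keep):
        for k in keep[a_pos + 1 :]:
            cosphi = float(
                np.dot(vecs[j], vecs[k])
                / (np.linalg.norm(vecs[j]) * np.linalg.norm(vecs[k]))
            )
            cosphi = min(1.0, max(-1.0, cosphi))
            records.append(
                PairAngleRecord(
                    pair=(j, k),
                    distance_sum=dists[j] + dists[k],
                    angle=float(np.degrees(np.arccos(cosphi))),
                )
            )
    return records


def intra_cluster_distribution(
    matrix: RmsdMatrix,
    cluster: Cluster,
    bins: int | Sequence[float] | str = "auto",
) -> tuple[np.ndarray, np.ndarray]:
    """Density histogram of all within-cluster pairwise RMSD values.

    Returns ``(densities, bin_edges)``.  Split (bimodal) distributions flag
    clusters that merged two distinct populations.
    """
    members = np.asarray(cluster.members, dtype=np.intp)
    if members.size < 2:
        raise ValueError("intra-cluster distribution needs at least two members")
    sub = matrix.values[np.ix_(members, members)]
    vals = sub[np.triu_indices(members.size, k=1)]
    densities, edges = np.histogram(vals, bins=bins, density=True)
    return densities, edges


def coverage_report(
    result: ClusteringResult, size_cutoffs: Sequence[int] = (10, 100)
) -> pd.DataFrame:
    """Cluster counts and population coverage above size cutoffs.

    For each cutoff c: how many clusters hold >= c members and what
    percentage of all configurations (assigned plus unassigned) they
    contain.  ``total_clusters`` is attached via the frame's attrs.
    """
    sizes = np.asarray(result.sizes, dtype=np.intp)
    total = int(sizes.sum()) + len(result.unassigned)
    rows = []
    for c in size_cutoffs:
        if c < 1:
            raise ValueError("size cutoffs must be positive")
        big = sizes[sizes >= c]
        pct = 100.0 * big.sum() / total if total else 0.0
        rows.append({"cutoff": int(c), "n_clusters": int(big.size),
                     "coverage_pct": float(pct)})
    table = pd.DataFrame(rows)
    table.attrs["total_clusters"] = int(sizes.size)
    table.attrs["total_configurations"] = total
    return table
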