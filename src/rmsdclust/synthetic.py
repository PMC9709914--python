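"""Synthetic ensembles with controlled cluster structure.

Two kinds of fixtures drive the test surface:

* planted ensembles — k well-separated isotropic Gaussian clusters in the
  configuration space of an ``n_atoms``-atom pseudo-molecule, with known
  labels, tunable per-coordinate spread sigma and a lower bound on the
  pairwise center separation (both in RMSD/nm units).  These emulate the
  high-density conformer regions with void surroundings that make a
  threshold physically meaningful, without any MD physics (no bonds, no
  Boltzmann weights): only the statistical geometry the algorithms are
  sensitive to.
* 2D point sets — a structureless disk (or Gaussian blob / multimodal
  mixture), treated as single-"atom" two-coordinate configurations with the
  prealigned metric.  On such dense, unstructured data a radial clustering
  at theta/2 and a diametral clustering at theta carve out equally sized
  clusters.

All generators take an explicit integer seed for numpy's PCG64 generator
(`numpy.random.default_rng`) and are bit-reproducible.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .geometry import ConfigurationEnsemble, fit_all_to_reference

__all__ = [
    "PlantedEnsembleSpec",
    "generate_planted_ensemble",
    "generate_2d_mixture",
    "points_as_ensemble",
    "project_to_2d",
    "subsample",
]


@dataclass(frozen=True)
class PlantedEnsembleSpec:
    """Recipe for a planted-cluster ensemble.

    Parameters
    ----------
    k_clusters : int
        Number of planted clusters.
    members_per_cluster : tuple of int
        Members in each cluster (length k_clusters, all positive).
    n_atoms : int
        Atoms per pseudo-configuration (3 coordinates each).
    intra_spread : float
        Per-coordinate Gaussian sigma around each center, nm.  The expected
        member-to-center RMSD is sigma * sqrt(3).
    min_separation : float
        Lower bound on the pairwise center-to-center RMSD, nm.  Well
        separated means min_separation well above twice the intra radius.
    seed_at_mean : bool
        Plant each cluster's first member exactly at its center.
    rng_seed : int
        Seed for the PCG64 generator; same seed, bit-identical output.
    """

    k_clusters: int = 3
    members_per_cluster: tuple[int, ...] = (100, 100, 100)
    n_atoms: int = 5
    intra_spread: float = 0.02
    min_separation: float = 0.5
    seed_at_mean: bool = True
    rng_seed: int = 0

    def __post_init__(self) -> None:
        object.__setattr__(
            self, "members_per_cluster", tuple(int(m) for m in self.members_per_cluster)
        )
        if self.k_clusters < 1:
            raise ValueError("k_clusters must be positive")
        if len(self.members_per_cluster) != self.k_clusters:
            raise ValueError("members_per_cluster must list one count per cluster")
        if any(m < 1 for m in self.members_per_cluster):
            raise ValueError("cluster member counts must be positive")
        if self.n_atoms < 1:
            raise ValueError("n_atoms must be positive")
        if self.intra_spread < 0:
            raise ValueError("intra_spread must be nonnegative")
        if self.min_separation <= 0:
            raise ValueError("min_separation must be positive")


def _sample_centers(spec: PlantedEnsembleSpec, rng: np.random.Generator) -> np.ndarray:
    """Rejection-sample cluster centers with pairwise RMSD >= min_separation.

    Centers are drawn uniformly in a hypercube in the flattened coordinate
    space.  The side is scaled so the separation constraint stays feasible:
    per coordinate, ``min_separation * k^(1/n) * 2`` where n = 3 * n_atoms
    (RMSD between two uniform corners grows like side / sqrt(3), so this
    leaves generous slack).
    """
    n = 3 * spec.n_atoms
    side = 2.0 * spec.min_separation * spec.k_clusters ** (1.0 / n) * np.sqrt(3.0)
    max_tries = 2000
    for _ in range(max_tries):
        centers = rng.uniform(0.0, side, size=(spec.k_clusters, n))
        if spec.k_clusters == 1:
            return centers
        diff = centers[:, None, :] - centers[None, :, :]
        rmsd = np.sqrt((diff**2).sum(-1) / spec.n_atoms)
        iu = np.triu_indices(spec.k_clusters, k=1)
        if rmsd[iu].min() >= spec.min_separation:
            return centers
    raise RuntimeError(
        f"could not place {spec.k_clusters} centers at separation "
        f">= {spec.min_separation} within {max_tries} tries"
    )


def generate_planted_ensemble(
    spec: PlantedEnsembleSpec,
) -> tuple[ConfigurationEnsemble, np.ndarray]:
    """Generate a planted ensemble and its ground-truth labels.

    Returns the ensemble (frames grouped by cluster, in label order) and an
    integer label array of the same length.  With ``seed_at_mean`` the first
    frame of each cluster sits exactly on its center, so threshold clustering
    can recover the partition and the planted seed coincides with the
    population mean.
    """
    rng = np.random.default_rng(spec.rng_seed)
    centers = _sample_centers(spec, rng)
    frames = []
    labels = []
    for c, count in enumerate(spec.members_per_cluster):
        center = centers[c]
        block = center + rng.normal(0.0, spec.intra_spread, size=(count, center.size))
        if spec.seed_at_mean:
            block[0] = center
        frames.append(block)
        labels.extend([c] * count)
    coords = np.concatenate(frames).reshape(-1, spec.n_atoms, 3)
    return ConfigurationEnsemble(coords=coords), np.asarray(labels, dtype=np.intp)


def generate_2d_mixture(
    n_points: int,
    profile: str = "disk",
    rng_seed: int = 0,
    scale: float = 5.0,
    centers: np.ndarray | None = None,
) -> np.ndarray:
    """2D point set, structureless or multimodal.

    Profiles
    --------
    ``disk``
        Uniform over a disk of radius ``scale`` — dense and structureless,
        so any partition is imposed purely by the threshold.
    ``gaussian``
        Isotropic normal with per-coordinate sigma ``scale``.
    ``mixture``
        Equal-weight isotropic normals (sigma ``scale``) at the given
        ``centers`` (default: three centers on a ring of radius 10*scale).
    """
    if n_points < 1:
        raise ValueError("n_points must be positive")
    rng = np.random.default_rng(rng_seed)
    if profile == "disk":
        r = scale * np.sqrt(rng.uniform(size=n_points))
        phi = rng.uniform(0.0, 2.0 * np.pi, size=n_points)
        return np.column_stack([r * np.cos(phi), r * np.sin(phi)])
    if profile == "gaussian":
        return rng.normal(0.0, scale, size=(n_points, 2))
    if profile == "mixture":
        if centers is None:
            ang = 2.0 * np.pi * np.arange(3) / 3.0
            centers = 10.0 * scale * np.column_stack([np.cos(ang), np.sin(ang)])
        centers = np.asarray(centers, dtype=np.float64)
        which = rng.integers(0, len(centers), size=n_points)
        return centers[which] + rng.normal(0.0, scale, size=(n_points, 2))
    raise ValueError(f"unknown profile {profile!r}")


def points_as_ensemble(points: np.ndarray) -> ConfigurationEnsemble:
    """Treat a (N, d) point set as single-atom d-coordinate configurations."""
    points = np.asarray(points, dtype=np.float64)
    if points.ndim != 2:
        raise ValueError("points must be a (N, d) array")
    return ConfigurationEnsemble(coords=points[:, None, :])


def project_to_2d(
    ensemble: ConfigurationEnsemble, atom: int, ref_frame: int
) -> np.ndarray:
    """(x, y) of one atom per frame, after fitting all frames to a reference.

    This is how a high-dimensional trajectory is reduced to a 2D example:
    least-squares fit every configuration to the reference frame, then keep
    the chosen atom's x and y.
    """
    if not 0 <= atom < ensemble.n_atoms:
        raise IndexError(f"atom {atom} out of range for n_atoms={ensemble.n_atoms}")
    fitted = fit_all_to_reference(ensemble, ref_frame)
    return fitted.coords[:, atom, :2].copy()


def subsample(items, stride: int, start: int = 1):
    """Every ``stride``-th element starting at 1-based position ``start``.

    6001 items at stride 4 from position 1 give 1501 items.  Works on any
    sliceable ordered collection, preserving order; returns empty when
    ``start`` exceeds the length.
    """
    if stride < 1:
        raise ValueError("stride must be >= 1")
    if start < 1:
        raise ValueError("start is 1-based and must be >= 1")
    return items[start - 1 :: stride]
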