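from __future__ import annotations

import numpy as np
import pytest

from rmsdclust import (
    ConfigurationEnsemble,
    RmsdMatrix,
    pairwise_rmsd_matrix,
)
from rmsdclust.synthetic import PlantedEnsembleSpec, generate_planted_ensemble


def matrix_from_points(points: np.ndarray) -> RmsdMatrix:
    """Prealigned RMSD matrix of 1-atom configurations at given positions."""
    points = np.asarray(points, dtype=float)
    if points.ndim == 1:
        points = points[:, None]
    ens = ConfigurationEnsemble(coords=points[:, None, :])
    return pairwise_rmsd_matrix(ens, mode="prealigned")


def random_rotation(rng: np.random.Generator) -> np.ndarray:
    """Uniform proper rotation via QR with determinant fix."""
    q, r = np.linalg.qr(rng.normal(size=(3, 3)))
    q *= np.sign(np.diagonal(r))
    if np.linalg.det(q) < 0:
        q[:, 0] = -q[:, 0]
    return q


@pytest.fixture(scope="session")
def line_matrix() -> RmsdMatrix:
    """Single-atom 1-D frames at 0, 1, 2, 10, 11; prealigned distances are
    absolute coordinate differences."""
    return matrix_from_points(np.array([0.0, 1.0, 2.0, 10.0, 11.0]))


@pytest.fixture(scope="session")
def triple_matrix() -> RmsdMatrix:
    """Single-atom 1-D frames at 0, 0.9, 1.8."""
    return matrix_from_points(np.array([0.0, 0.9, 1.8]))


@pytest.fixture(scope="session")
def planted():
    """Well-separated planted fixture at the default study conditions:
    k = 3 clusters of 100 members, sigma = 0.02 nm, separation >= 0.5 nm,
    planted seed at each cluster mean."""
    spec = PlantedEnsembleSpec()
    ensemble, labels = generate_planted_ensemble(spec)
    matrix = pairwise_rmsd_matrix(ensemble, mode="prealigned")
    return spec, ensemble, labels, matrix
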