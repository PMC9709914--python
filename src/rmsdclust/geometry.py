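"""Rigid-body superposition and pairwise RMSD matrices.

This is the metric layer both clustering algorithms consume: the
root-mean-squared difference (RMSD) between the Cartesian coordinates of
corresponding atoms of two configurations, optionally after least-squares
superposition (Kabsch), and the symmetric N x N matrix of all pairwise
values.

All coordinates are in nm.  RMSD is mass-unweighted: every selected atom
carries weight 1.
"""

from __future__ import annotations

import enum
from dataclasses import dataclass, field

import numpy as np

__all__ = [
    "ConfigurationEnsemble",
    "SuperpositionResult",
    "MatrixMode",
    "RmsdMatrix",
    "rmsd_raw",
    "superpose",
    "apply_superposition",
    "pairwise_rmsd_matrix",
    "fit_all_to_reference",
]


@dataclass(frozen=True)
class ConfigurationEnsemble:
    """N molecular configurations of n_a atoms in d spatial dimensions.

    Parameters
    ----------
    coords : ndarray, shape (N, n_atoms, ndim)
        Atomic coordinates per frame, in nm.  ``ndim`` is 3 for molecular
        data; 2D point sets are represented as single-atom 2-coordinate
        configurations.
    frame_ids : ndarray of int, optional
        Ordered 0-based frame labels; defaults to ``arange(N)``.
    atom_labels : list of (residue id, atom name), optional
        One entry per atom, e.g. ``(2, "CA")``.
    """

    coords: np.ndarray
    frame_ids: np.ndarray = field(default=None)  # type: ignore[assignment]
    atom_labels: list[tuple[int, str]] | None = None

    def __post_init__(self) -> None:
        coords = np.asarray(self.coords, dtype=np.float64)
        if coords.ndim != 3:
            raise ValueError(
                f"coords must have shape (N, n_atoms, ndim); got {coords.shape}"
            )
        if coords.shape[0] < 1 or coords.shape[1] < 1:
            raise ValueError("ensemble needs at least one frame and one atom")
        if not np.all(np.isfinite(coords)):
            raise ValueError("coords contain non-finite values")
        object.__setattr__(self, "coords", coords)
        fids = self.frame_ids
        if fids is None:
            fids = np.arange(coords.shape[0])
        fids = np.asarray(fids, dtype=np.intp)
        if fids.shape != (coords.shape[0],):
            raise ValueError("frame_ids must have one entry per frame")
        object.__setattr__(self, "frame_ids", fids)
        if self.atom_labels is not None and len(self.atom_labels) != coords.shape[1]:
            raise ValueError("atom_labels must have one entry per atom")

    @property
    def n_frames(self) -> int:
        return self.coords.shape[0]

    @property
    def n_atoms(self) -> int:
        return self.coords.shape[1]

    @property
    def ndim(self) -> int:
        return self.coords.shape[2]

    @property
    def n_coordinates(self) -> int:
        """Total coordinate count n = ndim * n_atoms per configuration."""
        return self.n_atoms * self.ndim

    def frame(self, i: int) -> np.ndarray:
        return self.coords[i]


@dataclass(frozen=True)
class SuperpositionResult:
    """Optimal rigid superposition of a mobile configuration onto a reference.

    The transform maps mobile coordinates ``x`` to ``x @ rotation.T +
    translation``; ``rmsd`` is the residual after the transform, the global
    minimum over all proper rotations and translations.
    """

    rotation: np.ndarray
    translation: np.ndarray
    rmsd: float


class MatrixMode(str, enum.Enum):
    """How pairwise RMSD entries are computed."""

    PAIRWISE_FIT = "pairwise_fit"
    PREALIGNED = "prealigned"


@dataclass(frozen=True)
class RmsdMatrix:
    """Symmetric N x N matrix of pairwise RMSD values (nm), zero diagonal."""

    values: np.ndarray
    mode: MatrixMode = MatrixMode.PAIRWISE_FIT

    def __post_init__(self) -> None:
        values = np.asarray(self.values, dtype=np.float64)
        if values.ndim != 2 or values.shape[0] != values.shape[1]:
            raise ValueError("rmsd matrix must be square")
        if not np.all(np.isfinite(values)):
            raise ValueError("rmsd matrix contains non-finite values")
        if np.any(values < 0):
            raise ValueError("rmsd values must be nonnegative")
        if np.any(np.diagonal(values) != 0.0):
            raise ValueError("rmsd matrix diagonal must be exactly zero")
        if not np.allclose(values, values.T, atol=1e-12):
            raise ValueError("rmsd matrix must be symmetric")
        # enforce exact symmetry so strict threshold comparisons cannot
        # disagree between (i, j) and (j, i)
        values = 0.5 * (values + values.T)
        object.__setattr__(self, "values", values)
        object.__setattr__(self, "mode", MatrixMode(self.mode))

    @property
    def n(self) -> int:
        return self.values.shape[0]

    def row(self, k: int) -> np.ndarray:
        return self.values[k]


def _check_same_shape(a: np.ndarray, b: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    a = np.asarray(a, dtype=np.float64)
    b = np.asarray(b, dtype=np.float64)
    if a.ndim != 2 or b.ndim != 2 or a.shape != b.shape:
        raise ValueError(
            f"configurations must be (n_atoms, ndim) arrays of equal shape; "
            f"got {a.shape} and {b.shape}"
        )
    if a.shape[0] < 1:
        raise ValueError("configurations need at least one atom")
    return a, b


def rmsd_raw(a: np.ndarray, b: np.ndarray) -> float:
    """RMSD between two configurations without any fitting.

    ``sqrt( (1/n_a) * sum over atoms of |a_i - b_i|^2 )``.
    """
    a, b = _check_same_shape(a, b)
    diff = a - b
    return float(np.sqrt(np.einsum("ij,ij->", diff, diff) / a.shape[0]))


def superpose(mobile: np.ndarray, reference: np.ndarray) -> SuperpositionResult:
    """Least-squares superposition of ``mobile`` onto ``reference``.

    Kabsch algorithm: after centering both configurations, the optimal
    rotation is ``V S W^T`` from the SVD ``H = U Sigma W^T`` of the
    covariance, with the smallest singular direction flipped when the
    unconstrained optimum is a reflection, so the returned rotation is
    always proper (det +1).  Degenerate inputs (single atom, collinear
    atoms) still return a valid minimizer.
    """
    mobile, reference = _check_same_shape(mobile, reference)
    n_a = mobile.shape[0]
    mob_center = mobile.mean(axis=0)
    ref_center = reference.mean(axis=0)
    a = mobile - mob_center
    b = reference - ref_center
    h = a.T @ b  # covariance, (d, d)
    u, s, vt = np.linalg.svd(h)
    d = np.sign(np.linalg.det(u @ vt))
    if d == 0:
        d = 1.0
    flip = np.ones(h.shape[0])
    flip[-1] = d
    rotation = (u * flip) @ vt  # maps centered mobile onto centered reference
    rotation = rotation.T  # convention: x @ rotation.T
    translation = ref_center - mob_center @ rotation.T
    e0 = np.einsum("ij,ij->", a, a) + np.einsum("ij,ij->", b, b)
    msd = max(e0 - 2.0 * (s[:-1].sum() + d * s[-1]), 0.0) / n_a
    return SuperpositionResult(
        rotation=rotation, translation=translation, rmsd=float(np.sqrt(msd))
    )


def apply_superposition(coords: np.ndarray, result: SuperpositionResult) -> np.ndarray:
    """Apply a fitted rigid transform to a configuration."""
    return np.asarray(coords, dtype=np.float64) @ result.rotation.T + result.translation


def _pairwise_fit_matrix(coords: np.ndarray) -> np.ndarray:
    """All-pairs minimized RMSD via row-blocked batched Kabsch SVDs."""
    n, n_a, _ = coords.shape
    centered = coords - coords.mean(axis=1, keepdims=True)
    sq_norms = np.einsum("nij,nij->n", centered, centered)
    values = np.zeros((n, n))
    for i in range(n - 1):
        rest = centered[i + 1 :]
        h = np.einsum("ak,mal->mkl", centered[i], rest)
        s = np.linalg.svd(h, compute_uv=False)
        det = np.linalg.det(h)
        trace = s[:, :-1].sum(axis=1) + np.where(det < 0, -s[:, -1], s[:, -1])
        msd = np.maximum(sq_norms[i] + sq_norms[i + 1 :] - 2.0 * trace, 0.0) / n_a
        values[i, i + 1 :] = np.sqrt(msd)
    return values + values.T


def pairwise_rmsd_matrix(
    ensemble: ConfigurationEnsemble,
    mode: MatrixMode | str = MatrixMode.PAIRWISE_FIT,
) -> RmsdMatrix:
    """Symmetric matrix of RMSDs between all pairs of configurations.

    ``pairwise_fit`` superposes every pair independently before measuring;
    ``prealigned`` measures raw coordinate differences and is appropriate
    when the trajectory is already fitted to a common reference.  Every
    pairwise-fit entry is bounded above by the prealigned one.
    """
    mode = MatrixMode(mode)
    coords = ensemble.coords
    if mode is MatrixMode.PREALIGNED:
        flat = coords.reshape(ensemble.n_frames, -1)
        from scipy.spatial.distance import pdist, squareform

        values = squareform(pdist(flat)) / np.sqrt(ensemble.n_atoms)
    else:
        values = _pairwise_fit_matrix(coords)
    np.fill_diagonal(values, 0.0)
    return RmsdMatrix(values=values, mode=mode)


def fit_all_to_reference(
    ensemble: ConfigurationEnsemble, ref_frame: int
) -> ConfigurationEnsemble:
    """Superpose every frame onto ``ref_frame``; the reference is unchanged."""
    n = ensemble.n_frames
    if not -n <= ref_frame < n:
        raise IndexError(f"reference frame {ref_frame} out of range for N={n}")
    ref = ensemble.coords[ref_frame]
    fitted = np.empty_like(ensemble.coords)
    for i in range(n):
        if i == ref_frame % n:
            fitted[i] = ref
            continue
        res = superpose(ensemble.coords[i], ref)
        fitted[i] = apply_superposition(ensemble.coords[i], res)
    return ConfigurationEnsemble(
        coords=fitted,
        frame_ids=ensemble.frame_ids.copy(),
        atom_labels=ensemble.atom_labels,
    )
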