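"""Radial-threshold (RTC) and quality-threshold (QTC) clustering.

Both algorithms consume a precomputed pairwise RMSD matrix and iterate the
same outer scheme: every configuration still available is tried as the seed
of a *tentative cluster*; the tentative cluster with the most elements is
promoted to the iteration's output cluster and its members are removed from
the available pool.  Iteration stops when the pool is empty or the newly
produced cluster falls below a preset minimum size.

The two algorithms differ only in how a seed's tentative cluster is built:

* RTC (radial threshold theta_r): the tentative cluster is every available
  configuration at RMSD strictly below theta_r from the seed.  Membership is
  a radial relation; the cluster diameter may approach (but in practice
  rarely reaches) 2 * theta_r.
* QTC (diametral / quality threshold theta_d): the tentative cluster is
  grown greedily from the seed — at each step the candidate whose inclusion
  extends the cluster diameter the least is added, provided the diameter
  stays strictly below theta_d.  Every pair of members is then guaranteed to
  be within theta_d (the quality guarantee).

Ties between equally sized tentative clusters are broken by a selection
rule ``f`` (default: lowest seed index); ties in the greedy growth between
candidates with identical resulting diameter are broken by lowest frame
index.  Floating-point ties are compared exactly, without an epsilon.

The statsmodels-style surface is :class:`ThresholdClustering` (model) whose
``fit`` returns :class:`ClusteringResults`; the per-iteration operations are
also exposed as plain functions.
"""

from __future__ import annotations

import enum
from dataclasses import dataclass, field
from typing import Callable, Iterable, Sequence

import numpy as np
import pandas as pd

from .geometry import ConfigurationEnsemble, MatrixMode, RmsdMatrix, pairwise_rmsd_matrix

__all__ = [
    "Algorithm",
    "Threshold",
    "ClusteringState",
    "TentativeCluster",
    "IterationRecord",
    "Cluster",
    "ClusteringResult",
    "neighbor_set",
    "rtc_iteration",
    "qtc_grow",
    "qtc_iteration",
    "cluster",
    "ThresholdClustering",
    "ClusteringResults",
]

SelectionRule = Callable[[Sequence[int]], int]


class Algorithm(str, enum.Enum):
    RTC = "rtc"
    QTC = "qtc"


class ThresholdKind(str, enum.Enum):
    RADIAL = "radial"
    DIAMETRAL = "diametral"


@dataclass(frozen=True)
class Threshold:
    """An RMSD cutoff theta > 0 (nm) with its interpretation.

    ``radial`` cutoffs apply between the seed and each member (RTC);
    ``diametral`` cutoffs apply between every pair of members (QTC).
    """

    value: float
    kind: ThresholdKind | str = ThresholdKind.RADIAL

    def __post_init__(self) -> None:
        if not self.value > 0:
            raise ValueError("threshold must be positive")
        object.__setattr__(self, "kind", ThresholdKind(self.kind))

    @property
    def algorithm(self) -> Algorithm:
        return Algorithm.RTC if self.kind is ThresholdKind.RADIAL else Algorithm.QTC


@dataclass
class ClusteringState:
    """Bookkeeping for the iterative outer loop.

    ``available`` and ``clustered`` partition the frame indices; iteration
    counting is 1-based and the clustered set starts empty.
    """

    available: np.ndarray
    clustered: frozenset[int] = frozenset()
    iteration: int = 1

    @classmethod
    def initial(cls, n: int) -> "ClusteringState":
        return cls(available=np.arange(n, dtype=np.intp))

    def advance(self, members: Iterable[int]) -> "ClusteringState":
        members = frozenset(int(m) for m in members)
        keep = np.array([i for i in self.available if int(i) not in members], dtype=np.intp)
        return ClusteringState(
            available=keep,
            clustered=self.clustered | members,
            iteration=self.iteration + 1,
        )


@dataclass(frozen=True)
class TentativeCluster:
    """The member set proposed by one seed, before size comparison."""

    seed: int
    members: tuple[int, ...]
    diameter_so_far: float = 0.0


@dataclass(frozen=True)
class IterationRecord:
    """Per-iteration audit: tentative sizes, tied winners, chosen seed."""

    sizes: dict[int, int]
    winners: tuple[int, ...]
    chosen_seed: int


@dataclass(frozen=True)
class Cluster:
    """The m-th output cluster: its rank, seed, sorted members, threshold."""

    rank: int
    seed: int
    members: tuple[int, ...]
    threshold: Threshold

    @property
    def size(self) -> int:
        return len(self.members)


@dataclass(frozen=True)
class ClusteringResult:
    """Ordered clusters plus the indices left unassigned by min_size."""

    clusters: tuple[Cluster, ...]
    algorithm: Algorithm
    min_size: int
    unassigned: tuple[int, ...]

    @property
    def sizes(self) -> list[int]:
        return [c.size for c in self.clusters]

    def labels(self, n: int) -> np.ndarray:
        """Per-frame cluster rank (1-based); 0 marks unassigned frames."""
        out = np.zeros(n, dtype=np.intp)
        for c in self.clusters:
            out[list(c.members)] = c.rank
        return out


def _as_index_array(available: Iterable[int]) -> np.ndarray:
    arr = np.asarray(sorted(int(i) for i in available), dtype=np.intp)
    return arr


def neighbor_set(
    matrix: RmsdMatrix, k: int, available: Iterable[int], theta: float
) -> np.ndarray:
    """Indices of available configurations strictly within ``theta`` of seed ``k``.

    Always contains ``k`` itself (rmsd_kk = 0); entries exactly equal to the
    threshold are excluded.
    """
    avail = _as_index_array(available)
    if int(k) not in set(avail.tolist()):
        raise ValueError(f"seed {k} is not in the available set")
    return avail[matrix.values[k, avail] < theta]


def _default_f(indices: Sequence[int]) -> int:
    return int(min(indices))


def rtc_iteration(
    matrix: RmsdMatrix,
    state: ClusteringState,
    theta_r: float,
    f: SelectionRule = _default_f,
) -> tuple[Cluster, IterationRecord, ClusteringState]:
    """One RTC iteration: count radial neighbors of every available seed.

    Every available configuration proposes the set of available
    configurations at RMSD < theta_r from it; the largest such set wins,
    ties broken by ``f`` (default lowest seed index).  The winner's members
    are removed from the available pool.
    """
    avail = state.available
    if avail.size == 0:
        raise ValueError("no configurations available")
    sub = matrix.values[np.ix_(avail, avail)] < theta_r
    counts = sub.sum(axis=1)
    best = counts.max()
    winners = tuple(int(s) for s in avail[counts == best])
    chosen = int(f(winners))
    members = tuple(int(i) for i in avail[matrix.values[chosen, avail] < theta_r])
    record = IterationRecord(
        sizes={int(s): int(c) for s, c in zip(avail, counts)},
        winners=winners,
        chosen_seed=chosen,
    )
    clus = Cluster(
        rank=state.iteration,
        seed=chosen,
        members=tuple(sorted(members)),
        threshold=Threshold(theta_r, ThresholdKind.RADIAL),
    )
    return clus, record, state.advance(members)


def qtc_grow(
    matrix: RmsdMatrix, k: int, available: Iterable[int], theta_d: float
) -> TentativeCluster:
    """Grow seed ``k``'s diametral tentative cluster greedily.

    Starting from {k}, repeatedly add the candidate whose inclusion
    minimizes the resulting diameter, subject to the diameter remaining
    strictly below theta_d; stop when no candidate qualifies.  Equal-diameter
    ties go to the lowest frame index.  The candidate pool is restricted to
    the seed's radial neighbor set at theta_d — a point at RMSD >= theta_d
    from the seed can never satisfy the diameter bound, so the output is
    identical to an unrestricted search.
    """
    cand = neighbor_set(matrix, k, available, theta_d)
    # distance of every candidate to the current member set (max over members)
    maxd = matrix.values[k, cand].astype(np.float64)
    in_members = cand == k
    maxd[in_members] = np.inf
    members = [int(k)]
    diameter = 0.0
    while True:
        feasible = maxd < theta_d
        if not feasible.any():
            break
        # resulting diameter if each feasible candidate were added; candidates
        # already inside the current diameter all tie at the current value
        resulting = np.maximum(diameter, maxd[feasible])
        best = resulting.min()
        # lowest-index tie-break among candidates achieving the minimum;
        # cand is sorted, so the first hit is the lowest frame index
        pick_local = np.flatnonzero(feasible)[np.flatnonzero(resulting == best)[0]]
        chosen = int(cand[pick_local])
        members.append(chosen)
        diameter = max(diameter, float(best))
        maxd = np.maximum(maxd, matrix.values[chosen, cand])
        maxd[pick_local] = np.inf
    return TentativeCluster(seed=int(k), members=tuple(members), diameter_so_far=diameter)


def qtc_iteration(
    matrix: RmsdMatrix,
    state: ClusteringState,
    theta_d: float,
    f: SelectionRule = _default_f,
    seed_order: Sequence[int] | None = None,
    _cache: dict[int, TentativeCluster] | None = None,
) -> tuple[Cluster, IterationRecord, ClusteringState]:
    """One QTC iteration: grow a tentative cluster from every available seed.

    The largest grown set is promoted, ties broken by ``f``.  ``seed_order``
    only changes the order seeds are evaluated in; the outcome depends on it
    solely through ``f``.  ``_cache`` lets the outer loop reuse grown sets
    whose candidate pool was untouched by the previous iteration.
    """
    avail = state.available
    if avail.size == 0:
        raise ValueError("no configurations available")
    order = avail if seed_order is None else np.asarray(seed_order, dtype=np.intp)
    if sorted(order.tolist()) != sorted(avail.tolist()):
        raise ValueError("seed_order must be a permutation of the available set")
    grown: dict[int, TentativeCluster] = {}
    for k in order:
        k = int(k)
        if _cache is not None and k in _cache:
            grown[k] = _cache[k]
        else:
            grown[k] = qtc_grow(matrix, k, avail, theta_d)
            if _cache is not None:
                _cache[k] = grown[k]
    sizes = {k: len(t.members) for k, t in grown.items()}
    best = max(sizes.values())
    winners = tuple(sorted(k for k, s in sizes.items() if s == best))
    chosen = int(f(winners))
    tent = grown[chosen]
    record = IterationRecord(sizes=sizes, winners=winners, chosen_seed=chosen)
    clus = Cluster(
        rank=state.iteration,
        seed=chosen,
        members=tuple(sorted(tent.members)),
        threshold=Threshold(theta_d, ThresholdKind.DIAMETRAL),
    )
    if _cache is not None:
        # invalidate seeds whose candidate pool intersects the removed members
        removed = np.asarray(tent.members, dtype=np.intp)
        removed_set = set(tent.members)
        cached = np.array([s for s in _cache if s not in removed_set], dtype=np.intp)
        stale: list[int] = [s for s in _cache if s in removed_set]
        if cached.size:
            hit = (matrix.values[np.ix_(cached, removed)] < theta_d).any(axis=1)
            stale.extend(int(s) for s in cached[hit])
        for s in stale:
            del _cache[s]
    return clus, record, state.advance(tent.members)


def cluster(
    matrix: RmsdMatrix,
    threshold: Threshold,
    min_size: int = 1,
    f: SelectionRule = _default_f,
    max_clusters: int | None = None,
) -> ClusteringResult:
    """Run RTC or QTC to completion.

    ``threshold.kind`` selects the algorithm (radial -> RTC, diametral ->
    QTC).  Iteration stops when no configurations remain, when the newly
    produced cluster has fewer than ``min_size`` members (that cluster is
    not emitted and all remaining indices are reported unassigned), or when
    ``max_clusters`` clusters have been emitted.
    """
    if min_size < 1:
        raise ValueError("min_size must be >= 1")
    algorithm = threshold.algorithm
    state = ClusteringState.initial(matrix.n)
    clusters: list[Cluster] = []
    cache: dict[int, TentativeCluster] = {}
    while state.available.size > 0:
        if max_clusters is not None and len(clusters) >= max_clusters:
            break
        if algorithm is Algorithm.RTC:
            clus, _rec, new_state = rtc_iteration(matrix, state, threshold.value, f)
        else:
            clus, _rec, new_state = qtc_iteration(
                matrix, state, threshold.value, f, _cache=cache
            )
        if clus.size < min_size:
            break
        clusters.append(clus)
        state = new_state
    return ClusteringResult(
        clusters=tuple(clusters),
        algorithm=algorithm,
        min_size=min_size,
        unassigned=tuple(int(i) for i in state.available),
    )


class ThresholdClustering:
    """Threshold clustering model over a pairwise RMSD matrix.

    Parameters
    ----------
    matrix : RmsdMatrix
        Pairwise RMSD matrix of the configurations to cluster.
    threshold : Threshold or float
        The cutoff; a bare float is interpreted with ``kind``.
    kind : {"radial", "diametral"}
        Interpretation of a bare-float threshold (radial -> RTC,
        diametral -> QTC).  Ignored when ``threshold`` is a Threshold.
    min_size : int
        Minimum cluster size; iteration stops when the winning cluster
        falls below it and the leftovers are reported unassigned.
    ensemble : ConfigurationEnsemble, optional
        The underlying coordinates; required only for the coordinate-space
        diagnostics on the results object (centroid distances, radius of
        gyration, pair-angle records).

    Examples
    --------
    >>> model = ThresholdClustering(matrix, 0.17, kind="radial")
    >>> res = model.fit()
    >>> print(res.summary())
    """

    def __init__(
        self,
        matrix: RmsdMatrix,
        threshold: Threshold | float,
        kind: ThresholdKind | str = ThresholdKind.RADIAL,
        min_size: int = 1,
        selection_rule: SelectionRule = _default_f,
        ensemble: ConfigurationEnsemble | None = None,
    ) -> None:
        if not isinstance(matrix, RmsdMatrix):
            matrix = RmsdMatrix(np.asarray(matrix))
        if not isinstance(threshold, Threshold):
            threshold = Threshold(float(threshold), ThresholdKind(kind))
        if ensemble is not None and ensemble.n_frames != matrix.n:
            raise ValueError("ensemble and matrix disagree on the frame count")
        self.matrix = matrix
        self.threshold = threshold
        self.min_size = int(min_size)
        self.selection_rule = selection_rule
        self.ensemble = ensemble

    @classmethod
    def from_ensemble(
        cls,
        ensemble: ConfigurationEnsemble,
        threshold: Threshold | float,
        kind: ThresholdKind | str = ThresholdKind.RADIAL,
        mode: MatrixMode | str = MatrixMode.PAIRWISE_FIT,
        **kwargs,
    ) -> "ThresholdClustering":
        """Build the model by computing the pairwise matrix from coordinates."""
        matrix = pairwise_rmsd_matrix(ensemble, mode=mode)
        return cls(matrix, threshold, kind=kind, ensemble=ensemble, **kwargs)

    def fit(self, max_clusters: int | None = None) -> "ClusteringResults":
        result = cluster(
            self.matrix,
            self.threshold,
            min_size=self.min_size,
            f=self.selection_rule,
            max_clusters=max_clusters,
        )
        return ClusteringResults(self, result)


class ClusteringResults:
    """Fitted clustering: the ordered clusters plus diagnostics.

    Thin results wrapper in the statsmodels idiom: estimates (the clusters),
    per-cluster geometry, coverage statistics, and a printable summary.
    """

    def __init__(self, model: ThresholdClustering, result: ClusteringResult) -> None:
        self.model = model
        self.result = result

    # -- basic accessors ---------------------------------------------------
    @property
    def clusters(self) -> tuple[Cluster, ...]:
        return self.result.clusters

    @property
    def n_clusters(self) -> int:
        return len(self.result.clusters)

    @property
    def sizes(self) -> list[int]:
        return self.result.sizes

    @property
    def unassigned(self) -> tuple[int, ...]:
        return self.result.unassigned

    @property
    def labels(self) -> np.ndarray:
        return self.result.labels(self.model.matrix.n)

    # -- diagnostics (delegating to the diagnostics module) ----------------
    def diameters(self) -> np.ndarray:
        from . import diagnostics

        return np.array(
            [diagnostics.cluster_diameter(self.model.matrix, c) for c in self.clusters]
        )

    def coverage(self, size_cutoffs: Sequence[int] = (10, 100)) -> pd.DataFrame:
        from . import diagnostics

        return diagnostics.coverage_report(self.result, size_cutoffs)

    def seed_profile(self, rank: int = 1, **kwargs):
        from . import diagnostics

        return diagnostics.seed_profile(
            self.model.matrix, self.clusters[rank - 1].seed, **kwargs
        )

    def cluster_geometry(self, rank: int):
        from . import diagnostics

        if self.model.ensemble is None:
            raise ValueError("coordinate diagnostics need the model's ensemble")
        return diagnostics.cluster_geometry(
            self.model.ensemble, self.model.matrix, self.clusters[rank - 1]
        )

    # -- tables ------------------------------------------------------------
    def summary_frame(self, max_rows: int | None = 10) -> pd.DataFrame:
        """Per-cluster table: rank, seed frame, size, diameter."""
        from . import diagnostics

        rows = self.clusters if max_rows is None else self.clusters[:max_rows]
        return pd.DataFrame(
            {
                "rank": [c.rank for c in rows],
                "seed_frame": [c.seed for c in rows],
                "size": [c.size for c in rows],
                "diameter": [
                    diagnostics.cluster_diameter(self.model.matrix, c) for c in rows
                ],
            }
        )

    def assignment_frame(self) -> pd.DataFrame:
        """Per-frame table: frame id, cluster rank (0 = unassigned), seed flag."""
        labels = self.labels
        seeds = {c.seed for c in self.clusters}
        return pd.DataFrame(
            {
                "frame_id": np.arange(self.model.matrix.n),
                "cluster_rank": labels,
                "is_seed": [int(i in seeds) for i in range(self.model.matrix.n)],
            }
        )

    # -- plotting ----------------------------------------------------------
    def plot_sizes(self, max_clusters: int = 20, ax=None):
        """Bar plot of cluster sizes by rank."""
        import matplotlib.pyplot as plt

        if ax is None:
            _, ax = plt.subplots()
        sizes = self.sizes[:max_clusters]
        ax.bar(range(1, len(sizes) + 1), sizes, color="0.3")
        ax.set_xlabel("cluster rank")
        ax.set_ylabel("members")
        thr = self.model.threshold
        ax.set_title(
            f"{self.result.algorithm.value.upper()}, "
            f"θ = {thr.value:g} nm ({thr.kind.value})"
        )
        return ax

    def plot_seed_profiles(self, n_profiles: int = 6, bins=60, ax=None):
        """Overlay the seed RMSD distributions of the top clusters —
        the raw material for choosing a radial threshold."""
        import matplotlib.pyplot as plt

        from . import diagnostics

        if ax is None:
            _, ax = plt.subplots()
        for c in self.clusters[:n_profiles]:
            prof = diagnostics.seed_profile(self.model.matrix, c.seed, bins=bins)
            centers = 0.5 * (prof.bin_edges[:-1] + prof.bin_edges[1:])
            ax.plot(centers, prof.densities, label=f"rank {c.rank}")
        ax.set_xlabel("rmsd from seed (nm)")
        ax.set_ylabel("probability density")
        ax.legend()
        return ax

    def summary(self, max_rows: int = 10) -> str:
        thr = self.model.threshold
        n = self.model.matrix.n
        assigned = n - len(self.unassigned)
        head = [
            "Threshold clustering results",
            "=" * 60,
            f"Algorithm:            {self.result.algorithm.value.upper()}",
            f"Threshold:            {thr.value:g} nm ({thr.kind.value})",
            f"Minimum cluster size: {self.result.min_size}",
            f"Configurations:       {n}  (assigned {assigned}, "
            f"unassigned {len(self.unassigned)})",
            f"Clusters:             {self.n_clusters}",
            "-" * 60,
        ]
        table = self.summary_frame(max_rows).to_string(index=False)
        tail = []
        if self.n_clusters > max_rows:
            tail.append(f"... ({self.n_clusters - max_rows} more clusters)")
        return "\n".join(head + [table] + tail)

    def __repr__(self) -> str:  # pragma: no cover - cosmetic
        return (
            f"<ClusteringResults: {self.result.algorithm.value.upper()}, "
            f"{self.n_clusters} clusters, N={self.model.matrix.n}>"
        )
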