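import numpy as np
import pytest

from rmsdclust import Threshold, cluster, pairwise_rmsd_matrix
from rmsdclust.clustering import Cluster
from rmsdclust.diagnostics import (
    cluster_diameter,
    cluster_geometry,
    coverage_report,
    intra_cluster_distribution,
    pair_sum_angle,
    radius_of_gyration,
    seed_centroid_rmsd,
    seed_profile,
    suggest_radial_threshold,
)
from rmsdclust.synthetic import PlantedEnsembleSpec, generate_planted_ensemble

from .conftest import matrix_from_points


def make_cluster(members, seed=None, rank=1, theta=1.0, kind="radial"):
    members = tuple(sorted(members))
    return Cluster(
        rank=rank,
        seed=members[0] if seed is None else seed,
        members=members,
        threshold=Threshold(theta, kind),
    )


@pytest.fixture(scope="module")
def two_population_fixture():
    """Two tight planted clusters separated by a wide empty gap."""
    spec = PlantedEnsembleSpec(
        k_clusters=2,
        members_per_cluster=(80, 80),
        intra_spread=0.02,
        min_separation=0.6,
        rng_seed=5,
    )
    ensemble, labels = generate_planted_ensemble(spec)
    matrix = pairwise_rmsd_matrix(ensemble, mode="prealigned")
    return spec, ensemble, labels, matrix


class TestClusterDiameter:
    def test_singleton_is_zero(self, line_matrix):
        assert cluster_diameter(line_matrix, make_cluster([2])) == 0.0

    def test_pair_is_their_distance(self, line_matrix):
        assert cluster_diameter(line_matrix, make_cluster([0, 2])) == pytest.approx(2.0)

    def test_qtc_quality_guarantee(self):
        rng = np.random.default_rng(2)
        m = matrix_from_points(rng.normal(size=(40, 2)))
        res = cluster(m, Threshold(0.9, "diametral"))
        for c in res.clusters:
            assert cluster_diameter(m, c) < 0.9


class TestSeedProfile:
    def test_distances_are_the_off_diagonal_row(self):
        m = matrix_from_points([0.0, 0.1, 0.4])
        prof = seed_profile(m, 0)
        np.testing.assert_allclose(sorted(prof.distances), [0.1, 0.4])
        assert len(prof.distances) == m.n - 1

    def test_identical_frames_all_zero(self):
        m = matrix_from_points([3.0, 3.0, 3.0, 3.0])
        prof = seed_profile(m, 1)
        np.testing.assert_array_equal(prof.distances, 0.0)

    def test_single_frame_rejected(self):
        m = matrix_from_points([0.0])
        with pytest.raises(ValueError):
            seed_profile(m, 0)

    def test_density_integrates_to_one(self, planted):
        _, _, _, matrix = planted
        prof = seed_profile(matrix, 0, bins=40)
        widths = np.diff(prof.bin_edges)
        assert np.sum(prof.densities * widths) == pytest.approx(1.0)

    def test_planted_two_cluster_profile_is_bimodal_with_gap(
        self, two_population_fixture
    ):
        spec, _, _, matrix = two_population_fixture
        hi = matrix.values.max() + 0.02
        prof = seed_profile(matrix, 0, bins=np.arange(0.0, hi, 0.02))
        centers = 0.5 * (prof.bin_edges[:-1] + prof.bin_edges[1:])
        # the gap between intra-cluster spread and the planted separation is empty
        gap = (centers > 6 * spec.intra_spread) & (centers < 0.8 * spec.min_separation)
        assert prof.densities[gap].sum() == 0.0
        assert prof.densities[centers < 6 * spec.intra_spread].sum() > 0
        assert prof.densities[centers > 0.8 * spec.min_separation].sum() > 0


class TestSuggestRadialThreshold:
    def test_unimodal_uniform_profile_ends_at_support(self):
        # flat density on [0, 0.1] with nothing beyond: the suggested cutoff
        # lands at the end of the support
        rng = np.random.default_rng(0)
        pts = np.sort(rng.uniform(0.0, 0.1, size=400))
        from rmsdclust.diagnostics import SeedProfile

        prof = SeedProfile(
            seed=0,
            distances=pts,
            bin_edges=np.array([0.0, 0.1]),
            densities=np.array([10.0]),
        )
        sug = suggest_radial_threshold([prof], bin_width=0.005)
        assert sug.threshold == pytest.approx(0.1, abs=0.01)

    def test_two_cluster_fixture_lands_in_the_gap(self, two_population_fixture):
        spec, _, _, matrix = two_population_fixture
        profiles = [seed_profile(matrix, s) for s in (0, 80)]
        sug = suggest_radial_threshold(profiles)
        assert spec.intra_spread < sug.threshold < spec.min_separation

    def test_duplicated_profiles_are_idempotent(self, two_population_fixture):
        _, _, _, matrix = two_population_fixture
        prof = seed_profile(matrix, 0)
        single = suggest_radial_threshold([prof]).threshold
        triple = suggest_radial_threshold([prof, prof, prof]).threshold
        assert single == triple

    def test_degenerate_profile_skipped_with_warning(self, two_population_fixture):
        _, _, _, matrix = two_population_fixture
        from rmsdclust.diagnostics import SeedProfile

        good = seed_profile(matrix, 0)
        flat = SeedProfile(
            seed=99,
            distances=np.zeros(10),
            bin_edges=np.array([0.0, 1.0]),
            densities=np.array([1.0]),
        )
        with pytest.warns(UserWarning):
            sug = suggest_radial_threshold([good, flat])
        assert sug.per_profile["seed"].tolist() == [0]


class TestClusterGeometryMeasures:
    def test_singleton_rog_and_centroid_distance_vanish(self, line_matrix, planted):
        _, ensemble, _, _ = planted
        c = make_cluster([4])
        assert radius_of_gyration(ensemble, c, "prealigned") == 0.0
        assert seed_centroid_rmsd(ensemble, c, "prealigned") == 0.0

    def test_symmetric_pair_gives_half_distance(self):
        from rmsdclust import ConfigurationEnsemble

        ens = ConfigurationEnsemble(coords=np.array([[[0.0]], [[0.8]]]))
        c = make_cluster([0, 1], seed=0)
        assert radius_of_gyration(ens, c, "prealigned") == pytest.approx(0.4)
        assert seed_centroid_rmsd(ens, c, "prealigned") == pytest.approx(0.4)

    def test_planted_gaussian_rog_approaches_sigma_sqrt3(self):
        sigma = 0.05
        spec = PlantedEnsembleSpec(
            k_clusters=1,
            members_per_cluster=(500,),
            intra_spread=sigma,
            min_separation=1.0,
            rng_seed=11,
        )
        ensemble, _ = generate_planted_ensemble(spec)
        c = make_cluster(range(500), seed=0)
        rog = radius_of_gyration(ensemble, c, "prealigned")
        assert rog == pytest.approx(sigma * np.sqrt(3.0), rel=0.10)

    def test_seed_planted_at_mean_sits_near_centroid(self, planted):
        spec, ensemble, labels, _ = planted
        first = make_cluster(np.flatnonzero(labels == 0), seed=0)
        d = seed_centroid_rmsd(ensemble, first, "prealigned")
        assert d <= 3 * spec.intra_spread / np.sqrt(100)

    def test_seed_centroid_bounded_by_max_member_to_centroid(self, planted):
        _, ensemble, labels, matrix = planted
        from rmsdclust.geometry import rmsd_raw

        members = np.flatnonzero(labels == 1)
        c = make_cluster(members, seed=int(members[0]))
        centroid = ensemble.coords[members].mean(axis=0)
        worst = max(rmsd_raw(ensemble.coords[m], centroid) for m in members)
        assert seed_centroid_rmsd(ensemble, c, "prealigned") <= worst

    def test_geometry_bundle_consistent(self, planted):
        _, ensemble, labels, matrix = planted
        members = np.flatnonzero(labels == 2)
        c = make_cluster(members, seed=int(members[0]))
        geom = cluster_geometry(ensemble, matrix, c)
        assert geom.diameter == pytest.approx(cluster_diameter(matrix, c))
        assert geom.rog == pytest.approx(
            radius_of_gyration(ensemble, c, "prealigned")
        )

    def test_qtc_seed_more_eccentric_than_rtc_majority_vote(self):
        # broad planted clusters carved below their full extent: the greedy
        # diametral growth runs away from its seed, the radial search does not
        spec = PlantedEnsembleSpec(
            k_clusters=20,
            members_per_cluster=(60,) * 20,
            intra_spread=0.05,
            min_separation=1.0,
            seed_at_mean=False,
            rng_seed=7,
        )
        ensemble, _ = generate_planted_ensemble(spec)
        matrix = pairwise_rmsd_matrix(ensemble, mode="prealigned")
        rtc = cluster(matrix, Threshold(0.08, "radial"), max_clusters=20)
        qtc = cluster(matrix, Threshold(0.16, "diametral"), max_clusters=20)
        pairs = [
            (
                seed_centroid_rmsd(ensemble, a, "prealigned"),
                seed_centroid_rmsd(ensemble, b, "prealigned"),
            )
            for a, b in zip(rtc.clusters, qtc.clusters)
        ]
        wins = sum(q > r for r, q in pairs)
        assert wins > len(pairs) / 2


class TestPairSumAngle:
    def _ens_1d(self, positions):
        from rmsdclust import ConfigurationEnsemble

        return ConfigurationEnsemble(coords=np.asarray(positions)[:, None, None])

    def test_collinear_same_sense_is_zero_degrees(self):
        ens = self._ens_1d([0.0, 1.0, 2.0])
        recs = pair_sum_angle(ens, make_cluster([0, 1, 2], seed=0), "prealigned")
        assert len(recs) == 1
        assert recs[0].angle == pytest.approx(0.0, abs=1e-9)
        assert recs[0].distance_sum == pytest.approx(3.0)

    def test_collinear_opposite_sense_is_180_degrees(self):
        ens = self._ens_1d([-1.0, 0.0, 1.0])
        recs = pair_sum_angle(ens, make_cluster([0, 1, 2], seed=1), "prealigned")
        assert recs[0].angle == pytest.approx(180.0, abs=1e-9)
        assert recs[0].distance_sum == pytest.approx(2.0)

    def test_orthogonal_members_are_90_degrees(self):
        from rmsdclust import ConfigurationEnsemble

        pts = np.array([[0.0, 0.0], [1.0, 0.0], [0.0, 1.0]])
        ens = ConfigurationEnsemble(coords=pts[:, None, :])
        recs = pair_sum_angle(ens, make_cluster([0, 1, 2], seed=0), "prealigned")
        assert recs[0].angle == pytest.approx(90.0, abs=1e-9)

    def test_coincident_member_skipped_with_warning(self):
        ens = self._ens_1d([0.0, 0.0, 1.0, 2.0])
        with pytest.warns(UserWarning):
            recs = pair_sum_angle(ens, make_cluster([0, 1, 2, 3], seed=0), "prealigned")
        assert {r.pair for r in recs} == {(2, 3)}

    def test_needs_at_least_two_non_seed_members(self):
        ens = self._ens_1d([0.0, 1.0])
        with pytest.raises(ValueError):
            pair_sum_angle(ens, make_cluster([0, 1], seed=0), "prealigned")

    def test_rtc_diameter_bounded_by_max_distance_sum(self, planted):
        _, ensemble, _, matrix = planted
        res = cluster(matrix, Threshold(0.1, "radial"), max_clusters=1)
        c = res.clusters[0]
        recs = pair_sum_angle(ensemble, c, "prealigned")
        max_sum = max(r.distance_sum for r in recs)
        assert cluster_diameter(matrix, c) <= max_sum + 1e-12


class TestIntraClusterDistribution:
    def test_pair_concentrates_at_their_distance(self, line_matrix):
        dens, edges = intra_cluster_distribution(
            line_matrix, make_cluster([0, 2]), bins=np.array([0.0, 1.0, 2.0, 3.0])
        )
        assert dens.tolist() == [0.0, 0.0, 1.0]

    def test_qtc_support_strictly_below_threshold(self):
        rng = np.random.default_rng(23)
        m = matrix_from_points(rng.normal(size=(50, 3)))
        res = cluster(m, Threshold(1.2, "diametral"))
        big = next(c for c in res.clusters if c.size >= 3)
        dens, edges = intra_cluster_distribution(m, big, bins=20)
        assert edges[-1] < 1.2

    def test_singleton_rejected(self, line_matrix):
        with pytest.raises(ValueError):
            intra_cluster_distribution(line_matrix, make_cluster([1]))

    def test_merged_populations_show_split_distribution(
        self, two_population_fixture
    ):
        spec, _, labels, matrix = two_population_fixture
        both = make_cluster(range(matrix.n), seed=0, theta=2.0)
        dens, edges = intra_cluster_distribution(
            matrix, both, bins=np.arange(0.0, matrix.values.max() + 0.02, 0.02)
        )
        centers = 0.5 * (edges[:-1] + edges[1:])
        low = dens[centers < 4 * spec.intra_spread].sum()
        mid = dens[
            (centers > 6 * spec.intra_spread) & (centers < 0.8 * spec.min_separation)
        ].sum()
        high = dens[centers > 0.8 * spec.min_separation].sum()
        assert low > 0 and high > 0 and mid == 0.0

    def test_density_integrates_to_one(self, planted):
        _, _, labels, matrix = planted
        c = make_cluster(np.flatnonzero(labels == 0), theta=0.5)
        dens, edges = intra_cluster_distribution(matrix, c, bins=30)
        assert np.sum(dens * np.diff(edges)) == pytest.approx(1.0)


class TestCoverageReport:
    def _result(self, sizes, n_total):
        from rmsdclust.clustering import Algorithm, ClusteringResult

        clusters = []
        start = 0
        for rank, s in enumerate(sizes, 1):
            clusters.append(
                make_cluster(range(start, start + s), rank=rank)
            )
            start += s
        return ClusteringResult(
            clusters=tuple(clusters),
            algorithm=Algorithm.RTC,
            min_size=1,
            unassigned=tuple(range(start, n_total)),
        )

    def test_cutoff_arithmetic(self):
        table = coverage_report(self._result([6, 3, 1], 10), [3])
        assert table.loc[0, "n_clusters"] == 2
        assert table.loc[0, "coverage_pct"] == pytest.approx(90.0)

    def test_cutoff_one_counts_everything_assigned(self):
        table = coverage_report(self._result([6, 3, 1], 12), [1])
        assert table.loc[0, "n_clusters"] == 3
        assert table.loc[0, "coverage_pct"] == pytest.approx(100.0 * 10 / 12)

    def test_cutoff_beyond_largest_is_empty(self):
        table = coverage_report(self._result([6, 3, 1], 10), [7])
        assert table.loc[0, "n_clusters"] == 0
        assert table.loc[0, "coverage_pct"] == 0.0
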