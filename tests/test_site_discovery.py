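"""Shared-nearest-neighbor clustering and density ranking against oracles."""

import numpy as np
import pytest

from floodsite.core_model import minimum_image
from floodsite.site_discovery import (
    PointCloud,
    cluster_average_density,
    collect_ligand_positions,
    jarvis_patrick,
    k_nearest_neighbors,
    rank_and_report_sites,
)
from .conftest import make_trajectory


def brute_force_jarvis_patrick(points, k, k_t, box=None):
    """Independent implementation straight from the definition.

    All pairwise distances; per-point neighbor list sorted by (distance,
    index); join i~j iff mutual k-NN and >= k_t shared neighbors; clusters
    are connected components found by union-find.
    """
    n = len(points)
    d = points[:, None, :] - points[None, :, :]
    if box is not None:
        d = minimum_image(d, box)
    dist = np.sqrt((d**2).sum(axis=2))
    knn = []
    for i in range(n):
        order = sorted((dist[i, j], j) for j in range(n) if j != i)
        knn.append([j for _, j in order[:k]])
    parent = list(range(n))

    def find(a):
        while parent[a] != a:
            parent[a] = parent[parent[a]]
            a = parent[a]
        return a

    for i in range(n):
        for j in range(i + 1, n):
            if (
                j in knn[i]
                and i in knn[j]
                and len(set(knn[i]) & set(knn[j])) >= k_t
            ):
                parent[find(i)] = find(j)
    return np.array([find(i) for i in range(n)])


def same_partition(a, b):
    return len(set(zip(a, b))) == len(set(a)) == len(set(b))


def make_cloud(points, box=None):
    n = len(points)
    return PointCloud(
        positions=np.asarray(points, float),
        frame_index=np.zeros(n, dtype=int),
        molecule_index=np.arange(n),
        box=None if box is None else np.asarray(box, float),
    )


class TestCollectPositions:
    def test_point_count_and_stride(self):
        rng = np.random.default_rng(0)
        pos = rng.uniform(0, 20, (10, 2, 3))
        traj = make_trajectory(pos, box=(20.0, 20.0, 20.0))
        cloud = collect_ligand_positions(traj, "ligand")
        assert cloud.n_points == 20
        strided = collect_ligand_positions(traj, "ligand", stride=5)
        assert strided.n_points == 4
        assert set(strided.frame_index) == {0, 5}

    def test_deterministic_and_provenanced(self):
        rng = np.random.default_rng(1)
        pos = rng.uniform(0, 20, (6, 3, 3))
        traj = make_trajectory(pos, box=(20.0, 20.0, 20.0))
        a = collect_ligand_positions(traj, "ligand", equilibration_cut=2)
        b = collect_ligand_positions(traj, "ligand", equilibration_cut=2)
        np.testing.assert_array_equal(a.positions, b.positions)
        assert a.provenance["equilibration_cut"] == 2

    def test_cut_beyond_length_rejected(self):
        traj = make_trajectory(np.zeros((3, 1, 3)))
        with pytest.raises(ValueError):
            collect_ligand_positions(traj, "ligand", equilibration_cut=3)


class TestJarvisPatrickOracle:
    @pytest.mark.parametrize("seed", [0, 1, 2, 3])
    @pytest.mark.parametrize("periodic", [False, True])
    def test_matches_brute_force_on_random_clouds(self, seed, periodic):
        rng = np.random.default_rng(seed)
        n = 150
        box = np.array([15.0, 15.0, 15.0]) if periodic else None
        pts = rng.uniform(0, 15, (n, 3))
        cloud = make_cloud(pts, box=box)
        got = jarvis_patrick(cloud, k=8, k_t=3).labels
        want = brute_force_jarvis_patrick(pts, 8, 3, box=box)
        assert same_partition(got, want)

    @pytest.mark.parametrize("n", [20, 60, 200])
    def test_matches_brute_force_clustered_data(self, n):
        rng = np.random.default_rng(n)
        centers = rng.uniform(0, 40, (4, 3))
        pts = np.concatenate(
            [c + rng.normal(0, 1.0, (n // 4, 3)) for c in centers]
        )
        cloud = make_cloud(pts)
        got = jarvis_patrick(cloud, k=8, k_t=3).labels
        want = brute_force_jarvis_patrick(pts, 8, 3)
        assert same_partition(got, want)

    def test_two_separated_blobs(self):
        rng = np.random.default_rng(5)
        a = rng.normal(0, 0.5, (12, 3))
        b = np.array([50.0, 0, 0]) + rng.normal(0, 0.5, (12, 3))
        sol = jarvis_patrick(make_cloud(np.vstack([a, b])), k=8, k_t=3)
        labels = sol.labels
        assert len(set(labels[:12])) == 1
        assert len(set(labels[12:])) == 1
        assert labels[0] != labels[12]

    def test_far_outlier_is_singleton(self):
        rng = np.random.default_rng(6)
        blob = rng.normal(0, 0.5, (20, 3))
        pts = np.vstack([blob, [[200.0, 200.0, 200.0]]])
        sol = jarvis_patrick(make_cloud(pts), k=8, k_t=3)
        assert (sol.labels == sol.labels[-1]).sum() == 1

    def test_too_few_points_rejected(self):
        cloud = make_cloud(np.random.default_rng(0).uniform(0, 1, (5, 3)))
        with pytest.raises(ValueError, match="lower K"):
            jarvis_patrick(cloud, k=8, k_t=3)

    def test_label_conservation(self):
        rng = np.random.default_rng(7)
        pts = rng.uniform(0, 10, (80, 3))
        sol = jarvis_patrick(make_cloud(pts), k=8, k_t=3)
        _, counts = np.unique(sol.labels, return_counts=True)
        assert counts.sum() == 80

    def test_rigid_motion_invariance(self):
        from scipy.spatial.transform import Rotation

        rng = np.random.default_rng(8)
        pts = rng.normal(0, 3.0, (60, 3))
        rot = Rotation.from_euler("xyz", [0.3, -1.1, 2.0]).as_matrix()
        moved = pts @ rot.T + np.array([5.0, -2.0, 9.0])
        a = jarvis_patrick(make_cloud(pts), k=8, k_t=3).labels
        b = jarvis_patrick(make_cloud(moved), k=8, k_t=3).labels
        assert same_partition(a, b)


class TestNeighborLists:
    def test_ties_broken_by_index(self):
        # four points at the corners of a square: each point's two nearest
        # are the equidistant adjacent corners -> order must follow index
        pts = np.array([[0, 0, 0], [1, 0, 0], [1, 1, 0], [0, 1, 0]], float)
        knn = k_nearest_neighbors(pts, 2)
        np.testing.assert_array_equal(knn[0], [1, 3])
        np.testing.assert_array_equal(knn[2], [1, 3])

    def test_periodic_neighbors_cross_boundary(self):
        box = np.array([10.0, 10.0, 10.0])
        pts = np.array([[0.5, 5, 5], [9.5, 5, 5], [5.0, 5, 5]])
        knn = k_nearest_neighbors(pts, 1, box=box)
        assert knn[0, 0] == 1 and knn[1, 0] == 0


class TestClusterDensity:
    def test_single_point_mass_is_one(self):
        rho, mass = cluster_average_density(np.array([[3.3, 7.1, 2.2]]))
        assert mass == pytest.approx(1.0, rel=0.01)

    def test_coincident_points_scale_linearly(self):
        p = np.array([[1.0, 2.0, 3.0]])
        rho1, mass1 = cluster_average_density(p)
        rho5, mass5 = cluster_average_density(np.repeat(p, 5, axis=0))
        assert mass5 == pytest.approx(5 * mass1, rel=1e-6)
        assert rho5 == pytest.approx(5 * rho1, rel=1e-6)

    def test_mass_equals_member_count(self):
        rng = np.random.default_rng(9)
        pts = rng.normal(0, 1.5, (40, 3))
        _, mass = cluster_average_density(pts)
        assert mass == pytest.approx(40.0, rel=0.01)

    def test_translation_invariance_within_grid_tolerance(self):
        rng = np.random.default_rng(10)
        pts = rng.normal(0, 1.0, (25, 3))
        rho0, mass0 = cluster_average_density(pts)
        for shift in ((0.13, 0.29, 0.07), (1.9, -3.2, 0.55)):
            rho, mass = cluster_average_density(pts + np.asarray(shift))
            assert mass == pytest.approx(mass0, rel=0.01)
            assert rho == pytest.approx(rho0, rel=0.01)

    def test_periodic_cluster_straddling_boundary(self):
        box = np.array([20.0, 20.0, 20.0])
        rng = np.random.default_rng(11)
        blob = rng.normal(0, 0.8, (30, 3)) % box  # wraps around the origin corner
        rho_wrapped, mass_wrapped = cluster_average_density(blob, box=box)
        assert mass_wrapped == pytest.approx(30.0, rel=0.01)


class TestRanking:
    def _three_blob_cloud(self, sizes=(60, 30, 15), seed=12):
        rng = np.random.default_rng(seed)
        centers = np.array([[5.0, 5, 5], [25.0, 5, 5], [5.0, 25, 5]])
        pts = np.concatenate(
            [c + rng.normal(0, 0.8, (s, 3)) for c, s in zip(centers, sizes)]
        )
        return make_cloud(pts), centers

    def test_density_orders_by_population_at_equal_spread(self):
        cloud, centers = self._three_blob_cloud()
        sol = jarvis_patrick(cloud, k=8, k_t=3)
        sites = rank_and_report_sites(sol, cloud, top_n=3)
        assert [s.rank for s in sites] == [1, 2, 3]
        for site, center in zip(sites, centers):
            assert np.linalg.norm(site.centroid - center) < 1.0
        assert sites[0].avg_density > sites[1].avg_density > sites[2].avg_density

    def test_member_fractions_accumulate(self):
        cloud, _ = self._three_blob_cloud()
        sol = jarvis_patrick(cloud, k=8, k_t=3)
        sites = rank_and_report_sites(sol, cloud, top_n=3)
        fractions = [s.member_fraction for s in sites]
        assert sites[-1].cumulative_fraction == pytest.approx(sum(fractions))
        assert sites[-1].cumulative_fraction <= 1.0

    def test_single_cluster_reports_one_site(self):
        rng = np.random.default_rng(13)
        cloud = make_cloud(rng.normal(0, 0.5, (20, 3)))
        sol = jarvis_patrick(cloud, k=8, k_t=3)
        sites = rank_and_report_sites(sol, cloud, top_n=3)
        main = [s for s in sites if s.n_members >= 10]
        assert len(main) == 1
        assert main[0].cumulative_fraction == pytest.approx(
            sum(s.member_fraction for s in sites)
        )

    def test_permutation_invariance(self):
        cloud, _ = self._three_blob_cloud()
        rng = np.random.default_rng(14)
        perm = rng.permutation(cloud.n_points)
        shuffled = make_cloud(cloud.positions[perm])
        a = rank_and_report_sites(jarvis_patrick(cloud), cloud, top_n=3)
        b = rank_and_report_sites(jarvis_patrick(shuffled), shuffled, top_n=3)
        for sa, sb in zip(a, b):
            np.testing.assert_allclose(sa.centroid, sb.centroid, atol=1e-9)
            assert sa.n_members == sb.n_members

    def test_no_nonsingleton_clusters_rejected(self):
        from floodsite.site_discovery import ClusterSolution

        pts = np.arange(30, dtype=float).reshape(10, 3)
        sol = ClusterSolution(
            labels=np.arange(10), k=8, k_t=3, periodic=False
        )  # every point its own singleton
        with pytest.raises(ValueError, match="non-singleton"):
            rank_and_report_sites(sol, make_cloud(pts))


class TestPlantedWellRecovery:
    """Site detection on Boltzmann clouds from planted Gaussian wells."""

    @staticmethod
    def _well_cloud(rng, center, depth, width, n):
        """Positions near the bottom of a Gaussian well of given depth.

        Harmonic approximation: the well bottom has curvature depth/width²
        (in kT/Å²), so bound positions spread as width/sqrt(depth).
        """
        spread = width / np.sqrt(depth)
        return np.asarray(center) + rng.normal(0, spread, (n, 3))

    def test_perfect_precision_and_recall_when_well_separated(self):
        # three wells, separation >= 5x width, plus sparse uniform background
        rng = np.random.default_rng(15)
        width = 1.5
        centers = np.array([[10.0, 10, 10], [30.0, 10, 10], [10.0, 30, 30]])
        depths = [6.0, 4.0, 2.0]
        occupancies = [60, 45, 30]  # deeper well -> larger share
        pts = [
            self._well_cloud(rng, c, d, width, n)
            for c, d, n in zip(centers, depths, occupancies)
        ]
        background = rng.uniform(0, 40, (60, 3))
        cloud = make_cloud(np.concatenate(pts + [background]))
        sol = jarvis_patrick(cloud, k=8, k_t=3)
        sites = rank_and_report_sites(
            sol, cloud, top_n=3, min_member_fraction=0.03
        )
        # recall: every planted well recovered in depth order; precision:
        # nothing else makes the top three
        assert len(sites) == 3
        for site, center in zip(sites, centers):
            assert np.linalg.norm(site.centroid - center) < 2.0
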