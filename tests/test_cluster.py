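"""Filtration, ligand RMSD, density clustering and residence bookkeeping."""

import numpy as np
import pytest

from pscore import (
    ClusteringParams,
    PoseTrajectory,
    SiteDefinition,
    ValidationError,
    build_clusters,
    cluster_poses,
    concatenate_replicates,
    dbscan_cluster,
    pairwise_rmsd,
    proximity_filter,
    subsample_snapshots,
)
from pscore.cluster import NOISE, _dbscan_features, _flatten_scaled

from conftest import make_traj


def reference_dbscan(dist, eps, min_pts):
    """Exhaustive oracle: region queries + BFS, border -> lowest core index."""
    n = dist.shape[0]
    neigh = [set(np.flatnonzero(dist[i] <= eps)) for i in range(n)]
    core = [len(neigh[i]) >= min_pts for i in range(n)]
    labels = [NOISE] * n
    next_label = 0
    for s in range(n):
        if not core[s] or labels[s] != NOISE:
            continue
        stack = [s]
        labels[s] = next_label
        while stack:
            i = stack.pop()
            for j in neigh[i]:
                if core[j] and labels[j] == NOISE:
                    labels[j] = next_label
                    stack.append(j)
        next_label += 1
    for i in range(n):
        if core[i] or labels[i] != NOISE:
            continue
        core_neighbours = sorted(j for j in neigh[i] if core[j])
        if core_neighbours:
            labels[i] = labels[core_neighbours[0]]
    return np.array(labels)


def same_partition(a, b):
    """Label-for-label agreement up to label permutation (noise fixed)."""
    a, b = np.asarray(a), np.asarray(b)
    if not np.array_equal(a == NOISE, b == NOISE):
        return False
    mapping = {}
    for x, y in zip(a, b):
        if x == NOISE:
            continue
        if mapping.setdefault(x, y) != y:
            return False
    return len(set(mapping.values())) == len(mapping)


def embed_1d(points):
    """n points on a line as 1-atom frames; RMSD = absolute difference."""
    coords = np.zeros((len(points), 1, 3))
    coords[:, 0, 0] = points
    return make_traj(coords)


class TestProximityFilter:
    def setup_method(self):
        self.site = SiteDefinition(site_center=[0.0, 0.0, 0.0], cutoff_A=9.0)

    @staticmethod
    def traj_at_distances(distances):
        coords = np.zeros((len(distances), 2, 3))
        coords[:, :, 0] = np.asarray(distances)[:, None]  # both atoms at x=d
        return make_traj(coords)

    def test_all_close_frames_unchanged(self):
        traj = self.traj_at_distances([3.0, 3.0, 3.0])
        assert proximity_filter(traj, self.site).n_frames == 3

    def test_far_frame_removed(self):
        traj = self.traj_at_distances([3.0, 9.5, 3.0])
        out = proximity_filter(traj, self.site)
        np.testing.assert_array_equal(out.frame_indices, [0, 2])

    def test_boundary_exactly_at_cutoff_retained(self):
        traj = self.traj_at_distances([9.0])
        assert proximity_filter(traj, self.site).n_frames == 1

    def test_all_removed_gives_empty_signal_not_crash(self):
        traj = self.traj_at_distances([20.0, 30.0])
        out = proximity_filter(traj, self.site)
        assert out.n_frames == 0
        clusters, labels, filtered = cluster_poses(out, ClusteringParams())
        assert clusters == []

    def test_min_atom_mode_uses_closest_atom(self):
        coords = np.zeros((1, 2, 3))
        coords[0, 0, 0] = 8.0   # one atom inside cutoff
        coords[0, 1, 0] = 30.0  # centroid would be at 19 -> centroid mode drops
        traj = make_traj(coords)
        site = SiteDefinition(site_coords=[[0, 0, 0]], cutoff_A=9.0)
        assert proximity_filter(traj, site, mode="centroid").n_frames == 0
        assert proximity_filter(traj, site, mode="min_atom").n_frames == 1


class TestPairwiseRmsd:
    def test_identical_frames_zero(self):
        coords = np.random.default_rng(0).normal(size=(1, 5, 3))
        traj = make_traj(np.repeat(coords, 2, axis=0))
        assert pairwise_rmsd(traj)[0, 1] == pytest.approx(0.0, abs=1e-12)

    def test_rigid_translation_closed_form(self):
        base = np.random.default_rng(1).normal(size=(5, 3))
        traj = make_traj([base, base + [1.0, 0.0, 0.0]])
        assert pairwise_rmsd(traj)[0, 1] == pytest.approx(1.0, abs=1e-9)

    def test_matches_double_loop_oracle(self, rng):
        traj = make_traj(rng.normal(size=(3, 5, 3)))
        m = pairwise_rmsd(traj)
        for i in range(3):
            for j in range(3):
                acc = sum(
                    np.sum((traj.coords[i, a] - traj.coords[j, a]) ** 2)
                    for a in range(5)
                )
                assert m[i, j] == pytest.approx(np.sqrt(acc / 5), abs=1e-9)

    def test_symmetric_zero_diagonal_triangle_inequality(self, rng):
        traj = make_traj(rng.normal(size=(6, 4, 3)))
        m = pairwise_rmsd(traj)
        np.testing.assert_allclose(m, m.T, atol=1e-9)
        np.testing.assert_allclose(np.diag(m), 0.0, atol=1e-12)
        for i in range(6):
            for j in range(6):
                for k in range(6):
                    assert m[i, j] <= m[i, k] + m[k, j] + 1e-9


class TestDbscan:
    def test_two_line_groups(self):
        traj = embed_1d([0.0, 0.1, 0.2, 5.0, 5.1])
        labels = dbscan_cluster(
            pairwise_rmsd(traj), ClusteringParams(eps_A=0.5, min_pts=2)
        )
        expected = reference_dbscan(pairwise_rmsd(traj), 0.5, 2)
        assert same_partition(labels, expected)
        assert NOISE not in labels
        assert len(set(labels)) == 2

    def test_isolated_point_is_noise(self):
        traj = embed_1d([0.0, 0.1, 10.0])
        labels = dbscan_cluster(
            pairwise_rmsd(traj), ClusteringParams(eps_A=0.5, min_pts=2)
        )
        assert labels[2] == NOISE

    def test_two_tight_blobs_of_100(self, rng):
        centers = np.array([[0.0, 0, 0], [10.0, 0, 0]])
        coords = np.concatenate(
            [c + rng.normal(scale=0.1, size=(100, 3, 3)) for c in centers]
        )
        traj = make_traj(coords)
        labels = dbscan_cluster(
            pairwise_rmsd(traj), ClusteringParams(eps_A=1.0, min_pts=100)
        )
        assert NOISE not in labels
        sizes = np.bincount(labels)
        np.testing.assert_array_equal(sizes, [100, 100])

    def test_non_square_matrix_rejected(self):
        with pytest.raises(ValidationError, match="square"):
            dbscan_cluster(np.zeros((3, 2)), ClusteringParams())

    @pytest.mark.parametrize("seed", range(8))
    def test_matches_exhaustive_oracle_on_random_instances(self, seed):
        rng = np.random.default_rng(seed)
        n = int(rng.integers(10, 120))
        pts = rng.normal(scale=rng.uniform(0.5, 3.0), size=(n, 2, 3))
        dist = pairwise_rmsd(make_traj(pts))
        for eps in (0.5, 1.5):
            for min_pts in (2, 5):
                got = dbscan_cluster(dist, ClusteringParams(eps_A=eps, min_pts=min_pts))
                want = reference_dbscan(dist, eps, min_pts)
                assert same_partition(got, want)

    def test_feature_path_equals_matrix_path(self, rng):
        coords = np.concatenate(
            [
                rng.normal(scale=0.3, size=(60, 2, 3)),
                np.array([8.0, 0, 0]) + rng.normal(scale=0.3, size=(40, 2, 3)),
            ]
        )
        traj = make_traj(coords)
        params = ClusteringParams(eps_A=1.0, min_pts=10)
        lab_matrix = dbscan_cluster(pairwise_rmsd(traj), params)
        lab_feature = _dbscan_features(_flatten_scaled(traj), params)
        np.testing.assert_array_equal(lab_matrix, lab_feature)

    @pytest.mark.parametrize("seed", range(5))
    def test_core_point_partition_agrees_with_sklearn(self, seed):
        # independent library cross-check; restricted to core points because
        # border-point ownership is implementation-defined in DBSCAN
        from sklearn.cluster import DBSCAN

        rng = np.random.default_rng(seed)
        n = int(rng.integers(30, 150))
        pts = rng.normal(scale=1.5, size=(n, 2, 3))
        traj = make_traj(pts)
        dist = pairwise_rmsd(traj)
        eps, min_pts = 1.0, 4
        ours = dbscan_cluster(dist, ClusteringParams(eps_A=eps, min_pts=min_pts))
        fit = DBSCAN(eps=eps, min_samples=min_pts, metric="precomputed").fit(dist)
        core = np.zeros(n, dtype=bool)
        core[fit.core_sample_indices_] = True
        assert np.array_equal(core, (dist <= eps).sum(axis=1) >= min_pts)
        assert same_partition(ours[core], fit.labels_[core])

    def test_reorder_invariance_up_to_relabelling(self, rng):
        coords = np.concatenate(
            [
                rng.normal(scale=0.2, size=(30, 2, 3)),
                np.array([6.0, 0, 0]) + rng.normal(scale=0.2, size=(30, 2, 3)),
            ]
        )
        traj = make_traj(coords)
        perm = rng.permutation(60)
        params = ClusteringParams(eps_A=1.0, min_pts=5)
        lab = dbscan_cluster(pairwise_rmsd(traj), params)
        lab_perm = dbscan_cluster(pairwise_rmsd(make_traj(coords[perm])), params)
        assert same_partition(lab[perm], lab_perm)


class TestBuildClusters:
    def test_residence_time_100_frames_at_20ps(self):
        traj = make_traj(np.zeros((100, 2, 3)), frame_dt_ps=20.0)
        clusters = build_clusters(np.zeros(100, dtype=int), traj)
        assert clusters[0].residence_time_ns == pytest.approx(2.0)

    def test_residence_time_13100_frames_is_262ns(self):
        traj = make_traj(np.zeros((13100, 1, 3)), frame_dt_ps=20.0)
        clusters = build_clusters(np.zeros(13100, dtype=int), traj)
        assert clusters[0].residence_time_ns == pytest.approx(262.0)

    def test_ids_ordered_by_residence_time_then_representative(self, rng):
        # two clusters, sizes 5 and 10 -> C-01 is the bigger one
        coords = np.concatenate(
            [
                rng.normal(scale=0.05, size=(5, 2, 3)),
                np.array([5.0, 0, 0]) + rng.normal(scale=0.05, size=(10, 2, 3)),
            ]
        )
        labels = np.array([0] * 5 + [1] * 10)
        clusters = build_clusters(labels, make_traj(coords))
        assert clusters[0].cluster_id == "C-01"
        assert clusters[0].size == 10

    def test_equal_sizes_tie_broken_by_smaller_representative_frame(self, rng):
        coords = np.concatenate(
            [
                rng.normal(scale=0.05, size=(5, 2, 3)),
                np.array([5.0, 0, 0]) + rng.normal(scale=0.05, size=(5, 2, 3)),
            ]
        )
        labels = np.array([0] * 5 + [1] * 5)
        clusters = build_clusters(labels, make_traj(coords))
        assert clusters[0].cluster_id == "C-01"
        assert clusters[0].representative_frame < clusters[1].representative_frame

    def test_representative_is_medoid(self, rng):
        coords = rng.normal(size=(7, 3, 3))
        traj = make_traj(coords)
        clusters = build_clusters(np.zeros(7, dtype=int), traj)
        m = pairwise_rmsd(traj)
        assert clusters[0].representative_frame == int(np.argmin(m.sum(axis=1)))

    def test_residence_sum_bounded_by_retained_time(self, rng):
        coords = np.concatenate(
            [
                rng.normal(scale=0.1, size=(40, 2, 3)),
                np.array([7.0, 0, 0]) + rng.normal(scale=0.1, size=(30, 2, 3)),
                np.array([0, 70.0, 0]) + rng.normal(scale=0.1, size=(1, 2, 3)),
            ]
        )
        traj = make_traj(coords)
        params = ClusteringParams(eps_A=1.0, min_pts=5)
        labels = dbscan_cluster(pairwise_rmsd(traj), params)
        clusters = build_clusters(labels, traj)
        total = sum(c.residence_time_ns for c in clusters)
        budget = traj.n_frames * traj.frame_dt_ps / 1000.0
        assert total <= budget
        has_noise = NOISE in labels
        assert (total < budget) == has_noise


class TestSubsampleSnapshots:
    def test_contiguous_10ns_span_every_2ns(self):
        n = 501  # 0..10 ns inclusive at 20 ps
        traj = make_traj(np.zeros((n, 1, 3)), frame_dt_ps=20.0)
        clusters = build_clusters(np.zeros(n, dtype=int), traj)
        snaps = subsample_snapshots(clusters[0], traj, interval_ns=2.0)
        times_ns = sorted(traj.times_ps[traj.frame_indices.searchsorted(snaps)] / 1000)
        assert times_ns == [0.0, 2.0, 4.0, 6.0, 8.0, 10.0]

    def test_single_frame_cluster(self):
        traj = make_traj(np.zeros((1, 1, 3)))
        from pscore import ClusterRecord

        cl = ClusterRecord("C-01", np.array([0]), 0.02, 0)
        assert subsample_snapshots(cl, traj) == [0]

    def test_interval_beyond_span_gives_one_snapshot(self):
        traj = make_traj(np.zeros((10, 1, 3)), frame_dt_ps=20.0)
        clusters = build_clusters(np.zeros(10, dtype=int), traj)
        assert len(subsample_snapshots(clusters[0], traj, interval_ns=100.0)) == 1

    def test_interval_never_crosses_replicate_seam(self):
        a = make_traj(np.zeros((5, 1, 3)), frame_dt_ps=20.0)
        b = make_traj(np.zeros((5, 1, 3)), frame_dt_ps=20.0)
        cat = concatenate_replicates([a, b])
        clusters = build_clusters(np.zeros(10, dtype=int), cat)
        snaps = subsample_snapshots(clusters[0], cat, interval_ns=100.0)
        # one snapshot per replicate, not one overall
        assert len(snaps) == 2
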