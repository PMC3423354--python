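import numpy as np
import pytest

from bindmode import (
    ANTI_PARALLEL,
    PARALLEL,
    PERPENDICULAR,
    AnalysisError,
    DockedPose,
    GeometryError,
    classify_orientation,
    daura_cluster,
    interconversion_counts,
    kabsch_fit,
    occupancy_timeline,
    pairwise_rmsd_matrix,
    rank_pose_clusters,
)
from bindmode.synthetic import gen_pose_set

from conftest import random_rigid_transform


def brute_force_daura(matrix, cutoff):
    """Independent greedy reference: sets and explicit loops, same tie rule."""
    n = matrix.shape[0]
    pool = set(range(n))
    clusters = []
    while pool:
        best_i, best_neighbors = None, None
        for i in sorted(pool):
            neighbors = {j for j in pool if matrix[i, j] <= cutoff}
            if best_neighbors is None or len(neighbors) > len(best_neighbors):
                best_i, best_neighbors = i, neighbors
        clusters.append(frozenset(best_neighbors))
        pool -= best_neighbors
    return clusters


def partition_of(assignment):
    return {
        frozenset(np.nonzero(assignment.labels == k)[0].tolist())
        for k in range(1, assignment.n_clusters + 1)
    }


class TestPairwiseRmsdMatrix:
    def test_identical_conformations_give_zero(self, rng):
        c = rng.normal(size=(5, 3))
        mat = pairwise_rmsd_matrix([c, c.copy()])
        assert mat[0, 1] < 1e-12

    def test_rigid_copy_zero_only_with_superposition(self, rng):
        c = rng.normal(size=(6, 3)) * 3
        R, t = random_rigid_transform(rng)
        moved = c @ R.T + t
        assert pairwise_rmsd_matrix([c, moved], superpose=True)[0, 1] < 1e-8
        assert pairwise_rmsd_matrix([c, moved], superpose=False)[0, 1] > 1.0

    def test_matches_per_pair_kabsch_oracle(self, rng):
        confs = rng.normal(size=(6, 5, 3)) * 2
        mat = pairwise_rmsd_matrix(confs, superpose=True)
        for i in range(6):
            for j in range(i + 1, 6):
                _, d = kabsch_fit(confs[i], confs[j])
                assert abs(mat[i, j] - d) < 1e-10
        assert np.allclose(mat, mat.T)
        assert np.all(np.diag(mat) == 0)

    def test_mismatched_atom_counts_raise(self, rng):
        with pytest.raises(AnalysisError):
            pairwise_rmsd_matrix(
                [rng.normal(size=(4, 3)), rng.normal(size=(5, 3))]
            )


class TestDauraCluster:
    def test_all_far_apart_gives_singletons(self):
        mat = np.array(
            [[0, 5, 5], [5, 0, 5], [5, 5, 0]], dtype=float
        )
        assignment = daura_cluster(mat, cutoff=1.5)
        assert assignment.n_clusters == 3
        assert assignment.sizes().tolist() == [1, 1, 1]

    def test_all_close_gives_one_cluster(self):
        mat = np.full((4, 4), 0.5)
        np.fill_diagonal(mat, 0.0)
        assignment = daura_cluster(mat, cutoff=1.5)
        assert assignment.n_clusters == 1
        assert assignment.sizes().tolist() == [4]

    @pytest.mark.parametrize("seed", range(10))
    def test_matches_brute_force_oracle(self, seed):
        rng = np.random.default_rng(seed)
        n = int(rng.integers(5, 31))
        pts = rng.normal(size=(n, 3)) * 2
        mat = np.linalg.norm(pts[:, None] - pts[None], axis=2)
        cutoff = float(np.median(mat[mat > 0]))
        assignment = daura_cluster(mat, cutoff)
        assert partition_of(assignment) == set(brute_force_daura(mat, cutoff))

    def test_sizes_non_increasing_and_partition_complete(self, rng):
        pts = rng.normal(size=(25, 3))
        mat = np.linalg.norm(pts[:, None] - pts[None], axis=2)
        assignment = daura_cluster(mat, 1.0)
        sizes = assignment.sizes()
        assert np.all(np.diff(sizes) <= 0)
        assert sizes.sum() == 25
        assert np.all(assignment.labels >= 1)

    def test_members_within_cutoff_of_center(self, rng):
        pts = rng.normal(size=(30, 3)) * 2
        mat = np.linalg.norm(pts[:, None] - pts[None], axis=2)
        assignment = daura_cluster(mat, 1.5)
        for k, center in enumerate(assignment.centers, start=1):
            members = np.nonzero(assignment.labels == k)[0]
            assert np.all(mat[center, members] <= 1.5)

    def test_invariant_under_input_permutation(self, rng):
        pts = rng.normal(size=(20, 3)) * 1.5
        mat = np.linalg.norm(pts[:, None] - pts[None], axis=2)
        base = partition_of(daura_cluster(mat, 1.2))
        for _ in range(20):
            perm = rng.permutation(20)
            shuffled = daura_cluster(mat[np.ix_(perm, perm)], 1.2)
            # map shuffled indices back to the original frame
            back = {
                frozenset(perm[list(c)].tolist())
                for c in partition_of(shuffled)
            }
            assert back == base

    def test_bad_inputs_raise(self):
        with pytest.raises(AnalysisError):
            daura_cluster(np.zeros((2, 3)), 1.0)
        with pytest.raises(AnalysisError):
            daura_cluster(np.zeros((3, 3)), -1.0)


class TestTimelines:
    def _assignment(self, labels):
        from bindmode import ClusterAssignment

        labels = np.asarray(labels)
        centers = [np.nonzero(labels == k)[0][0]
                   for k in range(1, labels.max() + 1)]
        # build with sizes ordered correctly for the test data
        return ClusterAssignment(labels=labels, centers=np.array(centers),
                                 cutoff=1.5)

    def test_single_replicate_single_cluster(self):
        assignment = self._assignment([1, 1, 1, 1])
        tl = occupancy_timeline(assignment, ["a"] * 4, np.arange(4.0))
        assert tl.timelines["a"]["cluster"].tolist() == [1, 1, 1, 1]

    def test_planted_switch_changes_id_exactly_once(self):
        labels = [1] * 500 + [2] * 300
        assignment = self._assignment(labels)
        tl = occupancy_timeline(assignment, ["a"] * 800, np.arange(800.0))
        ids = tl.timelines["a"]["cluster"].to_numpy()
        assert np.sum(ids[1:] != ids[:-1]) == 1

    def test_pooled_length_is_conserved(self, rng):
        n = 250
        labels = rng.integers(1, 3, n)
        labels[:10] = 1  # ensure cluster 1 is the largest
        assignment = self._assignment(np.sort(labels))
        reps = np.array([f"r{i % 5}" for i in range(n)])
        tl = occupancy_timeline(assignment, reps, np.arange(float(n)))
        assert tl.total_frames() == n
        assert len(tl.timelines) == 5

    def test_length_mismatch_raises(self):
        assignment = self._assignment([1, 1])
        with pytest.raises(AnalysisError):
            occupancy_timeline(assignment, ["a"], np.arange(2.0))


class TestInterconversion:
    def _timeline(self, ids_by_rep):
        from bindmode import OccupancyTimeline
        import pandas as pd

        return OccupancyTimeline(
            timelines={
                rep: pd.DataFrame(
                    {"time_ps": np.arange(float(len(ids))), "cluster": ids}
                )
                for rep, ids in ids_by_rep.items()
            }
        )

    def test_constant_timeline_has_zero_offdiagonals(self):
        inter = interconversion_counts(self._timeline({"a": [1] * 100}), top_k=4)
        m = inter.matrices["a"]
        assert m.sum() - np.trace(m) == 0
        assert not inter.interconverts("a")

    def test_planted_single_switch_counted_once(self):
        inter = interconversion_counts(
            self._timeline({"a": [1] * 50 + [2] * 50}), top_k=4
        )
        m = inter.matrices["a"]
        assert m[0, 1] == 1
        assert m.sum() - np.trace(m) == 1
        assert inter.interconverts("a")

    def test_symmetric_jumping_matches_expected_rate(self, rng):
        p = 0.02
        n = 20_000
        ids = np.empty(n, dtype=int)
        ids[0] = 1
        flips = rng.random(n - 1) < p
        ids[1:] = 1 + (np.cumsum(flips) % 2)
        inter = interconversion_counts(self._timeline({"a": ids}), top_k=2)
        m = inter.matrices["a"]
        off = m.sum() - np.trace(m)
        lam = p * (n - 1)
        assert abs(off - lam) < 4 * np.sqrt(lam)

    def test_transitions_outside_top_k_ignored(self):
        inter = interconversion_counts(
            self._timeline({"a": [1, 5, 1, 1]}), top_k=2
        )
        m = inter.matrices["a"]
        assert m.sum() - np.trace(m) == 0

    def test_top_k_below_two_raises(self):
        with pytest.raises(AnalysisError):
            interconversion_counts(self._timeline({"a": [1, 1]}), top_k=1)


class TestRankPoseClusters:
    def test_two_planted_energy_groups(self, rng):
        result = gen_pose_set(
            3, 3, 0, cluster_spread=1.0,
            energies=[-11.0, -11.5, -12.0, -10.0, -10.5, -11.0], seed=0,
        )
        table = rank_pose_clusters(result.poses, cutoff=2.0)
        assert len(table) == 2
        assert sorted(table["mean_energy"]) == [-11.5, -10.5]

    def test_single_pose_single_cluster(self, rng):
        pose = DockedPose(coords=rng.normal(size=(5, 3)), energy=-9.0)
        table = rank_pose_clusters([pose])
        assert len(table) == 1 and table["size"].iloc[0] == 1

    def test_close_means_flagged_indistinguishable(self):
        # docking scores within 2.5 kcal/mol cannot discriminate modes
        result = gen_pose_set(
            3, 3, 0, energies=[-11.8, -11.8, -11.8, -10.8, -10.8, -10.8], seed=1
        )
        table = rank_pose_clusters(result.poses, cutoff=2.0)
        assert table["indistinguishable"].all()

    def test_distant_mean_not_flagged(self):
        result = gen_pose_set(
            3, 3, 0, energies=[-12.0, -12.0, -12.0, -5.0, -5.0, -5.0], seed=2
        )
        table = rank_pose_clusters(result.poses, cutoff=2.0)
        assert table["indistinguishable"].tolist() == [True, False]

    def test_missing_energies_warn_and_rank_by_size(self, rng):
        poses = [
            DockedPose(coords=rng.normal(size=(5, 3)) + 10 * k)
            for k in range(3)
        ]
        with pytest.warns(UserWarning):
            table = rank_pose_clusters(poses, cutoff=2.0)
        assert np.isnan(table["mean_energy"]).all()


class TestClassifyOrientation:
    HELIX_N = np.zeros(3)
    HELIX_C = np.array([9.0, 0.0, 0.0])

    def _pose(self, axis):
        coords = np.zeros((2, 3))
        coords[1] = axis
        return DockedPose(coords=coords)

    def test_aligned_axis_is_parallel(self):
        call = classify_orientation(
            self._pose([5.0, 0, 0]), 0, 1, self.HELIX_N, self.HELIX_C
        )
        assert call.call == PARALLEL and call.cos_angle == pytest.approx(1.0)

    def test_reversed_axis_is_anti_parallel(self):
        call = classify_orientation(
            self._pose([-5.0, 0, 0]), 0, 1, self.HELIX_N, self.HELIX_C
        )
        assert call.call == ANTI_PARALLEL
        assert call.cos_angle == pytest.approx(-1.0)

    def test_orthogonal_axis_is_perpendicular(self):
        call = classify_orientation(
            self._pose([0, 0, 5.0]), 0, 1, self.HELIX_N, self.HELIX_C
        )
        assert call.call == PERPENDICULAR
        assert call.cos_angle == pytest.approx(0.0)

    def test_identical_anchors_raise(self):
        with pytest.raises(GeometryError):
            classify_orientation(
                self._pose([1.0, 0, 0]), 0, 0, self.HELIX_N, self.HELIX_C
            )

    def test_planted_pose_counts_recovered(self):
        result = gen_pose_set(5, 4, 3, seed=7)
        calls = [
            classify_orientation(
                p, result.n_anchor, result.c_anchor,
                result.helix_n, result.helix_c,
            ).call
            for p in result.poses
        ]
        assert calls == result.true_calls
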