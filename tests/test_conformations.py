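import numpy as np
import pytest
from sklearn.metrics import (adjusted_rand_score, calinski_harabasz_score,
                             davies_bouldin_score)

from mdpost.conformations import (davies_bouldin, kmeans_cluster, pseudo_f,
                                  representative_frame, select_k, ssr_sst,
                                  sums_of_squares, trajectory_features)
from mdpost import synthetic


def three_blobs(rng, n_per=100, d=2, sep=20.0, sigma=1.0):
    centers = sep * np.eye(3)[:, :d] if d >= 3 else sep * np.array([[0, 0], [1, 0], [0, 1.0]])[:, :d]
    X = np.vstack([c + sigma * rng.normal(size=(n_per, d)) for c in centers])
    labels = np.repeat([0, 1, 2], n_per)
    return X, labels


ONE_D = np.array([[0.0], [1.0], [10.0], [11.0]])
ONE_D_LABELS = np.array([0, 0, 1, 1])


class TestKMeans:
    def test_k1_single_cluster_mean_centroid(self, rng):
        X = rng.normal(size=(40, 3))
        m = kmeans_cluster(X, k=1, sieve=2, seed=0)
        assert set(m.labels) == {0}
        np.testing.assert_allclose(m.centroids[0], X[::2].mean(axis=0), atol=1e-9)

    def test_separated_blobs_fully_recovered(self, rng):
        X, truth = three_blobs(rng, sep=20.0, sigma=1.0)
        m = kmeans_cluster(X, k=3, sieve=1, seed=1)
        assert adjusted_rand_score(truth, m.labels) == 1.0

    def test_two_duplicated_points_exact_centroids(self):
        X = np.array([[0.0, 0], [0, 0], [5, 5], [5, 5]])
        m = kmeans_cluster(X, k=2, sieve=1, seed=0)
        got = sorted(map(tuple, m.centroids))
        assert got == [(0.0, 0.0), (5.0, 5.0)]

    def test_k_exceeding_distinct_points_rejected(self):
        X = np.array([[0.0], [0.0], [0.0]])
        with pytest.raises(ValueError):
            kmeans_cluster(X, k=2, sieve=1)

    def test_sieved_equals_full_when_states_covered(self, rng):
        X, _ = three_blobs(rng, n_per=100, sep=30.0)
        order = rng.permutation(len(X))  # interleave states so every 10th frame covers all
        X = X[order]
        full = kmeans_cluster(X, k=3, sieve=1, seed=3)
        sieved = kmeans_cluster(X, k=3, sieve=10, seed=3)
        assert adjusted_rand_score(full.labels, sieved.labels) == 1.0


class TestValidityIndices:
    def test_dbi_matches_brute_force_on_1d_fixture(self):
        # hand computation: s = mean|{0,1} - 0.5| = 0.5 each, d = 10
        # DBI = (0.5 + 0.5) / 10 = 0.1
        assert davies_bouldin(ONE_D, ONE_D_LABELS) == pytest.approx(0.1)

    def test_dbi_matches_sklearn(self, rng):
        X, labels = three_blobs(rng, sep=8.0, sigma=1.5)
        ours = davies_bouldin(X, labels)
        assert ours == pytest.approx(davies_bouldin_score(X, labels), rel=1e-9)

    def test_dbi_limits(self, rng):
        X, labels = three_blobs(rng, sep=1e6, sigma=1.0)
        assert davies_bouldin(X, labels) < 1e-4
        identical = np.zeros((4, 2))
        assert davies_bouldin(identical, np.array([0, 0, 1, 1])) == np.inf
        with pytest.raises(ValueError):
            davies_bouldin(X, np.zeros(len(X), dtype=int))

    def test_psf_matches_hand_value_on_1d_fixture(self):
        # SSR = 4 * 5.5^2 ... brute force: grand mean 5.5; cluster means 0.5, 10.5
        # SSR = 2*(5)^2 + 2*(5)^2 = 100; SSE = 4*0.25 = 1
        # pSF = (100/1) / (1/2) = 200
        assert pseudo_f(ONE_D, ONE_D_LABELS) == pytest.approx(200.0)

    def test_psf_matches_sklearn(self, rng):
        X, labels = three_blobs(rng, sep=8.0, sigma=1.5)
        assert pseudo_f(X, labels) == pytest.approx(
            calinski_harabasz_score(X, labels), rel=1e-9)

    def test_psf_degenerate_and_boundary(self):
        dup = np.array([[0.0], [0.0], [9.0], [9.0]])
        assert pseudo_f(dup, np.array([0, 0, 1, 1])) == np.inf
        # k = n - 1 boundary stays finite
        X = np.array([[0.0], [1.0], [10.0]])
        assert np.isfinite(pseudo_f(X, np.array([0, 0, 1])))
        with pytest.raises(ValueError):
            pseudo_f(X, np.array([0, 1, 2]))  # n == k

    def test_ssr_sst_limits_and_hand_value(self):
        assert ssr_sst(ONE_D, np.zeros(4, dtype=int)) == pytest.approx(0.0)
        assert ssr_sst(ONE_D, np.arange(4)) == pytest.approx(1.0)
        # hand: SST = SSR + SSE = 101; SSR/SST = 100/101
        assert ssr_sst(ONE_D, ONE_D_LABELS) == pytest.approx(100 / 101)
        with pytest.raises(ValueError):
            ssr_sst(np.zeros((4, 1)), ONE_D_LABELS)

    def test_conservation_ssr_plus_sse_equals_sst(self, rng):
        for _ in range(5):
            X = rng.normal(size=(60, 4))
            labels = rng.integers(0, 4, size=60)
            ssr, sse, sst = sums_of_squares(X, labels)
            assert ssr + sse == pytest.approx(sst, rel=1e-9)

    def test_indices_invariant_under_label_permutation(self, rng):
        X, labels = three_blobs(rng, sep=6.0)
        perm = np.array([2, 0, 1])[labels]
        assert davies_bouldin(X, labels) == pytest.approx(davies_bouldin(X, perm))
        assert pseudo_f(X, labels) == pytest.approx(pseudo_f(X, perm))
        assert ssr_sst(X, labels) == pytest.approx(ssr_sst(X, perm))


class TestRepresentativeFrame:
    def test_singleton_cluster_returns_that_frame(self):
        X = np.array([[0.0], [10.0], [10.5]])
        labels = np.array([0, 1, 1])
        reps = representative_frame(X, labels, np.array([[0.0], [10.25]]))
        assert reps[0] == 0

    def test_tie_broken_to_lowest_frame_index(self):
        X = np.array([[0.0], [1.0], [10.0]])
        labels = np.array([0, 0, 1])
        reps = representative_frame(X, labels, np.array([[0.5], [10.0]]))
        assert reps[0] == 0  # frames 0 and 1 equidistant from 0.5

    def test_unique_minimizer_found_exhaustively(self, rng):
        X = rng.normal(size=(30, 3))
        labels = rng.integers(0, 3, size=30)
        centroids = np.stack([X[labels == c].mean(axis=0) for c in range(3)])
        reps = representative_frame(X, labels, centroids)
        for c in range(3):
            members = np.flatnonzero(labels == c)
            dists = {m: np.linalg.norm(X[m] - centroids[c]) for m in members}
            assert dists[reps[c]] == min(dists.values())


class TestSelectK:
    def test_planted_three_states_selected(self):
        spec = synthetic.default_trajectory_spec(seed=11, n_residues=60, n_frames=600)
        traj = synthetic.make_trajectory(spec)
        features = trajectory_features(traj)
        k, table, models = select_k(features, range(2, 8), seed=11)
        assert k == 3
        assert not table["ambiguous"].any()
        assert adjusted_rand_score(spec.frame_states, models[3].labels) == 1.0

    def test_planted_two_states_selected(self, rng):
        base = synthetic.make_chain(50, seed=5)
        other = base.copy()
        other[10:20] += 8.0
        spec = synthetic.TrajectorySpec(
            states=[base, other], dwell_segments=[(0, 300), (1, 300)],
            sigma_per_residue=0.4, seed=5)
        traj = synthetic.make_trajectory(spec)
        k, _, _ = select_k(trajectory_features(traj), range(2, 8), seed=5)
        assert k == 2

    def test_single_blob_flagged_ambiguous(self, rng):
        X = rng.normal(size=(400, 20))
        _, table, _ = select_k(X, range(2, 8), seed=2)
        assert table["ambiguous"].all()

    def test_recovery_rate_over_seeds(self):
        # planted separation >= 10x within-state sigma: >= 95% of 20 seeds
        hits = 0
        for seed in range(20):
            spec = synthetic.default_trajectory_spec(
                seed=seed, n_residues=40, n_frames=400)
            traj = synthetic.make_trajectory(spec)
            k, _, _ = select_k(trajectory_features(traj), range(2, 7), seed=seed)
            hits += (k == 3)
        assert hits >= 19
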