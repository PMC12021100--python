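"""SNF stratification: kernel formula, fusion invariants, spectral oracle."""

import itertools

import numpy as np
import pytest
from sklearn.metrics import adjusted_rand_score

from stratomics.layers import LayerKind, OmicsLayer
from stratomics.snf import (AffinityMatrix, SNFParams, build_affinity,
                            estimate_num_clusters, nmi_concordance, snf_fuse,
                            spectral_cluster, validate_clusters, variance_filter)


def make_layer(values, kind=LayerKind.PROTEOMICS):
    n, p = values.shape
    return OmicsLayer(kind, [f"s{i}" for i in range(n)], [f"f{j}" for j in range(p)],
                      values)


def two_blob_layer(rng, n=60, p=40, sep=6.0):
    X = rng.standard_normal((n, p))
    X[n // 2:, : p // 2] += sep
    return make_layer(X)


class TestVarianceFilter:
    def test_constant_feature_removed_boundary_retained(self, rng):
        vals = rng.standard_normal((40, 3))
        vals[:, 0] = 5.0                                     # variance 0
        vals[:, 1] *= np.sqrt(0.2 / vals[:, 1].var())        # variance exactly 0.2
        layer = make_layer(vals)
        with pytest.warns(UserWarning):
            out = variance_filter(layer, 0.2)
        assert out.feature_ids == ["f1", "f2"]               # strict < removes only f0

    def test_counts_logged_on_fixture(self, rng):
        vals = rng.standard_normal((50, 10))
        vals[:, :3] *= 0.1                                   # variances ~0.01
        with pytest.warns(UserWarning, match="3 features"):
            out = variance_filter(make_layer(vals), 0.2)
        assert out.n_features == 7

    def test_all_removed_errors(self):
        layer = make_layer(np.ones((10, 2)))
        with pytest.raises(ValueError, match="every feature"):
            variance_filter(layer, 0.2)


class TestAffinity:
    def test_unit_diagonal(self, rng):
        aff = build_affinity(make_layer(rng.standard_normal((40, 8))), SNFParams(K=10))
        np.testing.assert_allclose(np.diag(aff.matrix), 1.0)

    def test_identical_samples_full_affinity(self, rng):
        vals = rng.standard_normal((40, 6))
        vals[1] = vals[0]
        aff = build_affinity(make_layer(vals), SNFParams(K=10))
        assert aff.matrix[0, 1] == pytest.approx(1.0)

    def test_matches_hand_evaluated_kernel(self, rng):
        # direct loop evaluation of the locally scaled kernel on 5 samples
        vals = rng.standard_normal((5, 3))
        K, alpha = 2, 0.7
        aff = build_affinity(make_layer(vals), SNFParams(K=K, alpha=alpha))
        Z = (vals - vals.mean(0)) / vals.std(0)
        n = 5
        d2 = np.array([[np.sum((Z[i] - Z[j]) ** 2) for j in range(n)] for i in range(n)])
        mu = np.array([np.sort(d2[i])[1:K + 1].mean() for i in range(n)])
        for i in range(n):
            for j in range(n):
                eps = (mu[i] + mu[j] + d2[i, j]) / 3
                w = np.exp(-d2[i, j] / (alpha * eps))
                assert aff.matrix[i, j] == pytest.approx(w, abs=1e-8)

    def test_too_few_samples_rejected(self, rng):
        with pytest.raises(ValueError, match="K\\+1"):
            build_affinity(make_layer(rng.standard_normal((10, 4))), SNFParams(K=30))


class TestFusion:
    def test_fused_matrix_invariants(self, rng):
        layers = [two_blob_layer(rng), make_layer(rng.standard_normal((60, 30)))]
        params = SNFParams(K=15)
        fused = snf_fuse([build_affinity(l, params) for l in layers], params)
        W = fused.matrix
        assert np.max(np.abs(W - W.T)) < 1e-10
        assert (W >= -1e-12).all()
        np.testing.assert_allclose(W.sum(axis=1), 1.0, atol=1e-8)

    def test_self_fusion_preserves_single_layer_clustering(self, rng):
        layer = two_blob_layer(rng)
        params = SNFParams(K=15)
        aff = build_affinity(layer, params)
        single = spectral_cluster(aff, 2, seed=0)
        fused = snf_fuse([aff, AffinityMatrix(aff.sample_ids, aff.matrix.copy(),
                                              "copy")], params)
        both = spectral_cluster(fused, 2, seed=0)
        assert adjusted_rand_score(single, both) == pytest.approx(1.0)

    def test_two_blob_recovery_with_noise_layer(self, rng):
        signal = two_blob_layer(rng)
        noise = make_layer(rng.standard_normal((60, 40)))
        params = SNFParams(K=15)
        fused = snf_fuse([build_affinity(signal, params),
                          build_affinity(noise, params)], params)
        labels = spectral_cluster(fused, 2, seed=0)
        truth = [0] * 30 + [1] * 30
        assert adjusted_rand_score(truth, labels) == pytest.approx(1.0)

    def test_sample_mismatch_rejected(self, rng):
        params = SNFParams(K=5)
        a = build_affinity(make_layer(rng.standard_normal((20, 5))), params)
        b = build_affinity(make_layer(rng.standard_normal((20, 5))), params)
        b.sample_ids[0] = "other"
        with pytest.raises(ValueError, match="mismatch"):
            snf_fuse([a, b], params)


def block_affinity(sizes, strong=1.0, weak=0.01):
    n = sum(sizes)
    W = np.full((n, n), weak)
    start = 0
    for s in sizes:
        W[start:start + s, start:start + s] = strong
        start += s
    np.fill_diagonal(W, 1.0)
    return AffinityMatrix([f"s{i}" for i in range(n)], W)


def ncut(W, labels):
    total = 0.0
    A = W.copy()
    np.fill_diagonal(A, 0.0)
    for c in np.unique(labels):
        mask = labels == c
        cut = A[mask][:, ~mask].sum()
        vol = A[mask].sum()
        total += cut / vol if vol else 0.0
    return total


class TestSpectral:
    def test_block_diagonal_exact_recovery(self):
        labels = spectral_cluster(block_affinity([5, 7]), 2, seed=0)
        truth = [0] * 5 + [1] * 7
        assert adjusted_rand_score(truth, labels) == 1.0

    def test_c_equals_n_degenerate(self, rng):
        aff = build_affinity(make_layer(rng.standard_normal((8, 4))), SNFParams(K=3))
        labels = spectral_cluster(aff, 8, seed=0)
        assert sorted(labels) == list(range(1, 9))

    def test_matches_min_ncut_on_small_graphs(self, rng):
        # exhaustive bipartition oracle on 8-sample structured graphs
        for trial in range(5):
            W = np.full((8, 8), 0.05) + 0.05 * rng.random((8, 8))
            W = (W + W.T) / 2
            W[:4, :4] += 1.0
            W[4:, 4:] += 1.0
            np.fill_diagonal(W, 1.0)
            aff = AffinityMatrix([f"s{i}" for i in range(8)], W)
            labels = spectral_cluster(aff, 2, seed=trial)
            best = min(
                (ncut(W, np.array([0] + list(bits))) for bits in
                 itertools.product([0, 1], repeat=7)
                 if len(set([0] + list(bits))) == 2),
            )
            assert ncut(W, labels) == pytest.approx(best, rel=1e-9)

    def test_disconnected_graph_labelled_by_component(self):
        aff = block_affinity([3, 3, 3], weak=0.0)
        with pytest.warns(UserWarning, match="component"):
            labels = spectral_cluster(aff, 2, seed=0)
        assert len(set(labels)) == 3


class TestModelSelection:
    def test_three_perfect_blocks_eigengap(self):
        aff = block_affinity([10, 10, 10], weak=1e-6)
        out = estimate_num_clusters(aff, range(2, 7))
        assert out["best_by_eigengap"] == 3
        assert len(out["eigengap"]) == 5 and len(out["rotation_cost"]) == 5

    def test_candidate_range_validated(self):
        aff = block_affinity([4, 4])
        with pytest.raises(ValueError, match="candidate range"):
            estimate_num_clusters(aff, range(2, 20))


class TestNMI:
    def test_identical_layer_gives_one(self, rng):
        layer = two_blob_layer(rng)
        aff = build_affinity(layer, SNFParams(K=15))
        out = nmi_concordance(aff, [aff], 2, seed=0)
        assert out["proteomics"] == pytest.approx(1.0)


class TestValidateClusters:
    def test_perfect_separation_accuracy_one(self, rng):
        layer = two_blob_layer(rng, sep=8.0)
        labels = np.array([0] * 30 + [1] * 30)
        from stratomics.layers import SampleTable
        samples = SampleTable(layer.sample_ids)
        rep = validate_clusters([layer], samples, labels, n_splits=5, seed=0)
        assert rep.mean_accuracy == pytest.approx(1.0)
        assert rep.auroc == pytest.approx(1.0)

    def test_confusion_rows_sum_to_test_counts(self, rng):
        layer = two_blob_layer(rng, sep=2.0)
        labels = np.array([0] * 30 + [1] * 30)
        from stratomics.layers import SampleTable
        rep = validate_clusters([layer], SampleTable(layer.sample_ids), labels,
                                n_splits=8, seed=1)
        # mean confusion total equals the mean test-set size; accuracy consistent
        assert 0 < rep.mean_confusion.sum() < 60
        assert rep.mean_accuracy == pytest.approx(np.mean(rep.per_split_accuracy))

    def test_permuted_labels_accuracy_near_prior(self, rng):
        layer = two_blob_layer(rng, sep=6.0)
        labels = rng.permutation([0] * 30 + [1] * 30)
        from stratomics.layers import SampleTable
        rep = validate_clusters([layer], SampleTable(layer.sample_ids), labels,
                                n_splits=10, seed=2)
        assert abs(rep.mean_accuracy - 0.5) < 0.15

    def test_small_cluster_rejected(self, rng):
        layer = two_blob_layer(rng)
        labels = np.array([0] * 58 + [1] * 2)
        from stratomics.layers import SampleTable
        with pytest.raises(ValueError, match=">= 5"):
            validate_clusters([layer], SampleTable(layer.sample_ids), labels)
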