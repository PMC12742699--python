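import numpy as np
import pandas as pd
import pytest

from ncmorph import (PartitionConfig, concordance, estimate_k, nest_centroids,
                     partition, run_partitioning, ward_tree)


def blobs(rng, centers, n_per, sd=1.0):
    pts = np.vstack([rng.normal(c, sd, size=(n_per, len(c))) for c in centers])
    ids = [f"n{i}" for i in range(len(pts))]
    truth = np.repeat(np.arange(len(centers)), n_per)
    return pd.DataFrame(pts, index=ids), pd.Series(truth, index=ids)


def accuracy(labels, truth):
    """Best label-matching agreement for two clusters (brute force)."""
    same = (labels.values == truth.values).mean()
    return max(same, 1 - same)


class TestWardTree:
    def test_two_tight_pairs_split_first(self):
        X = pd.DataFrame([[0, 0], [0.1, 0], [10, 10], [10.1, 10]],
                         index=list("abcd"))
        tree = ward_tree(X)
        cut = tree.cut(2)
        assert cut["a"] == cut["b"] and cut["c"] == cut["d"]
        assert cut["a"] != cut["c"]

    def test_heights_nondecreasing(self, rng):
        X, _ = blobs(rng, [(0, 0), (6, 6)], 10)
        heights = ward_tree(X).heights
        assert np.all(np.diff(heights) >= 0)

    def test_permutation_invariance(self, rng):
        X, _ = blobs(rng, [(0, 0, 0), (5, 5, 5)], 8)
        perm = X.sample(frac=1.0, random_state=3)
        t1, t2 = ward_tree(X), ward_tree(perm)
        np.testing.assert_allclose(np.sort(t1.heights), np.sort(t2.heights))
        c1, c2 = t1.cut(2), t2.cut(2)
        agree = (c1 == c2.reindex(c1.index)).mean()
        assert agree in (0.0, 1.0)  # identical up to label swap

    def test_duplicate_ids_rejected(self):
        X = pd.DataFrame([[0.0, 0], [1, 1], [2, 2]], index=["a", "a", "b"])
        with pytest.raises(ValueError, match="duplicate"):
            ward_tree(X)

    def test_newick_roundtrip(self, rng):
        dendropy = pytest.importorskip("dendropy")
        X, _ = blobs(rng, [(0, 0), (8, 8)], 6)
        tree = ward_tree(X)
        parsed = dendropy.Tree.get(data=tree.to_newick(), schema="newick")
        leaves = {leaf.taxon.label for leaf in parsed.leaf_node_iter()}
        assert leaves == set(X.index)
        # root-to-leaf depth equals the top merge height for every leaf
        depths = [leaf.distance_from_root() for leaf in parsed.leaf_node_iter()]
        assert np.allclose(depths, tree.heights[-1], rtol=1e-6)


class TestEstimateK:
    def test_two_separated_blobs(self, rng):
        X, _ = blobs(rng, [(0,) * 4, (10,) * 4], 12)
        for method in ("hclust", "kmeans"):
            assert estimate_k(X, method).k == 2

    def test_single_blob_collapses_to_one(self, rng):
        X, _ = blobs(rng, [(0, 0, 0)], 30)
        for method in ("hclust", "kmeans"):
            est = estimate_k(X, method)
            assert est.k == 1
            assert est.profile["score"].max() < 0.50

    def test_three_blobs_ari_one(self, rng):
        from sklearn.metrics import adjusted_rand_score
        X, truth = blobs(rng, [(0, 0), (10, 0), (0, 10)], 10)
        for method in ("hclust", "kmeans"):
            est = estimate_k(X, method)
            assert est.k == 3
            labels = partition(X, method, 3)
            assert adjusted_rand_score(truth, labels) == 1.0

    def test_gap_criterion_agrees_on_clear_structure(self, rng):
        X, _ = blobs(rng, [(0,) * 3, (12,) * 3], 10)
        config = PartitionConfig(criterion="gap", gap_n_reference=20)
        assert estimate_k(X, "kmeans", config).k == 2

    def test_silhouette_matches_bruteforce_oracle(self, rng):
        from sklearn.metrics import silhouette_score
        X, truth = blobs(rng, [(0, 0), (4, 4)], 9)
        pts = X.values
        labels = truth.values

        def brute_silhouette():
            n = len(pts)
            dist = np.sqrt(((pts[:, None] - pts[None]) ** 2).sum(-1))
            s = []
            for i in range(n):
                own = labels[i]
                a = dist[i][(labels == own) & (np.arange(n) != i)].mean()
                b = min(dist[i][labels == other].mean()
                        for other in set(labels) if other != own)
                s.append((b - a) / max(a, b))
            return np.mean(s)

        assert silhouette_score(pts, labels) == pytest.approx(brute_silhouette())


class TestPartition:
    def test_k_edges(self, rng):
        X, _ = blobs(rng, [(0, 0)], 6)
        assert partition(X, "hclust", 1).nunique() == 1
        assert partition(X, "kmeans", len(X)).nunique() == len(X)
        with pytest.raises(ValueError):
            partition(X, "kmeans", len(X) + 1)

    def test_two_blob_labels_match_truth(self, rng):
        X, truth = blobs(rng, [(0, 0), (9, 9)], 10)
        for method in ("hclust", "kmeans"):
            assert accuracy(partition(X, method, 2), truth) == 1.0

    def test_kmeans_reproducible(self, rng):
        X, _ = blobs(rng, [(0, 0), (5, 5)], 10)
        config = PartitionConfig(seed=42)
        a = partition(X, "kmeans", 2, config)
        b = partition(X, "kmeans", 2, config)
        pd.testing.assert_series_equal(a, b)


class TestConcordance:
    def test_identical_partitions(self):
        a = pd.Series([0, 0, 1, 1], index=list("abcd"))
        _, wild = concordance(a, a.copy())
        assert wild == []

    def test_single_disagreement_flagged(self):
        a = pd.Series([0, 0, 1, 1], index=list("abcd"))
        b = pd.Series([0, 1, 1, 1], index=list("abcd"))
        _, wild = concordance(a, b)
        assert wild == ["b"]

    def test_label_permutation_invariance(self):
        a = pd.Series([0, 0, 1, 1, 2], index=list("abcde"))
        b = pd.Series([2, 2, 0, 0, 1], index=list("abcde"))
        _, wild = concordance(a, b)
        assert wild == []

    def test_k1_vs_k2_minority_cluster_wildcarded(self):
        a = pd.Series([0, 0, 0, 0, 0], index=list("abcde"))
        b = pd.Series([0, 0, 0, 1, 1], index=list("abcde"))
        _, wild = concordance(a, b)
        assert set(wild) == {"d", "e"}


class TestPipelineRegimes:
    def test_default_synthetic_recovers_two_species(self, default_synth):
        records, truth = default_synth
        centroids = nest_centroids(records)
        matrix = centroids[[c for c in centroids.columns
                            if c not in ("n_workers", "species", "color_morph",
                                         "latitude", "longitude")]]
        parts = run_partitioning(matrix)
        assert parts.k_hclust == 2 and parts.k_kmeans == 2
        assert len(parts.wildcards) / len(matrix) < 0.10
        truth_labels = pd.Series(truth["nest_species"]).reindex(matrix.index)
        truth_codes = pd.Series((truth_labels == "imitans").astype(int).values,
                                index=matrix.index)
        assert accuracy(parts.labels_hclust, truth_codes) > 0.9

    def test_marginal_offsets_collapse_kmeans_to_one_group(self):
        # the weak-signal regime: raw-character clustering no longer passes
        # the silhouette threshold and the k-means route declares one group
        from ncmorph import SynthConfig, generate_specimens
        records, _ = generate_specimens(SynthConfig(species_offset=0.02, seed=3))
        centroids = nest_centroids(records)
        matrix = centroids[[c for c in centroids.columns
                            if c not in ("n_workers", "species", "color_morph",
                                         "latitude", "longitude")]]
        assert estimate_k(matrix, "kmeans").k == 1
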