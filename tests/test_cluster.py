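"""Pooling, embedding, cluster-number estimation, SOM metaclustering, and
cluster-index association."""

import numpy as np
import pandas as pd
import pytest
from sklearn.datasets import make_blobs
from sklearn.metrics import adjusted_rand_score, silhouette_score
from sklearn.neighbors import NearestNeighbors

from cytomet.cluster import (Embedding, PooledMatrix, TSNEParams,
                             associate_index, embed_tsne, estimate_k,
                             permutation_gap_test, pool_and_downsample,
                             som_metacluster)
from cytomet.events import EventMatrix
from cytomet.panel import MarkerPanel, PanelEntry


def _panel(m=4):
    return MarkerPanel([PanelEntry(f"ch{i}", f"M{i}", "X", "phenotypic")
                        for i in range(m)])


def _samples(sizes, panel, seed=0):
    rng = np.random.default_rng(seed)
    return {
        f"P{i}": EventMatrix(rng.normal(0, 1, (n, len(panel))), panel, "arcsinh", f"P{i}")
        for i, n in enumerate(sizes)
    }


def _pooled_from(X, labels=None, pids=None):
    n = len(X)
    return PooledMatrix(
        np.asarray(X, float), [f"M{i}" for i in range(X.shape[1])],
        np.asarray(pids if pids is not None else ["P0"] * n, dtype=object),
        np.arange(n), n,
    )


class TestPoolAndDownsample:
    def test_small_samples_dropped_then_min_rules(self):
        panel = _panel()
        samples = _samples([5_000, 3_000, 800], panel)
        pooled = pool_and_downsample(samples, min_cells=1_000, seed=0)
        assert pooled.downsample_n == 3_000
        assert pooled.n_cells == 6_000
        assert set(pooled.patient_ids) == {"P0", "P1"}

    def test_equal_sizes_keep_everything(self):
        panel = _panel()
        samples = _samples([400, 400, 400], panel)
        pooled = pool_and_downsample(samples, min_cells=100, seed=0)
        assert pooled.n_cells == 1_200
        for pid in samples:
            assert (pooled.patient_ids == pid).sum() == 400

    def test_deterministic(self):
        panel = _panel()
        samples = _samples([900, 500], panel)
        a = pool_and_downsample(samples, 100, seed=7)
        b = pool_and_downsample(samples, 100, seed=7)
        np.testing.assert_array_equal(a.values, b.values)
        np.testing.assert_array_equal(a.source_rows, b.source_rows)

    def test_all_dropped_errors(self):
        panel = _panel()
        with pytest.raises(ValueError, match="below min_cells"):
            pool_and_downsample(_samples([50, 60], panel), 100, seed=0)

    def test_needs_two_samples(self):
        panel = _panel()
        with pytest.raises(ValueError, match="2 samples"):
            pool_and_downsample(_samples([500], panel), 100, seed=0)


@pytest.fixture(scope="module")
def blobs3():
    X, y = make_blobs(n_samples=500, n_features=4, centers=3,
                      cluster_std=1.0, center_box=(-12, 12), random_state=5)
    return X, y


@pytest.fixture(scope="module")
def embedded3(blobs3):
    X, y = blobs3
    return embed_tsne(_pooled_from(X), TSNEParams.desk_scale(0)), y


class TestEmbedTSNE:
    def test_deterministic(self, blobs3):
        X, _ = blobs3
        p = TSNEParams(iterations=260, perplexity=25, seed=3)
        e1 = embed_tsne(_pooled_from(X[:200]), p)
        e2 = embed_tsne(_pooled_from(X[:200]), p)
        np.testing.assert_array_equal(e1.coords, e2.coords)

    def test_separated_blobs_keep_silhouette(self, embedded3):
        emb, y = embedded3
        assert silhouette_score(emb.coords, y) > 0.5

    def test_neighborhoods_preserved(self, blobs3, embedded3):
        """>= 60% of each cell's 10 nearest neighbors survive the embedding."""
        X, _ = blobs3
        emb, _ = embedded3
        nn_hi = NearestNeighbors(n_neighbors=11).fit(X)
        nn_lo = NearestNeighbors(n_neighbors=11).fit(emb.coords)
        idx_hi = nn_hi.kneighbors(return_distance=False)
        idx_lo = nn_lo.kneighbors(return_distance=False)
        overlap = np.mean([
            len(set(a) & set(b)) / 10 for a, b in zip(idx_hi, idx_lo)])
        assert overlap >= 0.6

    def test_perplexity_autoshrink_warns(self):
        rng = np.random.default_rng(0)
        X = rng.normal(0, 1, (40, 5))
        with pytest.warns(UserWarning, match="perplexity"):
            embed_tsne(_pooled_from(X), TSNEParams(iterations=260, perplexity=200))

    def test_nonfinite_rejected(self):
        X = np.full((30, 4), np.nan)
        with pytest.raises(ValueError, match="non-finite"):
            embed_tsne(_pooled_from(np.nan_to_num(X) * np.nan))


class TestEstimateK:
    def test_three_blobs(self, embedded3):
        emb, _ = embedded3
        assert estimate_k(emb, (2, 8), seed=0) == 3

    def test_two_blobs(self):
        X, _ = make_blobs(n_samples=400, n_features=8, centers=2,
                          cluster_std=1.0, center_box=(-12, 12), random_state=2)
        emb = embed_tsne(_pooled_from(X), TSNEParams.desk_scale(0))
        assert estimate_k(emb, (2, 8), seed=0) == 2

    def test_forced_range(self, embedded3):
        emb, _ = embedded3
        assert estimate_k(emb, (5, 5), seed=0) == 5

    def test_degenerate_coords_rejected(self):
        emb = Embedding(np.zeros((50, 2)), TSNEParams())
        with pytest.raises(ValueError, match="degenerate"):
            estimate_k(emb, (2, 4))

    def test_bad_range(self, embedded3):
        emb, _ = embedded3
        with pytest.raises(ValueError, match="k_range"):
            estimate_k(emb, (1, 4))


@pytest.fixture(scope="module")
def gauss4():
    X, y = make_blobs(n_samples=1_200, n_features=8, centers=4,
                      cluster_std=1.0, center_box=(-15, 15), random_state=11)
    pids = np.array([f"P{i % 3}" for i in range(len(X))], dtype=object)
    return _pooled_from(X, pids=pids), y


class TestSOMMetacluster:
    def test_recovers_four_populations(self, gauss4):
        pooled, y = gauss4
        assign = som_metacluster(pooled, (10, 10), k=4, seed=0)
        assert adjusted_rand_score(y, assign.labels) >= 0.9

    def test_partition_and_determinism(self, gauss4):
        pooled, _ = gauss4
        a = som_metacluster(pooled, (8, 8), k=4, seed=5)
        b = som_metacluster(pooled, (8, 8), k=4, seed=5)
        assert set(a.labels) == set(range(1, 5))
        assert a.counts.sum() == pooled.n_cells
        np.testing.assert_array_equal(a.labels, b.labels)

    def test_nesting_under_linkage_cut(self, gauss4):
        """Metaclusters at larger k refine those at smaller k (same SOM/seed)."""
        pooled, _ = gauss4
        a6 = som_metacluster(pooled, (8, 8), k=6, seed=2)
        a3 = som_metacluster(pooled, (8, 8), k=3, seed=2)
        mapping = pd.crosstab(a6.labels, a3.labels)
        assert ((mapping > 0).sum(axis=1) == 1).all()

    def test_k_exceeding_occupied_codes(self):
        # only 4 distinct points -> at most 4 occupied codes on a 3x3 grid
        X = np.repeat(np.eye(4) * 10, 50, axis=0)
        pooled = _pooled_from(X)
        with pytest.raises(ValueError, match="occupied"):
            som_metacluster(pooled, (3, 3), k=5, seed=0)

    def test_invalid_grid_or_k(self, gauss4):
        pooled, _ = gauss4
        with pytest.raises(ValueError, match="fewer codes"):
            som_metacluster(pooled, (1, 3), k=4, seed=0)
        with pytest.raises(ValueError, match=">= 2"):
            som_metacluster(pooled, (5, 5), k=1, seed=0)


def _clinical(rows):
    return pd.DataFrame(rows, columns=["patient_id", "ki67_pct",
                                       "n_pos_nodes", "n_excised_nodes"])


class TestAssociateIndex:
    def test_single_patient_cluster_inherits_patient_index(self, gauss4):
        pooled, _ = gauss4
        assign = som_metacluster(pooled, (6, 6), k=2, seed=0)
        # make every cell belong to one patient
        assign.patient_ids = np.repeat("A", pooled.n_cells)
        clinical = _clinical([("A", 60, 1, 5), ("B", 30, 2, 4)])
        assign = associate_index(assign, clinical)
        # patient A: norm_ki67 = 1, lnr = 0.2 -> every cluster index = 1.2
        assert np.allclose(assign.index.to_numpy(), 1.2)

    def test_two_patient_hand_mean(self, gauss4):
        pooled, _ = gauss4
        assign = som_metacluster(pooled, (6, 6), k=2, seed=0)
        half = pooled.n_cells // 2
        assign.patient_ids = np.array(
            ["A"] * half + ["B"] * (pooled.n_cells - half), dtype=object)
        # norm_ki67: A=0.6, B=1.0 ... choose ki67 so normalized values are 0.6/1.0
        clinical = _clinical([("A", 48, 1, 5), ("B", 80, 2, 5)])
        assign = associate_index(assign, clinical)
        assert ((assign.index >= 0) & (assign.index <= 2)).all()
        # cluster mixing both patients: index between the two patient indices
        pa, pb = 0.6 + 0.2, 1.0 + 0.4
        assert ((assign.index >= min(pa, pb) - 1e-9)
                & (assign.index <= max(pa, pb) + 1e-9)).all()

    def test_missing_patient_named(self, gauss4):
        pooled, _ = gauss4
        assign = som_metacluster(pooled, (6, 6), k=2, seed=0)
        clinical = _clinical([("P0", 50, 1, 5), ("P1", 30, 0, 5)])  # P2 missing
        with pytest.raises(ValueError, match="P2"):
            associate_index(assign, clinical)

    def test_planted_association_detected_by_permutation(
            self, small_cohort, gated_cancer):
        cancer, _ = gated_cancer
        pooled = pool_and_downsample(cancer, 30, seed=1)
        assign = som_metacluster(pooled, (8, 8), k=3, seed=1)
        assign = associate_index(assign, small_cohort.clinical)
        res = permutation_gap_test(assign, small_cohort.clinical,
                                   n_perm=200, seed=1)
        assert res["observed_gap"] > np.percentile(res["null_gaps"], 95)
        assert res["p_value"] < 0.05
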