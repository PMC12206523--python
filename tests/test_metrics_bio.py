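"""Bio-conservation metrics: analytic toys, oracles, invariances."""

import numpy as np
import pytest
from scipy.spatial.distance import cdist, pdist
from scipy.stats import spearmanr

import scintbench as sb
from scintbench.metrics_batch import lisi_per_cell
from scintbench.neighbors import NeighborGraph

from test_metrics_batch import TestBatchAsw, star_graph

brute_silhouette = TestBatchAsw.brute_silhouette


class TestClisi:
    def test_pure_neighborhoods_scale_to_one(self, rng):
        X = np.vstack([rng.standard_normal((30, 2)),
                       rng.standard_normal((30, 2)) + 50])
        ct = np.repeat(["t1", "t2"], 30)
        r = sb.clisi(X, ct, perplexity=5.0)
        assert r.value == pytest.approx(1.0, abs=0.01)

    def test_uniform_mixing_scales_to_zero(self):
        g = star_graph(["a", "a", "b", "b"])
        labels = np.array(["a", "a", "a", "b", "b"])
        per_cell = lisi_per_cell(g, labels, perplexity=2.0)
        # raw 2 with C=2 -> scaled (2-2)/(2-1) = 0 for that cell
        assert per_cell[0] == pytest.approx(2.0, abs=1e-9)

    def test_three_to_one_weights(self):
        g = star_graph(["a", "a", "a", "b"])
        labels = np.array(["x", "a", "a", "a", "b"])
        per_cell = lisi_per_cell(g, labels, perplexity=2.0)
        raw = per_cell[0]
        C = 2
        assert raw == pytest.approx(1.6, abs=1e-9)
        assert (C - raw) / (C - 1) == pytest.approx(0.4, abs=1e-9)


def nmi_oracle(a, b):
    """Direct p*log(p) summation over the contingency table."""
    a_vals, a_inv = np.unique(a, return_inverse=True)
    b_vals, b_inv = np.unique(b, return_inverse=True)
    n = len(a)
    joint = np.zeros((len(a_vals), len(b_vals)))
    for i, j in zip(a_inv, b_inv):
        joint[i, j] += 1
    joint /= n
    pa, pb = joint.sum(1), joint.sum(0)
    mi = sum(
        joint[i, j] * np.log(joint[i, j] / (pa[i] * pb[j]))
        for i in range(len(a_vals)) for j in range(len(b_vals))
        if joint[i, j] > 0
    )
    ha = -sum(p * np.log(p) for p in pa if p > 0)
    hb = -sum(p * np.log(p) for p in pb if p > 0)
    if ha == 0 and hb == 0:
        return 1.0
    return mi / ((ha + hb) / 2)


def ari_oracle(a, b):
    """Pair-counting definition over all cell pairs."""
    n = len(a)
    same_a = np.equal.outer(a, a)
    same_b = np.equal.outer(b, b)
    iu = np.triu_indices(n, 1)
    s11 = int((same_a[iu] & same_b[iu]).sum())
    s00 = int((~same_a[iu] & ~same_b[iu]).sum())
    s10 = int((same_a[iu] & ~same_b[iu]).sum())
    s01 = int((~same_a[iu] & same_b[iu]).sum())
    total = s11 + s00 + s10 + s01
    index = s11
    expected = (s11 + s10) * (s11 + s01) / total
    maximum = 0.5 * ((s11 + s10) + (s11 + s01))
    if maximum == expected:
        return 0.0
    return (index - expected) / (maximum - expected)


class TestNmiAri:
    def test_identical_partitions(self, rng):
        a = rng.integers(0, 4, 50)
        assert sb.nmi(a, a).value == pytest.approx(1.0, abs=1e-12)
        assert sb.ari(a, a).raw == pytest.approx(1.0, abs=1e-12)

    def test_independent_partitions(self):
        a = np.array(["a", "a", "b", "b"])
        b = np.array(["x", "y", "x", "y"])
        assert sb.nmi(a, b).value == pytest.approx(0.0, abs=1e-12)
        assert sb.ari(a, b).raw == pytest.approx(-0.5, abs=1e-12)

    def test_ari_brute_force_on_toy(self):
        # enumerate the 6 cell pairs by hand via the oracle
        a = np.array([0, 0, 1, 1])
        b = np.array([0, 1, 0, 1])
        assert ari_oracle(a, b) == pytest.approx(-0.5, abs=1e-12)

    def test_one_cluster_vs_anything_is_zero(self, rng):
        a = np.zeros(30, int)
        b = rng.integers(0, 3, 30)
        assert sb.ari(a, b).raw == pytest.approx(0.0, abs=1e-12)

    def test_single_cluster_both_sides_nmi_one(self):
        assert sb.nmi(np.zeros(5, int), np.zeros(5, int)).value == 1.0

    @pytest.mark.parametrize("seed", range(5))
    def test_matches_direct_formula_oracles(self, seed):
        rng = np.random.default_rng(seed)
        a = rng.integers(0, 5, 100)
        b = rng.integers(0, 4, 100)
        assert sb.nmi(a, b).value == pytest.approx(nmi_oracle(a, b), abs=1e-12)
        assert sb.ari(a, b).raw == pytest.approx(ari_oracle(a, b), abs=1e-12)

    def test_symmetry_and_rename_invariance(self, rng):
        a = rng.integers(0, 3, 60)
        b = rng.integers(0, 3, 60)
        assert sb.nmi(a, b).value == pytest.approx(sb.nmi(b, a).value, abs=1e-12)
        assert sb.ari(a, b).raw == pytest.approx(sb.ari(b, a).raw, abs=1e-12)
        a2 = np.array([chr(65 + x) for x in a])
        assert sb.nmi(a2, b).value == pytest.approx(sb.nmi(a, b).value, abs=1e-12)

    def test_length_mismatch_rejected(self):
        with pytest.raises(ValueError):
            sb.nmi(np.zeros(3), np.zeros(4))


class TestClusterForLabels:
    @staticmethod
    def _three_cliques():
        X = np.vstack([np.random.default_rng(s).standard_normal((12, 2)) * 0.2
                       + [10 * s, 0] for s in range(3)])
        g = sb.connectivities_from_distances(sb.knn_graph(X, 5))
        ct = np.repeat(["t0", "t1", "t2"], 12)
        return g, ct

    def test_well_separated_cliques_recovered(self):
        g, ct = self._three_cliques()
        part = sb.cluster_for_labels(g, ct, resolutions=[0.1, 0.5, 1.0], seed=0)
        assert sb.nmi(part, ct).value == pytest.approx(1.0, abs=1e-9)

    def test_single_resolution_returns_its_partition(self):
        g, ct = self._three_cliques()
        part = sb.cluster_for_labels(g, ct, resolutions=[1.0], seed=0)
        assert len(part) == g.n_cells

    def test_deterministic_given_seed(self):
        g, ct = self._three_cliques()
        a = sb.cluster_for_labels(g, ct, seed=5)
        b = sb.cluster_for_labels(g, ct, seed=5)
        np.testing.assert_array_equal(a, b)

    def test_empty_resolutions_rejected(self):
        g, ct = self._three_cliques()
        with pytest.raises(ValueError):
            sb.cluster_for_labels(g, ct, resolutions=[])


class TestCelltypeAsw:
    def test_one_dimensional_hand_example(self):
        X = np.array([[0.0], [1.0], [10.0], [11.0]])
        ct = np.array(["a", "a", "b", "b"])
        s = brute_silhouette(X, ct)
        # s(0) = (10.5 - 1)/10.5
        assert s[0] == pytest.approx((10.5 - 1) / 10.5, abs=1e-12)
        r = sb.celltype_asw(X, ct)
        assert r.raw == pytest.approx(s.mean(), abs=1e-10)
        assert r.value == pytest.approx((s.mean() + 1) / 2, abs=1e-10)

    def test_coincident_clusters_near_half(self, rng):
        X = rng.standard_normal((60, 2))
        ct = rng.choice(["a", "b"], 60)
        r = sb.celltype_asw(X, ct)
        assert r.value == pytest.approx(0.5, abs=0.1)

    def test_matches_brute_force_oracle(self, rng):
        X = rng.standard_normal((30, 3))
        ct = rng.choice(["a", "b", "c"], 30)
        r = sb.celltype_asw(X, ct)
        assert r.raw == pytest.approx(brute_silhouette(X, ct).mean(), abs=1e-10)


class TestGraphConnectivity:
    def test_fully_connected_labels_score_one(self, rng):
        X = rng.standard_normal((30, 2))
        g = sb.knn_graph(X, 29)  # complete graph
        ct = rng.choice(["a", "b"], 30)
        assert sb.graph_connectivity(g, ct).raw == 1.0

    def test_split_label_three_plus_one(self):
        # label a: cells 0,1,2 form a path, cell 3 isolated; label b: 4,5
        src = [0, 1, 4]
        dst = [1, 2, 5]
        g = NeighborGraph(6, 1, src=src, dst=dst, dist=np.ones(3))
        ct = np.array(["a", "a", "a", "a", "b", "b"])
        r = sb.graph_connectivity(g, ct)
        assert r.detail[0] == pytest.approx(0.75, abs=1e-12)
        assert r.raw == pytest.approx((0.75 + 1.0) / 2, abs=1e-12)

    def test_singleton_label_contributes_one(self):
        g = NeighborGraph(3, 1, src=[0], dst=[1], dist=[1.0])
        ct = np.array(["a", "a", "solo"])
        r = sb.graph_connectivity(g, ct)
        assert r.raw == pytest.approx(1.0, abs=1e-12)


class TestScGraph:
    @staticmethod
    def _dataset(rng, n_types=4, n_per=15):
        centers = rng.standard_normal((n_types, 3)) * 6
        ct = np.repeat([f"t{i}" for i in range(n_types)], n_per)
        X = centers[np.repeat(np.arange(n_types), n_per)] + \
            rng.standard_normal((n_types * n_per, 3)) * 0.3
        batch = np.tile(["A", "B"], n_types * n_per // 2)
        return X, ct, batch

    def test_rigid_transform_preserves_distances(self, rng):
        X, ct, batch = self._dataset(rng)
        Q, _ = np.linalg.qr(rng.standard_normal((3, 3)))
        r = sb.scgraph(X, X @ Q + 5.0, ct, batch)
        assert r.value == pytest.approx(1.0, abs=1e-9)

    def test_similarity_invariance(self, rng):
        X, ct, batch = self._dataset(rng)
        Y = rng.standard_normal(X.shape)
        a = sb.scgraph(X, Y, ct, batch)
        b = sb.scgraph(X * 3.0 + 1.0, Y, ct, batch)
        assert a.raw == pytest.approx(b.raw, abs=1e-10)

    def test_reversed_ranks_score_zero(self):
        # centroids on a line at 0,1,3 in reference; reversing pairwise
        # distance ranks maps scaled score to 0
        ct = np.repeat(["a", "b", "c"], 2)
        batch = np.array(["A"] * 6)
        ref = np.repeat([[0.0], [1.0], [3.0]], 2, axis=0)
        # ref distances (ab, ac, bc) = (1, 3, 2); integrated centroids
        # (0, 3, 1) give (3, 1, 2): exactly reversed ranks -> rho = -1
        intg = np.repeat([[0.0], [3.0], [1.0]], 2, axis=0)
        d_ref = pdist(np.array([[0.0], [1.0], [3.0]]))
        d_int = pdist(np.array([[0.0], [3.0], [1.0]]))
        assert spearmanr(d_ref, d_int).statistic == pytest.approx(-1.0)
        r = sb.scgraph(ref, intg, ct, batch)
        assert r.value == pytest.approx(0.0, abs=1e-12)

    def test_four_type_toy_matches_rank_oracle(self, rng):
        X, ct, batch = self._dataset(rng)
        Y = rng.standard_normal(X.shape)
        r = sb.scgraph(X, Y, ct, batch)
        rhos = []
        for b in ["A", "B"]:
            m = batch == b
            types = np.unique(ct[m])
            cr = np.stack([X[m & (ct == t)].mean(0) for t in types])
            ci = np.stack([Y[m & (ct == t)].mean(0) for t in types])
            rhos.append(spearmanr(pdist(cr), pdist(ci)).statistic)
        assert r.raw == pytest.approx(np.mean(rhos), abs=1e-12)

    def test_too_few_types_is_missing(self, rng):
        X = rng.standard_normal((20, 2))
        ct = np.repeat(["a", "b"], 10)
        batch = np.array(["A"] * 20)
        assert np.isnan(sb.scgraph(X, X, ct, batch).value)


class TestGeneSetScoring:
    @staticmethod
    def _ds(rng, n=80, g=120):
        X = rng.uniform(0, 1, (n, g))
        return sb.CellDataset(
            layers={"data": X},
            batch=np.array(["A"] * n),
            gene_names=[f"g{j}" for j in range(g)],
        )

    def test_uniform_data_scores_near_zero(self, rng):
        ds = self._ds(rng)
        s = sb.score_gene_set(ds, "data", [f"g{j}" for j in range(10)], seed=1)
        assert np.abs(s.mean()) < 0.1

    def test_shifted_cells_score_higher(self, rng):
        ds = self._ds(rng)
        X = ds.layers["data"]
        X[:40, :10] += 5.0  # first half of cells express the set
        s = sb.score_gene_set(ds, "data", [f"g{j}" for j in range(10)], seed=1)
        assert s[:40].mean() > s[40:].mean() + 3.0

    def test_deterministic_given_seed(self, rng):
        ds = self._ds(rng)
        genes = [f"g{j}" for j in range(8)]
        np.testing.assert_array_equal(
            sb.score_gene_set(ds, "data", genes, seed=9),
            sb.score_gene_set(ds, "data", genes, seed=9),
        )


class TestCellCycleConservation:
    def test_identical_spaces_score_one(self, rng):
        truth = sb.SyntheticTruth(
            n_batches=2, n_types=3, cells=np.full((2, 3), 30),
            n_genes=120, cc_program=True, cc_strength=2.0, seed=3,
        )
        ds = sb.simulate_counts(truth)
        s_idx, g_idx = truth.cc_gene_sets()
        X = ds.embeddings["latent_true"]
        r = sb.cell_cycle_conservation(ds, X, X, s_idx.tolist(), g_idx.tolist(),
                                       n_pcs=8)
        assert r.value == pytest.approx(1.0, abs=1e-9)

    def test_destroyed_signal_scores_zero(self, rng):
        truth = sb.SyntheticTruth(
            n_batches=2, n_types=3, cells=np.full((2, 3), 30),
            n_genes=120, cc_program=True, cc_strength=2.0, seed=4,
        )
        ds = sb.simulate_counts(truth)
        s_idx, g_idx = truth.cc_gene_sets()
        X = ds.embeddings["latent_true"]
        # after-space: pure noise, unrelated to the cc covariates... but
        # R^2 is never exactly 0; expect a large drop instead
        X_after = np.random.default_rng(0).standard_normal(X.shape)
        r = sb.cell_cycle_conservation(ds, X, X_after, s_idx.tolist(),
                                       g_idx.tolist(), n_pcs=8)
        assert r.value < 1.0
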