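"""Batch-mixing metrics: analytic toys, oracles, null behavior."""

import numpy as np
import pytest
from scipy.spatial.distance import cdist
from scipy.stats import norm

import scintbench as sb
from scintbench.metrics_batch import (
    density_overlap_1d,
    kbet_cell_statistic,
    lisi_per_cell,
)
from scintbench.neighbors import NeighborGraph


def star_graph(labels_of_neighbors):
    """Cell 0 with equidistant neighbors 1..m (degenerate -> uniform
    weights); remaining cells get an arbitrary back-edge."""
    m = len(labels_of_neighbors)
    src = [0] * m + list(range(1, m + 1))
    dst = list(range(1, m + 1)) + [0] * m
    return NeighborGraph(m + 1, m, src=src, dst=dst, dist=np.ones(2 * m))


class TestLisi:
    def test_uniform_two_label_neighborhood_is_two(self):
        g = star_graph(["a", "a", "b", "b"])
        labels = np.array(["x", "a", "a", "b", "b"])
        per_cell = lisi_per_cell(g, labels, perplexity=2.0)
        assert per_cell[0] == pytest.approx(2.0, abs=1e-9)

    def test_pure_neighborhood_is_one(self):
        g = star_graph(["a", "a", "a", "a"])
        labels = np.array(["a", "a", "a", "a", "a"])
        per_cell = lisi_per_cell(g, labels, perplexity=2.0)
        assert per_cell[0] == pytest.approx(1.0, abs=1e-9)

    def test_three_to_one_weights_give_1_6(self):
        # uniform weights over labels (a,a,a,b): p = (0.75, 0.25)
        g = star_graph(["a", "a", "a", "b"])
        labels = np.array(["x", "a", "a", "a", "b"])
        per_cell = lisi_per_cell(g, labels, perplexity=2.0)
        assert per_cell[0] == pytest.approx(1.0 / (0.5625 + 0.0625), abs=1e-9)

    def test_raw_bounded_by_label_count(self, rng):
        X = rng.standard_normal((60, 3))
        labels = rng.choice(["a", "b", "c"], 60)
        r = sb.lisi(X, labels, perplexity=10.0)
        assert 1.0 <= r.raw <= 3.0
        assert 0.0 <= r.value <= 1.0

    def test_invariant_to_label_renaming(self, rng):
        X = rng.standard_normal((40, 2))
        labels = rng.choice(["a", "b"], 40)
        renamed = np.where(labels == "a", "zebra", "yak")
        a = sb.lisi(X, labels, perplexity=8.0)
        b = sb.lisi(X, renamed, perplexity=8.0)
        assert a.raw == pytest.approx(b.raw, rel=1e-12)

    def test_single_label_warns_and_returns_one(self, rng):
        X = rng.standard_normal((10, 2))
        with pytest.warns(UserWarning):
            r = sb.lisi(X, np.array(["a"] * 10), perplexity=3.0)
        assert r.raw == 1.0


class TestKbet:
    def test_textbook_chi_squared_value(self):
        stat, p = kbet_cell_statistic(np.array([8, 2]), np.array([0.5, 0.5]))
        assert stat == pytest.approx(3.6, abs=1e-9)
        assert p == pytest.approx(0.05778, abs=5e-5)
        assert p > 0.05  # not rejected at alpha=0.05

    def test_perfectly_balanced_neighborhoods_accept(self):
        # 2 interleaved batches on a line: each cell's 2-neighborhood has
        # one cell of each batch
        X = np.arange(20, dtype=float)[:, None]
        batch = np.tile(["A", "B"], 10)
        g = sb.knn_graph(X, 2)
        r = sb.kbet(g, batch, alpha=0.05)
        assert r.raw == 0.0 and r.value == 1.0

    def test_separated_batches_all_rejected(self, rng):
        X = np.vstack([rng.standard_normal((50, 2)),
                       rng.standard_normal((50, 2)) + 50.0])
        batch = np.array(["A"] * 50 + ["B"] * 50)
        r = sb.kbet(sb.knn_graph(X, 10), batch, alpha=0.05)
        assert r.raw == 1.0

    def test_invariant_to_label_renaming(self, rng):
        X = rng.standard_normal((80, 2))
        batch = rng.choice(["A", "B"], 80)
        g = sb.knn_graph(X, 10)
        a = sb.kbet(g, batch)
        b = sb.kbet(g, np.where(batch == "A", "q", "p"))
        assert a.raw == b.raw

    def test_null_rejection_bounded_by_level(self):
        # i.i.d. labels at global frequencies: rejection <= alpha + 3 SE
        rng = np.random.default_rng(11)
        n, k, alpha = 600, 20, 0.05
        X = rng.standard_normal((n, 5))
        batch = rng.choice(["A", "B"], n)
        r = sb.kbet(sb.knn_graph(X, k), batch, alpha=alpha)
        se = np.sqrt(alpha * (1 - alpha) / n)
        assert r.raw <= alpha + 3 * se


class TestPcr:
    def test_embedding_equal_to_indicator_gives_one(self):
        batch = np.array(["A"] * 5 + ["B"] * 5)
        X = (batch == "B").astype(float)[:, None]
        r = sb.pcr_batch(X, batch, n_pcs=1)
        assert r.raw == pytest.approx(1.0, abs=1e-12)

    def test_permuted_labels_near_zero(self):
        rng = np.random.default_rng(3)
        X = rng.standard_normal((500, 10))
        batch = rng.permutation(np.repeat(["A", "B"], 250))
        r = sb.pcr_batch(X, batch, n_pcs=10)
        assert r.raw < 0.02  # ~ (B-1)/(n-1)

    def test_two_pc_case_matches_hand_formula(self):
        # scores on two orthogonal axes with known per-axis R^2
        rng = np.random.default_rng(4)
        n = 200
        batch = np.repeat(["A", "B"], n // 2)
        ind = (batch == "B").astype(float)
        pc1 = 10.0 * (ind - 0.5) + rng.standard_normal(n) * 0.1  # ~all batch
        pc2 = rng.standard_normal(n)  # no batch signal
        X = np.column_stack([pc1, pc2])
        r = sb.pcr_batch(X, batch, n_pcs=2)

        def r2(y):
            yc = y - y.mean()
            xc = ind - ind.mean()
            b = (xc @ yc) / (xc @ xc)
            return 1 - ((yc - b * xc) ** 2).sum() / (yc**2).sum()

        v1, v2 = pc1.var(ddof=1), pc2.var(ddof=1)
        expected = (v1 * r2(pc1) + v2 * r2(pc2)) / (v1 + v2)
        assert r.raw == pytest.approx(expected, rel=1e-6)

    def test_rotation_invariance(self, rng):
        X = rng.standard_normal((100, 4))
        batch = rng.choice(["A", "B"], 100)
        Q, _ = np.linalg.qr(rng.standard_normal((4, 4)))
        a = sb.pcr_batch(X, batch, n_pcs=4)
        b = sb.pcr_batch(X @ Q, batch, n_pcs=4)
        assert a.raw == pytest.approx(b.raw, rel=1e-8)

    def test_constant_input_rejected(self):
        with pytest.raises(ValueError):
            sb.pcr_batch(np.ones((10, 3)), np.array(["A", "B"] * 5))

    def test_comparison_identity_and_perfect_removal(self, rng):
        X = rng.standard_normal((60, 4))
        X[:30] += 4.0
        batch = np.repeat(["A", "B"], 30)
        same = sb.pcr_comparison(X, X, batch, n_pcs=4)
        assert same.value == pytest.approx(0.0, abs=1e-12)
        # perfect removal: after-space independent of batch up to noise
        after = np.vstack([X[:30] - 4.0, X[30:]])
        r = sb.pcr_comparison(X, after, batch, n_pcs=4)
        assert r.value > 0.95


class TestDpca:
    def test_identical_distributions_full_overlap(self, rng):
        x = rng.standard_normal(800)
        scores = np.concatenate([x, x])[:, None]
        batch = np.repeat(["A", "B"], 800)
        r = sb.dpca(scores, batch)
        assert r.raw == pytest.approx(1.0, abs=0.01)

    def test_disjoint_supports_no_overlap(self, rng):
        scores = np.concatenate([rng.uniform(0, 1, 300),
                                 rng.uniform(100, 101, 300)])[:, None]
        batch = np.repeat(["A", "B"], 300)
        assert sb.dpca(scores, batch).raw < 0.01

    def test_unit_normals_match_closed_form(self):
        # N(0,1) vs N(3,1): overlap = 2*Phi(-1.5)
        rng = np.random.default_rng(8)
        a = rng.standard_normal(5000)
        b = rng.standard_normal(5000) + 3.0
        got = density_overlap_1d(a, b)
        expected = 2 * norm.cdf(-1.5)
        assert got == pytest.approx(expected, abs=0.02)

    def test_symmetric_in_batch_order(self, rng):
        scores = rng.standard_normal((200, 2))
        batch = np.repeat(["A", "B"], 100)
        flipped = np.where(batch == "A", "B", "A")
        a = sb.dpca(scores, batch)
        b = sb.dpca(scores, flipped)
        assert a.raw == pytest.approx(b.raw, rel=1e-12)

    def test_variance_weighting(self, rng):
        # PC1 (high variance) disjoint, PC2 (low variance) identical:
        # weighted overlap must be near the PC1 (low) value
        shared = rng.standard_normal(400) * 0.1
        pc1 = np.concatenate([rng.standard_normal(200),
                              rng.standard_normal(200) + 100])
        scores = np.column_stack([pc1, np.concatenate([shared[:200], shared[:200]])])
        batch = np.repeat(["A", "B"], 200)
        r = sb.dpca(scores, batch)
        assert r.raw < 0.01


class TestBatchAsw:
    @staticmethod
    def brute_silhouette(X, labels):
        D = cdist(X, X)
        n = len(X)
        s = np.zeros(n)
        for i in range(n):
            same = (labels == labels[i]) & (np.arange(n) != i)
            if same.sum() == 0:
                s[i] = 0.0
                continue
            a = D[i, same].mean()
            b = min(D[i, labels == other].mean()
                    for other in np.unique(labels) if other != labels[i])
            s[i] = (b - a) / max(a, b)
        return s

    def test_interleaved_batches_score_high(self, rng):
        X = rng.standard_normal((100, 2))
        batch = np.tile(["A", "B"], 50)
        ct = np.repeat(["t1", "t2"], 50)
        r = sb.batch_asw(X, batch, ct)
        assert r.raw > 0.85

    def test_separated_batches_score_low(self, rng):
        X = np.vstack([rng.standard_normal((50, 2)),
                       rng.standard_normal((50, 2)) + 100])
        batch = np.repeat(["A", "B"], 50)
        ct = np.array(["t1"] * 100)
        r = sb.batch_asw(X, batch, ct)
        assert r.raw < 0.05

    def test_matches_brute_force_oracle(self, rng):
        X = rng.standard_normal((40, 3))
        batch = rng.choice(["A", "B"], 40)
        ct = np.array(["t1"] * 40)
        r = sb.batch_asw(X, batch, ct)
        s = self.brute_silhouette(X, batch)
        assert r.raw == pytest.approx(np.mean(1 - np.abs(s)), abs=1e-10)

    def test_no_eligible_group_is_missing(self, rng):
        X = rng.standard_normal((10, 2))
        batch = np.array(["A"] * 5 + ["B"] * 5)
        ct = np.where(batch == "A", "t1", "t2")  # 1 batch per type
        r = sb.batch_asw(X, batch, ct)
        assert np.isnan(r.value)
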