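"""Contrastive and spatial-regularization losses against brute-force oracles."""

import numpy as np
import pytest

from spagate import (Discriminator, EmbeddingSet, build_hybrid_graph,
                     contrastive_loss, corrupt, discriminate, readout,
                     spatial_regularization_loss, total_loss)
from spagate.objectives import LOG_EPS, sample_non_neighbors
from spagate._autodiff import Tensor
from spagate.io_preprocess import ExpressionMatrix, SpatialCoords


def _emb(rows):
    rows = np.asarray(rows, float)
    return EmbeddingSet(rows, spot_ids=[f"s{i}" for i in range(rows.shape[0])])


def _line_graph(n, radius=1.5):
    rng = np.random.default_rng(1)
    expr = ExpressionMatrix(rng.uniform(0.5, 2.0, size=(n, 4)),
                            [f"s{i}" for i in range(n)],
                            [f"g{j}" for j in range(4)])
    coords = SpatialCoords(np.column_stack([np.arange(float(n)), np.zeros(n)]),
                           expr.spot_ids)
    return expr, coords, build_hybrid_graph(expr, coords, radius=radius, bandwidth=0.75)


class TestCorrupt:
    def test_same_multiset_of_rows(self):
        expr, _, graph = _line_graph(8)
        res = corrupt(expr, graph, seed=3)
        got = np.sort(res.shuffled_expr.values, axis=0)
        want = np.sort(expr.values, axis=0)
        np.testing.assert_array_equal(got, want)
        np.testing.assert_array_equal(res.shuffled_expr.values,
                                      expr.values[res.permutation])

    def test_deterministic_per_seed(self):
        expr, _, graph = _line_graph(8)
        a = corrupt(expr, graph, seed=5).permutation
        b = corrupt(expr, graph, seed=5).permutation
        c = corrupt(expr, graph, seed=6).permutation
        np.testing.assert_array_equal(a, b)
        assert not np.array_equal(a, c)

    def test_topology_reused_by_default(self):
        expr, _, graph = _line_graph(8)
        res = corrupt(expr, graph, seed=3)
        assert res.graph_prime is graph

    def test_recompute_graph_requires_coords(self):
        expr, coords, graph = _line_graph(8)
        with pytest.raises(ValueError, match="coords"):
            corrupt(expr, graph, seed=0, recompute_graph=True)
        res = corrupt(expr, graph, seed=0, coords=coords, recompute_graph=True)
        assert res.graph_prime is not graph
        assert res.graph_prime.radius == graph.radius

    def test_two_spot_swap_frequency(self):
        """With N=2 the permutation is either identity or a swap; over 1000
        seeds the swap count should look binomial(1000, 1/2)."""
        expr, _, graph = _line_graph(2, radius=1.5)
        swaps = sum(corrupt(expr, graph, seed=s).permutation[0] == 1
                    for s in range(1000))
        assert 450 <= swaps <= 550


class TestReadoutDiscriminator:
    def test_readout_closed_form(self):
        emb = _emb([[2.0, -4.0], [0.0, 0.0]])
        np.testing.assert_allclose(readout(emb),
                                   1 / (1 + np.exp(-np.array([1.0, -2.0]))))

    def test_opposite_embeddings_give_half(self):
        v = np.array([0.7, -1.2, 3.0])
        np.testing.assert_allclose(readout(_emb([v, -v])), 0.5)

    def test_discriminate_closed_form(self):
        d = Discriminator(Tensor(np.eye(2)))
        u = np.array([1.0, 2.0])
        r = np.array([0.5, -0.25])
        s = u @ r  # identity bilinear matrix
        assert discriminate(d, u, r) == pytest.approx(1 / (1 + np.exp(-s)))
        assert 0.0 < discriminate(d, u * 50, r * 50) < 1.0

    def test_discriminate_dim_mismatch(self):
        d = Discriminator(Tensor(np.eye(2)))
        with pytest.raises(ValueError):
            discriminate(d, np.ones(3), np.ones(2))


class TestContrastive:
    def test_matches_scalar_loop_oracle(self):
        rng = np.random.default_rng(7)
        n, k = 9, 4
        pos, neg = _emb(rng.normal(size=(n, k))), _emb(rng.normal(size=(n, k)))
        summary = readout(pos)
        d = Discriminator(Tensor(rng.normal(size=(k, k))))
        got = contrastive_loss(pos, neg, summary, d)
        acc = 0.0
        for i in range(n):
            p = discriminate(d, pos.embeddings[i], summary)
            q = discriminate(d, neg.embeddings[i], summary)
            acc += np.log(max(p, LOG_EPS)) + np.log(max(1 - q, LOG_EPS))
        want = -acc / (2 * n)
        assert got == pytest.approx(want, abs=1e-10)

    def test_uninformative_discriminator_gives_log2(self):
        rng = np.random.default_rng(0)
        pos, neg = _emb(rng.normal(size=(6, 3))), _emb(rng.normal(size=(6, 3)))
        d = Discriminator(Tensor(np.zeros((3, 3))))
        got = contrastive_loss(pos, neg, readout(pos), d)
        assert got == pytest.approx(np.log(2.0), abs=1e-12)

    def test_shape_mismatch(self):
        d = Discriminator(Tensor(np.eye(2)))
        with pytest.raises(ValueError):
            contrastive_loss(_emb(np.ones((3, 2))), _emb(np.ones((4, 2))),
                             np.ones(2), d)


class TestSpatialRegularization:
    def test_exhaustive_matches_double_sum_oracle(self):
        expr, _, graph = _line_graph(10)
        rng = np.random.default_rng(2)
        u = rng.normal(size=(10, 5))
        got = spatial_regularization_loss(_emb(u), graph, negatives_per_spot=None)
        sig = lambda x: 1 / (1 + np.exp(-x))
        cos = lambda i, j: u[i] @ u[j] / (np.linalg.norm(u[i]) * np.linalg.norm(u[j]))
        adj = graph.weights.toarray() > 0
        acc = 0.0
        for i in range(10):
            for j in range(10):
                if adj[i, j]:
                    acc += np.log(max(sig(cos(i, j)), LOG_EPS))
                elif i != j:
                    acc += np.log(max(1 - sig(cos(i, j)), LOG_EPS))
        assert got == pytest.approx(-acc, abs=1e-10)

    def test_identical_embeddings_closed_form(self):
        """All cosines are 1: each edge contributes -log(sigma(1)) and each
        non-neighbor pair -log(1 - sigma(1))."""
        expr, _, graph = _line_graph(6)
        u = np.tile(np.array([1.0, 2.0, 3.0]), (6, 1))
        got = spatial_regularization_loss(_emb(u), graph, negatives_per_spot=None)
        n_edges_directed = graph.weights.nnz
        n_non = 6 * 5 - n_edges_directed
        sig1 = 1 / (1 + np.exp(-1.0))
        want = -(n_edges_directed * np.log(sig1) + n_non * np.log(1 - sig1))
        assert got == pytest.approx(want, rel=1e-12)

    def test_sampler_counts_and_validity(self):
        _, _, graph = _line_graph(12, radius=1.2)
        rng = np.random.default_rng(0)
        rows, cols = sample_non_neighbors(graph, 4, rng)
        assert rows.size == 12 * 4
        adj = graph.weights.toarray() > 0
        assert not np.any(adj[rows, cols])
        assert not np.any(rows == cols)
        for i in range(12):
            picks = cols[rows == i]
            assert len(set(picks)) == len(picks)  # without replacement

    def test_sampler_deterministic_per_seed(self):
        _, _, graph = _line_graph(12, radius=1.2)
        a = sample_non_neighbors(graph, 3, np.random.default_rng(9))
        b = sample_non_neighbors(graph, 3, np.random.default_rng(9))
        np.testing.assert_array_equal(a[1], b[1])

    def test_fully_connected_graph_has_no_negatives(self, caplog):
        expr, _, graph = _line_graph(3, radius=10.0)
        u = np.random.default_rng(0).normal(size=(3, 2))
        with caplog.at_level("WARNING"):
            got = spatial_regularization_loss(_emb(u), graph, negatives_per_spot=None)
        assert np.isfinite(got)
        assert any("non-neighbors" in r.message for r in caplog.records)

    def test_misaligned_inputs(self):
        _, _, graph = _line_graph(5)
        with pytest.raises(ValueError):
            spatial_regularization_loss(_emb(np.ones((4, 2))), graph)


class TestTotalLoss:
    def test_weighted_sum(self):
        assert total_loss(2.0, 3.0, 5.0, 1.0, 0.5, 0.1) == pytest.approx(4.0)

    def test_negative_weight_rejected(self):
        with pytest.raises(ValueError):
            total_loss(1.0, 1.0, 1.0, -1.0, 0.0, 0.0)
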