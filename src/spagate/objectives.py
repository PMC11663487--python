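"""Self-supervised training objectives.

Two signals complement the reconstruction loss:

* an infomax-style contrastive loss: spot embeddings from the true graph
  (positives) and from a row-shuffled expression matrix on the same
  topology (negatives) are scored against a logistic-squashed mean
  summary vector by a bilinear discriminator, with binary cross-entropy

      L_gcl = -(1/2N) sum_i [ log D(u_i, r) + log(1 - D(u'_i, r)) ]

* a spatial regularization loss pulling neighbor embeddings together and
  pushing sampled non-neighbors apart through logistic-squashed cosine
  similarities

      L_sr = -sum_i [ sum_{j in N_i} log psi(H_ij)
                      + sum_{o sampled non-neighbors} log(1 - psi(H_io)) ]

Probabilities are clamped at 1e-8 before the log.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np

from . import _autodiff as ad
from ._autodiff import Tensor
from .gate_model import EmbeddingSet, _xavier
from .hybrid_graph import HybridNeighborGraph, build_hybrid_graph
from .io_preprocess import ExpressionMatrix

logger = logging.getLogger(__name__)

#: clamp applied to probabilities before taking logs
LOG_EPS = 1e-8


@dataclass
class CorruptionResult:
    shuffled_expr: ExpressionMatrix
    permutation: np.ndarray
    graph_prime: HybridNeighborGraph


@dataclass
class Discriminator:
    """Bilinear scorer D(u, r) = logistic(u^T W r)."""

    bilinear_matrix: Tensor

    @classmethod
    def initialize(cls, latent_dim: int, rng: np.random.Generator) -> "Discriminator":
        return cls(Tensor(_xavier(rng, latent_dim, latent_dim), requires_grad=True))


# ----------------------------------------------------------------------
# corruption
# ----------------------------------------------------------------------

def corrupt(expr: ExpressionMatrix, graph: HybridNeighborGraph, seed: int,
            coords=None, recompute_graph: bool = False) -> CorruptionResult:
    """Row-shuffle the expression matrix to build the negative view.

    The negative graph reuses the original topology by default (the DGI
    convention); ``recompute_graph`` (requires ``coords``) instead rebuilds
    the hybrid similarities on the shuffled matrix with the same
    radius/bandwidth/weights.
    """
    if expr.n_spots < 2:
        raise ValueError("need at least 2 spots to corrupt")
    rng = np.random.default_rng(seed)
    perm = rng.permutation(expr.n_spots)
    shuffled = ExpressionMatrix(expr.values[perm],
                                [expr.spot_ids[i] for i in perm], expr.gene_ids)
    if recompute_graph:
        if coords is None:
            raise ValueError("recompute_graph=True requires coords")
        gprime = build_hybrid_graph(shuffled, coords, radius=graph.radius,
                                    bandwidth=graph.bandwidth, alpha=graph.alpha,
                                    beta=graph.beta)
    else:
        gprime = graph
    return CorruptionResult(shuffled, perm, gprime)


# ----------------------------------------------------------------------
# readout / discriminator
# ----------------------------------------------------------------------

def readout_tensor(u: Tensor) -> Tensor:
    return ad.sigmoid(u.mean(axis=0))


def readout(emb: EmbeddingSet) -> np.ndarray:
    """Graph-level summary: logistic-squashed mean of the embeddings."""
    return readout_tensor(Tensor(emb.embeddings)).data


def discriminate(d: Discriminator, spot_emb: np.ndarray, summary: np.ndarray) -> float:
    """D(u, r) = logistic(u^T W r), strictly inside (0, 1)."""
    u = np.asarray(spot_emb, float)
    r = np.asarray(summary, float)
    w = d.bilinear_matrix.data
    if u.shape[-1] != w.shape[0] or r.shape[0] != w.shape[1]:
        raise ValueError("discriminator dimension mismatch")
    s = float(u @ w @ r)
    return float(1.0 / (1.0 + np.exp(-s)))


# ----------------------------------------------------------------------
# contrastive loss
# ----------------------------------------------------------------------

def contrastive_loss_tensor(u_pos: Tensor, u_neg: Tensor, summary: Tensor,
                            d: Discriminator) -> Tensor:
    n = u_pos.shape[0]
    r_col = summary.reshape(-1, 1)
    p_pos = ad.sigmoid(ad.matmul(ad.matmul(u_pos, d.bilinear_matrix), r_col).reshape(-1))
    p_neg = ad.sigmoid(ad.matmul(ad.matmul(u_neg, d.bilinear_matrix), r_col).reshape(-1))
    pos_term = ad.log(ad.clip_min(p_pos, LOG_EPS)).sum()
    neg_term = ad.log(ad.clip_min(1.0 - p_neg, LOG_EPS)).sum()
    return -(pos_term + neg_term) / (2.0 * n)


def contrastive_loss(emb_pos: EmbeddingSet, emb_neg: EmbeddingSet,
                     summary: np.ndarray, d: Discriminator) -> float:
    if emb_pos.embeddings.shape != emb_neg.embeddings.shape:
        raise ValueError("positive/negative embedding shape mismatch")
    return float(contrastive_loss_tensor(Tensor(emb_pos.embeddings),
                                         Tensor(emb_neg.embeddings),
                                         Tensor(np.asarray(summary, float)), d).data)


# ----------------------------------------------------------------------
# spatial regularization
# ----------------------------------------------------------------------

class NonNeighborSampler:
    """Per-spot uniform sampling of non-neighbor pairs, without replacement.

    Candidate sets (everything outside the spot's closed neighborhood) are
    precomputed once per graph so per-epoch sampling is cheap.
    """

    def __init__(self, graph: HybridNeighborGraph):
        n = graph.n_spots
        self.candidates: list[np.ndarray] = []
        warned = False
        for i, neigh in enumerate(graph.neighbor_sets()):
            mask = np.ones(n, dtype=bool)
            mask[i] = False
            mask[neigh] = False
            cand = np.flatnonzero(mask)
            if cand.size == 0 and not warned:
                logger.warning("spot %d has no non-neighbors; negative term skipped", i)
                warned = True
            self.candidates.append(cand)

    def sample(self, negatives_per_spot: int | None,
               rng: np.random.Generator) -> tuple[np.ndarray, np.ndarray]:
        rows, cols = [], []
        for i, cand in enumerate(self.candidates):
            if cand.size == 0:
                continue
            if negatives_per_spot is None or negatives_per_spot >= cand.size:
                pick = cand
            else:
                pick = cand[rng.permutation(cand.size)[:negatives_per_spot]]
            rows.append(np.full(pick.size, i))
            cols.append(pick)
        if not rows:
            return np.array([], dtype=int), np.array([], dtype=int)
        return np.concatenate(rows), np.concatenate(cols)


def sample_non_neighbors(graph: HybridNeighborGraph, negatives_per_spot: int | None,
                         rng: np.random.Generator) -> tuple[np.ndarray, np.ndarray]:
    """Uniform non-neighbor pairs per spot.

    ``negatives_per_spot=None`` enumerates every non-neighbor (the
    exhaustive double sum; O(N^2), intended for small N / tests).
    """
    return NonNeighborSampler(graph).sample(negatives_per_spot, rng)


def _cosine_pairs(u: Tensor, rows: np.ndarray, cols: np.ndarray) -> Tensor:
    norms = ad.sqrt(ad.clip_min((u * u).sum(axis=1), 1e-30))
    ui = ad.gather_rows(u, rows)
    uj = ad.gather_rows(u, cols)
    dots = (ui * uj).sum(axis=1)
    return dots / (ad.gather_rows(norms, rows) * ad.gather_rows(norms, cols))


def spatial_regularization_loss_tensor(u: Tensor, pos_rows: np.ndarray,
                                       pos_cols: np.ndarray, neg_rows: np.ndarray,
                                       neg_cols: np.ndarray) -> Tensor:
    total = Tensor(0.0)
    if pos_rows.size:
        h = _cosine_pairs(u, pos_rows, pos_cols)
        total = total + ad.log(ad.clip_min(ad.sigmoid(h), LOG_EPS)).sum()
    if neg_rows.size:
        hp = _cosine_pairs(u, neg_rows, neg_cols)
        total = total + ad.log(ad.clip_min(1.0 - ad.sigmoid(hp), LOG_EPS)).sum()
    return -total


def spatial_regularization_loss(emb: EmbeddingSet, graph: HybridNeighborGraph,
                                negatives_per_spot: int | None = 30,
                                seed: int = 0) -> float:
    """Neighbor-attraction / non-neighbor-repulsion loss on the embeddings."""
    if emb.embeddings.shape[0] != graph.n_spots:
        raise ValueError("embeddings and graph are misaligned")
    rows, cols, _ = graph.edge_list()
    rng = np.random.default_rng(seed)
    nrows, ncols = sample_non_neighbors(graph, negatives_per_spot, rng)
    return float(spatial_regularization_loss_tensor(
        Tensor(emb.embeddings), rows, cols, nrows, ncols).data)


def total_loss(l_rec: float, l_gcl: float, l_sr: float,
               lambda_: float, mu: float, gamma: float) -> float:
    """Weighted training objective L = lambda*L_rec + mu*L_gcl + gamma*L_sr."""
    if min(lambda_, mu, gamma) < 0:
        raise ValueError("loss weights must be >= 0")
    return lambda_ * l_rec + mu * l_gcl + gamma * l_sr
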