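"""Graph attention auto-encoder (GATE) over the hybrid neighbor graph.

Each encoder layer transforms spot features with a trainable matrix and
aggregates them over the neighbor set with softmax-normalized attention

    u_i = sigma( sum_{j in G_i} a_ij * (W u_j) ),
    a_ij = softmax_j( phi( delta_s . (W u_i) + delta_r . (W u_j) ) ),

where the softmax runs over the neighbor set of spot i.  The decoder
mirrors the encoder stack in reverse (independent weights by default,
transposed encoder weights when tied) and reconstructs the input
expression; the reconstruction loss is the summed squared error.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import scipy.sparse as sp

from . import _autodiff as ad
from ._autodiff import Tensor
from .hybrid_graph import HybridNeighborGraph
from .io_preprocess import ExpressionMatrix

logger = logging.getLogger(__name__)

_ACTIVATIONS = {
    "elu": ad.elu,
    "relu": ad.relu,
    "identity": lambda t: t,
}
_ATTENTION_ACTIVATIONS = {
    "sigmoid": ad.sigmoid,
    "leaky_relu": ad.leaky_relu,
    "identity": lambda t: t,
}


@dataclass(frozen=True)
class GateConfig:
    """Architecture of the auto-encoder.

    ``layer_dims`` starts at the input gene dimension, e.g. ``[M, 256, 30]``
    for a two-layer encoder with a 30-dimensional latent space.
    """

    layer_dims: tuple[int, ...]
    activation: str = "elu"
    attention_activation: str = "sigmoid"
    tie_decoder_weights: bool = False
    self_attention: bool = True
    seed: int = 0

    def __post_init__(self):
        object.__setattr__(self, "layer_dims", tuple(int(d) for d in self.layer_dims))
        if len(self.layer_dims) < 2 or any(d <= 0 for d in self.layer_dims):
            raise ValueError("layer_dims needs >= 2 positive entries")
        if self.activation not in _ACTIVATIONS:
            raise ValueError(f"unknown activation {self.activation!r}")
        if self.attention_activation not in _ATTENTION_ACTIVATIONS:
            raise ValueError(f"unknown attention activation {self.attention_activation!r}")

    @property
    def latent_dim(self) -> int:
        return self.layer_dims[-1]


def _xavier(rng: np.random.Generator, fan_in: int, fan_out: int) -> np.ndarray:
    limit = np.sqrt(6.0 / (fan_in + fan_out))
    return rng.uniform(-limit, limit, size=(fan_in, fan_out))


@dataclass
class GateParams:
    """Trainable weights of encoder, decoder, and attention vectors."""

    encoder_weights: list[Tensor]
    decoder_weights: list[Tensor]          # empty when tied
    encoder_attention: list[tuple[Tensor, Tensor]]
    decoder_attention: list[tuple[Tensor, Tensor]]
    tied: bool

    @classmethod
    def initialize(cls, config: GateConfig, rng: np.random.Generator | None = None) -> "GateParams":
        """Xavier-uniform initialization from the config seed."""
        if rng is None:
            rng = np.random.default_rng(config.seed)
        dims = config.layer_dims
        enc_w, enc_a = [], []
        for fan_in, fan_out in zip(dims[:-1], dims[1:]):
            enc_w.append(Tensor(_xavier(rng, fan_in, fan_out), requires_grad=True))
            enc_a.append((Tensor(_xavier(rng, fan_out, 1), requires_grad=True),
                          Tensor(_xavier(rng, fan_out, 1), requires_grad=True)))
        dec_w, dec_a = [], []
        for fan_in, fan_out in zip(dims[::-1][:-1], dims[::-1][1:]):
            if not config.tie_decoder_weights:
                dec_w.append(Tensor(_xavier(rng, fan_in, fan_out), requires_grad=True))
            dec_a.append((Tensor(_xavier(rng, fan_out, 1), requires_grad=True),
                          Tensor(_xavier(rng, fan_out, 1), requires_grad=True)))
        return cls(enc_w, dec_w, enc_a, dec_a, tied=config.tie_decoder_weights)

    def decoder_weight(self, layer: int) -> Tensor:
        """Decoder weight for layer ``layer`` (0 = nearest the latent space)."""
        if self.tied:
            return self.encoder_weights[len(self.encoder_weights) - 1 - layer].T
        return self.decoder_weights[layer]

    def trainables(self) -> list[Tensor]:
        out = list(self.encoder_weights) + list(self.decoder_weights)
        for ds, dr in self.encoder_attention + self.decoder_attention:
            out.extend([ds, dr])
        return out


@dataclass
class EmbeddingSet:
    """Per-spot latent vectors, optional corrupted view, graph summary."""

    embeddings: np.ndarray
    corrupted_embeddings: np.ndarray | None = None
    summary: np.ndarray | None = None
    spot_ids: list[str] = field(default_factory=list)

    def __post_init__(self):
        self.embeddings = np.asarray(self.embeddings, dtype=np.float64)
        if not np.all(np.isfinite(self.embeddings)):
            raise ValueError("embeddings contain NaN/Inf")

    @property
    def latent_dim(self) -> int:
        return self.embeddings.shape[1]


# ----------------------------------------------------------------------
# edge bookkeeping
# ----------------------------------------------------------------------

def attention_edges(graph: HybridNeighborGraph, config: GateConfig) -> ad.EdgeIndex:
    """Directed edge index the attention layers operate on.

    Adds self-edges for every spot when ``self_attention`` is on; otherwise
    only isolated spots get one (their row would have an empty softmax),
    with a warning.
    """
    rows, cols, _ = graph.edge_list()
    n = graph.n_spots
    if config.self_attention:
        extra = np.arange(n)
    else:
        deg = np.bincount(rows, minlength=n)
        extra = np.flatnonzero(deg == 0)
        if extra.size:
            logger.warning("%d isolated spot(s) pass through a self-edge "
                           "(self_attention is disabled)", extra.size)
    rows = np.concatenate([rows, extra])
    cols = np.concatenate([cols, extra])
    order = np.lexsort((cols, rows))
    return ad.EdgeIndex(rows[order], cols[order], n)


# ----------------------------------------------------------------------
# tensor-level forward passes (shared by training and inference)
# ----------------------------------------------------------------------

def _attention_layer(h: Tensor, w: Tensor, d_s: Tensor, d_r: Tensor,
                     edges: ad.EdgeIndex, config: GateConfig) -> tuple[Tensor, Tensor]:
    """One attention aggregation; returns (aggregated features, edge attn)."""
    phi = _ATTENTION_ACTIVATIONS[config.attention_activation]
    z = ad.matmul(h, w)
    zs = ad.matmul(z, d_s).reshape(-1)
    zr = ad.matmul(z, d_r).reshape(-1)
    scores = phi(ad.gather_rows(zs, edges.rows) + ad.gather_rows(zr, edges.cols))
    attn = ad.segment_softmax(scores, edges.rows, edges.n)
    return ad.edge_aggregate(attn, z, edges), attn


def encode_tensor(x: Tensor, edges: ad.EdgeIndex, params: GateParams,
                  config: GateConfig,
                  collect_attention: list | None = None) -> Tensor:
    sigma = _ACTIVATIONS[config.activation]
    h = x
    for k, w in enumerate(params.encoder_weights):
        d_s, d_r = params.encoder_attention[k]
        agg, attn = _attention_layer(h, w, d_s, d_r, edges, config)
        h = sigma(agg)
        if collect_attention is not None:
            collect_attention.append(attn)
    return h


def decode_tensor(u: Tensor, edges: ad.EdgeIndex, params: GateParams,
                  config: GateConfig,
                  collect_attention: list | None = None) -> Tensor:
    sigma = _ACTIVATIONS[config.activation]
    n_layers = len(config.layer_dims) - 1
    h = u
    for k in range(n_layers):
        w = params.decoder_weight(k)
        d_s, d_r = params.decoder_attention[k]
        agg, attn = _attention_layer(h, w, d_s, d_r, edges, config)
        # the output layer is linear so reconstructions live on the input scale
        h = agg if k == n_layers - 1 else sigma(agg)
        if collect_attention is not None:
            collect_attention.append(attn)
    return h


def reconstruction_loss_tensor(x: Tensor, recon: Tensor) -> Tensor:
    diff = x - recon
    return (diff * diff).sum()


# ----------------------------------------------------------------------
# public numpy-facing operations
# ----------------------------------------------------------------------

def attention_coefficients(features: np.ndarray, graph: HybridNeighborGraph,
                           layer_params: tuple, config: GateConfig) -> sp.csr_matrix:
    """Row-stochastic attention matrix of one layer (sparse N x N)."""
    w, d_s, d_r = layer_params
    edges = attention_edges(graph, config)
    n = graph.n_spots
    _, attn = _attention_layer(Tensor(features), _as_t(w), _as_t(d_s), _as_t(d_r),
                               edges, config)
    return sp.csr_matrix((attn.data, (edges.rows, edges.cols)), shape=(n, n))


def _as_t(x) -> Tensor:
    return x if isinstance(x, Tensor) else Tensor(np.asarray(x, float))


def encode(expr: ExpressionMatrix, graph: HybridNeighborGraph,
           params: GateParams, config: GateConfig) -> EmbeddingSet:
    if expr.n_genes != config.layer_dims[0]:
        raise ValueError(f"expected {config.layer_dims[0]} input features, "
                         f"got {expr.n_genes}")
    edges = attention_edges(graph, config)
    u = encode_tensor(Tensor(expr.values), edges, params, config)
    return EmbeddingSet(u.data, spot_ids=list(expr.spot_ids))


def decode(emb: EmbeddingSet, graph: HybridNeighborGraph,
           params: GateParams, config: GateConfig) -> np.ndarray:
    if emb.latent_dim != config.latent_dim:
        raise ValueError(f"expected latent dim {config.latent_dim}, got {emb.latent_dim}")
    edges = attention_edges(graph, config)
    return decode_tensor(Tensor(emb.embeddings), edges, params, config).data


def reconstruction_loss(expr: ExpressionMatrix | np.ndarray, recon: np.ndarray) -> float:
    x = expr.values if isinstance(expr, ExpressionMatrix) else np.asarray(expr, float)
    recon = np.asarray(recon, float)
    if x.shape != recon.shape:
        raise ValueError(f"shape mismatch: {x.shape} vs {recon.shape}")
    return float(np.sum((x - recon) ** 2))
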