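"""Joint full-batch optimization of the auto-encoder and discriminator.

Minimizes ``L = lambda*L_rec + mu*L_gcl + gamma*L_sr`` with Adam.  One
run seed drives parameter initialization, the per-epoch corruption
permutations, and the spatial-loss negative sampling through a single
seed stream, so runs are exactly repeatable.
"""

from __future__ import annotations

import json
import logging
from dataclasses import dataclass, field, asdict

import numpy as np

from . import gate_model, objectives
from ._autodiff import Tensor
from .gate_model import EmbeddingSet, GateConfig, GateParams
from .hybrid_graph import HybridNeighborGraph
from .io_preprocess import ExpressionMatrix, SpatialCoords

logger = logging.getLogger(__name__)

ABLATIONS = ("full", "no_cs", "no_es", "no_cl", "no_reg")


@dataclass
class TrainConfig:
    epochs: int = 200
    learning_rate: float = 1e-3
    weight_decay: float = 1e-4
    lambda_: float = 1.0
    mu: float = 1.0
    gamma: float = 0.1
    seed: int = 0
    ablation: str = "full"
    negatives_per_spot: int = 30
    fixed_corruption: bool = False

    def __post_init__(self):
        if self.ablation not in ABLATIONS:
            raise ValueError(f"unknown ablation {self.ablation!r}")
        if self.epochs < 1 or self.learning_rate <= 0 or self.weight_decay < 0:
            raise ValueError("invalid optimizer settings")
        if min(self.lambda_, self.mu, self.gamma) < 0:
            raise ValueError("loss weights must be >= 0")
        # ablations that disable a loss force its weight to zero
        if self.ablation == "no_cl":
            self.mu = 0.0
        if self.ablation == "no_reg":
            self.gamma = 0.0


@dataclass
class TrainState:
    params: GateParams
    discriminator: objectives.Discriminator
    loss_trace: list[dict] = field(default_factory=list)
    epoch: int = 0

    def write_trace_tsv(self, path: str) -> None:
        with open(path, "w") as fh:
            fh.write("epoch\tL_rec\tL_gcl\tL_sr\tL\n")
            for rec in self.loss_trace:
                fh.write(f"{rec['epoch']}\t{rec['L_rec']:.10g}\t{rec['L_gcl']:.10g}"
                         f"\t{rec['L_sr']:.10g}\t{rec['L']:.10g}\n")


class Adam:
    """Adam with L2 weight decay folded into the gradient."""

    def __init__(self, params: list[Tensor], lr: float, weight_decay: float = 0.0,
                 beta1: float = 0.9, beta2: float = 0.999, eps: float = 1e-8):
        self.params = params
        self.lr, self.wd = lr, weight_decay
        self.b1, self.b2, self.eps = beta1, beta2, eps
        self.t = 0
        self.m = [np.zeros_like(p.data) for p in params]
        self.v = [np.zeros_like(p.data) for p in params]

    def step(self) -> None:
        self.t += 1
        for i, p in enumerate(self.params):
            if p.grad is None:
                continue
            g = p.grad + self.wd * p.data
            self.m[i] = self.b1 * self.m[i] + (1 - self.b1) * g
            self.v[i] = self.b2 * self.v[i] + (1 - self.b2) * g * g
            mhat = self.m[i] / (1 - self.b1 ** self.t)
            vhat = self.v[i] / (1 - self.b2 ** self.t)
            p.data -= self.lr * mhat / (np.sqrt(vhat) + self.eps)

    def zero_grad(self) -> None:
        for p in self.params:
            p.grad = None


def _check_graph_matches_ablation(graph: HybridNeighborGraph, ablation: str) -> None:
    if ablation == "no_cs" and graph.beta != 0:
        raise ValueError("ablation no_cs requires a graph built with beta=0")
    if ablation == "no_es" and graph.alpha != 0:
        raise ValueError("ablation no_es requires a graph built with alpha=0")


def train(expr: ExpressionMatrix, coords: SpatialCoords | None,
          graph: HybridNeighborGraph, gate_config: GateConfig,
          train_config: TrainConfig,
          trace_path: str | None = None) -> tuple[TrainState, EmbeddingSet]:
    """Full-batch joint training; returns the final state and embeddings.

    ``coords`` is accepted for interface symmetry (the graph already
    encodes the spatial structure) and may be ``None``.
    """
    tc, gc = train_config, gate_config
    if expr.n_genes != gc.layer_dims[0]:
        raise ValueError(f"expression has {expr.n_genes} genes but the model "
                         f"expects {gc.layer_dims[0]}")
    if expr.n_spots != graph.n_spots:
        raise ValueError("expression and graph are misaligned")
    _check_graph_matches_ablation(graph, tc.ablation)

    master = np.random.default_rng(tc.seed)
    init_rng = np.random.default_rng(int(master.integers(2 ** 31)))
    params = GateParams.initialize(gc, init_rng)
    disc = objectives.Discriminator.initialize(gc.latent_dim, init_rng)

    edges = gate_model.attention_edges(graph, gc)
    pos_rows, pos_cols, _ = graph.edge_list()
    x_t = Tensor(expr.values)
    n = expr.n_spots

    trainables = params.trainables()
    if tc.mu > 0:
        trainables = trainables + [disc.bilinear_matrix]
    opt = Adam(trainables, tc.learning_rate, tc.weight_decay)

    sampler = objectives.NonNeighborSampler(graph) if tc.gamma > 0 else None
    fixed_perm = None
    state = TrainState(params, disc)
    for epoch in range(1, tc.epochs + 1):
        corr_seed = int(master.integers(2 ** 31))
        neg_seed = int(master.integers(2 ** 31))
        opt.zero_grad()

        u = gate_model.encode_tensor(x_t, edges, params, gc)
        recon = gate_model.decode_tensor(u, edges, params, gc)
        l_rec = gate_model.reconstruction_loss_tensor(x_t, recon)
        total = tc.lambda_ * l_rec

        l_gcl_val = 0.0
        if tc.mu > 0:
            if tc.fixed_corruption:
                if fixed_perm is None:
                    fixed_perm = np.random.default_rng(corr_seed).permutation(n)
                perm = fixed_perm
            else:
                perm = np.random.default_rng(corr_seed).permutation(n)
            x_neg = Tensor(expr.values[perm])
            u_neg = gate_model.encode_tensor(x_neg, edges, params, gc)
            summary = objectives.readout_tensor(u)
            l_gcl = objectives.contrastive_loss_tensor(u, u_neg, summary, disc)
            total = total + tc.mu * l_gcl
            l_gcl_val = float(l_gcl.data)

        l_sr_val = 0.0
        if tc.gamma > 0:
            neg_rng = np.random.default_rng(neg_seed)
            nrows, ncols = sampler.sample(tc.negatives_per_spot, neg_rng)
            l_sr = objectives.spatial_regularization_loss_tensor(
                u, pos_rows, pos_cols, nrows, ncols)
            total = total + tc.gamma * l_sr
            l_sr_val = float(l_sr.data)

        l_total = float(total.data)
        l_rec_val = float(l_rec.data)
        if not np.isfinite(l_total):
            raise FloatingPointError(
                f"non-finite loss at epoch {epoch}: "
                f"L_rec={l_rec_val}, L_gcl={l_gcl_val}, L_sr={l_sr_val}")
        state.loss_trace.append({"epoch": epoch, "L_rec": l_rec_val,
                                 "L_gcl": l_gcl_val, "L_sr": l_sr_val, "L": l_total})
        logger.info("epoch %d\tL_rec=%.6g\tL_gcl=%.6g\tL_sr=%.6g\tL=%.6g",
                    epoch, l_rec_val, l_gcl_val, l_sr_val, l_total)

        total.backward()
        opt.step()
        state.epoch = epoch

    if trace_path is not None:
        state.write_trace_tsv(trace_path)
    emb = extract_embeddings(state, expr, graph, gc)
    return state, emb


def extract_embeddings(state: TrainState, expr: ExpressionMatrix,
                       graph: HybridNeighborGraph,
                       gate_config: GateConfig) -> EmbeddingSet:
    """A single clean (uncorrupted) encoder pass with the trained weights."""
    emb = gate_model.encode(expr, graph, state.params, gate_config)
    emb.summary = objectives.readout(emb)
    return emb


# ----------------------------------------------------------------------
# checkpointing
# ----------------------------------------------------------------------

def save_checkpoint(path: str, state: TrainState, gate_config: GateConfig,
                    train_config: TrainConfig) -> None:
    """Single-file JSON checkpoint: config echo, loss trace, all weights."""
    payload = {
        "gate_config": asdict(gate_config),
        "train_config": asdict(train_config),
        "epoch": state.epoch,
        "loss_trace": state.loss_trace,
        "weights": {
            "encoder_weights": [w.data.tolist() for w in state.params.encoder_weights],
            "decoder_weights": [w.data.tolist() for w in state.params.decoder_weights],
            "encoder_attention": [[a.data.tolist(), b.data.tolist()]
                                  for a, b in state.params.encoder_attention],
            "decoder_attention": [[a.data.tolist(), b.data.tolist()]
                                  for a, b in state.params.decoder_attention],
            "discriminator": state.discriminator.bilinear_matrix.data.tolist(),
        },
    }
    payload["gate_config"]["layer_dims"] = list(gate_config.layer_dims)
    with open(path, "w") as fh:
        json.dump(payload, fh)


def load_checkpoint(path: str) -> tuple[TrainState, GateConfig, TrainConfig]:
    with open(path) as fh:
        payload = json.load(fh)
    gc = GateConfig(**{**payload["gate_config"],
                       "layer_dims": tuple(payload["gate_config"]["layer_dims"])})
    tc = TrainConfig(**payload["train_config"])
    w = payload["weights"]
    params = GateParams(
        [Tensor(np.array(m), requires_grad=True) for m in w["encoder_weights"]],
        [Tensor(np.array(m), requires_grad=True) for m in w["decoder_weights"]],
        [(Tensor(np.array(a), requires_grad=True), Tensor(np.array(b), requires_grad=True))
         for a, b in w["encoder_attention"]],
        [(Tensor(np.array(a), requires_grad=True), Tensor(np.array(b), requires_grad=True))
         for a, b in w["decoder_attention"]],
        tied=gc.tie_decoder_weights,
    )
    disc = objectives.Discriminator(Tensor(np.array(w["discriminator"]), requires_grad=True))
    state = TrainState(params, disc, payload["loss_trace"], payload["epoch"])
    return state, gc, tc
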