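"""scikit-learn style estimators wrapping the full workflow.

:class:`SpatialGraphAutoencoder` learns spot embeddings (a transformer:
``fit`` trains on the spots-by-genes matrix plus coordinates, ``transform``
returns the latent embeddings, ``inverse_transform`` the denoised
reconstruction).  :class:`DomainClusterer` assigns spatial domains from
embeddings.  Both follow the estimator contract (``get_params`` /
``set_params``, fitted attributes with a trailing underscore), so the
clusterer composes with standard model-selection utilities; the
auto-encoder is transductive (the graph couples all spots), so
``transform`` applies to the fitted data.
"""

from __future__ import annotations

import numpy as np
from sklearn.base import BaseEstimator, ClusterMixin, TransformerMixin
from sklearn.utils.validation import check_array, check_is_fitted

from . import cluster_downstream, hybrid_graph, trainer
from .gate_model import EmbeddingSet, GateConfig
from .io_preprocess import ExpressionMatrix, SpatialCoords
from .synthetic_data import DomainLabels


def _as_expr(X) -> ExpressionMatrix:
    if isinstance(X, ExpressionMatrix):
        return X
    X = check_array(X, dtype=np.float64)
    return ExpressionMatrix(X, [f"spot_{i}" for i in range(X.shape[0])],
                            [f"gene_{j}" for j in range(X.shape[1])])


def _as_coords(coords, spot_ids) -> SpatialCoords:
    if isinstance(coords, SpatialCoords):
        return coords
    coords = check_array(coords, dtype=np.float64)
    return SpatialCoords(coords, spot_ids)


class SpatialGraphAutoencoder(TransformerMixin, BaseEstimator,
                              auto_wrap_output_keys=None):
    """Graph attention auto-encoder with contrastive and spatial losses.

    Parameters mirror the three stages: hybrid-graph construction
    (``radius``, ``bandwidth``, ``alpha``, ``beta``, ``target_neighbors``),
    the auto-encoder architecture (``hidden_dims``, ``n_latent``,
    activations, ``tie_decoder_weights``), and optimization (``epochs``,
    ``learning_rate``, ``weight_decay``, the loss weights ``lambda_rec`` /
    ``mu_contrastive`` / ``gamma_spatial``, ``negatives_per_spot``,
    ``ablation``).
    """

    def __init__(self, hidden_dims=(128,), n_latent=30, activation="elu",
                 attention_activation="sigmoid", tie_decoder_weights=False,
                 self_attention=True, radius=None, bandwidth=None,
                 alpha=0.5, beta=0.5, target_neighbors=6,
                 epochs=200, learning_rate=1e-3, weight_decay=1e-4,
                 lambda_rec=1.0, mu_contrastive=1.0, gamma_spatial=0.1,
                 negatives_per_spot=30, ablation="full", fixed_corruption=False,
                 random_state=0):
        self.hidden_dims = hidden_dims
        self.n_latent = n_latent
        self.activation = activation
        self.attention_activation = attention_activation
        self.tie_decoder_weights = tie_decoder_weights
        self.self_attention = self_attention
        self.radius = radius
        self.bandwidth = bandwidth
        self.alpha = alpha
        self.beta = beta
        self.target_neighbors = target_neighbors
        self.epochs = epochs
        self.learning_rate = learning_rate
        self.weight_decay = weight_decay
        self.lambda_rec = lambda_rec
        self.mu_contrastive = mu_contrastive
        self.gamma_spatial = gamma_spatial
        self.negatives_per_spot = negatives_per_spot
        self.ablation = ablation
        self.fixed_corruption = fixed_corruption
        self.random_state = random_state

    # ------------------------------------------------------------------
    def _graph_weights(self) -> tuple[float, float]:
        alpha, beta = self.alpha, self.beta
        if self.ablation == "no_cs":
            beta = 0.0
        elif self.ablation == "no_es":
            alpha = 0.0
        return alpha, beta

    def fit(self, X, y=None, *, coords=None, graph=None):
        """Train on a spots-by-genes matrix with per-spot 2-D coordinates."""
        expr = _as_expr(X)
        if graph is None:
            if coords is None:
                raise ValueError("fit requires coords (N x 2) or a prebuilt graph")
            coords = _as_coords(coords, expr.spot_ids)
            alpha, beta = self._graph_weights()
            graph = hybrid_graph.build_hybrid_graph(
                expr, coords, radius=self.radius, bandwidth=self.bandwidth,
                alpha=alpha, beta=beta, target_neighbors=self.target_neighbors)
        self.gate_config_ = GateConfig(
            layer_dims=(expr.n_genes, *tuple(self.hidden_dims), self.n_latent),
            activation=self.activation,
            attention_activation=self.attention_activation,
            tie_decoder_weights=self.tie_decoder_weights,
            self_attention=self.self_attention,
            seed=self.random_state)
        self.train_config_ = trainer.TrainConfig(
            epochs=self.epochs, learning_rate=self.learning_rate,
            weight_decay=self.weight_decay, lambda_=self.lambda_rec,
            mu=self.mu_contrastive, gamma=self.gamma_spatial,
            seed=self.random_state, ablation=self.ablation,
            negatives_per_spot=self.negatives_per_spot,
            fixed_corruption=self.fixed_corruption)
        self.graph_ = graph
        self.expr_ = expr
        self.state_, emb = trainer.train(expr, coords, graph,
                                         self.gate_config_, self.train_config_)
        self.embedding_set_ = emb
        self.embeddings_ = emb.embeddings
        self.summary_ = emb.summary
        self.loss_trace_ = self.state_.loss_trace
        return self

    def transform(self, X=None) -> np.ndarray:
        """Latent embeddings of the fitted spots (transductive)."""
        check_is_fitted(self, "state_")
        if X is None or X is self.expr_:
            return self.embeddings_
        expr = _as_expr(X)
        if not np.array_equal(expr.values, self.expr_.values):
            raise ValueError("transform is transductive: pass the fitted matrix or None")
        return self.embeddings_

    def inverse_transform(self, X=None) -> np.ndarray:
        """Decoder reconstruction of the fitted spots (denoised expression)."""
        check_is_fitted(self, "state_")
        return cluster_downstream.denoise(self.state_, self.expr_, self.graph_,
                                          self.gate_config_)

    def fit_transform(self, X, y=None, **fit_params) -> np.ndarray:
        return self.fit(X, y, **fit_params).transform()


class DomainClusterer(ClusterMixin, BaseEstimator):
    """Model-based clustering of embeddings into spatial domains."""

    def __init__(self, n_domains=4, method="gmm", pca_components=20, random_state=0):
        self.n_domains = n_domains
        self.method = method
        self.pca_components = pca_components
        self.random_state = random_state

    def fit(self, X, y=None):
        X = check_array(X, dtype=np.float64)
        emb = EmbeddingSet(X, spot_ids=[f"spot_{i}" for i in range(X.shape[0])])
        self.domain_labels_ = cluster_downstream.cluster_embeddings(
            emb, self.n_domains, method=self.method, seed=self.random_state,
            pca_components=self.pca_components)
        self.labels_ = self.domain_labels_.labels
        return self

    def fit_predict(self, X, y=None) -> np.ndarray:
        return self.fit(X, y).labels_


def identify_domains(X, coords, n_domains: int, *, method: str = "gmm",
                     random_state: int = 0,
                     **autoencoder_params) -> tuple[DomainLabels, SpatialGraphAutoencoder]:
    """End-to-end convenience: train the auto-encoder, cluster the latents."""
    model = SpatialGraphAutoencoder(random_state=random_state, **autoencoder_params)
    emb = model.fit_transform(X, coords=coords)
    clusterer = DomainClusterer(n_domains=n_domains, method=method,
                                random_state=random_state)
    clusterer.fit(emb)
    labels = DomainLabels(clusterer.labels_, n_domains, model.expr_.spot_ids)
    return labels, model
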