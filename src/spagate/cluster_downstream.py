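"""Domain assignment from embeddings, clustering metrics, and denoising.

The default clusterer is a full-covariance Gaussian mixture on (a PCA
of) the latent embeddings — the model-based clustering family the field
uses for spatial domains.  An optional bridge delegates to the reference
R ``mclust`` implementation (EEE model) through ``Rscript`` when it is
available.  Denoised expression is simply the trained decoder's
reconstruction.
"""

from __future__ import annotations

import json
import shutil
import subprocess
import tempfile
from pathlib import Path

import numpy as np

from . import gate_model
from .gate_model import EmbeddingSet, GateConfig
from .hybrid_graph import HybridNeighborGraph
from .io_preprocess import ExpressionMatrix
from .synthetic_data import DomainLabels
from .trainer import TrainState

__all__ = ["DomainLabels", "cluster_embeddings", "score_clustering",
           "internal_scores", "denoise", "mclust_available"]

#: latent spaces wider than this are PCA-reduced before mixture fitting
PCA_COMPONENTS = 20


def _maybe_pca(x: np.ndarray, n_components: int | None, seed: int) -> np.ndarray:
    if n_components is None or x.shape[1] <= n_components:
        return x
    from sklearn.decomposition import PCA

    return PCA(n_components=n_components, random_state=seed).fit_transform(x)


def mclust_available() -> bool:
    if shutil.which("Rscript") is None:
        return False
    try:
        r = subprocess.run(["Rscript", "-e", "suppressMessages(library(mclust))"],
                           capture_output=True, timeout=120)
        return r.returncode == 0
    except (OSError, subprocess.TimeoutExpired):
        return False


def _mclust_labels(x: np.ndarray, n_domains: int, seed: int) -> np.ndarray:
    if not mclust_available():
        raise RuntimeError("mclust bridge unavailable (needs Rscript + the mclust "
                           "package); fall back to method='gmm'")
    with tempfile.TemporaryDirectory() as tmp:
        data = Path(tmp) / "emb.csv"
        out = Path(tmp) / "labels.csv"
        np.savetxt(data, x, delimiter=",")
        script = (
            f"set.seed({seed}); suppressMessages(library(mclust));"
            f"x <- as.matrix(read.csv('{data}', header=FALSE));"
            f"fit <- Mclust(x, G={n_domains}, modelNames='EEE', verbose=FALSE);"
            f"write.csv(data.frame(label=fit$classification), '{out}', row.names=FALSE)"
        )
        r = subprocess.run(["Rscript", "-e", script], capture_output=True, text=True)
        if r.returncode != 0:
            raise RuntimeError(f"mclust bridge failed: {r.stderr.strip()[-500:]}")
        labels = np.loadtxt(out, delimiter=",", skiprows=1, dtype=float).astype(int)
    return labels - labels.min()  # mclust labels are 1-based


def cluster_embeddings(emb: EmbeddingSet, n_domains: int, method: str = "gmm",
                       seed: int = 0, pca_components: int | None = PCA_COMPONENTS) -> DomainLabels:
    """Model-based clustering of the latent embeddings into domains.

    ``gmm``: full-covariance Gaussian mixture, best of 10 initializations
    by log-likelihood.  ``mclust_bridge``: the reference R implementation
    (EEE model) via Rscript.
    """
    x = emb.embeddings
    n = x.shape[0]
    if n_domains > n:
        raise ValueError(f"n_domains={n_domains} exceeds the number of spots {n}")
    if n_domains < 1:
        raise ValueError("n_domains must be >= 1")
    x = _maybe_pca(x, pca_components, seed)
    if method == "gmm":
        from sklearn.mixture import GaussianMixture

        gm = GaussianMixture(n_components=n_domains, covariance_type="full",
                             n_init=10, random_state=seed)
        labels = gm.fit_predict(x)
    elif method == "mclust_bridge":
        labels = _mclust_labels(x, n_domains, seed)
    else:
        raise ValueError(f"unknown method {method!r}")
    return DomainLabels(np.asarray(labels, int), n_domains, list(emb.spot_ids))


def score_clustering(pred: DomainLabels, truth: DomainLabels) -> tuple[float, float]:
    """(ARI, NMI) of a predicted partition against ground truth."""
    from sklearn.metrics import adjusted_rand_score, normalized_mutual_info_score

    if pred.labels.size != truth.labels.size:
        raise ValueError("label vectors have different lengths")
    return (float(adjusted_rand_score(truth.labels, pred.labels)),
            float(normalized_mutual_info_score(truth.labels, pred.labels)))


def internal_scores(emb: EmbeddingSet, pred: DomainLabels) -> tuple[float, float]:
    """(Davies-Bouldin index, cophenetic correlation coefficient).

    DB needs at least two populated domains.  CCC correlates the pairwise
    embedding distances with the cophenetic distances of an
    average-linkage hierarchy over the embeddings.
    """
    from scipy.cluster.hierarchy import average, cophenet
    from scipy.spatial.distance import pdist
    from sklearn.metrics import davies_bouldin_score

    if len(np.unique(pred.labels)) < 2:
        raise ValueError("Davies-Bouldin is undefined for a single domain")
    db = float(davies_bouldin_score(emb.embeddings, pred.labels))
    d = pdist(emb.embeddings)
    ccc, _ = cophenet(average(d), d)
    return db, float(ccc)


def denoise(state: TrainState, expr: ExpressionMatrix, graph: HybridNeighborGraph,
            gate_config: GateConfig) -> np.ndarray:
    """Decoder reconstruction as the enhanced (noise-reduced) expression."""
    emb = gate_model.encode(expr, graph, state.params, gate_config)
    return gate_model.decode(emb, graph, state.params, gate_config)


def write_labels_csv(labels: DomainLabels, path: str) -> None:
    with open(path, "w") as fh:
        fh.write("spot_id,domain\n")
        for s, l in zip(labels.spot_ids, labels.labels):
            fh.write(f"{s},{int(l)}\n")


def read_labels_csv(path: str) -> DomainLabels:
    import pandas as pd

    df = pd.read_csv(path)
    labels = df["domain"].to_numpy(int)
    return DomainLabels(labels, int(labels.max()) + 1, df["spot_id"].astype(str).tolist())


def metrics_json(**metrics: float) -> str:
    return json.dumps({k: (float(v) if v is not None else None)
                       for k, v in metrics.items()})
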