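"""Readers and preprocessing for spot-level spatial expression data.

Accepted containers: AnnData ``.h5ad`` (matrix in ``X``, coordinates in
``obsm["spatial"]``), 10x-style MatrixMarket triplets plus a coordinate
CSV, and plain dense CSV matrices for small fixtures.  Preprocessing
follows the standard spatial-clustering recipe: keep the top highly
variable genes (ranked by binned normalized dispersion on the raw
matrix), scale each spot to a common library size, then log(1+x).
"""

from __future__ import annotations

import logging
import os
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

logger = logging.getLogger(__name__)

#: per-spot total after library-size normalization
TARGET_TOTAL = 10_000.0


@dataclass
class ExpressionMatrix:
    """N spots x M genes expression values with aligned identifiers."""

    values: np.ndarray
    spot_ids: list[str]
    gene_ids: list[str]

    def __post_init__(self):
        self.values = np.asarray(self.values, dtype=np.float64)
        self.spot_ids = [str(s) for s in self.spot_ids]
        self.gene_ids = [str(g) for g in self.gene_ids]
        self.validate()

    def validate(self) -> None:
        if self.values.ndim != 2:
            raise ValueError("expression matrix must be 2-D")
        n, m = self.values.shape
        if len(self.spot_ids) != n:
            raise ValueError(f"{len(self.spot_ids)} spot ids for {n} rows")
        if len(self.gene_ids) != m:
            raise ValueError(f"{len(self.gene_ids)} gene ids for {m} columns")
        if len(set(self.spot_ids)) != n:
            raise ValueError("duplicate spot ids")
        if len(set(self.gene_ids)) != m:
            raise ValueError("duplicate gene ids")
        if not np.all(np.isfinite(self.values)):
            raise ValueError("expression matrix contains NaN/Inf")

    @property
    def n_spots(self) -> int:
        return self.values.shape[0]

    @property
    def n_genes(self) -> int:
        return self.values.shape[1]


@dataclass
class SpatialCoords:
    """N x 2 planar coordinates, rows aligned with an ExpressionMatrix."""

    coords: np.ndarray
    spot_ids: list[str] = field(default_factory=list)

    def __post_init__(self):
        self.coords = np.asarray(self.coords, dtype=np.float64)
        self.spot_ids = [str(s) for s in self.spot_ids]
        if self.coords.ndim != 2 or self.coords.shape[1] != 2:
            raise ValueError("coordinates must be N x 2")
        if not np.all(np.isfinite(self.coords)):
            raise ValueError("coordinates contain NaN/Inf")
        if self.spot_ids and len(self.spot_ids) != self.coords.shape[0]:
            raise ValueError("spot_ids length mismatch")

    @property
    def n_spots(self) -> int:
        return self.coords.shape[0]


# ----------------------------------------------------------------------
# readers
# ----------------------------------------------------------------------

def _align(expr: ExpressionMatrix, coords: SpatialCoords) -> tuple[ExpressionMatrix, SpatialCoords]:
    """Intersect spots present in both inputs, preserving expression order."""
    coord_index = {s: i for i, s in enumerate(coords.spot_ids)}
    keep = [i for i, s in enumerate(expr.spot_ids) if s in coord_index]
    dropped = expr.n_spots - len(keep) + (coords.n_spots - len(keep))
    if dropped:
        logger.warning("dropping %d spot(s) present in only one of expression/coordinates", dropped)
    ids = [expr.spot_ids[i] for i in keep]
    expr2 = ExpressionMatrix(expr.values[keep], ids, expr.gene_ids)
    coords2 = SpatialCoords(coords.coords[[coord_index[s] for s in ids]], ids)
    return expr2, coords2


def _read_coords_csv(path: str) -> SpatialCoords:
    df = pd.read_csv(path)
    required = {"spot_id", "x", "y"}
    if not required.issubset(df.columns):
        raise ValueError(f"coordinates CSV {path} must have header spot_id,x,y")
    return SpatialCoords(df[["x", "y"]].to_numpy(float), df["spot_id"].astype(str).tolist())


def read_dataset(path: str, format: str | None = None, *,
                 coords_path: str | None = None) -> tuple[ExpressionMatrix, SpatialCoords]:
    """Read an expression matrix and spatial coordinates from disk.

    Parameters
    ----------
    path
        ``.h5ad`` file, MTX-triplet directory, or dense matrix CSV.
    format
        One of ``h5ad``, ``mtx_triplet``, ``csv``; inferred from ``path``
        when omitted.
    coords_path
        Required for ``mtx_triplet`` and ``csv``: CSV with header
        ``spot_id,x,y``.
    """
    if format is None:
        if str(path).endswith(".h5ad"):
            format = "h5ad"
        elif os.path.isdir(path):
            format = "mtx_triplet"
        else:
            format = "csv"

    if format == "h5ad":
        import anndata as ad

        adata = ad.read_h5ad(path)
        if "spatial" not in adata.obsm:
            raise ValueError(
                f"{path}: missing spatial coordinates (expected obsm['spatial'])")
        X = adata.X
        if not isinstance(X, np.ndarray):
            X = X.toarray()
        expr = ExpressionMatrix(np.asarray(X, float), list(adata.obs_names), list(adata.var_names))
        coords = SpatialCoords(np.asarray(adata.obsm["spatial"], float), list(adata.obs_names))
        return expr, coords

    if format == "mtx_triplet":
        from scipy.io import mmread

        if coords_path is None:
            raise ValueError("mtx_triplet requires coords_path (CSV with spot_id,x,y)")

        def _find(name):
            for cand in (name, name + ".gz"):
                p = os.path.join(path, cand)
                if os.path.exists(p):
                    return p
            raise FileNotFoundError(f"{path}: expected {name}[.gz]")

        mat = mmread(_find("matrix.mtx")).toarray()  # genes x spots, 10x layout
        barcodes = pd.read_csv(_find("barcodes.tsv"), sep="\t", header=None)[0].astype(str).tolist()
        feat = pd.read_csv(_find("features.tsv"), sep="\t", header=None)
        genes = feat[0].astype(str).tolist()
        expr = ExpressionMatrix(mat.T.astype(float), barcodes, genes)
        return _align(expr, _read_coords_csv(coords_path))

    if format == "csv":
        if coords_path is None:
            raise ValueError("csv format requires coords_path (CSV with spot_id,x,y)")
        df = pd.read_csv(path, index_col=0)
        try:
            values = df.to_numpy(dtype=float)
        except ValueError as e:
            raise ValueError(f"{path}: non-numeric matrix entries ({e})") from None
        expr = ExpressionMatrix(values, df.index.astype(str).tolist(),
                                df.columns.astype(str).tolist())
        return _align(expr, _read_coords_csv(coords_path))

    raise ValueError(f"unknown format {format!r}")


# ----------------------------------------------------------------------
# preprocessing
# ----------------------------------------------------------------------

def _normalized_dispersion(values: np.ndarray, n_bins: int = 20) -> np.ndarray:
    """Seurat-style dispersion: var/mean, z-scored within mean bins."""
    mean = values.mean(axis=0)
    var = values.var(axis=0)
    with np.errstate(divide="ignore", invalid="ignore"):
        disp = np.where(mean > 0, var / mean, 0.0)
    order = np.argsort(mean)
    bins = np.array_split(order, n_bins)
    z = np.zeros_like(disp)
    for b in bins:
        if len(b) == 0:
            continue
        d = disp[b]
        sd = d.std()
        z[b] = (d - d.mean()) / sd if sd > 0 else 0.0
    return z


def select_hvg(expr: ExpressionMatrix, n_hvg: int) -> ExpressionMatrix:
    """Keep the top ``n_hvg`` highly variable genes, preserving gene order."""
    if expr.n_genes <= n_hvg:
        logger.warning("requested %d HVGs but matrix has only %d genes; keeping all",
                       n_hvg, expr.n_genes)
        return expr
    z = _normalized_dispersion(expr.values)
    top = np.sort(np.argsort(-z, kind="stable")[:n_hvg])
    return ExpressionMatrix(expr.values[:, top],
                            expr.spot_ids,
                            [expr.gene_ids[i] for i in top])


def preprocess(expr: ExpressionMatrix, n_hvg: int = 3000,
               target_total: float = TARGET_TOTAL) -> ExpressionMatrix:
    """HVG selection, per-spot library-size normalization, log1p.

    Spots with zero total counts are dropped (their normalization is
    undefined).  Gene order is preserved.
    """
    if np.any(expr.values < 0):
        raise ValueError("expression values must be non-negative before log transform")
    sub = select_hvg(expr, n_hvg)
    totals = sub.values.sum(axis=1)
    keep = totals > 0
    if not np.all(keep):
        logger.warning("dropping %d spot(s) with zero total counts", int((~keep).sum()))
    vals = sub.values[keep]
    totals = totals[keep][:, None]
    vals = np.log1p(vals / totals * target_total)
    return ExpressionMatrix(vals, [s for s, k in zip(sub.spot_ids, keep) if k], sub.gene_ids)
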