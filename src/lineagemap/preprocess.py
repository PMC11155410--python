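"""Quality control, normalization, clustering and pseudobulk aggregation.

Counts live in an AnnData (cells x genes, sparse integers). QC follows the
standard scRNA-seq recipe with strict boundaries: cells with fewer than 200
detected genes or more than 15% mitochondrial counts are removed (cells
first), then genes detected in fewer than 3 cells. Normalization is
counts-per-``scale`` followed by log1p. Clustering is PCA on standardized
genes plus a kNN graph and Leiden community detection (via scanpy), with a
fixed seed. Pseudobulk profiles are per-cluster means of the normalized
expression.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Sequence

import anndata as ad
import numpy as np
import pandas as pd
import scanpy as sc
from scipy import sparse


class MissingMitoFlagsError(ValueError):
    pass


@dataclass
class QCReport:
    n_cells_in: int
    n_cells_out: int
    n_genes_in: int
    n_genes_out: int
    detected_genes: pd.Series | None = None  # per input cell
    mito_fraction: pd.Series | None = None

    def to_dict(self) -> dict:
        return {
            "n_cells_in": self.n_cells_in,
            "n_cells_out": self.n_cells_out,
            "n_genes_in": self.n_genes_in,
            "n_genes_out": self.n_genes_out,
        }


@dataclass
class PseudobulkMatrix:
    """Genes x profiles mean-expression table with profile provenance."""

    values: pd.DataFrame  # genes x profiles
    profile_meta: pd.DataFrame  # index: profile id; columns: origin_kind, label, n_cells

    @property
    def n_profiles(self) -> int:
        return self.values.shape[1]

    def concat(self, other: "PseudobulkMatrix") -> "PseudobulkMatrix":
        if not self.values.index.equals(other.values.index):
            raise ValueError("pseudobulk matrices must share an identical gene set")
        return PseudobulkMatrix(
            values=pd.concat([self.values, other.values], axis=1),
            profile_meta=pd.concat([self.profile_meta, other.profile_meta], axis=0),
        )


def _ensure_mito(adata: ad.AnnData) -> np.ndarray:
    if "mt" in adata.var:
        return adata.var["mt"].to_numpy(dtype=bool)
    flags = np.asarray(adata.var_names.str.startswith("MT-"))
    if not flags.any() and adata.n_vars > 0:
        raise MissingMitoFlagsError(
            "no 'mt' flags in var and no 'MT-' prefixed genes; "
            "set adata.var['mt'] explicitly"
        )
    return flags


def qc_filter_cells(
    adata: ad.AnnData,
    min_genes: int = 200,
    max_mito: float = 0.15,
    blocklist: Sequence[str] | None = None,
) -> tuple[ad.AnnData, QCReport]:
    """Remove cells with < ``min_genes`` detected genes or > ``max_mito``
    mitochondrial count fraction (both boundaries kept).

    ``blocklist`` removes named cells explicitly, standing in for the
    judgment-based removal of contaminating clusters and doublets.
    """
    if adata.n_obs == 0:
        return adata.copy(), QCReport(0, 0, adata.n_vars, adata.n_vars)
    mt = _ensure_mito(adata)
    X = sparse.csr_matrix(adata.X)
    detected = np.asarray((X > 0).sum(axis=1)).ravel()
    totals = np.asarray(X.sum(axis=1)).ravel()
    mito_counts = np.asarray(X[:, mt].sum(axis=1)).ravel() if mt.any() else np.zeros_like(totals)
    with np.errstate(invalid="ignore", divide="ignore"):
        mito_frac = np.where(totals > 0, mito_counts / np.maximum(totals, 1), 0.0)
    keep = (detected >= min_genes) & (mito_frac <= max_mito)
    if blocklist:
        keep &= ~adata.obs_names.isin(list(blocklist))
    out = adata[keep].copy()
    report = QCReport(
        n_cells_in=adata.n_obs,
        n_cells_out=out.n_obs,
        n_genes_in=adata.n_vars,
        n_genes_out=adata.n_vars,
        detected_genes=pd.Series(detected, index=adata.obs_names),
        mito_fraction=pd.Series(mito_frac, index=adata.obs_names),
    )
    return out, report


def qc_filter_genes(adata: ad.AnnData, min_cells: int = 3) -> tuple[ad.AnnData, QCReport]:
    """Remove genes detected (nonzero) in fewer than ``min_cells`` cells."""
    if adata.n_vars == 0:
        return adata.copy(), QCReport(adata.n_obs, adata.n_obs, 0, 0)
    X = sparse.csr_matrix(adata.X)
    n_cells_per_gene = np.asarray((X > 0).sum(axis=0)).ravel()
    keep = n_cells_per_gene >= min_cells
    out = adata[:, keep].copy()
    report = QCReport(
        n_cells_in=adata.n_obs,
        n_cells_out=adata.n_obs,
        n_genes_in=adata.n_vars,
        n_genes_out=out.n_vars,
    )
    return out, report


def normalize_log(adata: ad.AnnData, scale: float = 1e4) -> pd.DataFrame:
    """log1p of counts-per-``scale`` per cell, returned as cells x genes."""
    X = sparse.csr_matrix(adata.X).astype(float)
    totals = np.asarray(X.sum(axis=1)).ravel()
    if np.any(totals == 0):
        bad = adata.obs_names[totals == 0].tolist()
        raise ValueError(f"cells with zero total count cannot be normalized: {bad[:5]}")
    X = X.multiply(scale / totals[:, None]).tocsr()
    X.data = np.log1p(X.data)
    return pd.DataFrame(
        X.toarray(), index=adata.obs_names.copy(), columns=adata.var_names.copy()
    )


def normalize_total(adata: ad.AnnData, scale: float = 1e4) -> pd.DataFrame:
    """Linear counts-per-``scale`` normalization (no log); used for the
    deconvolution signature basis, which operates on a linear scale."""
    X = sparse.csr_matrix(adata.X).astype(float)
    totals = np.asarray(X.sum(axis=1)).ravel()
    if np.any(totals == 0):
        raise ValueError("cells with zero total count cannot be normalized")
    X = X.multiply(scale / totals[:, None]).tocsr()
    return pd.DataFrame(
        X.toarray(), index=adata.obs_names.copy(), columns=adata.var_names.copy()
    )


def cluster_cells(
    expr: pd.DataFrame,
    n_pcs: int = 15,
    resolution: float = 1.0,
    n_neighbors: int = 15,
    seed: int = 0,
) -> pd.Series:
    """Leiden clustering on a kNN graph over the top principal components.

    Genes are standardized before PCA. Labels are contiguous integers,
    deterministic for a fixed seed.
    """
    n_cells, n_genes = expr.shape
    if n_cells < 2:
        raise ValueError("clustering requires at least 2 cells")
    if n_pcs >= min(n_cells, n_genes):
        raise ValueError(
            f"n_pcs={n_pcs} must be below min(n_cells, n_genes)={min(n_cells, n_genes)}"
        )
    X = expr.to_numpy(copy=True)
    if np.allclose(X, X[0]):  # identical cells: one community by definition
        return pd.Series(0, index=expr.index, name="cluster")
    adata = ad.AnnData(X=X)
    adata.obs_names = expr.index.astype(str)
    adata.var_names = expr.columns.astype(str)
    sc.pp.scale(adata, zero_center=True)
    sc.tl.pca(adata, n_comps=n_pcs, svd_solver="arpack", random_state=seed)
    sc.pp.neighbors(adata, n_neighbors=min(n_neighbors, n_cells - 1), n_pcs=n_pcs,
                    random_state=seed)
    sc.tl.leiden(
        adata,
        resolution=resolution,
        random_state=seed,
        flavor="igraph",
        n_iterations=2,
        directed=False,
    )
    labels = adata.obs["leiden"].astype(int)
    # contiguous relabel in order of first appearance
    uniq = pd.unique(labels)
    remap = {u: i for i, u in enumerate(sorted(uniq))}
    return pd.Series([remap[v] for v in labels], index=expr.index, name="cluster")


def aggregate_pseudobulk(
    expr: pd.DataFrame,
    labels: pd.Series,
    origin_kind: str = "tumor_cluster",
    label_prefix: str = "",
) -> PseudobulkMatrix:
    """Mean expression per label, genes x profiles, with provenance."""
    labels = labels.reindex(expr.index)
    if labels.isna().any():
        raise ValueError("every cell needs a label")
    if len(labels) == 0:
        raise ValueError("empty label set")
    profiles, meta = {}, []
    for lab, idx in expr.groupby(labels, observed=True).groups.items():
        pid = f"{label_prefix}{lab}"
        profiles[pid] = expr.loc[idx].mean(axis=0)
        meta.append({"profile": pid, "origin_kind": origin_kind,
                     "label": str(lab), "n_cells": len(idx)})
    values = pd.DataFrame(profiles)
    values.index.name = "gene"
    profile_meta = pd.DataFrame(meta).set_index("profile")
    return PseudobulkMatrix(values=values, profile_meta=profile_meta)
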