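"""Readers and writers for the pipeline's on-disk formats.

Counts travel as MatrixMarket MTX (genes x cells, 1-based indices) with
``genes.tsv`` (gene, chromosome, start) and ``cells.tsv`` (cell, subset,
lineage, compartment) sidecars; bulk matrices and pseudobulk profiles as
CSV; rankings as two-column TSV; gene sets as GMT (see ``scoring``).
"""

from __future__ import annotations

import json
from pathlib import Path

import anndata as ad
import numpy as np
import pandas as pd
from scipy import io as spio
from scipy import sparse

from .preprocess import PseudobulkMatrix
from .synthetic import OmicsRanking, SyntheticCohort


def write_cohort(cohort: SyntheticCohort, outdir: str | Path) -> None:
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    adata = cohort.counts
    # genes x cells per the MTX convention
    spio.mmwrite(outdir / "matrix.mtx", sparse.csr_matrix(adata.X).T.astype(int))
    genes = adata.var[["chromosome", "start"]].copy()
    genes.insert(0, "gene", adata.var_names)
    genes.to_csv(outdir / "genes.tsv", sep="\t", index=False)
    cells = pd.DataFrame(
        {
            "cell": adata.obs_names,
            "subset": adata.obs["subset"].to_numpy(),
            "lineage": adata.obs["lineage"].to_numpy(),
            "sample": adata.obs["sample"].to_numpy(),
            "compartment": adata.obs["compartment"].to_numpy(),
        }
    )
    cells.to_csv(outdir / "cells.tsv", sep="\t", index=False)


def read_cohort(outdir: str | Path) -> ad.AnnData:
    outdir = Path(outdir)
    X = sparse.csr_matrix(spio.mmread(outdir / "matrix.mtx")).T  # cells x genes
    genes = pd.read_csv(outdir / "genes.tsv", sep="\t").set_index("gene")
    cells = pd.read_csv(outdir / "cells.tsv", sep="\t").set_index("cell")
    adata = ad.AnnData(X=X.astype(np.int32), obs=cells, var=genes)
    adata.var["mt"] = adata.var_names.str.startswith("MT-")
    return adata


def write_pseudobulk(pb: PseudobulkMatrix, path: str | Path, meta_path: str | Path | None = None) -> None:
    pb.values.to_csv(path)
    if meta_path is not None:
        pb.profile_meta.to_csv(meta_path)


def read_pseudobulk(path: str | Path, meta_path: str | Path | None = None) -> PseudobulkMatrix:
    values = pd.read_csv(path, index_col=0)
    if meta_path is not None:
        meta = pd.read_csv(meta_path, index_col=0)
    else:
        meta = pd.DataFrame(
            {"origin_kind": "unknown", "label": values.columns, "n_cells": 1},
            index=values.columns,
        )
    return PseudobulkMatrix(values=values, profile_meta=meta)


def read_ranking(path: str | Path, name: str | None = None) -> OmicsRanking:
    """TSV with columns (gene, rank): smaller rank = stronger evidence."""
    df = pd.read_csv(path, sep="\t")
    gene_col, rank_col = df.columns[:2]
    df = df.sort_values([rank_col, gene_col], kind="stable")
    return OmicsRanking(name=name or Path(path).stem, genes=df[gene_col].tolist())


def write_ranking(ranking: OmicsRanking, path: str | Path) -> None:
    pd.DataFrame(
        {"gene": ranking.genes, "rank": np.arange(1, len(ranking.genes) + 1)}
    ).to_csv(path, sep="\t", index=False)


def write_json(obj, path: str | Path) -> None:
    with open(path, "w") as fh:
        json.dump(obj, fh, indent=2, sort_keys=True, default=str)
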