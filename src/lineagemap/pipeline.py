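"""End-to-end orchestration: simulate -> preprocess -> project -> deconvolve
-> score -> cnv -> rank, with a reproducibility manifest.

Every stage consumes the previous stage's in-memory objects; ``run_all``
additionally writes each stage's outputs to disk and records parameter
values, seeds and output checksums in ``manifest.json`` so a run can be
reproduced bit-exactly.
"""

from __future__ import annotations

import hashlib
import json
import logging
from dataclasses import asdict, dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from . import cnv as cnv_mod
from . import deconvolution as dec
from . import io as lio
from . import preprocess as pp
from . import projection as proj
from . import ranking as rk
from . import scoring as sco
from .synthetic import (
    BulkCohort,
    GeneratorConfig,
    SyntheticCohort,
    make_bulk_mixtures,
    make_multiomics_rankings,
    make_normal_cells,
    make_tumor_cells,
)

log = logging.getLogger("lineagemap")


@dataclass
class PipelineConfig:
    """Stage parameters; defaults are the analysis' standard constants."""

    generator: GeneratorConfig = field(default_factory=GeneratorConfig)
    min_genes: int = 200
    max_mito: float = 0.15
    min_cells: int = 3
    n_pcs: int = 15
    tumor_resolution: float = 1.0
    subset_marker_top_n: int = 100
    variable_top_frac: float = 0.01
    lineage_marker_top_n: int = 150
    lp_marker_top_n: int = 100
    subpop_top_n: int = 50
    ks_weight: float = 0.25
    dominance: float = 0.5
    cnv_window: int = 101
    de_quartile: float = 0.25
    alpha: float = 0.05
    n_top_candidates: int = 10
    n_planted_targets: int = 15
    seed: int = 0

    @classmethod
    def from_json(cls, path: str | Path) -> "PipelineConfig":
        with open(path) as fh:
            raw = json.load(fh)
        gen = GeneratorConfig(**raw.pop("generator", {}))
        return cls(generator=gen, **raw)


@dataclass
class PipelineResult:
    normal: SyntheticCohort
    tumor: SyntheticCohort
    bulk: BulkCohort
    normal_expr: pd.DataFrame
    tumor_expr: pd.DataFrame
    normal_pseudobulk: pp.PseudobulkMatrix
    tumor_pseudobulk: pp.PseudobulkMatrix
    tumor_clusters: pd.Series
    meta_genes: proj.MetaGeneSet
    origin: proj.OriginAssignment
    cell_origins: pd.Series
    sample_subtypes: pd.Series
    basis: dec.SignatureBasis
    proportions: dec.BulkProportions
    lp_result: sco.LPScoreResult
    cnv_scores: pd.Series
    de_table: pd.DataFrame
    rankings: list
    rank_scores: pd.Series
    top_candidates: list[str]


def simulate(config: PipelineConfig):
    log.info("simulate: seed=%d", config.generator.seed)
    normal = make_normal_cells(config.generator)
    tumor = make_tumor_cells(config.generator, normal)
    bulk = make_bulk_mixtures(config.generator, normal)
    return normal, tumor, bulk


def preprocess_cohort(adata, config: PipelineConfig):
    filtered, cell_report = pp.qc_filter_cells(
        adata, min_genes=config.min_genes, max_mito=config.max_mito
    )
    filtered, gene_report = pp.qc_filter_genes(filtered, min_cells=config.min_cells)
    expr = pp.normalize_log(filtered)
    return filtered, expr, cell_report, gene_report


def run_all(config: PipelineConfig, outdir: str | Path | None = None) -> PipelineResult:
    rng_seed = config.seed
    normal, tumor, bulk = simulate(config)

    # --- preprocess -------------------------------------------------------
    normal_f, normal_expr, nc_rep, ng_rep = preprocess_cohort(normal.counts, config)
    tumor_f, tumor_expr, tc_rep, tg_rep = preprocess_cohort(tumor.counts, config)
    log.info(
        "preprocess: normal %d->%d cells, tumor %d->%d cells",
        nc_rep.n_cells_in, nc_rep.n_cells_out, tc_rep.n_cells_in, tc_rep.n_cells_out,
    )
    shared = normal_expr.columns.intersection(tumor_expr.columns)
    normal_expr, tumor_expr = normal_expr[shared], tumor_expr[shared]

    normal_subsets = normal_f.obs["subset"]
    normal_pb = pp.aggregate_pseudobulk(
        normal_expr, normal_subsets, origin_kind="normal_subset", label_prefix="normal:"
    )
    lin_of = {s: l for s, l in zip(normal_f.obs["subset"], normal_f.obs["lineage"])}
    normal_pb.profile_meta["lineage"] = normal_pb.profile_meta["label"].map(lin_of)

    tumor_clusters = pp.cluster_cells(
        tumor_expr, n_pcs=config.n_pcs, resolution=config.tumor_resolution,
        seed=rng_seed,
    )
    tumor_pb = pp.aggregate_pseudobulk(
        tumor_expr, tumor_clusters, origin_kind="tumor_cluster", label_prefix="tumor:"
    )

    # --- projection -------------------------------------------------------
    markers = proj.select_subset_markers(
        normal_expr, normal_subsets, top_n=config.subset_marker_top_n
    )
    variable = proj.select_variable_genes(tumor_pb, top_frac=config.variable_top_frac)
    meta_genes = proj.intersect_meta_genes(markers, variable)
    combined = proj.combine_and_correct(tumor_pb, normal_pb, meta_genes)
    origin = proj.cluster_major_groups(combined, k=3)
    tumor_profile_groups = origin.profile_group[tumor_pb.values.columns]
    cell_origins = proj.propagate_cell_origins(
        tumor_clusters, tumor_profile_groups, label_prefix="tumor:"
    )
    sample_subtypes = proj.assign_sample_subtype(
        cell_origins, tumor_f.obs["sample"], dominance=config.dominance
    )
    log.info("projection: %d meta-genes, subtypes %s",
             meta_genes.n_intersection, sample_subtypes.value_counts().to_dict())

    # --- deconvolution ----------------------------------------------------
    # per-sample lineage cell fractions from the projected origins
    frac = (
        pd.crosstab(tumor_f.obs["sample"], cell_origins, normalize="index")
        .reindex(columns=list(dec.LINEAGES), fill_value=0.0)
    )
    sample_expr = pp.aggregate_pseudobulk(
        tumor_expr, tumor_f.obs["sample"], origin_kind="tumor_sample"
    ).values
    coords = dec.compute_origin_correlations(sample_expr, frac)
    distances = dec.compute_D_distances(coords)
    marker_sets = dec.select_lineage_markers(
        coords, distances, top_n=config.lineage_marker_top_n
    )
    normal_linear = pp.normalize_total(normal_f)
    basis = dec.build_signature_basis(
        marker_sets, normal_linear, normal_f.obs["lineage"]
    )
    proportions = dec.dwls_deconvolve(basis, bulk.expression, seed=rng_seed)
    dec.call_bulk_subtype(proportions, dominance=config.dominance)

    # --- LP scoring -------------------------------------------------------
    pos, neg = sco.lp_correlation_markers(
        bulk.expression, proportions.proportions["LP"], top_n=config.lp_marker_top_n
    )
    lp_result = sco.lp_score(bulk.expression, pos, neg, weight=config.ks_weight)

    # --- CNV instability --------------------------------------------------
    all_expr = pd.concat([normal_expr, tumor_expr], axis=0)
    profile = cnv_mod.infer_cnv_profile(
        all_expr,
        reference_cells=normal_expr.index.tolist(),
        gene_positions=tumor.gene_positions,
        window=config.cnv_window,
    )
    scores = cnv_mod.cnv_score(profile)
    tumor_scores = scores.loc[tumor_expr.index]
    lp_cells = cell_origins == "LP"
    de_table = cnv_mod.quartile_de(
        tumor_expr, tumor_scores, group_mask=lp_cells,
        q=config.de_quartile, alpha=config.alpha,
    )

    # --- rank aggregation -------------------------------------------------
    # layer 1: the computed single-cell DE screen; layers 2-3 emulate the
    # bulk copy-number correlation and perturbation-screen evidence with
    # planted rankings over the same universe
    sc_rank = rk.OmicsRanking(name="scRNA-DE", genes=de_table["gene"].tolist())
    measured = set(sc_rank.genes)
    planted: list[str] = []
    if tumor.true_cnv is not None:
        reg_genes = tumor.gene_positions.index[: tumor.true_cnv.shape[1]]
        amp = reg_genes[tumor.true_cnv.max(axis=0) > 1.0]
        planted = [g for g in amp if g in measured][: config.n_planted_targets]
    synth = make_multiomics_rankings(
        n_genes=config.generator.n_genes - config.generator.n_mito_genes,
        planted=planted,
        n_lists=2,
        seed=rng_seed,
    )
    synth[0].name, synth[1].name = "bulk-CNA-correlation", "perturb-screen"
    # restrict the synthetic layers to the measured universe
    for lst in synth:
        lst.genes = [g for g in lst.genes if g in measured]
    rankings = [sc_rank, *synth]
    common = rk.intersect_rankings(rankings)
    rank_scores = rk.rank_score(rankings, common)
    top = rk.top_candidates(rank_scores, k=min(config.n_top_candidates, len(common)))
    log.info("ranking: %d common genes, top candidates %s", len(common), top[:5])

    result = PipelineResult(
        normal=normal, tumor=tumor, bulk=bulk,
        normal_expr=normal_expr, tumor_expr=tumor_expr,
        normal_pseudobulk=normal_pb, tumor_pseudobulk=tumor_pb,
        tumor_clusters=tumor_clusters, meta_genes=meta_genes, origin=origin,
        cell_origins=cell_origins, sample_subtypes=sample_subtypes,
        basis=basis, proportions=proportions, lp_result=lp_result,
        cnv_scores=scores, de_table=de_table, rankings=rankings,
        rank_scores=rank_scores, top_candidates=top,
    )
    if outdir is not None:
        _write_outputs(result, config, Path(outdir),
                       qc_reports={
                           "normal_cells": nc_rep.to_dict(),
                           "normal_genes": ng_rep.to_dict(),
                           "tumor_cells": tc_rep.to_dict(),
                           "tumor_genes": tg_rep.to_dict(),
                       })
    return result


def _sha256(path: Path) -> str:
    h = hashlib.sha256()
    h.update(path.read_bytes())
    return h.hexdigest()


def _write_outputs(result: PipelineResult, config: PipelineConfig, outdir: Path,
                   qc_reports: dict) -> None:
    outdir.mkdir(parents=True, exist_ok=True)
    lio.write_cohort(result.normal, outdir / "normal")
    lio.write_cohort(result.tumor, outdir / "tumor")
    result.bulk.expression.to_csv(outdir / "bulk.csv")
    lio.write_json(
        {"true_proportions": result.bulk.true_proportions.to_dict(orient="index")},
        outdir / "truth.json",
    )
    lio.write_json(qc_reports, outdir / "qc_report.json")
    result.tumor_clusters.rename("cluster").to_csv(outdir / "tumor_clusters.tsv", sep="\t")
    lio.write_pseudobulk(result.normal_pseudobulk, outdir / "normal_pseudobulk.csv")
    lio.write_pseudobulk(result.tumor_pseudobulk, outdir / "tumor_pseudobulk.csv")
    pd.DataFrame(
        {"profile": result.origin.profile_group.index,
         "group": result.origin.profile_group.to_numpy()}
    ).to_csv(outdir / "assignments.csv", index=False)
    props = result.proportions.proportions.copy()
    props["subtype"] = result.proportions.subtype
    props.rename_axis("sample").to_csv(outdir / "proportions.csv")
    result.lp_result.to_frame().rename_axis("sample").to_csv(outdir / "lp_scores.csv")
    result.cnv_scores.rename_axis("cell").to_csv(outdir / "cnv_scores.csv")
    result.de_table.to_csv(outdir / "cnv_de_table.csv", index=False)
    pd.DataFrame({"gene": result.rank_scores.index,
                  "score": result.rank_scores.to_numpy()}).to_csv(
        outdir / "rank_scores.csv", index=False)

    manifest = {
        "parameters": {k: v for k, v in asdict(config).items() if k != "generator"},
        "generator": {k: (list(v) if isinstance(v, tuple) else v)
                      for k, v in asdict(config.generator).items()},
        "seeds": {"pipeline": config.seed, "generator": config.generator.seed},
        "outputs": {},
    }
    for f in sorted(outdir.rglob("*")):
        if f.is_file() and f.name != "manifest.json":
            manifest["outputs"][str(f.relative_to(outdir))] = _sha256(f)
    lio.write_json(manifest, outdir / "manifest.json")
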