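"""Synthetic single-cell / bulk cohorts with known ground truth.

The generator emulates the statistical structure the downstream analysis
assumes about the mammary epithelium: three lineages (basal-myoepithelial
``BM``, luminal progenitor ``LP``, mature luminal ``ML``) split into seven
minor subsets, each subset over-expressing a disjoint marker program on top
of a shared baseline; tumor cells drawn from the lineage programs with
planted copy-number segments; bulk samples that are known simplex mixtures
of the lineage mean-expression vectors; and concordant multi-omics gene
rankings with planted top candidates.

Counts follow a negative-binomial (gamma-Poisson) model parameterized by
mean and dispersion, with log-normal library-size variation. A fixed block
of ``MT-`` genes carries a Beta-distributed per-cell mitochondrial fraction
so that quality-control filters are exercisable. All randomness flows
through numpy Generators seeded from a single integer.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Mapping, Sequence

import anndata as ad
import numpy as np
import pandas as pd
from scipy import sparse

__all__ = [
    "GeneratorConfig",
    "SyntheticCohort",
    "BulkCohort",
    "OmicsRanking",
    "make_normal_cells",
    "make_tumor_cells",
    "make_bulk_mixtures",
    "make_multiomics_rankings",
]

LINEAGES = ("BM", "LP", "ML")

DEFAULT_SUBSET_MAP: dict[str, tuple[str, ...]] = {
    "BM": ("basal", "myoepithelial"),
    "LP": ("LTF_LP", "KRT23_LP"),
    "ML": ("AREG_ML", "TNFSF10_ML", "MUCL1_ML"),
}


class InvalidConfigError(ValueError):
    """Raised when a generator configuration violates its invariants."""


@dataclass
class GeneratorConfig:
    """Parameters of the synthetic cohort generator.

    Defaults define the study conditions used throughout the test suite:
    2,000 genes, seven epithelial subsets of 150 cells each, six-fold marker
    over-expression, 600 tumor cells with three planted copy-number segments
    in half of them, and 100 bulk mixtures.
    """

    n_genes: int = 2000
    n_marker_genes_per_subset: int = 25
    lineage_names: tuple[str, str, str] = LINEAGES
    subset_map: Mapping[str, tuple[str, ...]] = field(
        default_factory=lambda: dict(DEFAULT_SUBSET_MAP)
    )
    cells_per_subset: int = 150
    n_tumor_cells: int = 600
    n_tumor_samples: int = 8
    tumor_origin_fractions: tuple[float, float, float] = (0.3, 0.4, 0.3)
    nb_dispersion: float = 2.0
    marker_fold_change: float = 6.0
    # (chromosome, start gene index within chromosome, end index exclusive, copy ratio)
    # defaults plant arm-to-chromosome scale aneuploidy over ~18% of the genome,
    # the burden scale typical of chromosomally unstable breast tumors
    cnv_segments: list[tuple[str, int, int, float]] = field(
        default_factory=lambda: [
            ("chr1", 0, 85, 2.0),
            ("chr5", 0, 85, 0.5),
            ("chr8", 0, 50, 3.0),
            ("chr13", 0, 60, 1.5),
            ("chr17", 0, 70, 0.5),
        ]
    )
    cnv_clone_fraction: float = 0.5
    n_bulk_samples: int = 100
    bulk_noise_sd: float = 0.5
    n_mito_genes: int = 10
    mito_beta: tuple[float, float] = (2.0, 38.0)
    high_mito_fraction: float = 0.03
    library_size_log_sd: float = 0.3
    n_chromosomes: int = 22
    seed: int = 0

    def __post_init__(self) -> None:
        self.validate()

    def validate(self) -> None:
        numeric = [
            self.n_genes,
            self.n_marker_genes_per_subset,
            self.cells_per_subset,
            self.n_tumor_cells,
            self.nb_dispersion,
            self.marker_fold_change,
            self.n_bulk_samples,
            self.bulk_noise_sd,
            *self.tumor_origin_fractions,
        ]
        if not all(math.isfinite(float(v)) for v in numeric):
            raise InvalidConfigError("configuration contains non-finite values")
        if tuple(self.subset_map.keys()) and set(self.subset_map) != set(self.lineage_names):
            raise InvalidConfigError(
                "subset_map must cover exactly the three lineages"
            )
        if any(len(v) < 1 for v in self.subset_map.values()):
            raise InvalidConfigError("every lineage needs at least one subset")
        fr = np.asarray(self.tumor_origin_fractions, dtype=float)
        if fr.min() < 0 or abs(fr.sum() - 1.0) > 1e-9:
            raise InvalidConfigError(
                "tumor_origin_fractions must be a 3-simplex point"
            )
        if not self.marker_fold_change >= 1:
            raise InvalidConfigError("marker_fold_change must be >= 1")
        if not self.nb_dispersion > 0:
            raise InvalidConfigError("nb_dispersion must be positive")
        if self.bulk_noise_sd < 0:
            raise InvalidConfigError("bulk_noise_sd must be nonnegative")
        n_marker_blocks = len(self.subsets()) + len(self.lineage_names)
        if n_marker_blocks * self.n_marker_genes_per_subset > self.n_genes - self.n_mito_genes:
            raise InvalidConfigError("marker blocks do not fit into the gene universe")

    def subsets(self) -> list[str]:
        return [s for lin in self.lineage_names for s in self.subset_map[lin]]

    def subset_lineage(self) -> dict[str, str]:
        return {s: lin for lin in self.lineage_names for s in self.subset_map[lin]}


@dataclass
class SyntheticCohort:
    """A generated single-cell cohort with its ground truth.

    ``counts`` is an AnnData of raw integer counts (cells x genes) whose
    ``obs`` carries subset/lineage/sample labels and whose ``var`` carries
    gene positions and the mitochondrial flag. ``true_cnv`` (tumor cohorts
    only) is the planted per-cell, per-gene copy ratio.
    """

    counts: ad.AnnData
    true_subset: pd.Series
    true_lineage: pd.Series
    gene_positions: pd.DataFrame
    true_cnv: np.ndarray | None = None
    marker_map: dict[str, np.ndarray] | None = None


@dataclass
class BulkCohort:
    """Bulk mixtures with the simplex ground truth used to grade deconvolution."""

    expression: pd.DataFrame  # genes x samples, nonnegative
    true_proportions: pd.DataFrame  # samples x (BM, LP, ML), rows on the simplex


@dataclass
class OmicsRanking:
    """An ordered gene list from one omics layer, best evidence first."""

    name: str
    genes: list[str]

    def __post_init__(self) -> None:
        if len(set(self.genes)) != len(self.genes):
            raise ValueError(f"ranking {self.name!r} contains duplicate genes")

    def __len__(self) -> int:
        return len(self.genes)


# ---------------------------------------------------------------------------
# gene universe layout


def _gene_table(config: GeneratorConfig) -> pd.DataFrame:
    """Gene ids, chromosome assignments and starts; MT- genes live on chrM."""
    n_reg = config.n_genes - config.n_mito_genes
    names = [f"G{i:04d}" for i in range(n_reg)]
    per_chrom = int(np.ceil(n_reg / config.n_chromosomes))
    chroms = [f"chr{(i // per_chrom) + 1}" for i in range(n_reg)]
    starts = [(i % per_chrom) * 10_000 for i in range(n_reg)]
    names += [f"MT-{i + 1}" for i in range(config.n_mito_genes)]
    chroms += ["chrM"] * config.n_mito_genes
    starts += [i * 100 for i in range(config.n_mito_genes)]
    return pd.DataFrame(
        {"chromosome": chroms, "start": starts},
        index=pd.Index(names, name="gene"),
    )


def _marker_layout(config: GeneratorConfig) -> dict[str, np.ndarray]:
    """Disjoint marker blocks: one shared block per lineage, one per subset.

    Marker genes are spread across the genome (strided placement) so that
    planted CNV segments and marker programs stay largely independent.
    """
    n_blocks = len(config.lineage_names) + len(config.subsets())
    k = config.n_marker_genes_per_subset
    n_reg = config.n_genes - config.n_mito_genes
    stride = n_reg // (n_blocks * k)
    idx = np.arange(n_blocks * k) * max(stride, 1)
    layout: dict[str, np.ndarray] = {}
    pos = 0
    for lin in config.lineage_names:
        layout[f"lineage:{lin}"] = idx[pos : pos + k]
        pos += k
    for s in config.subsets():
        layout[s] = idx[pos : pos + k]
        pos += k
    return layout


def _base_rates(config: GeneratorConfig) -> np.ndarray:
    """Per-gene baseline expression rates, log-normal across genes."""
    rng = np.random.default_rng([config.seed, 101])
    n_reg = config.n_genes - config.n_mito_genes
    rates = rng.lognormal(mean=0.0, sigma=1.0, size=n_reg)
    return rates


def _subset_rate_matrix(config: GeneratorConfig) -> pd.DataFrame:
    """Generative mean-rate vector per subset (regular genes only)."""
    base = _base_rates(config)
    layout = _marker_layout(config)
    lin_of = config.subset_lineage()
    cols = {}
    for s in config.subsets():
        r = base.copy()
        r[layout[s]] *= config.marker_fold_change
        r[layout[f"lineage:{lin_of[s]}"]] *= config.marker_fold_change
        cols[s] = r
    n_reg = config.n_genes - config.n_mito_genes
    genes = [f"G{i:04d}" for i in range(n_reg)]
    return pd.DataFrame(cols, index=genes)


def _sample_counts(
    rng: np.random.Generator,
    mean_rates: np.ndarray,
    mito_fracs: np.ndarray,
    config: GeneratorConfig,
) -> np.ndarray:
    """Gamma-Poisson counts for a block of cells.

    ``mean_rates`` is cells x regular-genes; mitochondrial gene rates are
    appended so that each cell's expected mito fraction equals its drawn
    Beta value.
    """
    n_cells = mean_rates.shape[0]
    lib = rng.lognormal(mean=0.0, sigma=config.library_size_log_sd, size=n_cells)
    reg_tot = mean_rates.sum(axis=1)
    mt_rate = (mito_fracs / (1.0 - mito_fracs)) * reg_tot / config.n_mito_genes
    full = np.concatenate(
        [mean_rates, np.repeat(mt_rate[:, None], config.n_mito_genes, axis=1)], axis=1
    )
    full = full * lib[:, None]
    theta = config.nb_dispersion
    lam = rng.gamma(shape=theta, scale=full / theta)
    return rng.poisson(lam).astype(np.int32)


def _draw_mito_fracs(rng: np.random.Generator, n: int, config: GeneratorConfig) -> np.ndarray:
    a, b = config.mito_beta
    f = rng.beta(a, b, size=n)
    high = rng.random(n) < config.high_mito_fraction
    f[high] = rng.beta(8.0, 12.0, size=int(high.sum()))
    return np.clip(f, 1e-4, 0.95)


def _assemble(
    counts: np.ndarray,
    cell_ids: list[str],
    obs: pd.DataFrame,
    gene_table: pd.DataFrame,
) -> ad.AnnData:
    adata = ad.AnnData(
        X=sparse.csr_matrix(counts),
        obs=obs.set_index(pd.Index(cell_ids, name="cell")),
        var=gene_table.copy(),
    )
    adata.var["mt"] = adata.var_names.str.startswith("MT-")
    return adata


# ---------------------------------------------------------------------------
# public operations


def make_normal_cells(config: GeneratorConfig) -> SyntheticCohort:
    """Generate the normal-epithelium cohort: seven subsets across three lineages.

    Each subset over-expresses its own marker block and its lineage's shared
    block by ``marker_fold_change``; everything else follows the common
    baseline. Fully reproducible from ``config.seed``.
    """
    config.validate()
    rng = np.random.default_rng([config.seed, 1])
    rates = _subset_rate_matrix(config)
    gene_table = _gene_table(config)
    subsets = config.subsets()
    lin_of = config.subset_lineage()

    blocks, subset_labels = [], []
    for s in subsets:
        mean = np.repeat(rates[s].to_numpy()[None, :], config.cells_per_subset, axis=0)
        mito = _draw_mito_fracs(rng, config.cells_per_subset, config)
        blocks.append(_sample_counts(rng, mean, mito, config))
        subset_labels += [s] * config.cells_per_subset
    counts = np.vstack(blocks)
    n = counts.shape[0]
    cell_ids = [f"N{i:05d}" for i in range(n)]
    obs = pd.DataFrame(
        {
            "subset": subset_labels,
            "lineage": [lin_of[s] for s in subset_labels],
            "sample": "normal_0",
            "dataset": "synthetic_normal",
            "compartment": "normal_epithelium",
        }
    )
    adata = _assemble(counts, cell_ids, obs, gene_table)
    layout = _marker_layout(config)
    genes = rates.index.to_numpy()
    marker_map = {k: genes[v] for k, v in layout.items()}
    return SyntheticCohort(
        counts=adata,
        true_subset=adata.obs["subset"].copy(),
        true_lineage=adata.obs["lineage"].copy(),
        gene_positions=gene_table[["chromosome", "start"]].copy(),
        marker_map=marker_map,
    )


def _segment_gene_mask(
    config: GeneratorConfig, gene_table: pd.DataFrame
) -> tuple[np.ndarray, np.ndarray]:
    """Per-gene copy-ratio vector implied by ``cnv_segments`` (regular genes)."""
    n_reg = config.n_genes - config.n_mito_genes
    ratio = np.ones(n_reg)
    reg = gene_table.iloc[:n_reg]
    for chrom, lo, hi, r in config.cnv_segments:
        in_chrom = np.flatnonzero((reg["chromosome"] == chrom).to_numpy())
        if in_chrom.size == 0 or lo < 0 or hi > in_chrom.size or lo >= hi:
            raise IndexError(
                f"cnv segment ({chrom}, {lo}, {hi}) outside the gene range"
            )
        order = np.argsort(reg["start"].to_numpy()[in_chrom], kind="stable")
        ratio[in_chrom[order[lo:hi]]] = r
    affected = ratio != 1.0
    return ratio, affected


def make_tumor_cells(config: GeneratorConfig, normal: SyntheticCohort) -> SyntheticCohort:
    """Generate tumor cells that inherit one of the three lineage programs.

    Cell lineages are drawn from ``tumor_origin_fractions``. A random
    ``cnv_clone_fraction`` of the cells forms the unstable clone whose
    expression rates inside each planted segment are multiplied by the
    segment's copy ratio before count sampling; the remaining cells are
    copy-neutral. The planted per-cell copy-ratio vector is returned as
    ``true_cnv``.
    """
    config.validate()
    rng = np.random.default_rng([config.seed, 2])
    rates = _subset_rate_matrix(config)
    gene_table = _gene_table(config)
    # lineage program = mean of its subsets' programs
    lin_rates = {
        lin: rates[list(config.subset_map[lin])].mean(axis=1).to_numpy()
        for lin in config.lineage_names
    }
    n = config.n_tumor_cells
    lineages = rng.choice(
        config.lineage_names, size=n, p=np.asarray(config.tumor_origin_fractions)
    )
    clone = rng.random(n) < config.cnv_clone_fraction
    ratio, _ = _segment_gene_mask(config, gene_table)

    n_reg = config.n_genes - config.n_mito_genes
    mean = np.empty((n, n_reg))
    true_cnv = np.ones((n, n_reg))
    for i in range(n):
        m = lin_rates[lineages[i]].copy()
        if clone[i]:
            m *= ratio
            true_cnv[i] = ratio
        mean[i] = m
    mito = _draw_mito_fracs(rng, n, config)
    counts = _sample_counts(rng, mean, mito, config)

    samples = rng.integers(0, config.n_tumor_samples, size=n)
    cell_ids = [f"T{i:05d}" for i in range(n)]
    obs = pd.DataFrame(
        {
            "subset": "tumor",
            "lineage": lineages,
            "sample": [f"tumor_{s}" for s in samples],
            "dataset": "synthetic_tumor",
            "compartment": "tumor",
            "cnv_clone": clone,
        }
    )
    adata = _assemble(counts, cell_ids, obs, gene_table)
    return SyntheticCohort(
        counts=adata,
        true_subset=adata.obs["subset"].copy(),
        true_lineage=adata.obs["lineage"].copy(),
        gene_positions=gene_table[["chromosome", "start"]].copy(),
        true_cnv=true_cnv,
        marker_map=normal.marker_map,
    )


def lineage_mean_expression(
    normal: SyntheticCohort, scale: float = 1e4
) -> pd.DataFrame:
    """Per-lineage mean library-normalized expression (genes x lineages).

    This is the linear-scale signature the bulk mixtures are built from and
    the deconvolution basis estimates.
    """
    adata = normal.counts
    X = np.asarray(adata.X.todense(), dtype=float)
    totals = X.sum(axis=1, keepdims=True)
    norm = X / totals * scale
    out = {}
    for lin in sorted(normal.true_lineage.unique()):
        mask = (normal.true_lineage == lin).to_numpy()
        out[lin] = norm[mask].mean(axis=0)
    return pd.DataFrame(out, index=adata.var_names)


def make_bulk_mixtures(config: GeneratorConfig, normal: SyntheticCohort) -> BulkCohort:
    """Bulk samples as known simplex mixtures of the lineage mean expression.

    Each sample is sum_l p_l * m_l plus Gaussian noise (sd ``bulk_noise_sd``),
    truncated at zero; p is drawn from a flat Dirichlet.
    """
    config.validate()
    rng = np.random.default_rng([config.seed, 3])
    M = lineage_mean_expression(normal)
    n = config.n_bulk_samples
    P = rng.dirichlet(np.ones(3), size=n)  # samples x 3, columns (BM, LP, ML)
    expr = M.to_numpy() @ P.T
    if config.bulk_noise_sd > 0:
        expr = expr + rng.normal(0.0, config.bulk_noise_sd, size=expr.shape)
    expr = np.clip(expr, 0.0, None)
    samples = [f"bulk_{i:03d}" for i in range(n)]
    expression = pd.DataFrame(expr, index=M.index, columns=samples)
    props = pd.DataFrame(P, index=samples, columns=list(M.columns))
    return BulkCohort(expression=expression, true_proportions=props)


def make_multiomics_rankings(
    n_genes: int,
    planted: Sequence[str],
    n_lists: int,
    seed: int,
    jitter: float = 1.0,
) -> list[OmicsRanking]:
    """Concordant ranked gene lists with planted top candidates.

    Every list covers the same universe of ``n_genes`` genes; planted genes
    receive a large evidence score plus seeded jitter so they rank near the
    top of every list.
    """
    if n_lists < 1:
        raise ValueError("n_lists must be >= 1")
    universe = [f"G{i:04d}" for i in range(n_genes)]
    uset = set(universe)
    missing = [g for g in planted if g not in uset]
    if missing:
        raise KeyError(f"planted genes not in the universe: {missing}")
    rng = np.random.default_rng([seed, 4])
    planted_mask = np.isin(universe, list(planted))
    lists = []
    for k in range(n_lists):
        score = rng.normal(0.0, 1.0, size=n_genes)
        score[planted_mask] = 10.0 + (
            rng.normal(0.0, jitter, size=int(planted_mask.sum())) if jitter > 0 else 0.0
        )
        order = np.lexsort((universe, -score))  # score desc, gene id asc on ties
        lists.append(OmicsRanking(name=f"omics_{k + 1}", genes=[universe[i] for i in order]))
    return lists
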