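"""Single-sample gene-set scoring and the LP signature score.

The core statistic is a weighted Kolmogorov-Smirnov running-sum enrichment
score computed per sample from expression ranks alone, so it is invariant to
any monotone transform of a sample's expression. The LP score of a sample is
the difference between the enrichment of LP-positively and LP-negatively
correlated marker sets (top/bottom 100 genes by Spearman correlation with
the LP proportion across a training cohort); samples strictly above the
cohort median LP score are called LP-high.

``module_score`` implements the familiar expression-bin control-gene score
used for per-cell signature scoring (naive/cytotoxic/exhausted/Treg and
cell-cycle programs): mean expression of the set minus the mean of control
genes drawn from matched average-expression bins.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.stats import rankdata


@dataclass
class GeneSet:
    name: str
    genes: list[str]

    def __post_init__(self) -> None:
        if not self.genes:
            raise ValueError(f"gene set {self.name!r} is empty")
        if len(set(self.genes)) != len(self.genes):
            raise ValueError(f"gene set {self.name!r} contains duplicates")


@dataclass
class LPScoreResult:
    positive_score: pd.Series
    negative_score: pd.Series
    lp_score: pd.Series
    lp_high: pd.Series | None = None
    median: float | None = None

    def to_frame(self) -> pd.DataFrame:
        df = pd.DataFrame(
            {
                "positive": self.positive_score,
                "negative": self.negative_score,
                "lp_score": self.lp_score,
            }
        )
        if self.lp_high is not None:
            df["lp_high"] = self.lp_high
        return df


def rank_enrichment_score(
    expr: pd.DataFrame,  # genes x samples
    gene_set: GeneSet,
    weight: float = 0.25,
) -> pd.Series:
    """Weighted KS running-sum enrichment of ``gene_set`` in every sample.

    Genes are ordered by decreasing expression (ties broken by gene id).
    Set members contribute rank-magnitude^weight increments, non-members a
    flat penalty; the score is the running sum's maximum deviation from
    zero (signed), normalized so scores lie in [-1, 1].
    """
    genes = expr.index
    if len(genes) < 2:
        raise ValueError("need at least 2 genes")
    in_set = genes.isin(gene_set.genes)
    n_in = int(in_set.sum())
    if n_in == 0:
        raise KeyError(f"gene set {gene_set.name!r} shares no genes with expression")
    if n_in == len(genes):
        raise ValueError("gene set covers every gene; complement is empty")

    n = len(genes)
    gene_order_key = np.argsort(genes.to_numpy())  # for deterministic tie-break
    tie_rank = np.empty(n)
    tie_rank[gene_order_key] = np.arange(n)

    scores = {}
    for sample in expr.columns:
        x = expr[sample].to_numpy(dtype=float)
        # order genes by decreasing expression, gene id ascending on ties
        order = np.lexsort((tie_rank, -x))
        ranks = rankdata(x, method="average")  # 1..n, n = highest expression
        hit = in_set[order]
        w = ranks[order] ** weight
        hit_inc = np.where(hit, w, 0.0)
        denom = hit_inc.sum()
        miss_inc = np.where(hit, 0.0, 1.0 / (n - n_in))
        running = np.cumsum(hit_inc / denom - miss_inc)
        i = int(np.argmax(np.abs(running)))
        scores[sample] = float(running[i])
    return pd.Series(scores, name=f"es_{gene_set.name}")


def lp_correlation_markers(
    bulk: pd.DataFrame,  # genes x samples
    lp_fraction: pd.Series,
    top_n: int = 100,
) -> tuple[GeneSet, GeneSet]:
    """Top/bottom ``top_n`` genes by Spearman correlation with the LP
    fraction, as the LP-positive and LP-negative marker sets (disjoint)."""
    if bulk.shape[1] < 3:
        raise ValueError("need at least 3 samples")
    fr = lp_fraction.reindex(bulk.columns)
    X = bulk.to_numpy(dtype=float)
    RX = rankdata(X, axis=1)
    RX = RX - RX.mean(axis=1, keepdims=True)
    rf = rankdata(fr.to_numpy())
    rf = rf - rf.mean()
    with np.errstate(invalid="ignore", divide="ignore"):
        rho = (RX @ rf) / (np.sqrt((RX**2).sum(axis=1)) * np.sqrt((rf**2).sum()))
    rho = pd.Series(rho, index=bulk.index).dropna()
    if len(rho) < 2 * top_n:
        raise ValueError(
            f"only {len(rho)} genes with finite correlations; need {2 * top_n}"
        )
    order = np.lexsort((rho.index.to_numpy(), -rho.to_numpy()))
    pos = rho.index[order[:top_n]].tolist()
    neg = rho.index[order[-top_n:]].tolist()
    return GeneSet("LP_positive", sorted(pos)), GeneSet("LP_negative", sorted(neg))


def lp_score(
    expr: pd.DataFrame,
    positive: GeneSet,
    negative: GeneSet,
    weight: float = 0.25,
    split: bool = True,
) -> LPScoreResult:
    """LP score = enrichment(positive set) - enrichment(negative set);
    LP-high = strictly above the cohort median."""
    pos = rank_enrichment_score(expr, positive, weight=weight)
    neg = rank_enrichment_score(expr, negative, weight=weight)
    score = (pos - neg).rename("lp_score")
    result = LPScoreResult(positive_score=pos, negative_score=neg, lp_score=score)
    if split:
        if len(score) < 2:
            raise ValueError("median split needs at least 2 samples")
        med = float(score.median())
        result.median = med
        result.lp_high = (score > med).rename("lp_high")
    return result


def module_score(
    expr: pd.DataFrame,  # cells x genes
    gene_set: GeneSet,
    n_bins: int = 25,
    n_ctrl: int = 100,
    seed: int = 0,
) -> pd.Series:
    """Expression-bin control score: mean expression of the set genes minus
    the mean of ``n_ctrl`` control genes per set gene sampled (seeded) from
    the same average-expression bin."""
    genes = expr.columns
    if n_bins > len(genes):
        raise ValueError(f"n_bins={n_bins} exceeds the {len(genes)} genes available")
    members = [g for g in gene_set.genes if g in genes]
    if not members:
        raise KeyError(f"gene set {gene_set.name!r} shares no genes with expression")
    avg = expr.mean(axis=0)
    # equal-frequency bins on average expression, ties collapsed
    bins = pd.qcut(avg.rank(method="first"), q=n_bins, labels=False)
    rng = np.random.default_rng(seed)
    member_set = set(members)
    ctrl: list[str] = []
    for g in members:
        pool = bins.index[(bins == bins[g]).to_numpy()]
        pool = pool[~pool.isin(member_set)]  # controls never overlap the set
        if len(pool) == 0:
            continue
        take = rng.choice(pool, size=min(n_ctrl, len(pool)), replace=False)
        ctrl.extend(take)
    if not ctrl:
        raise ValueError("no control genes available outside the gene set")
    ctrl_mean = expr[ctrl].mean(axis=1)
    set_mean = expr[members].mean(axis=1)
    return (set_mean - ctrl_mean).rename(f"score_{gene_set.name}")


def subpop_signature(
    de_table: pd.DataFrame,
    top_n: int = 50,
    alpha: float = 0.05,
    name: str = "subpopulation",
) -> GeneSet:
    """Top-``top_n`` significant genes by effect size from a DE table with
    columns ``gene``, ``statistic`` and ``p_adj``."""
    sig = de_table[de_table["p_adj"] < alpha]
    if sig.empty:
        raise ValueError("no significant genes at the given alpha")
    if len(sig) < top_n:
        warnings.warn(
            f"only {len(sig)} significant genes; returning all of them",
            stacklevel=2,
        )
    order = np.lexsort((sig["gene"].to_numpy(), -sig["statistic"].to_numpy()))
    genes = sig["gene"].to_numpy()[order[:top_n]].tolist()
    return GeneSet(name, genes)


# ---------------------------------------------------------------------------
# GMT I/O


def read_gmt(path) -> list[GeneSet]:
    sets = []
    with open(path) as fh:
        for line in fh:
            parts = line.rstrip("\n").split("\t")
            if len(parts) >= 3:
                sets.append(GeneSet(parts[0], [g for g in parts[2:] if g]))
    return sets


def write_gmt(sets: list[GeneSet], path) -> None:
    with open(path, "w") as fh:
        for s in sets:
            fh.write("\t".join([s.name, ""] + list(s.genes)) + "\n")
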