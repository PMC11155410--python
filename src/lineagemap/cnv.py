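"""Expression-inferred copy-number profiles and the per-cell CNV score.

A cell's copy-number profile is its log-normalized expression minus the mean
of a reference cell population, smoothed gene-wise along each chromosome
with a centered moving average (truncated at chromosome ends), clipped to
[-3, 3] and re-centered by the cell's median. The CNV score is the
population variance of a cell's smoothed region values: a proxy for
chromosomal-instability burden. Candidate instability genes come from a
rank-sum differential-expression screen of the top-quartile versus
bottom-quartile CNV-score cells, with Benjamini-Hochberg correction.
"""

from __future__ import annotations

import re
import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.stats import norm, rankdata
from statsmodels.stats.multitest import multipletests


@dataclass
class CNVProfile:
    values: pd.DataFrame  # cells x regions, ordered by chromosome then position
    region_meta: pd.DataFrame  # index: region (gene) id; columns: chromosome, start


def _natural_chrom_key(chrom: str):
    m = re.match(r"^chr(\d+)$", chrom)
    return (0, int(m.group(1)), "") if m else (1, 0, chrom)


def _moving_average_truncated(block: np.ndarray, window: int) -> np.ndarray:
    """Centered moving average along axis 1, window truncated at the edges."""
    n = block.shape[1]
    half = window // 2
    csum = np.cumsum(block, axis=1)
    csum = np.concatenate([np.zeros((block.shape[0], 1)), csum], axis=1)
    lo = np.maximum(np.arange(n) - half, 0)
    hi = np.minimum(np.arange(n) + half + 1, n)
    return (csum[:, hi] - csum[:, lo]) / (hi - lo)


def infer_cnv_profile(
    expr: pd.DataFrame,  # cells x genes, log-normalized
    reference_cells: list[str],
    gene_positions: pd.DataFrame,  # index gene; columns chromosome, start
    window: int = 101,
    clip: float = 3.0,
) -> CNVProfile:
    """Reference-subtracted, chromosome-smoothed relative expression.

    A window wider than a chromosome degrades to that chromosome's running
    average over all its genes. Chromosomes with fewer than 2 genes are
    excluded with a warning.
    """
    ref = [c for c in reference_cells if c in expr.index]
    if not ref:
        raise ValueError("reference cell set is empty or disjoint from expression")
    pos = gene_positions.reindex(expr.columns).dropna(subset=["chromosome", "start"])
    missing = expr.shape[1] - len(pos)
    if missing:
        warnings.warn(f"{missing} genes without positions excluded", stacklevel=2)

    chrom_sizes = pos.groupby("chromosome").size()
    small = chrom_sizes[chrom_sizes < 2].index.tolist()
    if small:
        warnings.warn(f"chromosomes with < 2 genes excluded: {small}", stacklevel=2)
        pos = pos[~pos["chromosome"].isin(small)]

    chroms = sorted(pos["chromosome"].unique(), key=_natural_chrom_key)
    ordered_genes: list[str] = []
    blocks: list[np.ndarray] = []
    ref_mean = expr.loc[ref].mean(axis=0)
    rel = expr.sub(ref_mean, axis=1)
    for chrom in chroms:
        sub = pos[pos["chromosome"] == chrom].sort_values(
            ["start"], kind="stable"
        )
        genes = sub.index.tolist()
        ordered_genes.extend(genes)
        blocks.append(_moving_average_truncated(rel[genes].to_numpy(dtype=float), window))
    smoothed = np.concatenate(blocks, axis=1)
    smoothed = np.clip(smoothed, -clip, clip)
    smoothed = smoothed - np.median(smoothed, axis=1, keepdims=True)
    values = pd.DataFrame(smoothed, index=expr.index, columns=ordered_genes)
    region_meta = pos.loc[ordered_genes, ["chromosome", "start"]]
    return CNVProfile(values=values, region_meta=region_meta)


def cnv_score(profile: CNVProfile) -> pd.Series:
    """Per-cell population variance of the smoothed region values."""
    if profile.values.shape[1] < 2:
        raise ValueError("CNV score needs at least 2 regions")
    return profile.values.var(axis=1, ddof=0).rename("cnv_score")


def _rank_sum_two_sample(top: np.ndarray, bottom: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    """Vectorized two-sample rank-sum z and two-sided normal p per gene."""
    n1, n2 = top.shape[0], bottom.shape[0]
    both = np.vstack([top, bottom])
    ranks = rankdata(both, axis=0)
    r1 = ranks[:n1].sum(axis=0)
    u = r1 - n1 * (n1 + 1) / 2.0
    mu = n1 * n2 / 2.0
    n = n1 + n2
    sigma2 = np.empty(both.shape[1])
    for j in range(both.shape[1]):
        _, counts = np.unique(both[:, j], return_counts=True)
        tie = (counts**3 - counts).sum()
        sigma2[j] = n1 * n2 / 12.0 * ((n + 1) - tie / (n * (n - 1)))
    with np.errstate(invalid="ignore", divide="ignore"):
        z = (u - mu) / np.sqrt(sigma2)
    z = np.where(sigma2 <= 0, 0.0, z)
    p = 2.0 * norm.sf(np.abs(z))
    return z, p


def quartile_de(
    expr: pd.DataFrame,  # cells x genes
    scores: pd.Series,
    group_mask: pd.Series | None = None,
    q: float = 0.25,
    alpha: float = 0.05,
) -> pd.DataFrame:
    """Rank-sum DE of top-``q`` versus bottom-``q`` CNV-score cells.

    Returns a table (gene, statistic, p, p_adj, direction, candidate) sorted
    by decreasing statistic; candidates satisfy BH-adjusted p < ``alpha``.
    """
    if group_mask is not None:
        cells = expr.index[group_mask.reindex(expr.index).fillna(False).to_numpy(dtype=bool)]
    else:
        cells = expr.index
    if len(cells) < 4:
        raise ValueError("need at least 4 cells in the group")
    s = scores.reindex(cells)
    n_arm = int(np.ceil(q * len(cells)))
    if n_arm < 2:
        raise ValueError("fewer than 2 cells per arm")
    order = np.lexsort((cells.to_numpy(), -s.to_numpy()))
    top_cells = cells[order[:n_arm]]
    bottom_cells = cells[order[-n_arm:]]
    z, p = _rank_sum_two_sample(
        expr.loc[top_cells].to_numpy(dtype=float),
        expr.loc[bottom_cells].to_numpy(dtype=float),
    )
    _, p_adj, _, _ = multipletests(p, method="fdr_bh")
    effect = expr.loc[top_cells].mean(axis=0) - expr.loc[bottom_cells].mean(axis=0)
    table = pd.DataFrame(
        {
            "gene": expr.columns,
            "statistic": z,
            "effect": effect.to_numpy(),
            "p": p,
            "p_adj": p_adj,
            "direction": np.where(z >= 0, "up", "down"),
            "candidate": p_adj < alpha,
        }
    )
    order = np.lexsort((table["gene"].to_numpy(), -table["statistic"].to_numpy()))
    return table.iloc[order].reset_index(drop=True)
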