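"""Multi-omics rank aggregation for candidate-target nomination.

Ranked gene lists from independent omics layers (e.g. a single-cell DE
screen, bulk copy-number correlations, a CRISPR perturbation screen) are
intersected; within the common gene set of size N each list is re-oriented
so its strongest gene carries rank value N and its weakest 1, and the rank
score of a gene is the sum of these values over the lists. Higher score =
stronger multi-omics support; ties in the final ordering break
lexicographically.
"""

from __future__ import annotations

import pandas as pd

from .synthetic import OmicsRanking

__all__ = ["OmicsRanking", "intersect_rankings", "rank_score", "top_candidates"]


def intersect_rankings(lists: list[OmicsRanking]) -> list[str]:
    """Genes present in every ranking; error if the intersection is empty."""
    if len(lists) < 2:
        raise ValueError("need at least 2 rankings to intersect")
    common = set(lists[0].genes)
    for lst in lists[1:]:
        common &= set(lst.genes)
    if not common:
        raise ValueError("rankings share no genes")
    return sorted(common)


def rank_score(lists: list[OmicsRanking], genes: list[str]) -> pd.Series:
    """Sum over lists of each gene's orientation-normalized rank within the
    intersection: the strongest gene of a list gets N, the weakest 1."""
    n = len(genes)
    gene_set = set(genes)
    total = pd.Series(0, index=sorted(genes), dtype=int)
    for lst in lists:
        present = [g for g in lst.genes if g in gene_set]
        if len(present) != n:
            missing = gene_set - set(lst.genes)
            raise KeyError(f"genes missing from ranking {lst.name!r}: {sorted(missing)[:5]}")
        # position 0 = strongest -> rank value N
        for pos, g in enumerate(present):
            total[g] += n - pos
    return total.rename("rank_score")


def top_candidates(scores: pd.Series, k: int) -> list[str]:
    """Top-``k`` genes by rank score, ties broken lexicographically."""
    if k > len(scores):
        raise ValueError(f"k={k} exceeds the {len(scores)} scored genes")
    df = scores.rename("score").rename_axis("gene").reset_index()
    df = df.sort_values(["score", "gene"], ascending=[False, True], kind="stable")
    return df["gene"].head(k).tolist()
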