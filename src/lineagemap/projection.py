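"""Tumor-normal projection: meta-gene selection, combined clustering, and
cell-of-origin assignment.

Tumor pseudobulk profiles are projected against normal-epithelium reference
profiles inside a "meta-gene" space: the intersection of (a) the union of
top-N one-vs-rest markers of each normal subset and (b) the top fraction of
most variable genes across tumor profiles. The combined profile matrix is
batch-corrected by per-cohort gene standardization, clustered hierarchically
(correlation distance, average linkage) into k major groups, and each group
is labelled by the lineage of the normal reference profiles it contains.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.cluster import hierarchy
from scipy.spatial.distance import pdist
from scipy.stats import rankdata

from .preprocess import PseudobulkMatrix


class EmptyIntersectionError(ValueError):
    pass


class UnlabelableGroupError(ValueError):
    pass


class AmbiguousLabelError(ValueError):
    pass


@dataclass
class MetaGeneSet:
    genes: list[str]
    n_from_normal_markers: int
    n_from_tumor_variable: int

    @property
    def n_intersection(self) -> int:
        return len(self.genes)


@dataclass
class OriginAssignment:
    """Major-group labels for every profile, plus PCA coordinates for the
    concordance check."""

    profile_group: pd.Series  # per profile: BM / LP / ML
    pca_coords: pd.DataFrame  # profiles x 2
    linkage: np.ndarray


def _rank_sum_one_vs_rest(expr: pd.DataFrame, mask: np.ndarray) -> np.ndarray:
    """Vectorized Mann-Whitney z statistic (positive = up in the group)."""
    n1 = int(mask.sum())
    n2 = int((~mask).sum())
    ranks = rankdata(expr.to_numpy(), axis=0)
    r1 = ranks[mask].sum(axis=0)
    u = r1 - n1 * (n1 + 1) / 2.0
    mu = n1 * n2 / 2.0
    # tie-corrected variance
    n = n1 + n2
    sigma2 = np.full(expr.shape[1], n1 * n2 * (n + 1) / 12.0)
    for j in range(expr.shape[1]):
        _, counts = np.unique(expr.iloc[:, j].to_numpy(), return_counts=True)
        tie = (counts**3 - counts).sum()
        sigma2[j] = n1 * n2 / 12.0 * ((n + 1) - tie / (n * (n - 1)))
    sigma = np.sqrt(np.maximum(sigma2, 1e-12))
    return (u - mu) / sigma


def select_subset_markers(
    normal_expr: pd.DataFrame,
    labels: pd.Series,
    top_n: int = 100,
) -> list[str]:
    """Union of each subset's top-``top_n`` positively expressed markers.

    Markers are ranked per subset by a one-vs-rest rank-sum z statistic
    (positive direction only); the union is deduplicated, so a gene marking
    several subsets appears once. Ties break by gene id.
    """
    if top_n <= 0:
        raise ValueError("top_n must be positive")
    labels = labels.reindex(normal_expr.index)
    genes = normal_expr.columns.to_numpy()
    selected: set[str] = set()
    for subset in sorted(labels.unique()):
        mask = (labels == subset).to_numpy()
        if mask.sum() < 2:
            raise ValueError(f"subset {subset!r} has fewer than 2 cells")
        z = _rank_sum_one_vs_rest(normal_expr, mask)
        order = np.lexsort((genes, -z))
        selected.update(genes[i] for i in order[:top_n] if z[i] > 0)
    return sorted(selected)


def select_variable_genes(tumor_pseudobulk: PseudobulkMatrix, top_frac: float = 0.01) -> list[str]:
    """Top ``ceil(top_frac * n_genes)`` genes by variance across tumor profiles.

    Ties break by gene id; requires at least 2 profiles.
    """
    values = tumor_pseudobulk.values
    if values.shape[1] < 2:
        raise ValueError("variance selection needs at least 2 tumor profiles")
    n_take = max(1, int(np.ceil(top_frac * values.shape[0])))
    var = values.var(axis=1, ddof=1)
    order = np.lexsort((values.index.to_numpy(), -var.to_numpy()))
    return sorted(values.index[order[:n_take]].tolist())


def intersect_meta_genes(markers: list[str], variable: list[str]) -> MetaGeneSet:
    """Intersection of normal-subset markers and tumor high-variance genes."""
    if not markers or not variable:
        raise ValueError("both gene sets must be nonempty")
    inter = sorted(set(markers) & set(variable))
    if not inter:
        raise EmptyIntersectionError(
            "marker and variable gene sets are disjoint; "
            "increase top_n or top_frac"
        )
    return MetaGeneSet(
        genes=inter,
        n_from_normal_markers=len(markers),
        n_from_tumor_variable=len(variable),
    )


def combine_and_correct(
    tumor: PseudobulkMatrix,
    normal: PseudobulkMatrix,
    meta: MetaGeneSet,
) -> PseudobulkMatrix:
    """Column-concatenate the two cohorts restricted to the meta-genes and
    remove cohort batch effects by per-cohort gene standardization.

    Within each source cohort every gene is centered and scaled to unit
    variance (constant genes are centered only), so an additive per-cohort
    offset vanishes exactly.
    """
    for name, pb in (("tumor", tumor), ("normal", normal)):
        missing = [g for g in meta.genes if g not in pb.values.index]
        if missing:
            raise KeyError(f"meta genes missing from {name} pseudobulk: {missing[:5]}")

    def _standardize(values: pd.DataFrame) -> pd.DataFrame:
        sub = values.loc[meta.genes]
        mu = sub.mean(axis=1)
        sd = sub.std(axis=1, ddof=0).replace(0.0, 1.0)
        return sub.sub(mu, axis=0).div(sd, axis=0)

    combined = pd.concat([_standardize(tumor.values), _standardize(normal.values)], axis=1)
    meta_df = pd.concat([tumor.profile_meta, normal.profile_meta], axis=0)
    return PseudobulkMatrix(values=combined, profile_meta=meta_df)


def cluster_major_groups(combined: PseudobulkMatrix, k: int = 3) -> OriginAssignment:
    """Hierarchical clustering (correlation distance, average linkage) of the
    combined profiles cut at ``k`` groups, labelled by the lineage of the
    normal reference profiles each group contains."""
    meta = combined.profile_meta
    ref_mask = meta["origin_kind"] == "normal_subset"
    if not ref_mask.any():
        raise UnlabelableGroupError("combined matrix contains no normal reference profiles")
    if "lineage" not in meta.columns:
        raise KeyError(
            "profile_meta needs a 'lineage' column on normal reference profiles"
        )
    ref_lineages = set(meta.loc[ref_mask, "lineage"].dropna())
    if k < len(ref_lineages):
        raise ValueError(
            f"k={k} cannot separate {len(ref_lineages)} reference lineages"
        )
    X = combined.values.to_numpy().T  # profiles x genes
    dist = pdist(X, metric="correlation")
    Z = hierarchy.linkage(dist, method="average")
    groups = hierarchy.fcluster(Z, t=k, criterion="maxclust")
    profiles = combined.values.columns

    group_label: dict[int, str] = {}
    for g in np.unique(groups):
        members = profiles[groups == g]
        refs = meta.loc[members].loc[lambda d: d["origin_kind"] == "normal_subset"]
        if refs.empty:
            raise UnlabelableGroupError(
                f"group {g} contains no normal reference profile"
            )
        lins = set(refs["lineage"])
        if len(lins) > 1:
            raise AmbiguousLabelError(
                f"group {g} contains references from lineages {sorted(lins)}"
            )
        group_label[g] = next(iter(lins))

    assignment = pd.Series(
        [group_label[g] for g in groups], index=profiles, name="group"
    )
    # PCA coordinates for the concordance check
    Xc = X - X.mean(axis=0, keepdims=True)
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        _, _, vt = np.linalg.svd(Xc, full_matrices=False)
    coords = pd.DataFrame(Xc @ vt[:2].T, index=profiles, columns=["PC1", "PC2"])
    return OriginAssignment(profile_group=assignment, pca_coords=coords, linkage=Z)


def propagate_cell_origins(
    cell_clusters: pd.Series, profile_group: pd.Series, label_prefix: str = ""
) -> pd.Series:
    """Propagate each tumor cluster's lineage group to its member cells."""
    mapping = {p: g for p, g in profile_group.items()}
    out = cell_clusters.map(lambda c: mapping.get(f"{label_prefix}{c}"))
    if out.isna().any():
        missing = sorted(cell_clusters[out.isna()].unique())
        raise KeyError(f"clusters without a group assignment: {missing}")
    return out.rename("origin")


def assign_sample_subtype(
    cell_origins: pd.Series,
    sample_ids: pd.Series,
    dominance: float = 0.5,
) -> pd.Series:
    """Per-sample subtype: the dominant lineage if its cell fraction reaches
    ``dominance``, else ``Mixed``."""
    sample_ids = sample_ids.reindex(cell_origins.index)
    if sample_ids.isna().any() or cell_origins.isna().any():
        raise ValueError("every cell needs both an origin label and a sample id")
    out = {}
    for sample, idx in cell_origins.groupby(sample_ids, observed=True).groups.items():
        fr = cell_origins.loc[idx].value_counts(normalize=True)
        if fr.empty:
            raise ValueError(f"sample {sample!r} has no labelled tumor cells")
        top = fr.sort_values(ascending=False)
        out[sample] = top.index[0] if top.iloc[0] >= dominance else "Mixed"
    return pd.Series(out, name="subtype")
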