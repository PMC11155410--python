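"""Meta-gene selection and tumor-normal group assignment."""

import numpy as np
import pandas as pd
import pytest

from lineagemap import projection as proj
from lineagemap.preprocess import PseudobulkMatrix


def _pseudobulk(values: np.ndarray, genes, profiles, origin_kind="tumor_cluster",
                lineages=None) -> PseudobulkMatrix:
    df = pd.DataFrame(values, index=genes, columns=profiles)
    meta = pd.DataFrame(
        {"origin_kind": origin_kind, "label": profiles, "n_cells": 10}, index=profiles
    )
    if lineages is not None:
        meta["lineage"] = lineages
    return PseudobulkMatrix(values=df, profile_meta=meta)


class TestSubsetMarkers:
    def test_planted_blocks_recovered(self, small_normal, small_normal_expr):
        # top_n=60 leaves room for the lineage-shared block that also ranks
        # high in each subset's one-vs-rest comparison
        markers = proj.select_subset_markers(
            small_normal_expr,
            small_normal.true_subset.reindex(small_normal_expr.index),
            top_n=60,
        )
        for subset in ("basal", "LTF_LP", "AREG_ML"):
            planted = [g for g in small_normal.marker_map[subset]
                       if g in small_normal_expr.columns]
            hit = np.mean([g in markers for g in planted])
            assert hit > 0.9, f"{subset}: only {hit:.0%} planted markers recovered"

    def test_top_n_zero_error(self, small_normal_expr, small_normal):
        with pytest.raises(ValueError):
            proj.select_subset_markers(
                small_normal_expr, small_normal.true_subset, top_n=0
            )

    def test_union_deduplicates(self):
        """A gene marking two subsets appears once in the union."""
        rng = np.random.default_rng(0)
        base = rng.lognormal(size=(40, 30))
        labels = pd.Series(["A"] * 20 + ["B"] * 20,
                           index=[f"c{i}" for i in range(40)])
        expr = pd.DataFrame(base, index=labels.index,
                            columns=[f"G{i:02d}" for i in range(30)])
        expr.loc[:, "G00"] += 10  # high everywhere: a top marker of neither alone
        expr.loc[labels == "A", "G01"] += 10
        expr.loc[labels == "B", "G02"] += 10
        markers = proj.select_subset_markers(expr, labels, top_n=5)
        assert len(markers) == len(set(markers))

    def test_tiny_subset_error(self):
        expr = pd.DataFrame(np.ones((3, 4)), index=["a", "b", "c"])
        labels = pd.Series(["A", "A", "B"], index=["a", "b", "c"])
        with pytest.raises(ValueError, match="fewer than 2"):
            proj.select_subset_markers(expr, labels, top_n=2)


class TestVariableGenes:
    def test_ceiling_rule(self):
        """200 genes at top_frac=0.01 -> ceil(2) = 2 genes."""
        rng = np.random.default_rng(1)
        pb = _pseudobulk(rng.normal(size=(200, 5)),
                         [f"G{i:03d}" for i in range(200)],
                         [f"p{i}" for i in range(5)])
        assert len(proj.select_variable_genes(pb, top_frac=0.01)) == 2

    def test_highest_variance_gene_included(self):
        values = np.ones((10, 4))
        values[3] = [0, 10, 0, 10]
        pb = _pseudobulk(values, [f"G{i}" for i in range(10)], list("abcd"))
        assert "G3" in proj.select_variable_genes(pb, top_frac=0.01)

    def test_constant_matrix_tie_break_by_gene_id(self):
        pb = _pseudobulk(np.ones((5, 3)), ["G4", "G0", "G2", "G1", "G3"], list("abc"))
        assert proj.select_variable_genes(pb, top_frac=0.3) == ["G0", "G1"]

    def test_single_profile_error(self):
        pb = _pseudobulk(np.ones((5, 1)), [f"G{i}" for i in range(5)], ["a"])
        with pytest.raises(ValueError):
            proj.select_variable_genes(pb)


class TestIntersection:
    def test_identical_sets(self):
        meta = proj.intersect_meta_genes(["A", "B"], ["B", "A"])
        assert meta.genes == ["A", "B"]
        assert meta.n_intersection == 2

    def test_disjoint_sets_error(self):
        with pytest.raises(proj.EmptyIntersectionError):
            proj.intersect_meta_genes(["A"], ["B"])

    def test_monotone_in_top_n(self, small_normal, small_normal_expr, small_tumor):
        """Enlarging either source list never shrinks the intersection."""
        from lineagemap import preprocess as pp

        labels = small_normal.true_subset.reindex(small_normal_expr.index)
        m_small = set(proj.select_subset_markers(small_normal_expr, labels, top_n=20))
        m_large = set(proj.select_subset_markers(small_normal_expr, labels, top_n=60))
        assert m_small <= m_large


class TestCombineAndCorrect:
    def _toy(self, offset=0.0):
        rng = np.random.default_rng(2)
        genes = [f"G{i}" for i in range(12)]
        tumor = _pseudobulk(rng.normal(size=(12, 6)) + offset, genes,
                            [f"t{i}" for i in range(6)])
        normal = _pseudobulk(rng.normal(size=(12, 3)), genes, ["n0", "n1", "n2"],
                             origin_kind="normal_subset",
                             lineages=["BM", "LP", "ML"])
        return tumor, normal

    def test_profile_count_conserved(self):
        tumor, normal = self._toy()
        meta = proj.MetaGeneSet(genes=[f"G{i}" for i in range(12)],
                                n_from_normal_markers=12, n_from_tumor_variable=12)
        combined = proj.combine_and_correct(tumor, normal, meta)
        assert combined.n_profiles == 9

    def test_cohort_offset_removed_exactly(self):
        tumor, normal = self._toy(offset=5.0)
        meta = proj.MetaGeneSet(genes=[f"G{i}" for i in range(12)],
                                n_from_normal_markers=12, n_from_tumor_variable=12)
        combined = proj.combine_and_correct(tumor, normal, meta)
        t_cols = [c for c in combined.values.columns if c.startswith("t")]
        n_cols = [c for c in combined.values.columns if c.startswith("n")]
        assert np.allclose(combined.values[t_cols].mean(axis=1), 0.0, atol=1e-12)
        assert np.allclose(combined.values[n_cols].mean(axis=1), 0.0, atol=1e-12)

    def test_missing_meta_gene_error(self):
        tumor, normal = self._toy()
        meta = proj.MetaGeneSet(genes=["NOPE"], n_from_normal_markers=1,
                                n_from_tumor_variable=1)
        with pytest.raises(KeyError):
            proj.combine_and_correct(tumor, normal, meta)


def _noiseless_combined(n_tumor_per_lineage=4, noise=0.0, seed=0,
                        permute=False) -> PseudobulkMatrix:
    rng = np.random.default_rng(seed)
    genes = [f"G{i:02d}" for i in range(30)]
    centers = {"BM": rng.normal(0, 1, 30), "LP": rng.normal(0, 1, 30),
               "ML": rng.normal(0, 1, 30)}
    cols, kinds, lineages, names = [], [], [], []
    for lin in ("BM", "LP", "ML"):
        for i in range(n_tumor_per_lineage):
            cols.append(centers[lin] + rng.normal(0, noise, 30))
            kinds.append("tumor_cluster"); lineages.append(lin)
            names.append(f"t_{lin}_{i}")
        cols.append(centers[lin] + rng.normal(0, noise, 30))
        kinds.append("normal_subset"); lineages.append(lin)
        names.append(f"n_{lin}")
    order = rng.permutation(len(names)) if permute else np.arange(len(names))
    values = pd.DataFrame(np.array(cols).T[:, order], index=genes,
                          columns=[names[i] for i in order])
    meta = pd.DataFrame({"origin_kind": [kinds[i] for i in order],
                         "label": values.columns, "n_cells": 5,
                         "lineage": [lineages[i] for i in order]},
                        index=values.columns)
    meta.loc[meta["origin_kind"] == "tumor_cluster", "lineage"] = None
    return PseudobulkMatrix(values=values, profile_meta=meta), \
        {names[i]: lineages[i] for i in range(len(names))}


class TestMajorGroups:
    def test_noiseless_profiles_perfectly_assigned(self):
        combined, truth = _noiseless_combined(noise=0.05)
        origin = proj.cluster_major_groups(combined, k=3)
        for profile, group in origin.profile_group.items():
            assert group == truth[profile]

    def test_k_below_lineage_count_error(self):
        combined, _ = _noiseless_combined()
        with pytest.raises(ValueError):
            proj.cluster_major_groups(combined, k=1)

    def test_group_without_reference_error(self):
        combined, _ = _noiseless_combined()
        meta = combined.profile_meta
        keep = meta["origin_kind"] != "normal_subset"
        keep |= meta.index.str.endswith("BM")
        trimmed = PseudobulkMatrix(values=combined.values.loc[:, keep],
                                   profile_meta=meta.loc[keep])
        with pytest.raises(proj.UnlabelableGroupError):
            proj.cluster_major_groups(trimmed, k=3)

    def test_order_invariance(self):
        c1, truth = _noiseless_combined(noise=0.05, seed=3)
        c2, _ = _noiseless_combined(noise=0.05, seed=3, permute=True)
        g1 = proj.cluster_major_groups(c1, k=3).profile_group
        g2 = proj.cluster_major_groups(c2, k=3).profile_group
        assert g1.sort_index().equals(g2.sort_index())

    def test_synthetic_lineage_recovery(self, small_normal, small_tumor,
                                        small_normal_expr):
        """Tumor pseudobulk profiles cluster with their generative lineage."""
        from sklearn.metrics import adjusted_rand_score

        from lineagemap import preprocess as pp

        tf, _ = pp.qc_filter_cells(small_tumor.counts)
        tf, _ = pp.qc_filter_genes(tf)
        shared = small_normal_expr.columns.intersection(tf.var_names)
        tumor_expr = pp.normalize_log(tf)[shared]
        normal_expr = small_normal_expr[shared]
        labels = small_normal.true_subset.reindex(normal_expr.index)
        normal_pb = pp.aggregate_pseudobulk(normal_expr, labels,
                                            origin_kind="normal_subset",
                                            label_prefix="n:")
        lin_of = {s: l for s, l in zip(small_normal.true_subset,
                                       small_normal.true_lineage)}
        normal_pb.profile_meta["lineage"] = normal_pb.profile_meta["label"].map(lin_of)
        clusters = pp.cluster_cells(tumor_expr, n_pcs=10, resolution=1.0, seed=0)
        tumor_pb = pp.aggregate_pseudobulk(tumor_expr, clusters,
                                           origin_kind="tumor_cluster",
                                           label_prefix="t:")
        markers = proj.select_subset_markers(normal_expr, labels, top_n=100)
        variable = proj.select_variable_genes(tumor_pb, top_frac=0.05)
        meta = proj.intersect_meta_genes(markers, variable)
        combined = proj.combine_and_correct(tumor_pb, normal_pb, meta)
        origin = proj.cluster_major_groups(combined, k=3)
        cell_origin = proj.propagate_cell_origins(
            clusters, origin.profile_group[tumor_pb.values.columns],
            label_prefix="t:")
        true_lin = small_tumor.true_lineage.reindex(cell_origin.index)
        assert adjusted_rand_score(true_lin, cell_origin) > 0.9


class TestSampleSubtype:
    def test_dominant_lineage(self):
        origins = pd.Series(["BM"] * 9 + ["LP", "ML"], index=range(11))
        samples = pd.Series(["s1"] * 11, index=range(11))
        out = proj.assign_sample_subtype(origins, samples)
        assert out["s1"] == "BM"

    def test_mixed_below_dominance(self):
        origins = pd.Series(["BM"] * 40 + ["LP"] * 35 + ["ML"] * 25, index=range(100))
        samples = pd.Series(["s1"] * 100, index=range(100))
        assert proj.assign_sample_subtype(origins, samples, dominance=0.5)["s1"] == "Mixed"

    def test_zero_dominance_always_argmax(self):
        origins = pd.Series(["BM", "LP", "LP"], index=range(3))
        samples = pd.Series(["s1"] * 3, index=range(3))
        out = proj.assign_sample_subtype(origins, samples, dominance=0.0)
        assert out["s1"] == "LP"

    def test_unlabelled_cells_error(self):
        origins = pd.Series(["BM", None], index=range(2))
        samples = pd.Series(["s1", "s1"], index=range(2))
        with pytest.raises(ValueError):
            proj.assign_sample_subtype(origins, samples)
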