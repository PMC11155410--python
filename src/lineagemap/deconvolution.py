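"""Lineage marker selection via the D-distance scheme and dampened weighted
least-squares (DWLS) deconvolution of bulk expression into BM/LP/ML
proportions.

Each gene is placed in a correlation plane: x = Spearman correlation of its
expression with the BM composition across samples, y = with the LP
composition. Genes near the flag (0, 1) track LP alone, near (1, 1) track
both LP and BM, near (1, 0) track BM alone. Squared distances to these
flags,

    D1 = x^2 + (y - 1)^2
    D2 = (x - 1)^2 + (y - 1)^2
    D3 = (x - 1)^2 + y^2

define the marker sets: LP markers are the union of the top-150 smallest-D1
and smallest-D2 genes, BM markers the union of the top-150 smallest-D2 and
smallest-D3 genes, and ML markers the top-150 genes by correlation with the
ML composition.

The solver estimates per-sample proportions p >= 0 from bulk = S p by
iteratively reweighted nonnegative least squares with per-gene weights
1 / max((S p)_g^2, eps), dampened by capping the weights at d times the
minimum weight; d is chosen per sample from {1, 2, 4, 8, 16, 32} by
cross-validation over gene folds. The final p is clipped at zero and
renormalized to the simplex.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.optimize import nnls

LINEAGES = ("BM", "LP", "ML")
_EPS = 1e-12


@dataclass
class DistanceCoordinates:
    """Per-gene Spearman correlations with the lineage compositions."""

    x: pd.Series  # correlation with BM composition
    y: pd.Series  # correlation with LP composition
    rho_ml: pd.Series  # correlation with ML composition

    def finite_genes(self) -> pd.Index:
        ok = self.x.notna() & self.y.notna() & self.rho_ml.notna()
        return self.x.index[ok]


@dataclass
class SignatureBasis:
    """Marker-gene x lineage mean-expression basis for the solver."""

    values: pd.DataFrame  # genes x (BM, LP, ML)
    marker_sets: dict[str, list[str]]

    def __post_init__(self) -> None:
        if list(self.values.columns) != list(LINEAGES):
            self.values = self.values[list(LINEAGES)]


@dataclass
class BulkProportions:
    proportions: pd.DataFrame  # samples x (BM, LP, ML)
    subtype: pd.Series | None = None
    dampening: pd.Series | None = None
    n_iterations: pd.Series | None = None


def compute_origin_correlations(
    expr_by_sample: pd.DataFrame,  # genes x samples
    lineage_fractions: pd.DataFrame,  # samples x (BM, LP, ML)
) -> DistanceCoordinates:
    """Spearman correlation of every gene with each lineage composition.

    Constant genes get missing coordinates and are excluded downstream.
    """
    if expr_by_sample.shape[1] < 3:
        raise ValueError("need at least 3 samples for rank correlations")
    fr = lineage_fractions.reindex(expr_by_sample.columns)
    if fr.isna().any().any():
        raise ValueError("lineage fractions missing for some samples")
    X = expr_by_sample.to_numpy(dtype=float)
    const = X.std(axis=1) == 0
    # Spearman = Pearson on ranks, vectorized over genes
    from scipy.stats import rankdata

    RX = rankdata(X, axis=1)
    RX = RX - RX.mean(axis=1, keepdims=True)
    xnorm = np.sqrt((RX**2).sum(axis=1))
    rho = {}
    for lin in LINEAGES:
        rf = rankdata(fr[lin].to_numpy())
        rf = rf - rf.mean()
        fnorm = np.sqrt((rf**2).sum())
        if fnorm == 0:
            r = np.full(X.shape[0], np.nan)
        else:
            with np.errstate(invalid="ignore", divide="ignore"):
                r = (RX @ rf) / (xnorm * fnorm)
        r[const] = np.nan
        rho[lin] = pd.Series(r, index=expr_by_sample.index)
    return DistanceCoordinates(x=rho["BM"], y=rho["LP"], rho_ml=rho["ML"])


def compute_D_distances(coords: DistanceCoordinates) -> pd.DataFrame:
    """Squared distances of each gene to the three correlation-plane flags."""
    x, y = coords.x, coords.y
    ok = x.notna() & y.notna()
    if (~ok).any():
        warnings.warn(
            f"{int((~ok).sum())} genes with missing coordinates excluded",
            stacklevel=2,
        )
    x, y = x[ok], y[ok]
    return pd.DataFrame(
        {
            "D1": x**2 + (y - 1) ** 2,
            "D2": (x - 1) ** 2 + (y - 1) ** 2,
            "D3": (x - 1) ** 2 + y**2,
        }
    )


def _top_by(series: pd.Series, top_n: int, ascending: bool) -> list[str]:
    vals = series.dropna()
    if len(vals) < top_n:
        warnings.warn(
            f"only {len(vals)} finite genes available for top_n={top_n}; taking all",
            stacklevel=3,
        )
        top_n = len(vals)
    sign = 1.0 if ascending else -1.0
    order = np.lexsort((vals.index.to_numpy(), sign * vals.to_numpy()))
    return vals.index[order[:top_n]].tolist()


def select_lineage_markers(
    coords: DistanceCoordinates,
    distances: pd.DataFrame,
    top_n: int = 150,
) -> dict[str, list[str]]:
    """Marker sets per lineage.

    ML = top-``top_n`` genes by correlation with the ML composition;
    LP = union of the ``top_n`` smallest-D1 and smallest-D2 genes;
    BM = union of the ``top_n`` smallest-D2 and smallest-D3 genes.
    LP and BM may overlap through D2.
    """
    ml = _top_by(coords.rho_ml, top_n, ascending=False)
    lp = sorted(set(_top_by(distances["D1"], top_n, True))
                | set(_top_by(distances["D2"], top_n, True)))
    bm = sorted(set(_top_by(distances["D2"], top_n, True))
                | set(_top_by(distances["D3"], top_n, True)))
    return {"BM": bm, "LP": lp, "ML": ml}


def build_signature_basis(
    marker_sets: dict[str, list[str]],
    normal_expr: pd.DataFrame,  # cells x genes, linear normalized
    lineage_labels: pd.Series,
) -> SignatureBasis:
    """Mean normalized expression of every marker gene per lineage."""
    genes = sorted(set().union(*marker_sets.values()))
    missing = [g for g in genes if g not in normal_expr.columns]
    if missing:
        raise KeyError(f"marker genes absent from expression: {missing[:5]}")
    labels = lineage_labels.reindex(normal_expr.index)
    cols = {}
    for lin in LINEAGES:
        mask = (labels == lin).to_numpy()
        if mask.sum() == 0:
            raise ValueError(f"lineage {lin} has zero cells")
        cols[lin] = normal_expr.loc[mask, genes].mean(axis=0)
    return SignatureBasis(values=pd.DataFrame(cols), marker_sets=marker_sets)


# ---------------------------------------------------------------------------
# DWLS solver


def _wnnls(S: np.ndarray, b: np.ndarray, w: np.ndarray) -> np.ndarray:
    sw = np.sqrt(w)
    sol, _ = nnls(S * sw[:, None], b * sw)
    return sol


def _dampened_weights(S: np.ndarray, p: np.ndarray, d: float) -> np.ndarray:
    fitted = S @ p
    w = 1.0 / np.maximum(fitted**2, _EPS)
    return np.minimum(w, d * w.min())


def _solve_sample(
    S: np.ndarray,
    b: np.ndarray,
    dampening_grid: tuple[float, ...] = (1, 2, 4, 8, 16, 32),
    n_folds: int = 4,
    tol: float = 1e-6,
    max_iter: int = 100,
    seed: int = 0,
) -> tuple[np.ndarray, float, int]:
    """One bulk sample: initial NNLS, cross-validated dampening constant,
    then iteratively reweighted NNLS to convergence."""
    p0, _ = nnls(S, b)
    if p0.sum() > 0:
        p0 = p0 / p0.sum()

    n_genes = S.shape[0]
    rng = np.random.default_rng(seed)
    perm = rng.permutation(n_genes)
    folds = np.array_split(perm, n_folds)

    def _iterate(
        Sm: np.ndarray, bm: np.ndarray, d: float, start: np.ndarray, max_iter: int = max_iter
    ) -> tuple[np.ndarray, int]:
        p = start.copy()
        for it in range(max_iter):
            w = _dampened_weights(Sm, p, d)
            p_new = _wnnls(Sm, bm, w)
            if p_new.sum() > 0:
                p_new = p_new / p_new.sum()
            if np.max(np.abs(p_new - p)) < tol:
                return p_new, it + 1
            p = p_new
        return p, max_iter

    best_d, best_err = dampening_grid[0], np.inf
    if len(dampening_grid) > 1 and n_genes >= 2 * n_folds:
        for d in dampening_grid:
            err = 0.0
            for fold in folds:
                mask = np.ones(n_genes, dtype=bool)
                mask[fold] = False
                # a short iteration budget suffices to rank dampening constants
                p_fit, _ = _iterate(S[mask], b[mask], d, p0, max_iter=min(max_iter, 20))
                err += float(np.sum((b[fold] - S[fold] @ p_fit) ** 2))
            if err < best_err - 1e-15:
                best_err, best_d = err, d
    p, n_iter = _iterate(S, b, best_d, p0)
    p = np.clip(p, 0.0, None)
    if p.sum() == 0:
        raise RuntimeError("solver collapsed to the zero vector")
    return p / p.sum(), best_d, n_iter


def dwls_deconvolve(
    basis: SignatureBasis,
    bulk: pd.DataFrame,  # genes x samples
    tol: float = 1e-6,
    max_iter: int = 100,
    seed: int = 0,
) -> BulkProportions:
    """Deconvolute every bulk sample into (BM, LP, ML) proportions.

    Shared genes between the basis and the bulk matrix are used; the basis
    must have full column rank on them.
    """
    shared = basis.values.index.intersection(bulk.index)
    if len(shared) < 3:
        raise ValueError("need at least 3 genes shared between basis and bulk")
    S = basis.values.loc[shared].to_numpy(dtype=float)
    if np.linalg.matrix_rank(S) < S.shape[1]:
        raise ValueError("signature basis is rank-deficient on the shared genes")
    B = bulk.loc[shared]
    out, damp, iters = {}, {}, {}
    for j, sample in enumerate(B.columns):
        b = B[sample].to_numpy(dtype=float)
        if not np.any(b > 0):
            raise ValueError(f"bulk sample {sample!r} is all zero")
        p, d, it = _solve_sample(S, b, tol=tol, max_iter=max_iter, seed=seed + j)
        out[sample] = p
        damp[sample], iters[sample] = d, it
    props = pd.DataFrame(out, index=list(LINEAGES)).T
    return BulkProportions(
        proportions=props,
        dampening=pd.Series(damp),
        n_iterations=pd.Series(iters),
    )


def call_bulk_subtype(props: BulkProportions, dominance: float = 0.5) -> pd.Series:
    """Dominant lineage per sample if its proportion reaches ``dominance``,
    else ``Mixed``."""
    P = props.proportions
    top = P.idxmax(axis=1)
    top_val = P.max(axis=1)
    subtype = top.where(top_val >= dominance, "Mixed").rename("subtype")
    props.subtype = subtype
    return subtype
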