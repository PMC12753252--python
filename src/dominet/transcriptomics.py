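"""PLS association between a regional statistic map and gene expression.

The combined-z (or T) map of a group contrast is regressed on a regions x
genes expression matrix with partial least squares.  Significance of the
first component's explained expression variance comes from a permutation
test over region labels; gene-weight stability from bootstrap resampling of
regions; downstream gene lists are ranked by the full-model component-1
weight magnitudes, and candidate gene sets are scored with an upper-tail
hypergeometric test.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats
from sklearn.cross_decomposition import PLSRegression

from .mega import fdr_bh

__all__ = [
    "PLSResult",
    "pls_fit",
    "pls_permutation",
    "pls_bootstrap",
    "rank_top_genes",
    "hypergeom_enrich",
    "read_gmt",
]


@dataclass
class PLSResult:
    """First components of a PLS fit of map ~ genes.

    ``x_variance_explained`` is each component's share of the (standardized)
    gene-block variance; ``y_variance_explained`` its share of the response
    variance.  ``weights`` are the component-defining gene weight vectors
    (columns = components); sign convention: correlation(PLS1 scores,
    response) >= 0.
    """

    scores: np.ndarray  # regions x components
    weights: np.ndarray  # genes x components
    x_variance_explained: np.ndarray
    y_variance_explained: np.ndarray
    component1_response_r: float
    gene_names: list[str]
    n_components: int
    permutation_p: float | None = None
    bootstrap: pd.DataFrame | None = None


def _standardize(X: np.ndarray, ddof: int = 1) -> np.ndarray:
    X = np.asarray(X, dtype=float)
    mu = X.mean(axis=0)
    sd = X.std(axis=0, ddof=ddof)
    sd = np.where(sd > 0, sd, 1.0)
    return (X - mu) / sd


def pls_fit(
    response: np.ndarray,
    genes: pd.DataFrame | np.ndarray,
    n_components: int = 10,
) -> PLSResult:
    """PLS regression of a regional map on standardized gene expression.

    Requires at least 10 regions and a non-constant response.  Component 1
    is oriented so its scores correlate nonnegatively with the response.
    """
    y = np.asarray(response, dtype=float)
    if isinstance(genes, pd.DataFrame):
        gene_names = [str(c) for c in genes.columns]
        X = genes.to_numpy(dtype=float)
    else:
        X = np.asarray(genes, dtype=float)
        gene_names = [f"g{k}" for k in range(X.shape[1])]
    n_regions = X.shape[0]
    if y.size != n_regions:
        raise ValueError("response length must match the gene matrix rows")
    if n_regions < 10:
        raise ValueError(f"need at least 10 regions, got {n_regions}")
    if np.std(y) == 0:
        raise ValueError("constant response map")
    n_components = min(n_components, n_regions - 1, X.shape[1])

    Xs = _standardize(X)
    ys = (y - y.mean()) / y.std(ddof=1)
    pls = PLSRegression(n_components=n_components, scale=False)
    pls.fit(Xs, ys)
    T = pls.x_scores_  # regions x comps, orthogonal columns
    P = pls.x_loadings_
    W = pls.x_weights_

    total_x = np.sum(Xs**2)
    total_y = np.sum(ys**2)
    x_var = np.array(
        [np.sum(T[:, a] ** 2) * np.sum(P[:, a] ** 2) / total_x for a in range(n_components)]
    )
    y_var = np.array(
        [(T[:, a] @ ys) ** 2 / (np.sum(T[:, a] ** 2) * total_y) for a in range(n_components)]
    )

    # orient each component so scores correlate nonnegatively with the response
    for a in range(n_components):
        if np.corrcoef(T[:, a], ys)[0, 1] < 0:
            T[:, a] *= -1
            W[:, a] *= -1
            P[:, a] *= -1
    r1 = float(np.corrcoef(T[:, 0], ys)[0, 1])

    return PLSResult(
        scores=T,
        weights=W,
        x_variance_explained=x_var,
        y_variance_explained=y_var,
        component1_response_r=r1,
        gene_names=gene_names,
        n_components=n_components,
    )


def pls1_explained_x(response: np.ndarray, Xs: np.ndarray) -> float:
    """Share of gene-block variance explained by the first PLS component.

    For a univariate response the first weight vector is proportional to
    X^T y, so the statistic has the closed form ||X^T t||^2 / (||t||^2 ||X||_F^2)
    with t = X X^T y.  Used by the permutation test, where refitting the full
    model thousands of times would be wasteful; equivalence with
    :func:`pls_fit` is exercised in the test suite.
    """
    y = np.asarray(response, dtype=float)
    ys = (y - y.mean()) / y.std(ddof=1)
    w = Xs.T @ ys
    t = Xs @ w
    tt = t @ t
    if tt == 0:
        return 0.0
    return float((np.sum((Xs.T @ t) ** 2) / tt) / np.sum(Xs**2))


def pls_permutation(
    response: np.ndarray,
    genes: pd.DataFrame | np.ndarray,
    B: int = 5000,
    seed: int = 0,
    exact: bool = False,
) -> float:
    """Permutation p-value for the PLS1 explained expression variance.

    Region labels of the response are permuted ``B`` times;
    p = (1 + #{permuted statistic >= observed}) / (B + 1).  With
    ``exact=True`` all n! orderings are enumerated instead (feasible only
    for small region counts) and p is the exact proportion of orderings
    with statistic >= observed (the identity ordering guarantees p >= 1/n!).
    """
    if B < 1:
        raise ValueError("B must be >= 1")
    y = np.asarray(response, dtype=float)
    X = genes.to_numpy(dtype=float) if isinstance(genes, pd.DataFrame) else np.asarray(genes, dtype=float)
    Xs = _standardize(X)
    observed = pls1_explained_x(y, Xs)
    ys = (y - y.mean()) / y.std(ddof=1)
    if exact:
        from itertools import permutations
        from math import factorial

        if y.size > 8:
            raise ValueError("exact enumeration is limited to 8 regions")
        perms = list(permutations(range(y.size)))
        Yp = np.column_stack([ys[list(p)] for p in perms])
        B = factorial(y.size)
    else:
        rng = np.random.default_rng(seed)
        # vectorized over permutations: columns of Yp are permuted responses
        Yp = np.empty((y.size, B))
        for b in range(B):
            Yp[:, b] = ys[rng.permutation(y.size)]
    W = Xs.T @ Yp  # genes x B
    T = Xs @ W  # regions x B
    tt = np.sum(T**2, axis=0)
    num = np.sum((Xs.T @ T) ** 2, axis=0)
    with np.errstate(divide="ignore", invalid="ignore"):
        stat = np.where(tt > 0, num / tt, 0.0) / np.sum(Xs**2)
    exceed = int(np.sum(stat >= observed - 1e-12))
    if exact:
        return exceed / B
    return (1 + exceed) / (B + 1)


def pls_bootstrap(
    response: np.ndarray,
    genes: pd.DataFrame | np.ndarray,
    B: int = 5000,
    seed: int = 0,
) -> pd.DataFrame:
    """Bootstrap stability of PLS1 gene weights.

    Regions are resampled with replacement; each resample's first weight
    vector is sign-aligned to the full-model component before accumulating.
    Returns a per-gene table with the full-model weight, bootstrap SE and
    stability Z = weight / SE.  Degenerate resamples (a single unique
    region) are redrawn and counted.
    """
    if B < 2:
        raise ValueError("B must be >= 2")
    y = np.asarray(response, dtype=float)
    if isinstance(genes, pd.DataFrame):
        gene_names = [str(c) for c in genes.columns]
        X = genes.to_numpy(dtype=float)
    else:
        X = np.asarray(genes, dtype=float)
        gene_names = [f"g{k}" for k in range(X.shape[1])]
    n = y.size
    Xs = _standardize(X)
    ys = (y - y.mean()) / y.std(ddof=1)
    w_full = Xs.T @ ys
    norm = np.linalg.norm(w_full)
    if norm == 0:
        raise ValueError("response is orthogonal to every gene")
    w_full = w_full / norm

    rng = np.random.default_rng(seed)
    acc = np.zeros(X.shape[1])
    acc2 = np.zeros(X.shape[1])
    redrawn = 0
    b = 0
    while b < B:
        idx = rng.integers(0, n, size=n)
        yb = y[idx]
        if np.unique(idx).size < 2 or np.std(yb) == 0:
            redrawn += 1
            continue
        Xb = _standardize(X[idx])
        ysb = (yb - yb.mean()) / yb.std(ddof=1)
        wb = Xb.T @ ysb
        nb = np.linalg.norm(wb)
        if nb == 0:
            redrawn += 1
            continue
        wb = wb / nb
        if wb @ w_full < 0:
            wb = -wb
        acc += wb
        acc2 += wb**2
        b += 1
    mean = acc / B
    se = np.sqrt(np.maximum(acc2 / B - mean**2, 0.0) * B / (B - 1))
    with np.errstate(divide="ignore", invalid="ignore"):
        z = np.where(se > 0, w_full / se, np.inf * np.sign(w_full))
    return pd.DataFrame(
        {
            "gene": gene_names,
            "weight": w_full,
            "boot_mean": mean,
            "boot_se": se,
            "stability_z": z,
            "n_redrawn": redrawn,
        }
    )


def rank_top_genes(result: PLSResult, k: int = 500) -> list[str]:
    """Top-k genes by |full-model PLS1 weight|, ties broken by gene name."""
    n_genes = len(result.gene_names)
    if k > n_genes:
        raise ValueError(f"k={k} exceeds the {n_genes} available genes")
    w = result.weights[:, 0]
    order = sorted(range(n_genes), key=lambda g: (-abs(w[g]), result.gene_names[g]))
    return [result.gene_names[g] for g in order[:k]]


def hypergeom_enrich(
    gene_list: list[str],
    gene_sets: dict[str, set[str] | list[str]],
    background: list[str],
    q: float = 0.05,
) -> pd.DataFrame:
    """Upper-tail hypergeometric enrichment of a ranked gene list.

    Each candidate set is intersected with the background; p is
    P(overlap >= observed) under sampling len(gene_list) genes without
    replacement from the background.  BH-FDR is applied across sets.
    """
    bg = set(background)
    if not bg:
        raise ValueError("empty background")
    hits = set(gene_list)
    if not hits <= bg:
        raise ValueError("gene_list must be a subset of the background")
    M, n_draw = len(bg), len(hits)
    rows = []
    for name, members in gene_sets.items():
        members_bg = set(members) & bg
        k_set = len(members_bg)
        overlap = len(members_bg & hits)
        p = float(stats.hypergeom.sf(overlap - 1, M, k_set, n_draw))
        rows.append({"set": name, "set_size": k_set, "overlap": overlap, "p": p})
    df = pd.DataFrame(rows)
    if len(df):
        df["p_adjusted"], df["significant"] = fdr_bh(df["p"].to_numpy(), q=q)
    return df


def read_gmt(path) -> dict[str, set[str]]:
    """Read gene sets from a GMT file (set name, description, members...)."""
    sets: dict[str, set[str]] = {}
    with open(path) as fh:
        for line in fh:
            parts = line.rstrip("\n").split("\t")
            if len(parts) < 3:
                continue
            sets[parts[0]] = set(g for g in parts[2:] if g)
    return sets
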