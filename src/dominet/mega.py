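"""Multi-site mega-analysis of regional centrality values.

Each acquisition site is tested separately (group contrast with age and sex
adjusted in a linear model), the per-site p-values are turned into signed
z-scores, and the sites are combined with the sample-size-weighted
Liptak-Stouffer formula

    z = sum_i w_i z_i / sqrt(sum_i w_i^2),    w_i = sqrt(n_i).

Benjamini-Hochberg FDR control is applied across regions.
"""

from __future__ import annotations

from dataclasses import dataclass, field
import warnings

import numpy as np
import pandas as pd
from scipy import stats
from statsmodels.stats.multitest import multipletests

__all__ = [
    "SiteTestResult",
    "MegaResult",
    "site_group_test",
    "stouffer_combine",
    "fdr_bh",
    "mega_contrast",
]


@dataclass
class SiteTestResult:
    """Covariate-adjusted group contrast at one site, per region."""

    site: str
    t: np.ndarray
    p: np.ndarray
    n: int
    contrast: str = ""


@dataclass
class MegaResult:
    """Combined evidence across sites, per region."""

    combined_z: np.ndarray
    combined_p: np.ndarray
    p_adjusted: np.ndarray
    significant: np.ndarray
    site_z: np.ndarray  # sites x regions
    weights: np.ndarray  # per-site sqrt(n_i)
    k: int
    contrast: str = ""
    site_results: list[SiteTestResult] = field(default_factory=list)

    def to_frame(self, region_ids: np.ndarray | None = None) -> pd.DataFrame:
        n_regions = self.combined_z.size
        if region_ids is None:
            region_ids = np.arange(1, n_regions + 1)  # 1-based for users
        df = pd.DataFrame(
            {
                "region": region_ids,
                "combined_z": self.combined_z,
                "combined_p": self.combined_p,
                "p_adjusted": self.p_adjusted,
                "significant": self.significant,
            }
        )
        for res in self.site_results:
            df[f"t_{res.site}"] = res.t
            df[f"p_{res.site}"] = res.p
        return df


def _check_collinear(X: np.ndarray, names: list[str]) -> None:
    """Raise naming the first column linearly dependent on its predecessors."""
    r = np.linalg.matrix_rank(X)
    if r == X.shape[1]:
        return
    for j in range(1, X.shape[1]):
        if np.linalg.matrix_rank(X[:, : j + 1]) < j + 1:
            raise ValueError(f"design is collinear: covariate {names[j]!r}")
    raise ValueError("design is rank deficient")  # pragma: no cover


def linear_model_t(
    Y: np.ndarray, X: np.ndarray, coef_index: int, names: list[str] | None = None
) -> tuple[np.ndarray, np.ndarray]:
    """t statistic and two-sided p of one coefficient, fitted per column of Y.

    Ordinary least squares via the normal equations, vectorized across the
    columns of ``Y`` (regions).  Returns (t, p) arrays of length Y.shape[1].
    """
    Y = np.asarray(Y, dtype=float)
    X = np.asarray(X, dtype=float)
    n, p_dim = X.shape
    if names is None:
        names = [f"x{j}" for j in range(p_dim)]
    _check_collinear(X, names)
    xtx_inv = np.linalg.inv(X.T @ X)
    beta = xtx_inv @ X.T @ Y
    resid = Y - X @ beta
    dof = n - p_dim
    if dof <= 0:
        raise ValueError(f"not enough observations ({n}) for {p_dim} coefficients")
    sigma2 = (resid**2).sum(axis=0) / dof
    se = np.sqrt(sigma2 * xtx_inv[coef_index, coef_index])
    with np.errstate(divide="ignore", invalid="ignore"):
        t = np.where(se > 0, beta[coef_index] / se, 0.0)
    p = 2 * stats.t.sf(np.abs(t), dof)
    return t, p


def site_group_test(
    values: np.ndarray,
    groups: np.ndarray,
    covariates: pd.DataFrame | None = None,
    site: str = "",
    contrast: tuple[str, str] = ("HC", "AD"),
) -> SiteTestResult:
    """Group contrast at one site, adjusting for age and sex.

    Fits value ~ intercept + group + covariates per region and reports the t
    and two-sided p of the group coefficient (second group of ``contrast``
    coded 1, first coded 0, so positive t means higher values in the second
    group).
    """
    values = np.asarray(values, dtype=float)
    groups = np.asarray(groups)
    cov_arr = None
    cov_names: list[str] = []
    if covariates is not None:
        cov_arr = np.asarray(covariates, dtype=float)
        cov_names = [str(c) for c in covariates.columns]
    mask = np.isin(groups, contrast)
    if mask.sum() < values.shape[0]:
        values = values[mask]
        groups = groups[mask]
        if cov_arr is not None:
            cov_arr = cov_arr[mask]
    for g in contrast:
        if (groups == g).sum() < 3:
            raise ValueError(f"site {site!r}: fewer than 3 subjects in group {g!r}")
    indicator = (groups == contrast[1]).astype(float)
    cols = [np.ones(values.shape[0]), indicator]
    names = ["intercept", "group"]
    if cov_arr is not None:
        for j, name in enumerate(cov_names):
            cols.append(cov_arr[:, j])
            names.append(name)
    X = np.column_stack(cols)
    t, p = linear_model_t(values, X, coef_index=1, names=names)
    return SiteTestResult(
        site=site, t=t, p=p, n=int(values.shape[0]), contrast=f"{contrast[0]} vs {contrast[1]}"
    )


def stouffer_combine(site_results: list[SiteTestResult], q: float = 0.05) -> MegaResult:
    """Liptak-Stouffer combination of per-site tests with sqrt(n) weights.

    The printed transform z_i = Phi^-1(1 - p_i/2) is magnitude-only, so the
    sign of the site t is attached to z_i before weighting — increases and
    decreases combine directionally rather than cancelling into magnitudes.
    """
    if not site_results:
        raise ValueError("no site results to combine")
    n_regions = site_results[0].p.size
    for res in site_results:
        if res.p.size != n_regions:
            raise ValueError("sites cover different region sets")
    k = len(site_results)
    tiny = np.finfo(float).tiny
    site_z = np.empty((k, n_regions))
    weights = np.empty(k)
    for i, res in enumerate(site_results):
        p = np.asarray(res.p, dtype=float)
        if np.any(p <= 0):
            warnings.warn("p-value of 0 clipped to smallest positive float")
            p = np.clip(p, tiny, None)
        site_z[i] = np.sign(res.t) * stats.norm.isf(p / 2)
        weights[i] = np.sqrt(res.n)
    combined_z = (weights @ site_z) / np.sqrt((weights**2).sum())
    combined_p = 2 * stats.norm.sf(np.abs(combined_z))
    p_adj, reject = fdr_bh(combined_p, q=q)
    return MegaResult(
        combined_z=combined_z,
        combined_p=combined_p,
        p_adjusted=p_adj,
        significant=reject,
        site_z=site_z,
        weights=weights,
        k=k,
        contrast=site_results[0].contrast,
        site_results=list(site_results),
    )


def fdr_bh(pvals: np.ndarray, q: float = 0.05) -> tuple[np.ndarray, np.ndarray]:
    """Benjamini-Hochberg step-up: (monotone adjusted p, rejection mask)."""
    pvals = np.asarray(pvals, dtype=float)
    if pvals.size == 0:
        return np.empty(0), np.empty(0, dtype=bool)
    reject, p_adj, _, _ = multipletests(pvals, alpha=q, method="fdr_bh")
    return p_adj, reject


def mega_contrast(
    values: np.ndarray,
    subjects: pd.DataFrame,
    contrast: tuple[str, str] = ("HC", "AD"),
    covariate_names: tuple[str, ...] = ("age", "sex"),
    q: float = 0.05,
) -> MegaResult:
    """Full mega-analysis over a subjects x regions value table.

    ``subjects`` must carry columns ``site``, ``diagnosis`` and the requested
    covariates, aligned row-wise with ``values``.
    """
    site_results = []
    for site_id in sorted(subjects["site"].unique()):
        at_site = np.asarray(subjects["site"] == site_id)
        in_contrast = at_site & np.asarray(subjects["diagnosis"].isin(contrast))
        covs = subjects.loc[in_contrast, list(covariate_names)].reset_index(drop=True)
        res = site_group_test(
            values[in_contrast],
            np.asarray(subjects.loc[in_contrast, "diagnosis"]),
            covariates=covs,
            site=str(site_id),
            contrast=contrast,
        )
        site_results.append(res)
    return stouffer_combine(site_results, q=q)
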