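"""Demographic-table statistics for multi-site cohorts.

Sex distributions between diagnostic groups are compared with Pearson's
chi-square test (no continuity correction); age and cognitive-score
comparisons use one-way ANOVA reconstructed from per-group (n, mean, sd)
summaries, so published demographic tables can be checked without raw data.

The module ships the published seven-site MCADI demographic summaries as
structured data; the synthetic-cohort preset mirrors their group sizes.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import stats

__all__ = [
    "ContingencyTable",
    "GroupSummary",
    "chisq_independence",
    "anova_from_summary",
    "MCADI_SEX_COUNTS",
    "MCADI_AGE_SUMMARIES",
    "MCADI_MMSE_SUMMARIES",
    "MCADI_GROUP_SIZES",
]


@dataclass
class ContingencyTable:
    counts: np.ndarray
    row_labels: tuple[str, ...] = ()
    col_labels: tuple[str, ...] = ()

    def __post_init__(self) -> None:
        self.counts = np.asarray(self.counts)
        if self.counts.ndim != 2:
            raise ValueError("counts must be 2-D")
        if np.any(self.counts < 0):
            raise ValueError("counts must be nonnegative")
        if self.counts.sum() == 0:
            raise ValueError("grand total must be positive")


@dataclass
class GroupSummary:
    """Per-group sufficient statistics for one-way ANOVA."""

    n: int
    mean: float
    sd: float

    def __post_init__(self) -> None:
        if self.n < 2:
            raise ValueError("each group needs n >= 2")
        if self.sd < 0:
            raise ValueError("sd must be nonnegative")


def chisq_independence(table: ContingencyTable) -> tuple[float, int, float]:
    """Pearson chi-square test of independence, no continuity correction.

    Returns (chi2, df, upper-tail p).  Raises on a zero row or column
    marginal (expected counts undefined).
    """
    counts = table.counts
    if np.any(counts.sum(axis=0) == 0) or np.any(counts.sum(axis=1) == 0):
        raise ValueError("table has a zero marginal row or column")
    chi2, p, df, _ = stats.chi2_contingency(counts, correction=False)
    return float(chi2), int(df), float(p)


def anova_from_summary(groups: list[GroupSummary]) -> tuple[float, int, int, float]:
    """One-way ANOVA from (n, mean, sd) group summaries.

    Between-group sums of squares come from the group means; within-group
    from (n-1) * sd^2.  Returns (F, df1, df2, p).  If all within-group
    variance is zero and the means agree, F is defined as 0 with p = 1.
    """
    if len(groups) < 2:
        raise ValueError("need at least 2 groups")
    ns = np.array([g.n for g in groups], dtype=float)
    means = np.array([g.mean for g in groups], dtype=float)
    sds = np.array([g.sd for g in groups], dtype=float)
    n_total = ns.sum()
    grand = (ns * means).sum() / n_total
    ssb = (ns * (means - grand) ** 2).sum()
    ssw = ((ns - 1) * sds**2).sum()
    df1 = len(groups) - 1
    df2 = int(n_total) - len(groups)
    msb = ssb / df1
    msw = ssw / df2
    if msw == 0:
        if msb == 0:
            return 0.0, df1, df2, 1.0
        return float("inf"), df1, df2, 0.0
    f = msb / msw
    return float(f), df1, df2, float(stats.f.sf(f, df1, df2))


# ---------------------------------------------------------------------------
# Published MCADI demographic summaries (seven sites, HC/MCI/AD).
# Sex counts are (male, female) per group; age and MMSE are (n, mean, sd).
# ---------------------------------------------------------------------------

MCADI_SEX_COUNTS: dict[str, list[tuple[int, int]]] = {
    "S01": [(19, 22), (13, 21), (20, 24)],
    "S02": [(11, 10), (11, 12), (6, 18)],
    "S03": [(9, 15), (10, 23), (18, 19)],
    "S04": [(12, 30), (8, 8), (29, 37)],
    "S05": [(25, 39), (46, 47), (14, 25)],
    "S06": [(7, 14), (10, 8), (16, 17)],
    "S07": [(20, 22), (13, 24), (16, 25)],
}

MCADI_AGE_SUMMARIES: dict[str, list[tuple[int, float, float]]] = {
    "S01": [(41, 68.6, 6.7), (34, 69.5, 8.8), (44, 69.9, 8.9)],
    "S02": [(21, 68.6, 4.7), (23, 73.3, 8.3), (24, 72.8, 8.3)],
    "S03": [(24, 65.5, 6.2), (33, 65.4, 8.3), (37, 67.7, 8.3)],
    "S04": [(42, 65.5, 6.8), (16, 66.1, 7.4), (66, 68.0, 7.1)],
    "S05": [(64, 66.6, 6.3), (93, 67.9, 10.0), (39, 68.8, 8.8)],
    "S06": [(21, 65.0, 8.2), (18, 70.2, 7.9), (33, 65.5, 7.9)],
    "S07": [(42, 68.3, 8.0), (37, 69.8, 6.9), (41, 70.2, 8.7)],
}

MCADI_MMSE_SUMMARIES: dict[str, list[tuple[int, float, float]]] = {
    "S01": [(41, 28.5, 1.4), (34, 26.6, 2.5), (44, 17.3, 6.5)],
    "S02": [(21, 28.9, 1.1), (23, 27.0, 1.8), (24, 19.2, 4.6)],
    "S03": [(24, 28.8, 1.2), (33, 25.9, 2.5), (37, 15.8, 5.5)],
    "S04": [(42, 28.5, 1.7), (16, 24.8, 1.5), (66, 18.9, 3.4)],
    "S05": [(64, 28.1, 2.2), (93, 24.1, 3.7), (39, 16.6, 6.7)],
    "S06": [(21, 28.5, 1.4), (18, 21.9, 5.0), (33, 10.0, 6.8)],
    "S07": [(42, 28.8, 1.2), (37, 26.3, 2.6), (41, 15.8, 5.8)],
}

#: per-site (n_HC, n_MCI, n_AD), consistent with the sex counts above
MCADI_GROUP_SIZES: list[tuple[int, int, int]] = [
    (41, 34, 44),
    (21, 23, 24),
    (24, 33, 37),
    (42, 16, 66),
    (64, 93, 39),
    (21, 18, 33),
    (42, 37, 41),
]


def demographics_report() -> "pd.DataFrame":  # noqa: F821 - lazy import
    """Per-site sex chi-square and age/MMSE ANOVA p-values for MCADI."""
    import pandas as pd

    rows = []
    for site in sorted(MCADI_SEX_COUNTS):
        chi2, df, p_sex = chisq_independence(
            ContingencyTable(np.array(MCADI_SEX_COUNTS[site]))
        )
        _, _, _, p_age = anova_from_summary(
            [GroupSummary(*g) for g in MCADI_AGE_SUMMARIES[site]]
        )
        _, _, _, p_mmse = anova_from_summary(
            [GroupSummary(*g) for g in MCADI_MMSE_SUMMARIES[site]]
        )
        rows.append(
            {"site": site, "chi2_sex": chi2, "p_sex": p_sex, "p_age": p_age, "p_mmse": p_mmse}
        )
    return pd.DataFrame(rows)
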