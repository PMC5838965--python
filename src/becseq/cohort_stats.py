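"""Cohort-level statistics: demographic tests, ANCOVA, proportion comparison.

Covers the descriptive/comparative layer of the study: Fisher exact tests
for categorical demographics, Student/Welch t for continuous ones,
single-covariate ANCOVA for covariate-adjusted group differences in
(log10) transcript abundance, and the N-1 chi-squared comparison of two
proportions used for the cis-regulatory-SNP enrichment test.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats
import statsmodels.api as sm

__all__ = [
    "ContingencyTable2x2",
    "AncovaResult",
    "fisher_exact",
    "two_sample_t",
    "ancova_group_difference",
    "n1_chi_squared",
    "demographics_table",
]


@dataclass(frozen=True)
class ContingencyTable2x2:
    a: int
    b: int
    c: int
    d: int

    def __post_init__(self) -> None:
        if min(self.a, self.b, self.c, self.d) < 0:
            raise ValueError("counts must be non-negative")
        if self.a + self.b + self.c + self.d == 0:
            raise ValueError("empty table")

    def as_array(self) -> np.ndarray:
        return np.array([[self.a, self.b], [self.c, self.d]])


@dataclass(frozen=True)
class AncovaResult:
    adjusted_difference: float
    F: float
    p: float
    covariates: tuple[str, ...]
    flag: str | None = None


def fisher_exact(table: ContingencyTable2x2) -> float:
    """Two-sided Fisher exact p by the probability-mass rule.

    Sums hypergeometric probabilities of all tables (with the observed
    margins) whose point probability does not exceed the observed one —
    the convention of R's ``fisher.test``.
    """
    return float(stats.fisher_exact(table.as_array(), alternative="two-sided")[1])


def two_sample_t(
    group1: np.ndarray, group2: np.ndarray, welch: bool = False
) -> tuple[float, float]:
    """Two-sided two-sample t test.

    Pooled-variance (Student) form by default; ``welch`` switches to the
    unequal-variance form.  Degenerate input (both groups constant and
    equal) returns (0, 1).
    """
    g1 = np.asarray(group1, dtype=float)
    g2 = np.asarray(group2, dtype=float)
    if g1.size < 2 or g2.size < 2:
        raise ValueError("need at least 2 values per group")
    if np.var(g1) == 0 and np.var(g2) == 0:
        if g1.mean() == g2.mean():
            return 0.0, 1.0
    res = stats.ttest_ind(g1, g2, equal_var=not welch)
    return float(res.statistic), float(res.pvalue)


def ancova_group_difference(
    y: np.ndarray,
    group: np.ndarray,
    covariate: np.ndarray | None = None,
    covariate_name: str = "covariate",
) -> AncovaResult:
    """Covariate-adjusted group difference by least squares.

    Fits ``y ~ intercept + group + covariate`` and reports the group
    coefficient (adjusted difference, group1 - group2 in sorted label
    order) with its partial F test.  With no covariate this reduces
    exactly to the pooled-variance two-sample t test (F = t^2).  A
    covariate collinear with the group indicator cannot be adjusted for:
    the unadjusted result is returned with a flag.
    """
    y = np.asarray(y, dtype=float)
    group = np.asarray(group)
    labels = np.unique(group)
    if labels.size != 2:
        raise ValueError("exactly two groups required")
    if y.size <= 3:
        raise ValueError("need more than 3 observations")
    g = (group == labels[0]).astype(float)
    cols = [np.ones_like(y), g]
    names = ["intercept", "group"]
    flag = None
    if covariate is not None:
        cov = np.asarray(covariate, dtype=float)
        if np.var(cov) == 0:
            flag = "constant_covariate"
        else:
            r = np.corrcoef(cov, g)[0, 1]
            if abs(r) > 1 - 1e-10:
                flag = "collinear_covariate"
            else:
                cols.append(cov)
                names.append(covariate_name)
    Xd = np.column_stack(cols)
    model = sm.OLS(y, Xd).fit()
    idx = names.index("group")
    coef = float(model.params[idx])
    tval = float(model.tvalues[idx])
    F = tval**2
    p = float(model.pvalues[idx])
    covs = tuple(names[2:])
    return AncovaResult(coef, F, p, covs, flag)


def n1_chi_squared(k1: int, n1: int, k2: int, n2: int) -> tuple[float, float]:
    """N-1 chi-squared comparison of two proportions k1/n1 vs k2/n2.

    Pearson's chi-squared on the 2x2 table scaled by (N-1)/N — the
    recommended small-sample comparison of two independent proportions.
    A zero margin (e.g. both proportions 0 or 1) carries no information
    and returns (0, 1).
    """
    if n1 <= 0 or n2 <= 0 or not (0 <= k1 <= n1) or not (0 <= k2 <= n2):
        raise ValueError("invalid proportion counts")
    a, b = k1, n1 - k1
    c, d = k2, n2 - k2
    N = n1 + n2
    margins = [(a + b), (c + d), (a + c), (b + d)]
    if 0 in margins:
        return 0.0, 1.0
    chi2 = (a * d - b * c) ** 2 * (N - 1) / np.prod([float(m) for m in margins])
    return float(chi2), float(stats.chi2.sf(chi2, df=1))


def demographics_table(meta: pd.DataFrame) -> pd.DataFrame:
    """Group comparison of the standard demographic/clinical variables.

    ``meta`` needs columns cohort, age, sex, pack_years, smoking_status,
    fev1_fvc.  Continuous variables use the Student t test; categorical
    ones the Fisher exact test — the conventional Table-1 layout.
    """
    cohorts = sorted(meta["cohort"].unique())
    if len(cohorts) != 2:
        raise ValueError("need exactly two cohorts")
    g1 = meta[meta["cohort"] == cohorts[0]]
    g2 = meta[meta["cohort"] == cohorts[1]]
    rows = []
    for var in ("age", "pack_years", "fev1_fvc"):
        _, p = two_sample_t(g1[var], g2[var])
        rows.append((var, g1[var].mean(), g2[var].mean(), p, "t"))
    for var, level in (("sex", "male"), ("smoking_status", "current")):
        t = ContingencyTable2x2(
            int((g1[var] == level).sum()), int((g1[var] != level).sum()),
            int((g2[var] == level).sum()), int((g2[var] != level).sum()),
        )
        rows.append((var, (g1[var] == level).mean(), (g2[var] == level).mean(),
                     fisher_exact(t), "fisher"))
    return pd.DataFrame(
        rows, columns=["variable", cohorts[0], cohorts[1], "p", "test"]
    ).set_index("variable")
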