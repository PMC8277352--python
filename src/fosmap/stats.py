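"""Statistical tests used across the pipeline, returned in a uniform record.

Repeated-binary and repeated-ordinal acquisition curves are tested with
Cochran's Q and Friedman's rank test (both implemented from their closed forms,
with tie correction and explicit degenerate-case handling); group comparisons
use Student's pooled t, one-way ANOVA, Wilcoxon signed-rank and Pearson
correlation via scipy.  ``opener_power`` enumerates the exact power of a
one-sided Fisher test for the incidence-of-openers design.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy import stats as sps

__all__ = [
    "TestResult",
    "cochran_q",
    "friedman",
    "ttest_two_sample",
    "anova_oneway",
    "wilcoxon_signed_rank",
    "pearson",
    "correct_pvalues",
    "opener_power",
]


@dataclass
class TestResult:
    """Uniform record of a statistical test."""

    method: str
    statistic: float
    df: float | tuple
    p_value: float
    n: int
    extras: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        if not (np.isnan(self.p_value) or 0.0 <= self.p_value <= 1.0):
            raise ValueError(f"p_value {self.p_value} outside [0, 1]")

    @property
    def degenerate(self) -> bool:
        return bool(self.extras.get("degenerate", False))

    def to_record(self) -> dict:
        if np.isscalar(self.df):
            df = float(self.df)
        else:
            df = [float(v) for v in np.atleast_1d(self.df)]
        return {
            "method": self.method,
            "statistic": float(self.statistic),
            "df": df,
            "p": float(self.p_value),
            "n": int(self.n),
        }


def cochran_q(binary_matrix) -> TestResult:
    """Cochran's Q for related binary outcomes (rats x days).

    Q = (k-1) * [k * sum(C_j^2) - N^2] / (k * N - sum(R_i^2)), referred to a
    chi-square with k-1 df.  Rows that are all-0 or all-1 contribute nothing.
    If every row is constant the statistic is degenerate (Q = 0, p = 1).
    """
    x = np.asarray(binary_matrix, dtype=float)
    if x.ndim != 2 or x.shape[1] < 2:
        raise ValueError("need a 2-D matrix with >= 2 columns")
    if np.isnan(x).any():
        raise ValueError("missing entries not allowed")
    if not np.isin(x, (0.0, 1.0)).all():
        raise ValueError("entries must be 0/1")
    n_rows, k = x.shape
    col = x.sum(axis=0)
    row = x.sum(axis=1)
    N = x.sum()
    denom = k * N - (row**2).sum()
    if denom == 0:
        return TestResult(
            "cochran_q", 0.0, k - 1, 1.0, n_rows, {"degenerate": True}
        )
    q = (k - 1) * (k * (col**2).sum() - N**2) / denom
    p = float(sps.chi2.sf(q, k - 1))
    return TestResult("cochran_q", float(q), k - 1, p, n_rows)


def friedman(matrix) -> TestResult:
    """Friedman rank test for related samples (rats x days), tie-corrected.

    Rows are ranked with mid-ranks; the tie-corrected statistic is
    chi2 = (12 / (n k (k+1)) * sum(R_j^2) - 3 n (k+1)) / C with
    C = 1 - sum(t^3 - t) / (n k (k^2 - 1)) over tie groups.
    """
    x = np.asarray(matrix, dtype=float)
    if x.ndim != 2 or x.shape[1] < 2:
        raise ValueError("need a 2-D matrix with >= 2 columns")
    if np.isnan(x).any():
        raise ValueError("missing entries not allowed")
    n, k = x.shape
    ranks = np.apply_along_axis(sps.rankdata, 1, x)
    rj = ranks.sum(axis=0)
    chi2 = 12.0 / (n * k * (k + 1)) * (rj**2).sum() - 3.0 * n * (k + 1)
    # tie correction over rows
    tie_sum = 0.0
    for i in range(n):
        _, counts = np.unique(x[i], return_counts=True)
        tie_sum += float((counts**3 - counts).sum())
    correction = 1.0 - tie_sum / (n * k * (k**2 - 1))
    if correction <= 0:  # all rows entirely tied
        return TestResult("friedman", 0.0, k - 1, 1.0, n, {"degenerate": True})
    chi2 /= correction
    p = float(sps.chi2.sf(chi2, k - 1))
    return TestResult("friedman", float(chi2), k - 1, p, n)


def ttest_two_sample(a, b, paired: bool = False) -> TestResult:
    """Two-sample t test: Student's pooled-variance (unpaired) or paired."""
    a = np.asarray(a, dtype=float)
    b = np.asarray(b, dtype=float)
    if paired:
        if len(a) != len(b) or len(a) < 2:
            raise ValueError("paired test needs equal lengths >= 2")
        if np.std(a - b) == 0 and not np.allclose(a, b):
            raise ValueError("zero variance of differences")
        res = sps.ttest_rel(a, b)
        df = len(a) - 1
        n = len(a)
        method = "paired_t"
    else:
        if len(a) < 2 or len(b) < 2:
            raise ValueError("unpaired test needs n >= 2 per group")
        sp2 = ((len(a) - 1) * np.var(a, ddof=1) + (len(b) - 1) * np.var(b, ddof=1))
        if sp2 == 0:
            raise ValueError("zero pooled variance")
        res = sps.ttest_ind(a, b, equal_var=True)
        df = len(a) + len(b) - 2
        n = len(a) + len(b)
        method = "student_t"
    stat = float(res.statistic)
    extras = {"mean_a": float(a.mean()), "mean_b": float(b.mean())}
    return TestResult(method, stat, df, float(res.pvalue), n, extras)


def anova_oneway(groups) -> TestResult:
    """One-way ANOVA with a Bonferroni pairwise post-hoc table in ``extras``."""
    arrs = [np.asarray(g, dtype=float) for g in groups]
    if len(arrs) < 2 or any(len(g) < 2 for g in arrs):
        raise ValueError("need >= 2 groups with n >= 2 each")
    if all(np.var(g) == 0 for g in arrs) and len({g[0] for g in arrs}) <= len(arrs):
        if sum((len(g) - 1) * np.var(g, ddof=1) for g in arrs) == 0:
            raise ValueError("zero within-group variance")
    res = sps.f_oneway(*arrs)
    g = len(arrs)
    N = sum(len(a) for a in arrs)
    m = g * (g - 1) // 2
    posthoc = []
    for i in range(g):
        for j in range(i + 1, g):
            t = ttest_two_sample(arrs[i], arrs[j])
            posthoc.append(
                {
                    "pair": (i, j),
                    "t": t.statistic,
                    "p_raw": t.p_value,
                    "p_bonferroni": min(1.0, m * t.p_value),
                }
            )
    extras = {
        "group_means": [float(a.mean()) for a in arrs],
        "posthoc_bonferroni": posthoc,
    }
    return TestResult(
        "anova_oneway", float(res.statistic), (g - 1, N - g), float(res.pvalue), N,
        extras,
    )


def wilcoxon_signed_rank(pre, post) -> TestResult:
    """Wilcoxon signed-rank for paired samples.

    Zero differences are dropped; exact null distribution for n <= 25, else a
    continuity-corrected normal approximation.  All-zero differences give a
    degenerate result with p = 1.
    """
    pre = np.asarray(pre, dtype=float)
    post = np.asarray(post, dtype=float)
    if len(pre) != len(post):
        raise ValueError("paired vectors must have equal length")
    d = post - pre
    nz = d[d != 0]
    if len(nz) == 0:
        return TestResult(
            "wilcoxon_signed_rank", 0.0, np.nan, 1.0, 0, {"degenerate": True}
        )
    if len(nz) < 5:
        raise ValueError("need >= 5 nonzero differences")
    if len(nz) <= 25:
        res = sps.wilcoxon(nz, method="exact")
    else:
        res = sps.wilcoxon(nz, method="approx", correction=True)
    return TestResult(
        "wilcoxon_signed_rank",
        float(res.statistic),
        np.nan,
        float(res.pvalue),
        len(nz),
        {"mode": "exact" if len(nz) <= 25 else "normal_approx"},
    )


def pearson(x, y) -> TestResult:
    """Pearson correlation with t-based p value (no multiplicity correction)."""
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if len(x) != len(y) or len(x) < 3:
        raise ValueError("need equal-length vectors with n >= 3")
    if np.var(x) == 0 or np.var(y) == 0:
        raise ValueError("zero variance")
    res = sps.pearsonr(x, y)
    r = float(res.statistic)
    return TestResult(
        "pearson", r, len(x) - 2, float(res.pvalue), len(x), {"r_squared": r**2}
    )


def correct_pvalues(p, method: str = "bonferroni") -> np.ndarray:
    """Multiple-comparison correction: bonferroni min(1, m*p) or sidak 1-(1-p)^m."""
    p = np.asarray(p, dtype=float)
    if ((p < 0) | (p > 1)).any():
        raise ValueError("p values must lie in [0, 1]")
    m = len(p)
    if method == "bonferroni":
        return np.minimum(1.0, m * p)
    if method == "sidak":
        return 1.0 - (1.0 - p) ** m
    raise ValueError(f"unknown method {method!r}")


def opener_power(
    n_per_group: int,
    p_ingroup: float,
    p_outgroup: float,
    alpha: float = 0.05,
    alternative: str = "greater",
) -> float:
    """Exact power of a one-sided Fisher test for opener incidence.

    Enumerates all (k1, k2) binomial outcomes for two groups of *n_per_group*
    rats with opener probabilities *p_ingroup* and *p_outgroup*, applies a
    Fisher exact test to each 2x2 table, and sums the probability of
    rejection at level *alpha*.
    """
    if not (0 <= p_ingroup <= 1 and 0 <= p_outgroup <= 1):
        raise ValueError("probabilities must lie in [0, 1]")
    n = n_per_group
    pmf1 = sps.binom.pmf(np.arange(n + 1), n, p_ingroup)
    pmf2 = sps.binom.pmf(np.arange(n + 1), n, p_outgroup)
    power = 0.0
    for k1 in range(n + 1):
        for k2 in range(n + 1):
            table = [[k1, n - k1], [k2, n - k2]]
            _, p = sps.fisher_exact(table, alternative=alternative)
            if p <= alpha:
                power += pmf1[k1] * pmf2[k2]
    return float(power)
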