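"""Nonparametric contrast statistics for drug-state comparisons.

The analysis uses rank tests throughout: a Kolmogorov-Smirnov normality
check documents that the data are non-Gaussian (the pipeline proceeds
nonparametrically regardless of its outcome), paired contrasts use the
Wilcoxon signed-rank test (exact null distribution for small samples) and
unpaired contrasts the Wilcoxon rank-sum / Mann-Whitney U test.  All tests
are two-sided; p > alpha (0.05) is considered not significant.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import stats as sps

ALPHA = 0.05
#: Largest n for which the signed-rank / rank-sum null is enumerated exactly.
EXACT_N_MAX = 25


@dataclass
class TestResult:
    test: str                      # wilcoxon_signed_rank | wilcoxon_rank_sum | ks_normality
    statistic: float
    p_value: float
    n: int
    n2: int | None = None
    alpha: float = ALPHA
    flagged: str | None = None     # e.g. "all differences zero"

    def __post_init__(self) -> None:
        if not 0.0 <= self.p_value <= 1.0:
            raise ValueError(f"p-value {self.p_value} outside [0, 1]")

    @property
    def significant(self) -> bool:
        return self.p_value <= self.alpha


def ks_normality_gate(sample: np.ndarray, alpha: float = ALPHA) -> TestResult:
    """Kolmogorov-Smirnov test against a normal with the sample's mean/SD.

    The gate only documents (non-)normality; downstream contrasts are
    nonparametric either way.
    """
    x = np.asarray(sample, dtype=float).ravel()
    if x.size < 8:
        raise ValueError(f"need at least 8 samples, got {x.size}")
    sd = x.std(ddof=1)
    if sd == 0:
        raise ValueError("degenerate (constant) sample")
    stat, p = sps.kstest(x, "norm", args=(x.mean(), sd))
    return TestResult(test="ks_normality", statistic=float(stat),
                      p_value=float(p), n=x.size, alpha=alpha)


def paired_contrast(
    baseline_values: np.ndarray,
    post_values: np.ndarray,
    alpha: float = ALPHA,
) -> TestResult:
    """Two-sided Wilcoxon signed-rank test on paired values.

    Exact null distribution when the number of non-zero differences is at
    most 25 and |differences| are tie-free; otherwise the normal
    approximation with tie/zero handling.  All-zero differences return the
    p = 1 convention, flagged.
    """
    base = np.asarray(baseline_values, dtype=float).ravel()
    post = np.asarray(post_values, dtype=float).ravel()
    if base.size != post.size:
        raise ValueError("paired samples must have equal length")
    if base.size == 0:
        raise ValueError("empty sample")
    d = post - base
    nz = d[d != 0]
    if nz.size == 0:
        return TestResult(test="wilcoxon_signed_rank", statistic=0.0,
                          p_value=1.0, n=base.size, alpha=alpha,
                          flagged="all differences zero")
    tie_free = np.unique(np.abs(nz)).size == nz.size
    method = "exact" if (nz.size <= EXACT_N_MAX and tie_free) else "approx"
    res = sps.wilcoxon(d, zero_method="wilcox", alternative="two-sided",
                       method=method)
    return TestResult(test="wilcoxon_signed_rank",
                      statistic=float(res.statistic),
                      p_value=float(res.pvalue), n=base.size, alpha=alpha)


def unpaired_contrast(
    group1: np.ndarray,
    group2: np.ndarray,
    alpha: float = ALPHA,
) -> TestResult:
    """Two-sided Wilcoxon rank-sum (Mann-Whitney U), exact for small n."""
    g1 = np.asarray(group1, dtype=float).ravel()
    g2 = np.asarray(group2, dtype=float).ravel()
    if g1.size < 3 or g2.size < 3:
        raise ValueError("each group needs at least 3 values")
    pooled = np.concatenate([g1, g2])
    tie_free = np.unique(pooled).size == pooled.size
    method = "exact" if (tie_free and g1.size + g2.size <= 2 * EXACT_N_MAX) \
        else "asymptotic"
    res = sps.mannwhitneyu(g1, g2, alternative="two-sided", method=method)
    return TestResult(test="wilcoxon_rank_sum", statistic=float(res.statistic),
                      p_value=float(res.pvalue), n=g1.size, n2=g2.size,
                      alpha=alpha)


def benjamini_hochberg(p_values: np.ndarray, alpha: float = ALPHA) -> np.ndarray:
    """FDR-adjusted significance flags (optional; off by default upstream)."""
    from statsmodels.stats.multitest import multipletests
    p = np.asarray(p_values, dtype=float)
    reject, *_ = multipletests(p, alpha=alpha, method="fdr_bh")
    return reject
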