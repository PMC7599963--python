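"""Cohort-level classical statistics and ROI correlation analysis.

Conventions match the three-group migraine study design these tools
serve: Pearson chi-square without continuity correction for r x c
contingency tables, two-sided Fisher exact for 2 x 2, pooled-variance
two-tailed t (df = n_a + n_b - 2, so summaries printed as mean +/- SD
per group suffice), Mann-Whitney U reported as the smaller U,
Kruskal-Wallis with tie correction, a Kolmogorov-Smirnov + Levene gate
between parametric and rank tests, and Spearman rank correlations with
Benjamini-Hochberg FDR adjustment across the regions of one
measure-covariate family.
"""
from __future__ import annotations

import warnings
from dataclasses import dataclass
from typing import Sequence

import numpy as np
import pandas as pd
from scipy import stats
from statsmodels.stats.multitest import multipletests

from .data_io import ValidationError

__all__ = [
    "TestResult", "CorrelationRecord", "GateDecision",
    "chi_square_test", "fisher_exact_test", "two_sample_test",
    "kruskal_wallis", "normality_homogeneity_gate", "bh_adjust",
    "roi_correlations", "one_way_anova",
]


@dataclass(frozen=True)
class TestResult:
    test: str
    statistic: float
    p: float
    df: float | None = None
    groups: tuple | None = None

    def __post_init__(self):
        if not (0 <= self.p <= 1):
            raise ValidationError(f"p-value {self.p} outside [0, 1]")


@dataclass(frozen=True)
class CorrelationRecord:
    region: str
    measure: str
    covariate: str
    rho: float
    p: float
    p_adjusted: float
    n: int

    @property
    def significant(self) -> bool:
        return self.p_adjusted < 0.05


def _as_table(table) -> np.ndarray:
    t = np.asarray(table, dtype=float)
    if t.ndim != 2 or t.shape[0] < 2 or t.shape[1] < 2:
        raise ValidationError("contingency table must be at least 2 x 2")
    if np.any(t < 0) or not np.allclose(t, np.round(t)):
        raise ValidationError("contingency table must hold non-negative counts")
    if np.any(t.sum(axis=0) == 0) or np.any(t.sum(axis=1) == 0):
        raise ValidationError("contingency table has a zero marginal")
    return t


def chi_square_test(table) -> TestResult:
    """Pearson chi-square on an r x c count table, no continuity correction."""
    t = _as_table(table)
    chi2, p, df, _ = stats.chi2_contingency(t, correction=False)
    return TestResult("chi-square", float(chi2), float(p), df=float(df))


def fisher_exact_test(table) -> TestResult:
    """Two-sided Fisher exact test on a 2 x 2 table.

    Two-sided rule: sum of hypergeometric probabilities of tables no
    more probable than the observed one.
    """
    t = _as_table(table)
    if t.shape != (2, 2):
        raise ValidationError("Fisher exact test requires a 2 x 2 table")
    odds, p = stats.fisher_exact(t, alternative="two-sided")
    return TestResult("fisher-exact", float(odds), float(p))


def _is_summary(x) -> bool:
    return isinstance(x, tuple) and len(x) == 3 and np.isscalar(x[0])


def two_sample_test(a, b, kind: str = "t") -> TestResult:
    """Two-tailed unpaired comparison of two independent samples.

    ``kind="t"``: pooled-variance t; ``a``/``b`` may be raw arrays or
    ``(mean, sd, n)`` summaries.  ``kind="mann_whitney"``: Mann-Whitney
    U from raw samples (smaller U reported; normal approximation with
    tie correction when both n > 20, exact otherwise).
    """
    if kind == "t":
        if _is_summary(a) or _is_summary(b):
            if not (_is_summary(a) and _is_summary(b)):
                raise ValidationError("mix of raw and summary input")
            (m1, s1, n1), (m2, s2, n2) = a, b
        else:
            a = np.asarray(a, float)
            b = np.asarray(b, float)
            if len(a) < 2 or len(b) < 2:
                raise ValidationError("each group needs n >= 2")
            m1, s1, n1 = a.mean(), a.std(ddof=1), len(a)
            m2, s2, n2 = b.mean(), b.std(ddof=1), len(b)
        if n1 < 2 or n2 < 2:
            raise ValidationError("each group needs n >= 2")
        res = stats.ttest_ind_from_stats(m1, s1, n1, m2, s2, n2, equal_var=True)
        return TestResult("t", float(res.statistic), float(res.pvalue),
                          df=float(n1 + n2 - 2))
    if kind == "mann_whitney":
        if _is_summary(a) or _is_summary(b):
            raise ValidationError("the Mann-Whitney U test needs raw samples")
        a = np.asarray(a, float)
        b = np.asarray(b, float)
        if len(a) < 2 or len(b) < 2:
            raise ValidationError("each group needs n >= 2")
        method = "asymptotic" if min(len(a), len(b)) > 20 else "exact"
        try:
            res = stats.mannwhitneyu(a, b, alternative="two-sided", method=method)
        except ValueError:
            res = stats.mannwhitneyu(a, b, alternative="two-sided",
                                     method="asymptotic")
        u_small = min(float(res.statistic), len(a) * len(b) - float(res.statistic))
        return TestResult("mann-whitney", u_small, float(res.pvalue))
    raise ValueError(f"unknown test kind {kind!r}")


def kruskal_wallis(*samples) -> TestResult:
    """Kruskal-Wallis H across >= 3 groups, tie-corrected."""
    if len(samples) < 3:
        raise ValidationError("Kruskal-Wallis needs >= 3 groups "
                              "(use two_sample_test for two)")
    arrays = [np.asarray(s, float) for s in samples]
    if any(len(s) < 2 for s in arrays):
        raise ValidationError("each group needs >= 2 values")
    pooled = np.concatenate(arrays)
    if np.ptp(pooled) == 0:
        return TestResult("kruskal-wallis", 0.0, 1.0, df=float(len(samples) - 1))
    h, p = stats.kruskal(*arrays)
    return TestResult("kruskal-wallis", float(h), float(p),
                      df=float(len(samples) - 1))


def one_way_anova(*samples) -> TestResult:
    """Standard one-way ANOVA (the parametric three-group branch)."""
    if len(samples) < 3:
        raise ValidationError("one-way ANOVA here is for >= 3 groups")
    f, p = stats.f_oneway(*[np.asarray(s, float) for s in samples])
    k = len(samples)
    n = sum(len(s) for s in samples)
    return TestResult("anova", float(f), float(p), df=float(k - 1))


@dataclass(frozen=True)
class GateDecision:
    choice: str                 # "parametric" | "rank"
    ks_pvalues: tuple
    levene_p: float | None
    reason: str


def normality_homogeneity_gate(samples: Sequence, alpha: float = 0.05
                               ) -> GateDecision:
    """Choose parametric vs rank-based testing.

    Kolmogorov-Smirnov against a normal with each sample's mean/SD, and
    Levene's test (center = mean) across samples; if either rejects at
    ``alpha`` the rank-based branch is selected.  Samples smaller than 5
    default to rank-based with a warning.
    """
    arrays = [np.asarray(s, float) for s in samples]
    if any(len(s) < 5 for s in arrays):
        warnings.warn("sample of n < 5: defaulting to rank-based tests",
                      stacklevel=2)
        return GateDecision("rank", (), None, "n < 5")
    ks_ps = []
    for s in arrays:
        sd = s.std(ddof=1)
        if sd == 0:
            return GateDecision("rank", tuple(ks_ps), None, "zero variance")
        ks_ps.append(float(stats.kstest(s, "norm", args=(s.mean(), sd)).pvalue))
    lev_p = float(stats.levene(*arrays, center="mean").pvalue)
    if any(p < alpha for p in ks_ps):
        return GateDecision("rank", tuple(ks_ps), lev_p, "normality rejected")
    if lev_p < alpha:
        return GateDecision("rank", tuple(ks_ps), lev_p, "homogeneity rejected")
    return GateDecision("parametric", tuple(ks_ps), lev_p, "assumptions hold")


def bh_adjust(pvalues) -> np.ndarray:
    """Benjamini-Hochberg step-up adjusted p-values."""
    p = np.asarray(pvalues, dtype=float)
    if p.size == 0:
        return p
    return multipletests(p, method="fdr_bh")[1]


def roi_correlations(roi_means: pd.DataFrame, covariate, measure: str,
                     covariate_name: str) -> list:
    """Spearman correlation of per-region means against one covariate.

    ``roi_means`` is subjects x regions for a single measure; BH
    adjustment runs across the regions of this one (measure, covariate)
    family.  Ties use average ranks (Spearman's convention).
    """
    cov = np.asarray(covariate, dtype=float)
    if roi_means.shape[0] != cov.size:
        raise ValidationError("covariate length does not match subject count")
    if cov.size < 4:
        raise ValidationError("correlation needs >= 4 subjects")
    if np.ptp(cov) == 0:
        raise ValidationError("covariate is constant")
    rhos, ps = [], []
    for region in roi_means.columns:
        rho, p = stats.spearmanr(roi_means[region].to_numpy(), cov)
        rhos.append(float(rho))
        ps.append(float(p))
    adj = bh_adjust(ps)
    return [
        CorrelationRecord(str(region), measure, covariate_name,
                          rhos[i], ps[i], float(adj[i]), int(cov.size))
        for i, region in enumerate(roi_means.columns)
    ]
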