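"""Group-comparison statistics used across the study's figures.

Covers the Yates-corrected chi-square on 2x2 responder tables, Mann-Whitney U
(min-U convention, exact p for small samples), the two-sample
Kolmogorov-Smirnov test on amplitude distributions, paired/unpaired t tests,
the normality/equal-variance-gated choice between t and U, and the Bonferroni
threshold used for the multi-group comparisons (0.05/3 -> 0.017).

Everything standard delegates to scipy.stats; the chi-square with continuity
correction is written out explicitly because the correction is load-bearing:
the printed test statistics on the responder tables are reproduced only with
the |O-E| - 0.5 correction applied.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy import stats

__all__ = [
    "ContingencyTable",
    "TestResult",
    "chi2_yates",
    "mann_whitney",
    "ks_two_sample",
    "t_test",
    "select_two_sample_test",
    "bonferroni_alpha",
]


@dataclass
class ContingencyTable:
    """2x2 counts, rows = condition, columns = responding / non-responding."""

    counts: np.ndarray

    def __post_init__(self) -> None:
        self.counts = np.asarray(self.counts, dtype=float)
        if self.counts.shape != (2, 2):
            raise ValueError("contingency table must be 2x2")
        if (self.counts < 0).any():
            raise ValueError("counts must be non-negative")
        if (self.counts.sum(axis=0) == 0).any() or (self.counts.sum(axis=1) == 0).any():
            raise ValueError("zero margin in contingency table")


@dataclass
class TestResult:
    statistic_name: str
    statistic: float
    p: float
    df: float | None = None
    test: str = ""
    correction: str | None = None
    note: str | None = None
    extra: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        if np.isfinite(self.p) and not (0.0 <= self.p <= 1.0):
            raise ValueError("p outside [0, 1]")


def chi2_yates(table: ContingencyTable | np.ndarray) -> TestResult:
    """Chi-square test on a 2x2 table with the Yates continuity correction.

    statistic = sum over cells of max(|O - E| - 0.5, 0)^2 / E with df = 1.
    The correction term is clamped at zero so a table with exactly equal
    proportions yields chi2 = 0.
    """
    if not isinstance(table, ContingencyTable):
        table = ContingencyTable(np.asarray(table))
    obs = table.counts
    expected = np.outer(obs.sum(axis=1), obs.sum(axis=0)) / obs.sum()
    corrected = np.maximum(np.abs(obs - expected) - 0.5, 0.0)
    chi2 = float(np.sum(corrected ** 2 / expected))
    p = float(stats.chi2.sf(chi2, df=1))
    return TestResult("chi2", chi2, p, df=1, test="chi2",
                      correction="yates")


def _has_ties(a: np.ndarray, b: np.ndarray) -> bool:
    pooled = np.concatenate([a, b])
    return len(np.unique(pooled)) < len(pooled)


def mann_whitney(a, b) -> TestResult:
    """Two-sided Mann-Whitney U test; U reported as min(U1, U2).

    Exact p by enumeration when both samples have n <= 8 and the pooled data
    are tie-free; otherwise the normal approximation with midrank tie
    correction and continuity correction.
    """
    a = np.asarray(a, dtype=float)
    b = np.asarray(b, dtype=float)
    if a.size == 0 or b.size == 0:
        raise ValueError("empty sample")
    exact = a.size <= 8 and b.size <= 8 and not _has_ties(a, b)
    method = "exact" if exact else "asymptotic"
    res = stats.mannwhitneyu(a, b, alternative="two-sided", method=method)
    u1 = float(res.statistic)
    u_min = min(u1, a.size * b.size - u1)
    return TestResult("U", u_min, float(res.pvalue), test="mann_whitney",
                      note=method, extra={"U1": u1})


def ks_two_sample(a, b) -> TestResult:
    """Two-sample Kolmogorov-Smirnov test, D = sup |ECDF_a - ECDF_b|."""
    a = np.asarray(a, dtype=float)
    b = np.asarray(b, dtype=float)
    if a.size == 0 or b.size == 0:
        raise ValueError("empty sample")
    # scipy's auto method: exact for small samples, asymptotic for the large
    # per-cell samples the amplitude comparisons actually involve
    res = stats.ks_2samp(a, b, method="auto")
    return TestResult("D", float(res.statistic), float(res.pvalue),
                      test="ks_two_sample", note="auto")


def t_test(a, b, paired: bool = False) -> TestResult:
    """Student's t test, paired or two-sample (pooled variance).

    Degenerate zero-variance inputs are flagged rather than raising: identical
    paired samples give t = 0 with a ``zero-variance`` note; a constant
    non-zero paired shift gives |t| = inf.
    """
    a = np.asarray(a, dtype=float)
    b = np.asarray(b, dtype=float)
    if paired:
        if a.size != b.size:
            raise ValueError("paired samples must have equal length")
        diff = a - b
        df = a.size - 1
        if np.allclose(diff.std(ddof=1) if a.size > 1 else 0.0, 0.0):
            if np.allclose(diff, 0.0):
                return TestResult("t", 0.0, 1.0, df=df, test="t_paired",
                                  note="zero-variance")
            t_val = np.inf if diff.mean() > 0 else -np.inf
            return TestResult("t", float(t_val), 0.0, df=df, test="t_paired",
                              note="zero-variance")
        res = stats.ttest_rel(a, b)
        return TestResult("t", float(res.statistic), float(res.pvalue),
                          df=df, test="t_paired")
    res = stats.ttest_ind(a, b, equal_var=True)
    df = a.size + b.size - 2
    stat = float(res.statistic)
    if not np.isfinite(stat):
        return TestResult("t", stat, float(res.pvalue), df=df,
                          test="t_unpaired", note="zero-variance")
    return TestResult("t", stat, float(res.pvalue), df=df, test="t_unpaired")


def select_two_sample_test(a, b, alpha_gate: float = 0.05) -> TestResult:
    """Choose Student's t versus Mann-Whitney U for two independent samples.

    Student's t is used iff the Shapiro-Wilk normality test passes for both
    samples AND the Brown-Forsythe equal-variance test (Levene with median
    centring) passes, all at ``alpha_gate``; otherwise Mann-Whitney. Samples
    with n < 3 cannot be gated and fall through to Mann-Whitney.
    """
    a = np.asarray(a, dtype=float)
    b = np.asarray(b, dtype=float)
    gates: dict = {}
    if a.size < 3 or b.size < 3:
        res = mann_whitney(a, b)
        res.note = "n<3: normality gate unavailable, Mann-Whitney forced"
        return res
    p_sw_a = float(stats.shapiro(a).pvalue)
    p_sw_b = float(stats.shapiro(b).pvalue)
    p_bf = float(stats.levene(a, b, center="median").pvalue)
    gates = {"shapiro_a": p_sw_a, "shapiro_b": p_sw_b, "brown_forsythe": p_bf}
    if min(p_sw_a, p_sw_b, p_bf) > alpha_gate:
        res = t_test(a, b, paired=False)
    else:
        res = mann_whitney(a, b)
    res.extra.update(gates)
    return res


def bonferroni_alpha(base: float = 0.05, k: int = 1) -> float:
    """Per-comparison significance threshold base/k, rounded to 3 decimals
    (0.05 over three comparisons reports as 0.017)."""
    if k < 1:
        raise ValueError("k must be >= 1")
    return round(base / k, 3)
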