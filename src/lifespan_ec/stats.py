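"""Nonparametric inference utilities: Wilcoxon tests, BH-FDR, Cohen's d.

Two-sided Wilcoxon rank-sum (independent samples, e.g. nodal peak ages
between networks) and signed-rank (paired samples, e.g. early- vs
late-life trajectory SD per region), Benjamini-Hochberg FDR adjustment
across a family of tests, and the pooled-SD Cohen's d effect size.

Exact null distributions are used at small sample sizes (rank-sum:
both groups < 10 and no ties; signed-rank: n <= 25), the tie-corrected,
continuity-corrected normal approximation otherwise.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import stats as sps
from statsmodels.stats.multitest import multipletests

RANKSUM_EXACT_MAX = 10   # exact enumeration below this per-group size
SIGNEDRANK_EXACT_MAX = 25


@dataclass
class TestResult:
    test: str
    statistic: float        # Z for approximate, exact statistic otherwise
    p_value: float
    n1: int
    n2: int
    effect_size: float = np.nan
    p_adjusted: float = np.nan
    alternative: str = "two-sided"
    note: str = ""


def _rank_sum_z(x: np.ndarray, y: np.ndarray) -> float:
    """Tie-corrected, continuity-corrected Z for the rank-sum statistic."""
    n1, n2 = len(x), len(y)
    combined = np.concatenate([x, y])
    ranks = sps.rankdata(combined)
    w = ranks[:n1].sum()
    mu = n1 * (n1 + n2 + 1) / 2.0
    _, counts = np.unique(combined, return_counts=True)
    tie_term = np.sum(counts**3 - counts) / ((n1 + n2) * (n1 + n2 - 1.0))
    var = n1 * n2 / 12.0 * (n1 + n2 + 1 - tie_term)
    if var == 0:
        return 0.0
    correction = 0.5 * np.sign(w - mu)
    return float((w - mu - correction) / np.sqrt(var))


def ranksum_test(x, y) -> TestResult:
    """Two-sided Wilcoxon rank-sum (Mann-Whitney) test.

    Positive Z means x tends larger than y.  All-tied data give p = 1.
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if len(x) == 0 or len(y) == 0:
        raise ValueError("both samples must be nonempty")
    if np.all(np.concatenate([x, y]) == np.concatenate([x, y])[0]):
        return TestResult("ranksum", 0.0, 1.0, len(x), len(y),
                          effect_size=cohens_d(x, y) if min(len(x), len(y)) >= 2 else np.nan,
                          note="all values tied")
    has_ties = len(np.unique(np.concatenate([x, y]))) < len(x) + len(y)
    exact = min(len(x), len(y)) < RANKSUM_EXACT_MAX and not has_ties
    method = "exact" if exact else "asymptotic"
    res = sps.mannwhitneyu(x, y, alternative="two-sided", method=method)
    z = _rank_sum_z(x, y)
    d = cohens_d(x, y) if min(len(x), len(y)) >= 2 else np.nan
    return TestResult("ranksum", z if not exact else float(res.statistic),
                      float(res.pvalue), len(x), len(y), effect_size=d,
                      note=method)


def signedrank_test(x, y) -> TestResult:
    """Two-sided Wilcoxon signed-rank test for paired samples.

    Zero differences are dropped (their count is reported); all-zero
    differences give p = 1.
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if len(x) != len(y):
        raise ValueError("paired samples must have equal length")
    diff = x - y
    nz = diff[diff != 0]
    n_dropped = len(diff) - len(nz)
    if len(nz) == 0:
        return TestResult("signedrank", 0.0, 1.0, len(x), len(y),
                          note=f"all {len(diff)} differences zero")
    method = "exact" if len(nz) <= SIGNEDRANK_EXACT_MAX and len(np.unique(np.abs(nz))) == len(nz) else "approx"
    res = sps.wilcoxon(nz, method=method, correction=(method == "approx"))
    d = cohens_d(x, y) if len(x) >= 2 else np.nan
    note = method + (f"; {n_dropped} zero differences dropped" if n_dropped else "")
    return TestResult("signedrank", float(res.statistic), float(res.pvalue),
                      len(x), len(y), effect_size=d, note=note)


def fdr_bh(p_values) -> np.ndarray:
    """Benjamini-Hochberg step-up adjusted p-values (input order kept)."""
    p = np.asarray(p_values, dtype=float)
    if p.size == 0:
        return p
    if np.any((p < 0) | (p > 1)) or not np.all(np.isfinite(p)):
        raise ValueError("p-values must lie in [0, 1]")
    return multipletests(p, method="fdr_bh")[1]


def cohens_d(x, y) -> float:
    """Cohen's d: mean difference over the pooled standard deviation.

    Pooled SD uses the (n1 + n2 - 2) denominator.  Returns NaN (the
    undefined-effect flag) when the pooled SD is zero.
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if len(x) < 2 or len(y) < 2:
        raise ValueError("each group needs at least 2 values")
    n1, n2 = len(x), len(y)
    pooled_var = ((n1 - 1) * x.var(ddof=1) + (n2 - 1) * y.var(ddof=1)) / (n1 + n2 - 2)
    if pooled_var == 0:
        return np.nan
    return float((x.mean() - y.mean()) / np.sqrt(pooled_var))


def pairwise_network_tests(
    values_by_group: dict, test: str = "ranksum", adjust: bool = True
) -> list[TestResult]:
    """All pairwise two-group comparisons with one BH family.

    ``values_by_group`` maps group name (e.g. network) to a 1-D sample.
    For ``test='signedrank'`` each group's entry is a (x, y) pair of
    equal-length arrays instead and groups are tested one at a time.
    """
    results: list[tuple[str, TestResult]] = []
    if test == "ranksum":
        names = list(values_by_group)
        for i, a in enumerate(names):
            for b in names[i + 1:]:
                results.append((f"{a} vs {b}", ranksum_test(values_by_group[a], values_by_group[b])))
    elif test == "signedrank":
        for name, (x, y) in values_by_group.items():
            results.append((name, signedrank_test(x, y)))
    else:
        raise ValueError(f"unknown test {test!r}")
    if adjust and results:
        adj = fdr_bh([r.p_value for _, r in results])
        for (label, r), pa in zip(results, adj):
            r.p_adjusted = float(pa)
            r.note = (r.note + "; " if r.note else "") + label
    return [r for _, r in results]
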