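"""Organism-level statistics: Mendelian segregation and summary t-tests.

Chi-square goodness-of-fit compares observed genotype counts from a cross
to expected Mendelian ratios (plain Pearson, no continuity correction).
Two-sample Student's t-tests are computed from group summary statistics
(mean, sd or sem, n) in pooled or Welch form; sem inputs are converted to
sd via sd = sem * sqrt(n) before any variance arithmetic.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

from .io_formats import CrossCounts, GroupSummary


@dataclass(frozen=True)
class TestResult:
    statistic: float
    df: float
    p: float
    method: str
    degenerate: bool = False


def chi_square_gof(cross: CrossCounts) -> TestResult:
    """Pearson chi-square goodness-of-fit to the expected ratio.

    statistic = sum (O_i - E_i)^2 / E_i with E_i = ratio_i * total,
    df = k - 1, upper-tail p.  Expected cells below 1 trigger an
    approximation-quality warning but the computation proceeds.
    """
    observed = np.asarray(cross.observed, float)
    expected = np.array([float(r) for r in cross.expected_ratio]) * observed.sum()
    if (expected < 1).any():
        warnings.warn("expected cell count below 1: chi-square approximation is poor",
                      stacklevel=2)
    stat, p = stats.chisquare(observed, f_exp=expected)
    return TestResult(float(stat), float(len(observed) - 1), float(p), "chi2_gof")


def t_from_summary(g1: GroupSummary, g2: GroupSummary,
                   variant: str = "pooled") -> TestResult:
    """Two-sample t-test from summary statistics (pooled or Welch)."""
    if variant not in ("pooled", "welch"):
        raise ValueError("variant must be 'pooled' or 'welch'")
    s1, s2 = g1.sd, g2.sd
    if s1 == 0 and s2 == 0:
        degenerate_p = 1.0 if g1.mean == g2.mean else 0.0
        stat = 0.0 if g1.mean == g2.mean else np.inf * np.sign(g1.mean - g2.mean)
        return TestResult(float(stat), float(g1.n + g2.n - 2), degenerate_p,
                          f"t_{variant}", degenerate=True)
    stat, p = stats.ttest_ind_from_stats(g1.mean, s1, g1.n, g2.mean, s2, g2.n,
                                         equal_var=(variant == "pooled"))
    if variant == "pooled":
        df = g1.n + g2.n - 2
    else:
        v1, v2 = s1 ** 2 / g1.n, s2 ** 2 / g2.n
        df = (v1 + v2) ** 2 / (v1 ** 2 / (g1.n - 1) + v2 ** 2 / (g2.n - 1))
    return TestResult(float(stat), float(df), float(p), f"t_{variant}")


def mendelian_report(crosses: dict[str, CrossCounts] | list[CrossCounts]) -> pd.DataFrame:
    """Per-cross table of observed %, counts, expected % and chi-square p."""
    if isinstance(crosses, dict):
        items = list(crosses.items())
    else:
        items = [(f"cross{i + 1}", c) for i, c in enumerate(crosses)]
    rows = []
    for cid, cross in items:
        total = sum(cross.observed)
        res = chi_square_gof(cross)
        rows.append({
            "cross_id": cid,
            "genotype_labels": ",".join(cross.genotype_labels),
            "observed": ",".join(str(o) for o in cross.observed),
            "observed_pct": ",".join(f"{100.0 * o / total:.1f}" for o in cross.observed),
            "expected_pct": ",".join(f"{100.0 * float(r):.1f}" for r in cross.expected_ratio),
            "n": total,
            "chi2": res.statistic,
            "df": res.df,
            "p": res.p,
        })
    return pd.DataFrame(rows, columns=["cross_id", "genotype_labels", "observed",
                                       "observed_pct", "expected_pct", "n",
                                       "chi2", "df", "p"])


def ttest_report(comparisons: dict[str, tuple[GroupSummary, GroupSummary]],
                 variant: str = "pooled") -> pd.DataFrame:
    """Per-comparison t-test table from group summaries."""
    rows = []
    for cid, (g1, g2) in comparisons.items():
        res = t_from_summary(g1, g2, variant=variant)
        rows.append({
            "comparison": cid,
            "group1": g1.label, "mean1": g1.mean, "n1": g1.n,
            "group2": g2.label, "mean2": g2.mean, "n2": g2.n,
            "t": res.statistic, "df": res.df, "p": res.p, "method": res.method,
        })
    return pd.DataFrame(rows, columns=["comparison", "group1", "mean1", "n1",
                                       "group2", "mean2", "n2", "t", "df", "p",
                                       "method"])
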