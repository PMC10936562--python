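"""Group-comparison statistics and the study's reporting conventions.

Wraps scipy/statsmodels: two-sided Fisher exact (probability-mass definition),
Pearson chi-square without continuity correction, Mann–Whitney U (exact for
small samples without ties), and Lilliefors/KS normality.  ``compare_word``
applies the test-selection rule used for the per-word 2×2 tables: chi-square
when at most 20% of expected cell counts fall below 5, Fisher otherwise.

Reporting conventions: means are rounded half-up to 1 decimal, percentage
shares half-up to 2 decimals, p-values to 3 decimals (printed ``<0.001``
below that); the overall percentage of the 60-word list written incorrectly
is truncated, not rounded, to 2 decimals.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from decimal import Decimal, ROUND_HALF_UP
from typing import Optional, Sequence, Union

import numpy as np
import pandas as pd
from scipy import stats

__all__ = [
    "TestResult",
    "fisher_exact_2x2",
    "chi_square_2x2",
    "expected_counts",
    "select_test",
    "compare_word",
    "compare_all_words",
    "mann_whitney",
    "ks_normality",
    "round_half_up",
    "round_p",
    "format_p",
    "truncate_pct",
    "grade_summaries",
    "describe_totals",
]

Table = Sequence[Sequence[Union[int, float]]]


@dataclass(frozen=True)
class TestResult:
    test: str  # "fisher" | "chi2" | "mannwhitney" | "lilliefors" | "ks"
    statistic: Optional[float]
    p_value: float

    @property
    def p_rounded(self) -> float:
        return round_p(self.p_value)

    @property
    def p_formatted(self) -> str:
        return format_p(self.p_value)


def _as_table(table: Table) -> np.ndarray:
    arr = np.asarray(table, dtype=float)
    if arr.shape != (2, 2):
        raise ValueError(f"expected a 2x2 table, got shape {arr.shape}")
    if (arr < 0).any():
        raise ValueError("cell counts must be non-negative")
    return arr


def fisher_exact_2x2(table: Table) -> TestResult:
    """Two-sided Fisher exact test (probability-mass two-sidedness)."""
    arr = _as_table(table)
    odds, p = stats.fisher_exact(arr, alternative="two-sided")
    return TestResult("fisher", float(odds), float(p))


def chi_square_2x2(table: Table, correction: bool = False) -> TestResult:
    """Pearson chi-square; no continuity correction by default."""
    arr = _as_table(table)
    stat, p, _, _ = stats.chi2_contingency(arr, correction=correction)
    return TestResult("chi2", float(stat), float(p))


def expected_counts(table: Table) -> np.ndarray:
    arr = _as_table(table)
    total = arr.sum()
    if total == 0:
        raise ValueError("empty table")
    return np.outer(arr.sum(axis=1), arr.sum(axis=0)) / total


def select_test(table: Table, small_expected: float = 5.0,
                max_small_fraction: float = 0.2) -> str:
    """Choose ``"chi2"`` when at most ``max_small_fraction`` of expected cell
    counts are below ``small_expected``, else ``"fisher"``."""
    exp = expected_counts(table)
    frac = float((exp < small_expected).mean())
    return "fisher" if frac > max_small_fraction else "chi2"


def compare_word(gd_correct: int, gd_incorrect: int,
                 gwd_correct: int, gwd_incorrect: int) -> Optional[TestResult]:
    """Group comparison for one word's 2×2 correct/incorrect table; ``None``
    when neither group made an error (the table is degenerate)."""
    if gd_incorrect == 0 and gwd_incorrect == 0:
        return None
    table = [[gd_correct, gd_incorrect], [gwd_correct, gwd_incorrect]]
    if select_test(table) == "chi2":
        return chi_square_2x2(table)
    return fisher_exact_2x2(table)


def compare_all_words(counts: pd.DataFrame) -> pd.DataFrame:
    """Run ``compare_word`` over a per-word count table (columns
    ``gd_correct, gd_incorrect, gwd_correct, gwd_incorrect``)."""
    rows = []
    for _, row in counts.iterrows():
        res = compare_word(row["gd_correct"], row["gd_incorrect"],
                           row["gwd_correct"], row["gwd_incorrect"])
        rows.append({
            "word_id": row["word_id"],
            "test": res.test if res else None,
            "p_value": res.p_value if res else None,
            "p": res.p_formatted if res else None,
        })
    return pd.DataFrame(rows)


def mann_whitney(x: Sequence[float], y: Sequence[float],
                 exact_max_n: int = 20) -> TestResult:
    """Two-sided Mann–Whitney U; exact null distribution when the combined
    sample is small and tie-free, asymptotic otherwise."""
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.size == 0 or y.size == 0:
        raise ValueError("both samples must be non-empty")
    pooled = np.concatenate([x, y])
    ties = len(np.unique(pooled)) < pooled.size
    method = "exact" if (pooled.size <= exact_max_n and not ties) else "asymptotic"
    res = stats.mannwhitneyu(x, y, alternative="two-sided", method=method)
    return TestResult("mannwhitney", float(res.statistic), float(res.pvalue))


def ks_normality(x: Sequence[float], method: str = "lilliefors") -> TestResult:
    """Normality check: Lilliefors-corrected KS by default; ``method="ks"``
    gives the plain KS test against N(mean, sd)."""
    x = np.asarray(x, dtype=float)
    if x.size < 4:
        raise ValueError("need at least 4 observations")
    if method == "lilliefors":
        from statsmodels.stats.diagnostic import lilliefors
        stat, p = lilliefors(x, dist="norm")
        return TestResult("lilliefors", float(stat), float(p))
    if method == "ks":
        mu, sd = x.mean(), x.std(ddof=1)
        stat, p = stats.kstest(x, "norm", args=(mu, sd))
        return TestResult("ks", float(stat), float(p))
    raise ValueError(f"unknown method {method!r}")


def round_half_up(value: float, ndigits: int = 1) -> float:
    """Decimal round-half-up (3.25 → 3.3 at 1 digit), as in the study's
    reported means and shares."""
    q = Decimal(1).scaleb(-ndigits)
    return float(Decimal(repr(float(value))).quantize(q, rounding=ROUND_HALF_UP))


def round_p(p: float) -> float:
    return round_half_up(p, 3)


def format_p(p: float) -> str:
    r = round_p(p)
    if r < 0.001:
        return "<0.001"
    return f"{r:.3f}"


def truncate_pct(numerator: float, denominator: float, ndigits: int = 2) -> float:
    """Percentage truncated (not rounded) to ``ndigits`` decimals — the
    convention behind the reported share of the word list written
    incorrectly (e.g. 28.3/60 → 47.16)."""
    if denominator == 0:
        raise ZeroDivisionError("denominator is zero")
    scale = 10 ** ndigits
    return math.floor(numerator / denominator * 100 * scale) / scale


def grade_summaries(grade_totals: pd.DataFrame) -> pd.DataFrame:
    """Per grade and group: mean incorrect words per student (half-up,
    1 decimal) and the group's share of that grade's errors (half-up,
    2 decimals)."""
    df = grade_totals.copy()
    rows = []
    for grade, sub in df.groupby("grade"):
        total = sub["total_incorrect"].sum()
        for _, row in sub.iterrows():
            share = (round_half_up(100.0 * row["total_incorrect"] / total, 2)
                     if total else float("nan"))
            rows.append({
                "grade": grade,
                "group": row["group"],
                "n_students": row["n_students"],
                "total_incorrect": row["total_incorrect"],
                "mean_incorrect": round_half_up(
                    row["total_incorrect"] / row["n_students"], 1),
                "share_pct": share,
            })
    return pd.DataFrame(rows)


def describe_totals(totals: Sequence[float]) -> dict:
    """Mean, SD, median, quartiles, min and max of per-student error totals,
    rounded per the reporting conventions."""
    x = np.asarray(totals, dtype=float)
    if x.size == 0:
        raise ValueError("empty sample")
    q1, med, q3 = np.percentile(x, [25, 50, 75])
    return {
        "n": int(x.size),
        "mean": round_half_up(float(x.mean()), 1),
        "sd": round_half_up(float(x.std(ddof=1)), 1) if x.size > 1 else 0.0,
        "median": round_half_up(float(med), 1),
        "q1": round_half_up(float(q1), 1),
        "q3": round_half_up(float(q3), 1),
        "min": float(x.min()),
        "max": float(x.max()),
    }
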