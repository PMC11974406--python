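"""Paired-rater hypothesis tests.

Two raters assess the same women, so comparisons must respect the pairing:

* :func:`mcnemar` — paired-proportion test on a binary trait, driven only by
  the discordant pairs (b = AI has the trait, radiologist does not;
  c = the reverse).
* :func:`marginal_homogeneity` — Stuart-Maxwell test that the two raters'
  category distributions agree in a paired k x k table; with k = 2 it
  reduces to the McNemar chi-square without continuity correction.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Iterable, Sequence

import numpy as np
import pandas as pd
from scipy import stats as sps

from .cohort import Cohort
from .patterns import PatternLabel, classify_cohort, percent, percent_difference

#: Below this many discordant pairs the exact binomial test is used by default.
EXACT_THRESHOLD = 25


class DegenerateTableError(ValueError):
    """Paired table too degenerate for the requested test (singular covariance)."""


@dataclass(frozen=True)
class McNemarResult:
    n_discordant_b: int  # AI has trait, reader lacks it
    n_discordant_c: int  # reader has trait, AI lacks it
    statistic: float
    p_value: float
    method: str

    def to_dict(self) -> dict:
        return {
            "n_discordant_b": self.n_discordant_b,
            "n_discordant_c": self.n_discordant_c,
            "statistic": self.statistic,
            "p_value": self.p_value,
            "method": self.method,
        }


@dataclass(frozen=True)
class MarginalHomogeneityResult:
    statistic: float
    df: int
    p_value: float
    method: str = "stuart_maxwell"

    def to_dict(self) -> dict:
        return {
            "statistic": self.statistic,
            "df": self.df,
            "p_value": self.p_value,
            "method": self.method,
        }


def mcnemar_from_counts(b: int, c: int, method: str = "auto") -> McNemarResult:
    """McNemar test given the two discordant-pair counts.

    ``method``: ``exact`` (two-sided binomial, p = min(1, 2 * BinomCDF(min(b, c);
    b + c, 1/2))), ``chi2_cc`` ((|b - c| - 1)^2 / (b + c), df = 1),
    ``chi2`` ((b - c)^2 / (b + c)), or ``auto`` — exact when b + c < 25,
    else chi-square with continuity correction (standard practice).
    With b = c = 0 the raters never disagree and p = 1, statistic 0.
    """
    if b < 0 or c < 0:
        raise ValueError("discordant counts must be non-negative")
    if method == "auto":
        method = "exact" if b + c < EXACT_THRESHOLD else "chi2_cc"
    n = b + c
    if n == 0:
        return McNemarResult(b, c, 0.0, 1.0, method)
    if method == "exact":
        stat = float(min(b, c))
        p = min(1.0, 2.0 * sps.binom.cdf(min(b, c), n, 0.5))
        # exact two-sided doubling can only overshoot through the shared
        # central term; clip handles the even-split case (p capped at 1)
        return McNemarResult(b, c, stat, float(p), "exact")
    if method == "chi2_cc":
        stat = (abs(b - c) - 1) ** 2 / n  # R/statsmodels convention, also at b == c
        p = float(sps.chi2.sf(stat, df=1))
        return McNemarResult(b, c, float(stat), p, "chi2_cc")
    if method == "chi2":
        stat = (b - c) ** 2 / n
        p = float(sps.chi2.sf(stat, df=1))
        return McNemarResult(b, c, float(stat), p, "chi2")
    raise ValueError(f"unknown method {method!r}")


def mcnemar(
    paired_flags: Sequence[tuple[bool, bool]], method: str = "auto"
) -> McNemarResult:
    """McNemar test on per-subject (ai_flag, reader_flag) boolean pairs."""
    flags = list(paired_flags)
    if not flags:
        raise ValueError("paired_flags must be non-empty")
    arr = np.asarray(flags, dtype=bool)
    b = int(np.sum(arr[:, 0] & ~arr[:, 1]))
    c = int(np.sum(~arr[:, 0] & arr[:, 1]))
    return mcnemar_from_counts(b, c, method)


@dataclass(frozen=True)
class PatternComparison:
    """AI-vs-radiologist comparison of one pattern's prevalence."""

    trait: str
    context: str
    n_women: int
    ai_count: int
    reader_count: int
    ai_percent: float
    reader_percent: float
    difference_pp: float  # rounded AI % minus rounded reader %
    ai_proportion: float
    reader_proportion: float
    test: McNemarResult

    def to_dict(self) -> dict:
        return {
            "trait": self.trait,
            "context": self.context,
            "n_women": self.n_women,
            "ai_count": self.ai_count,
            "reader_count": self.reader_count,
            "ai_percent": self.ai_percent,
            "reader_percent": self.reader_percent,
            "difference_pp": self.difference_pp,
            "ai_proportion": self.ai_proportion,
            "reader_proportion": self.reader_proportion,
            "test": self.test.to_dict(),
        }


def compare_pattern_proportions(
    cohort: Cohort,
    context: str,
    trait: PatternLabel | str,
    method: str = "auto",
) -> PatternComparison:
    """Paired comparison of how often each rater produces ``trait``.

    Each woman contributes one paired indicator (AI label == trait,
    radiologist label == trait); the indicators feed McNemar.  Percentages
    are rounded to one decimal and the headline difference is the difference
    of the rounded percentages.
    """
    trait = PatternLabel(trait)
    ai = classify_cohort(cohort, "ai", context)
    reader = classify_cohort(cohort, "reader", context)
    ai_flag = ai == trait.value
    rd_flag = reader.reindex(ai.index) == trait.value
    res = mcnemar(list(zip(ai_flag.to_numpy(), rd_flag.to_numpy())), method=method)
    n = len(cohort)
    a_cnt, r_cnt = int(ai_flag.sum()), int(rd_flag.sum())
    return PatternComparison(
        trait=trait.value,
        context=context,
        n_women=n,
        ai_count=a_cnt,
        reader_count=r_cnt,
        ai_percent=percent(a_cnt, n),
        reader_percent=percent(r_cnt, n),
        difference_pp=percent_difference(a_cnt, r_cnt, n),
        ai_proportion=a_cnt / n,
        reader_proportion=r_cnt / n,
        test=res,
    )


def paired_category_table(pairs: Iterable[tuple[int, int]]) -> np.ndarray:
    """k x k contingency table of paired (ai_category, reader_category) codes."""
    df = pd.DataFrame(list(pairs), columns=["ai", "reader"])
    cats = sorted(set(df["ai"]) | set(df["reader"]))
    tab = (
        pd.crosstab(df["ai"], df["reader"])
        .reindex(index=cats, columns=cats, fill_value=0)
        .to_numpy()
    )
    return tab


def marginal_homogeneity(
    paired_categories: Iterable[tuple[int, int]]
) -> MarginalHomogeneityResult:
    """Stuart-Maxwell test of marginal homogeneity on paired categories.

    The statistic is d' S^{-1} d on the first k - 1 marginal differences
    d_h = row_h - col_h, with S_hh = row_h + col_h - 2 n_hh and
    S_hj = -(n_hj + n_jh); it is chi-square with k - 1 df under the null.
    """
    table = paired_category_table(paired_categories)
    return marginal_homogeneity_from_table(table)


def marginal_homogeneity_from_table(table: np.ndarray) -> MarginalHomogeneityResult:
    table = np.asarray(table, dtype=float)
    k = table.shape[0]
    if table.ndim != 2 or table.shape != (k, k):
        raise ValueError("need a square paired-category table")
    if k < 2:
        raise DegenerateTableError(
            "all mass in one category; marginal homogeneity is undefined"
        )
    row = table.sum(axis=1)
    col = table.sum(axis=0)
    if int(np.sum((row + col) > 0)) < 2:
        raise DegenerateTableError(
            "all mass in one category; marginal homogeneity is undefined"
        )
    d = (row - col)[: k - 1]
    s = np.empty((k - 1, k - 1))
    for h in range(k - 1):
        for j in range(k - 1):
            if h == j:
                s[h, j] = row[h] + col[h] - 2 * table[h, h]
            else:
                s[h, j] = -(table[h, j] + table[j, h])
    if np.allclose(d, 0):
        # identical marginals (e.g. a perfectly concordant table): nothing
        # to test even when the discordance covariance is singular
        return MarginalHomogeneityResult(0.0, k - 1, 1.0)
    try:
        sol = np.linalg.solve(s, d)
    except np.linalg.LinAlgError as exc:
        raise DegenerateTableError(
            "singular discordance covariance; table too degenerate for "
            "the Stuart-Maxwell test"
        ) from exc
    stat = float(d @ sol)
    df = k - 1
    return MarginalHomogeneityResult(stat, df, float(sps.chi2.sf(stat, df)))


def exam_level_pairs(cohort: Cohort) -> list[tuple[int, int]]:
    """All per-examination (ai_density, reader_density) pairs in a cohort."""
    return [
        (e.ai_density, e.reader_density) for t in cohort for e in t.exams
    ]
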