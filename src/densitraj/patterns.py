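"""Longitudinal density-pattern classification and tabulation.

A woman's ordered sequence of ordinal density assessments is summarised by
one of four labels based on the signs of its consecutive differences:

* ``constant`` — no change anywhere,
* ``ascending`` — at least one increase and no decrease,
* ``descending`` — at least one decrease and no increase,
* ``bi-directional`` — both an increase and a decrease.

The four labels partition all sequences of length >= 3.  Plateaus inside an
otherwise monotone sequence (e.g. b, b, c) do not break monotonicity; only a
sign change does.  Over a short screening window (~5 years) a bi-directional
trajectory is physiologically implausible and is read as a signature of
assessment variability.
"""

from __future__ import annotations

from dataclasses import dataclass
from enum import Enum
from pathlib import Path
from typing import Sequence

import numpy as np
import pandas as pd

from .cohort import Cohort, to_binary

RATERS = ("ai", "reader")
CONTEXTS = ("four_category", "binary")


class PatternLabel(str, Enum):
    CONSTANT = "constant"
    ASCENDING = "ascending"
    DESCENDING = "descending"
    BIDIRECTIONAL = "bi-directional"


PATTERN_ORDER = (
    PatternLabel.CONSTANT,
    PatternLabel.ASCENDING,
    PatternLabel.DESCENDING,
    PatternLabel.BIDIRECTIONAL,
)


def classify_pattern(seq: Sequence[int]) -> PatternLabel:
    """Classify an ordinal sequence of length >= 3 into its longitudinal pattern.

    Deterministic in the consecutive-difference signs: ``constant`` iff no
    difference is nonzero, ``ascending``/``descending`` iff only one sign
    occurs, ``bi-directional`` iff both occur.
    """
    if len(seq) < 3:
        raise ValueError(f"need at least 3 assessments, got {len(seq)}")
    diffs = np.diff(np.asarray(seq))
    has_up = bool((diffs > 0).any())
    has_down = bool((diffs < 0).any())
    if has_up and has_down:
        return PatternLabel.BIDIRECTIONAL
    if has_up:
        return PatternLabel.ASCENDING
    if has_down:
        return PatternLabel.DESCENDING
    return PatternLabel.CONSTANT


def binarize(seq: Sequence[int]) -> tuple[int, ...]:
    """Elementwise collapse of 4-category codes to binary density (0/1)."""
    return tuple(to_binary(c) for c in seq)


def _sequence(timeline, rater: str, context: str) -> Sequence[int]:
    seq = timeline.densities(rater)
    if context == "binary":
        return binarize(seq)
    if context != "four_category":
        raise ValueError(f"context must be one of {CONTEXTS}, got {context!r}")
    return seq


def classify_cohort(cohort: Cohort, rater: str, context: str) -> pd.Series:
    """Per-woman pattern labels, indexed by woman_id."""
    if len(cohort) == 0:
        raise ValueError("empty cohort")
    labels = {
        t.woman_id: classify_pattern(_sequence(t, rater, context)).value
        for t in cohort
    }
    return pd.Series(labels, name=f"{rater}_{context}_pattern")


def pattern_table(cohort: Cohort, rater: str, context: str) -> pd.DataFrame:
    """Counts and one-decimal percentages of the four patterns for one rater.

    Returns a frame indexed by pattern label with columns ``count`` and
    ``percent``; counts sum to the number of women.
    """
    labels = classify_cohort(cohort, rater, context)
    counts = labels.value_counts().reindex(
        [p.value for p in PATTERN_ORDER], fill_value=0
    )
    n = int(counts.sum())
    out = pd.DataFrame({"count": counts.astype(int)})
    out["percent"] = [percent(c, n) for c in out["count"]]
    out.index.name = "pattern"
    return out


@dataclass(frozen=True)
class PairedPatternTable:
    """4x4 cross-tabulation of AI pattern (rows) vs radiologist pattern (columns)."""

    counts: pd.DataFrame
    n_women: int

    def __post_init__(self) -> None:
        if int(self.counts.to_numpy().sum()) != self.n_women:
            raise ValueError("cross-tab entries must sum to n_women")


def paired_pattern_table(cohort: Cohort, context: str) -> PairedPatternTable:
    """Cross-tabulate per-woman (AI label, radiologist label) pairs.

    Marginals reproduce the two single-rater :func:`pattern_table` counts.
    """
    ai = classify_cohort(cohort, "ai", context)
    reader = classify_cohort(cohort, "reader", context)
    order = [p.value for p in PATTERN_ORDER]
    tab = (
        pd.crosstab(ai, reader)
        .reindex(index=order, columns=order, fill_value=0)
        .astype(int)
    )
    tab.index.name = "ai_pattern"
    tab.columns.name = "reader_pattern"
    return PairedPatternTable(tab, int(len(cohort)))


@dataclass(frozen=True)
class TransitionTable:
    """First-exam to last-exam 4-category transitions for one rater."""

    counts: pd.DataFrame
    rater: str

    @property
    def n_women(self) -> int:
        return int(self.counts.to_numpy().sum())


def transition_table(cohort: Cohort, rater: str) -> TransitionTable:
    """Count women by (first-exam category, last-exam category) for one rater."""
    if len(cohort) == 0:
        raise ValueError("empty cohort")
    first = pd.Series({t.woman_id: t.densities(rater)[0] for t in cohort})
    last = pd.Series({t.woman_id: t.densities(rater)[-1] for t in cohort})
    order = [0, 1, 2, 3]
    tab = (
        pd.crosstab(first, last)
        .reindex(index=order, columns=order, fill_value=0)
        .astype(int)
    )
    tab.index = pd.Index(["a", "b", "c", "d"], name="first_category")
    tab.columns = pd.Index(["a", "b", "c", "d"], name="last_category")
    return TransitionTable(tab, rater)


def sankey_frame(table: TransitionTable) -> pd.DataFrame:
    """Long-format (source_category, target_category, count) rows for Sankey plotters."""
    rows = [
        {"source_category": i, "target_category": j, "count": int(v)}
        for i, row in table.counts.iterrows()
        for j, v in row.items()
    ]
    return pd.DataFrame(rows, columns=["source_category", "target_category", "count"])


def write_sankey_csv(table: TransitionTable, path: str | Path) -> Path:
    path = Path(path)
    sankey_frame(table).to_csv(path, index=False)
    return path


def percent(count: int, n: int) -> float:
    """Percentage rounded half-up to one decimal, the tables' printing convention."""
    if n <= 0:
        raise ValueError("n must be positive")
    x = 100.0 * count / n
    return np.floor(x * 10 + 0.5) / 10


def percent_difference(count_a: int, count_b: int, n: int) -> float:
    """Difference of one-decimal-rounded percentages, in percentage points.

    The printed headline differences are computed on the rounded
    percentages (e.g. 81.0 - 56.8 = 24.2 where the unrounded difference is
    24.25), so the same convention is used here.
    """
    return round(percent(count_a, n) - percent(count_b, n), 1)
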