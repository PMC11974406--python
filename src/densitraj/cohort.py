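"""Domain types and CSV I/O for longitudinal breast-density cohorts.

A cohort is a set of women, each with an ordered sequence of at least three
screening examinations.  Every examination carries two BI-RADS density
assessments of the same mammogram: one by the interpreting radiologist and
one by an AI density model.  Density is stored internally as an ordinal
integer code (a=0 < b=1 < c=2 < d=3); the letter labels appear only at the
CSV boundary.
"""

from __future__ import annotations

import datetime as _dt
import json
import math
from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import Iterable, Iterator, Sequence

import pandas as pd

DENSITY_LABELS = ("a", "b", "c", "d")
_LABEL_TO_CODE = {lab: i for i, lab in enumerate(DENSITY_LABELS)}

#: Minimum number of examinations for a woman to enter the analysis.
MIN_EXAMS = 3

CSV_COLUMNS = [
    "woman_id",
    "exam_date",
    "reader_id",
    "reader_fellowship",
    "reader_density",
    "ai_density",
    "age_years",
    "bmi",
    "fat_measure",
    "thickness_mm",
]

_REQUIRED_COLUMNS = CSV_COLUMNS[:7]  # last three optional / blank-allowed

AGE_RANGE = (18.0, 110.0)
BMI_RANGE = (10.0, 80.0)


class CohortFormatError(ValueError):
    """Structurally unusable input (missing columns, bad header, ...)."""


class RowError(ValueError):
    """A single malformed row (strict mode only; lenient mode tallies)."""


def density_code(label: str) -> int:
    """Map a BI-RADS letter (a-d, case-insensitive) to its ordinal code 0-3."""
    try:
        return _LABEL_TO_CODE[str(label).strip().lower()]
    except KeyError:
        raise ValueError(f"not a BI-RADS density label: {label!r}") from None


def density_label(code: int) -> str:
    """Inverse of :func:`density_code`."""
    if code not in (0, 1, 2, 3):
        raise ValueError(f"not a density code: {code!r}")
    return DENSITY_LABELS[code]


def to_binary(code: int) -> int:
    """Collapse 4-category density to binary: non-dense {a,b} -> 0, dense {c,d} -> 1."""
    if code not in (0, 1, 2, 3):
        raise ValueError(f"not a density code: {code!r}")
    return int(code >= 2)


@dataclass(frozen=True)
class ExamRecord:
    """One screening examination with both raters' density assessments."""

    woman_id: str
    exam_date: _dt.date
    reader_id: str
    reader_fellowship: bool
    reader_density: int  # ordinal code 0-3
    ai_density: int  # ordinal code 0-3
    age_years: float
    bmi: float | None = None
    fat_measure: float | None = None
    thickness_mm: float | None = None

    def __post_init__(self) -> None:
        for name in ("reader_density", "ai_density"):
            v = getattr(self, name)
            if v not in (0, 1, 2, 3):
                raise ValueError(f"{name} must be an ordinal code 0-3, got {v!r}")
        if not (AGE_RANGE[0] <= self.age_years <= AGE_RANGE[1]):
            raise ValueError(f"age_years {self.age_years} outside {AGE_RANGE}")
        if self.bmi is not None and not (BMI_RANGE[0] < self.bmi < BMI_RANGE[1]):
            raise ValueError(f"bmi {self.bmi} outside {BMI_RANGE}")
        if self.fat_measure is not None and not (0.0 <= self.fat_measure <= 1.0):
            raise ValueError(f"fat_measure {self.fat_measure} outside [0, 1]")
        if self.thickness_mm is not None and self.thickness_mm <= 0:
            raise ValueError(f"thickness_mm must be positive, got {self.thickness_mm}")


@dataclass(frozen=True)
class WomanTimeline:
    """Ordered sequence of >= 3 examinations belonging to one woman."""

    woman_id: str
    exams: tuple[ExamRecord, ...]

    def __post_init__(self) -> None:
        if len(self.exams) < MIN_EXAMS:
            raise ValueError(
                f"timeline for {self.woman_id!r} has {len(self.exams)} exams; "
                f"at least {MIN_EXAMS} required"
            )
        if any(e.woman_id != self.woman_id for e in self.exams):
            raise ValueError("all exams must share the timeline's woman_id")
        dates = [e.exam_date for e in self.exams]
        if any(b <= a for a, b in zip(dates, dates[1:])):
            raise ValueError(f"exam dates for {self.woman_id!r} not strictly increasing")

    def __len__(self) -> int:
        return len(self.exams)

    def densities(self, rater: str) -> tuple[int, ...]:
        """Ordinal density sequence for ``rater`` ('ai' or 'reader')."""
        if rater == "ai":
            return tuple(e.ai_density for e in self.exams)
        if rater == "reader":
            return tuple(e.reader_density for e in self.exams)
        raise ValueError(f"rater must be 'ai' or 'reader', got {rater!r}")

    @property
    def first_exam(self) -> ExamRecord:
        return self.exams[0]

    @property
    def last_exam(self) -> ExamRecord:
        return self.exams[-1]


@dataclass(frozen=True)
class Provenance:
    """Bookkeeping of where a cohort came from and what was excluded."""

    source: str = "<memory>"
    n_rows: int = 0
    n_rows_malformed: int = 0
    n_women_seen: int = 0
    n_women_excluded_short: int = 0
    n_women_excluded_duplicate_dates: int = 0
    n_women_included: int = 0

    def to_dict(self) -> dict:
        return {
            "source": self.source,
            "n_rows": self.n_rows,
            "n_rows_malformed": self.n_rows_malformed,
            "n_women_seen": self.n_women_seen,
            "n_women_excluded_short": self.n_women_excluded_short,
            "n_women_excluded_duplicate_dates": self.n_women_excluded_duplicate_dates,
            "n_women_included": self.n_women_included,
        }


@dataclass(frozen=True)
class Cohort:
    """A collection of woman timelines plus provenance of their selection."""

    timelines: tuple[WomanTimeline, ...]
    provenance: Provenance = field(default_factory=Provenance)

    def __post_init__(self) -> None:
        ids = [t.woman_id for t in self.timelines]
        if len(ids) != len(set(ids)):
            raise ValueError("woman_id must be unique across timelines")

    def __len__(self) -> int:
        return len(self.timelines)

    def __iter__(self) -> Iterator[WomanTimeline]:
        return iter(self.timelines)

    @property
    def n_women(self) -> int:
        return len(self.timelines)

    @property
    def n_exams(self) -> int:
        return sum(len(t) for t in self.timelines)

    def subset(self, woman_ids: Iterable[str], source_note: str = "subset") -> "Cohort":
        """Cohort restricted to ``woman_ids`` (order of timelines preserved)."""
        keep = set(woman_ids)
        kept = tuple(t for t in self.timelines if t.woman_id in keep)
        prov = replace(
            self.provenance,
            source=f"{self.provenance.source}::{source_note}",
            n_women_included=len(kept),
        )
        return Cohort(kept, prov)

    def to_frame(self) -> pd.DataFrame:
        """Flatten to one row per examination, columns as in the CSV schema."""
        rows = []
        for t in self.timelines:
            for e in t.exams:
                rows.append(
                    {
                        "woman_id": e.woman_id,
                        "exam_date": e.exam_date.isoformat(),
                        "reader_id": e.reader_id,
                        "reader_fellowship": int(e.reader_fellowship),
                        "reader_density": density_label(e.reader_density),
                        "ai_density": density_label(e.ai_density),
                        "age_years": e.age_years,
                        "bmi": e.bmi,
                        "fat_measure": e.fat_measure,
                        "thickness_mm": e.thickness_mm,
                    }
                )
        return pd.DataFrame(rows, columns=CSV_COLUMNS)


def _opt_float(value) -> float | None:
    if value is None:
        return None
    if isinstance(value, str) and value.strip() == "":
        return None
    v = float(value)
    return None if math.isnan(v) else v


def _parse_row(row: dict) -> ExamRecord:
    date = _dt.date.fromisoformat(str(row["exam_date"]).strip())
    fellowship_raw = str(row["reader_fellowship"]).strip()
    if fellowship_raw not in {"0", "1"}:
        raise ValueError(f"reader_fellowship must be 0/1, got {fellowship_raw!r}")
    return ExamRecord(
        woman_id=str(row["woman_id"]).strip(),
        exam_date=date,
        reader_id=str(row["reader_id"]).strip(),
        reader_fellowship=fellowship_raw == "1",
        reader_density=density_code(row["reader_density"]),
        ai_density=density_code(row["ai_density"]),
        age_years=float(row["age_years"]),
        bmi=_opt_float(row.get("bmi")),
        fat_measure=_opt_float(row.get("fat_measure")),
        thickness_mm=_opt_float(row.get("thickness_mm")),
    )


def read_cohort(path: str | Path, strict: bool = False) -> Cohort:
    """Read a per-examination CSV into a :class:`Cohort`.

    Rows are grouped into per-woman timelines ordered by date.  Women with
    fewer than :data:`MIN_EXAMS` valid examinations, or with duplicated exam
    dates, are excluded and tallied in provenance.  In ``strict`` mode any
    malformed row raises :class:`RowError`; otherwise it is dropped and
    counted in ``n_rows_malformed``.
    """
    path = Path(path)
    try:
        frame = pd.read_csv(path, dtype=str, keep_default_na=False)
    except Exception as exc:  # pragma: no cover - pandas error text varies
        raise CohortFormatError(f"cannot read {path}: {exc}") from exc
    missing = [c for c in _REQUIRED_COLUMNS if c not in frame.columns]
    if missing:
        raise CohortFormatError(f"missing required columns: {missing}")

    records: dict[str, list[ExamRecord]] = {}
    n_malformed = 0
    for idx, row in enumerate(frame.to_dict("records")):
        try:
            rec = _parse_row(row)
        except Exception as exc:
            if strict:
                raise RowError(f"row {idx + 2} of {path}: {exc}") from exc
            n_malformed += 1
            continue
        records.setdefault(rec.woman_id, []).append(rec)

    timelines: list[WomanTimeline] = []
    n_short = 0
    n_dup = 0
    for wid, exams in records.items():
        if len(exams) < MIN_EXAMS:
            n_short += 1
            continue
        exams.sort(key=lambda e: e.exam_date)
        dates = [e.exam_date for e in exams]
        if len(set(dates)) != len(dates):
            msg = f"duplicate exam dates for woman {wid!r}"
            if strict:
                raise RowError(msg)
            n_dup += 1
            continue
        timelines.append(WomanTimeline(wid, tuple(exams)))

    prov = Provenance(
        source=str(path),
        n_rows=len(frame),
        n_rows_malformed=n_malformed,
        n_women_seen=len(records),
        n_women_excluded_short=n_short,
        n_women_excluded_duplicate_dates=n_dup,
        n_women_included=len(timelines),
    )
    return Cohort(tuple(timelines), prov)


def write_cohort(cohort: Cohort, path: str | Path) -> Path:
    """Write a cohort back to the per-examination CSV schema.

    Round-trips: ``read_cohort(write_cohort(c))`` reproduces ``c`` field by
    field (provenance aside).
    """
    path = Path(path)
    cohort.to_frame().to_csv(path, index=False)
    return path


def write_provenance(cohort: Cohort, path: str | Path) -> Path:
    """Write the JSON provenance sidecar for a cohort."""
    path = Path(path)
    path.write_text(json.dumps(cohort.provenance.to_dict(), indent=2, sort_keys=True))
    return path


def build_cohort(timelines: Sequence[WomanTimeline], source: str = "<memory>") -> Cohort:
    """Assemble a cohort from already-validated timelines."""
    prov = Provenance(
        source=source,
        n_rows=sum(len(t) for t in timelines),
        n_women_seen=len(timelines),
        n_women_included=len(timelines),
    )
    return Cohort(tuple(timelines), prov)
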