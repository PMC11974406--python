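"""Shared fixtures: hand-built cohorts and small simulated ones."""

from __future__ import annotations

import datetime as dt

import pytest

from densitraj.cohort import Cohort, ExamRecord, WomanTimeline, build_cohort
from densitraj.simulate import SimulationConfig, generate


def make_timeline(
    woman_id: str,
    reader_seq,
    ai_seq=None,
    *,
    ages=None,
    bmis=None,
    reader_ids=None,
    fellowship=None,
    start=dt.date(2016, 1, 15),
) -> WomanTimeline:
    """Build a timeline from ordinal density sequences with annual exams."""
    ai_seq = list(reader_seq) if ai_seq is None else list(ai_seq)
    n = len(reader_seq)
    ages = ages or [50.0 + t for t in range(n)]
    bmis = bmis if bmis is not None else [None] * n
    reader_ids = reader_ids or ["R1"] * n
    fellowship = fellowship if fellowship is not None else [True] * n
    exams = tuple(
        ExamRecord(
            woman_id=woman_id,
            exam_date=start + dt.timedelta(days=365 * t),
            reader_id=reader_ids[t],
            reader_fellowship=fellowship[t],
            reader_density=reader_seq[t],
            ai_density=ai_seq[t],
            age_years=ages[t],
            bmi=bmis[t],
        )
        for t in range(n)
    )
    return WomanTimeline(woman_id, exams)


def make_cohort(*timelines) -> Cohort:
    return build_cohort(list(timelines))


@pytest.fixture(scope="session")
def sim_cohort():
    """Small default-parameter simulated cohort shared across tests."""
    cohort, truth = generate(SimulationConfig(n_women=800, seed=11))
    return cohort, truth


@pytest.fixture
def perfect_agreement_cohort():
    """Both raters produce identical sequences for every woman."""
    return make_cohort(
        make_timeline("P1", [2, 2, 2]),
        make_timeline("P2", [1, 2, 3]),
        make_timeline("P3", [3, 2, 1, 1]),
        make_timeline("P4", [1, 0, 1]),
    )
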