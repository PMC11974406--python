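"""Cohort CSV reading, validation, exclusion accounting and round-trips."""

from __future__ import annotations

import datetime as dt

import pytest

from densitraj.cohort import (
    Cohort,
    CohortFormatError,
    ExamRecord,
    RowError,
    WomanTimeline,
    density_code,
    density_label,
    read_cohort,
    to_binary,
    write_cohort,
)
from densitraj.simulate import SimulationConfig, generate

from conftest import make_cohort, make_timeline

HEADER = (
    "woman_id,exam_date,reader_id,reader_fellowship,reader_density,"
    "ai_density,age_years,bmi,fat_measure,thickness_mm"
)


def _write(tmp_path, rows, name="cohort.csv"):
    path = tmp_path / name
    path.write_text("\n".join([HEADER, *rows]) + "\n")
    return path


def _row(wid, date, density="b", reader="R1", fellow="1", age="50", extra=",,"):
    return f"{wid},{date},{reader},{fellow},{density},{density},{age}{extra}"


class TestDensityCodes:
    @pytest.mark.parametrize("label,code", [("a", 0), ("b", 1), ("c", 2), ("d", 3)])
    def test_bijection(self, label, code):
        assert density_code(label) == code
        assert density_label(code) == label
        assert density_code(label.upper()) == code

    def test_binary_split(self):
        assert [to_binary(c) for c in range(4)] == [0, 0, 1, 1]

    def test_invalid_label(self):
        with pytest.raises(ValueError):
            density_code("e")


class TestReadCohort:
    def test_minimal_three_exam_woman(self, tmp_path):
        path = _write(
            tmp_path,
            [_row("A", f"2016-0{m}-01") for m in (1, 2, 3)],
        )
        cohort = read_cohort(path)
        assert cohort.n_women == 1
        assert len(cohort.timelines[0]) == 3
        assert cohort.timelines[0].densities("reader") == (1, 1, 1)

    def test_short_timelines_excluded_and_tallied(self, tmp_path):
        rows = [_row("A", f"2016-0{m}-01") for m in (1, 2, 3)]
        rows += [_row("B", f"2016-0{m}-01") for m in (1, 2)]
        cohort = read_cohort(_write(tmp_path, rows))
        assert cohort.n_women == 1
        assert cohort.timelines[0].woman_id == "A"
        assert cohort.provenance.n_women_excluded_short == 1

    def test_lenient_mode_tallies_corrupt_rows(self, tmp_path):
        rows = []
        for w in ("A", "B", "C", "D"):
            for m in (1, 2, 3):
                rows.append(_row(w, f"2016-0{m}-01"))
        rows[4] = rows[4].replace(",b,", ",x,", 1)  # corrupt B's density cell
        cohort = read_cohort(_write(tmp_path, rows), strict=False)
        assert cohort.provenance.n_rows == 12
        assert cohort.provenance.n_rows_malformed == 1
        # B drops to 2 valid exams and is excluded by the >= 3 rule
        assert cohort.n_women == 3
        assert cohort.provenance.n_women_excluded_short == 1

    def test_strict_mode_aborts_on_corrupt_row(self, tmp_path):
        rows = [_row("A", "2016-01-01", density="z")]
        with pytest.raises(RowError):
            read_cohort(_write(tmp_path, rows), strict=True)

    def test_missing_required_column(self, tmp_path):
        path = tmp_path / "bad.csv"
        path.write_text("woman_id,exam_date\nA,2016-01-01\n")
        with pytest.raises(CohortFormatError):
            read_cohort(path)

    def test_duplicate_dates_exclude_woman(self, tmp_path):
        rows = [
            _row("A", "2016-01-01"),
            _row("A", "2016-01-01"),
            _row("A", "2016-03-01"),
            _row("A", "2016-04-01"),
        ]
        cohort = read_cohort(_write(tmp_path, rows))
        assert cohort.n_women == 0
        assert cohort.provenance.n_women_excluded_duplicate_dates == 1

    def test_exclusion_accounting_balances(self, tmp_path):
        rows = [_row("A", f"2016-0{m}-01") for m in (1, 2, 3)]
        rows += [_row("B", "2016-01-01")]
        rows += [_row("C", "2016-01-01"), _row("C", "2016-01-01"), _row("C", "2016-02-01")]
        cohort = read_cohort(_write(tmp_path, rows))
        p = cohort.provenance
        assert (
            p.n_women_included
            + p.n_women_excluded_short
            + p.n_women_excluded_duplicate_dates
            == p.n_women_seen
        )


class TestRoundTrip:
    def test_empty_cohort_writes_header_only(self, tmp_path):
        path = write_cohort(Cohort(()), tmp_path / "empty.csv")
        lines = path.read_text().strip().splitlines()
        assert lines == [HEADER]

    def test_single_timeline_round_trip(self, tmp_path):
        cohort = make_cohort(make_timeline("W1", [1, 2, 3], bmis=[25.0, 25.5, 26.0]))
        back = read_cohort(write_cohort(cohort, tmp_path / "c.csv"))
        assert back.timelines[0].exams == cohort.timelines[0].exams

    def test_simulated_cohort_round_trips_field_by_field(self, tmp_path):
        cohort, _ = generate(SimulationConfig(n_women=100, seed=5))
        back = read_cohort(write_cohort(cohort, tmp_path / "sim.csv"))
        assert back.n_women == cohort.n_women
        orig = {t.woman_id: t for t in cohort}
        for t in back:
            assert t.exams == orig[t.woman_id].exams


class TestDomainInvariants:
    def test_timeline_requires_three_exams(self):
        with pytest.raises(ValueError):
            make_timeline("W", [1, 2])

    def test_timeline_rejects_non_increasing_dates(self):
        e = lambda d: ExamRecord("W", d, "R1", True, 1, 1, 50.0)
        with pytest.raises(ValueError):
            WomanTimeline("W", (e(dt.date(2016, 1, 1)),) * 3)

    def test_exam_record_validates_ranges(self):
        with pytest.raises(ValueError):
            ExamRecord("W", dt.date(2016, 1, 1), "R", True, 4, 1, 50.0)
        with pytest.raises(ValueError):
            ExamRecord("W", dt.date(2016, 1, 1), "R", True, 1, 1, 8.0)
        with pytest.raises(ValueError):
            ExamRecord("W", dt.date(2016, 1, 1), "R", True, 1, 1, 50.0, bmi=5.0)

    def test_cohort_rejects_duplicate_women(self):
        t = make_timeline("W", [1, 1, 1])
        with pytest.raises(ValueError):
            Cohort((t, t))
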