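"""Overlapping subgroup filters and the per-subgroup analysis driver.

Four subgroups refine the full cohort, each designed to suppress one source
of apparent density change or assessment variability:

* ``postmenopausal`` — first-exam age strictly above a threshold (default 55
  years), a proxy for post-menopausal status;
* ``stable_bmi`` — every consecutive BMI change below a relative threshold
  (default 5%), suppressing true parenchymal change driven by weight;
* ``same_reader`` — all of a woman's exams interpreted by one radiologist,
  removing inter-observer variability;
* ``fellowship`` — all exams interpreted by fellowship-trained radiologists.

The subgroups overlap: a woman may appear in several.
"""

from __future__ import annotations

from dataclasses import dataclass

from .cohort import Cohort
from .patterns import CONTEXTS, PATTERN_ORDER, pattern_table
from .stats import PatternComparison, compare_pattern_proportions

SUBGROUP_NAMES = ("full", "postmenopausal", "stable_bmi", "same_reader", "fellowship")

DEFAULT_AGE_THRESHOLD = 55.0
DEFAULT_BMI_REL_THRESHOLD = 0.05


@dataclass(frozen=True)
class SubgroupSpec:
    name: str
    age_threshold: float = DEFAULT_AGE_THRESHOLD
    bmi_rel_threshold: float = DEFAULT_BMI_REL_THRESHOLD

    def __post_init__(self) -> None:
        if self.name not in SUBGROUP_NAMES:
            raise ValueError(f"unknown subgroup {self.name!r}")
        if self.age_threshold <= 0 or self.bmi_rel_threshold <= 0:
            raise ValueError("thresholds must be positive")


def filter_postmenopausal(
    cohort: Cohort, age_threshold: float = DEFAULT_AGE_THRESHOLD
) -> Cohort:
    """Women strictly older than ``age_threshold`` at their first examination."""
    keep = [
        t.woman_id for t in cohort if t.first_exam.age_years > age_threshold
    ]
    return cohort.subset(keep, "postmenopausal")


def filter_stable_bmi(
    cohort: Cohort, rel_threshold: float = DEFAULT_BMI_REL_THRESHOLD
) -> Cohort:
    """Women whose BMI changes by less than ``rel_threshold`` between every
    consecutive pair of examinations.

    Women missing BMI on any exam cannot be evaluated and are excluded.
    """
    keep = []
    for t in cohort:
        bmis = [e.bmi for e in t.exams]
        if any(b is None for b in bmis):
            continue
        stable = all(
            abs(b1 - b0) / b0 < rel_threshold for b0, b1 in zip(bmis, bmis[1:])
        )
        if stable:
            keep.append(t.woman_id)
    return cohort.subset(keep, "stable_bmi")


def filter_same_reader(cohort: Cohort) -> Cohort:
    """Women whose examinations were all interpreted by one radiologist."""
    keep = [
        t.woman_id
        for t in cohort
        if len({e.reader_id for e in t.exams}) == 1
    ]
    return cohort.subset(keep, "same_reader")


def filter_fellowship(cohort: Cohort) -> Cohort:
    """Women whose examinations were all interpreted by fellowship-trained
    radiologists."""
    keep = [
        t.woman_id
        for t in cohort
        if all(e.reader_fellowship for e in t.exams)
    ]
    return cohort.subset(keep, "fellowship")


def subgroup_cohorts(
    cohort: Cohort,
    age_threshold: float = DEFAULT_AGE_THRESHOLD,
    bmi_rel_threshold: float = DEFAULT_BMI_REL_THRESHOLD,
) -> dict[str, Cohort]:
    """The full cohort plus its four analysis subgroups, keyed by name."""
    return {
        "full": cohort,
        "postmenopausal": filter_postmenopausal(cohort, age_threshold),
        "stable_bmi": filter_stable_bmi(cohort, bmi_rel_threshold),
        "same_reader": filter_same_reader(cohort),
        "fellowship": filter_fellowship(cohort),
    }


def run_all(
    cohort: Cohort,
    age_threshold: float = DEFAULT_AGE_THRESHOLD,
    bmi_rel_threshold: float = DEFAULT_BMI_REL_THRESHOLD,
    mcnemar_method: str = "auto",
) -> dict:
    """Full analysis over every subgroup, context, rater and pattern trait.

    Returns a nested mapping
    ``{subgroup: {"n_women": int,
                  "tables": {context: {rater: pattern DataFrame}},
                  "comparisons": {context: {trait: PatternComparison}}}}``.
    An empty subgroup is reported with ``n_women == 0`` and no tables.
    """
    report: dict = {}
    for name, sub in subgroup_cohorts(cohort, age_threshold, bmi_rel_threshold).items():
        entry: dict = {"n_women": len(sub), "tables": {}, "comparisons": {}}
        if len(sub) > 0:
            for context in CONTEXTS:
                entry["tables"][context] = {
                    rater: pattern_table(sub, rater, context)
                    for rater in ("ai", "reader")
                }
                entry["comparisons"][context] = {
                    trait.value: compare_pattern_proportions(
                        sub, context, trait, method=mcnemar_method
                    )
                    for trait in PATTERN_ORDER
                }
        report[name] = entry
    return report
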