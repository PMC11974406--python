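"""Emission of the analysis report bundle.

:func:`run_analysis` ties the pipeline together: load (or accept) a cohort,
optionally fill missing BMI through the image-based proxy, run the
subgroup-stratified pattern analysis, and write a deterministic bundle of
CSV/JSON outputs:

* ``density_distribution.csv`` / ``.json`` — exam-level paired category
  distribution for both raters with the Stuart-Maxwell marginal-homogeneity
  test;
* ``patterns_<subgroup>.csv`` — per-subgroup table (rows: pattern; columns:
  AI count/%, radiologist count/%, McNemar p) in both contexts;
* ``crosstab_<context>.csv`` — AI-vs-radiologist pattern confusion matrix;
* ``sankey_<rater>.csv`` — first-to-last category transitions in long form;
* ``results.json`` — every comparison at full precision;
* ``run.log`` — inclusion/exclusion tallies and settings.

Running twice on the same input produces byte-identical reports apart from
timestamps in the log.
"""

from __future__ import annotations

import json
import logging
from dataclasses import dataclass
from pathlib import Path

import pandas as pd

from .bmi_proxy import BmiProxyModel, fill_missing_bmi
from .cohort import Cohort, read_cohort
from .patterns import (
    CONTEXTS,
    PATTERN_ORDER,
    paired_pattern_table,
    percent,
    transition_table,
    write_sankey_csv,
)
from .stats import (
    DegenerateTableError,
    exam_level_pairs,
    marginal_homogeneity,
)
from .subgroups import (
    DEFAULT_AGE_THRESHOLD,
    DEFAULT_BMI_REL_THRESHOLD,
    run_all,
)

logger = logging.getLogger("densitraj")


@dataclass(frozen=True)
class AnalysisConfig:
    input_path: str | Path
    output_dir: str | Path
    age_threshold: float = DEFAULT_AGE_THRESHOLD
    bmi_rel_threshold: float = DEFAULT_BMI_REL_THRESHOLD
    mcnemar_method: str = "auto"
    alpha: float = 0.05
    bmi_proxy_path: str | Path | None = None
    strict: bool = False

    def __post_init__(self) -> None:
        if not 0 < self.alpha < 1:
            raise ValueError("alpha must be in (0, 1)")


def _subgroup_table_frame(entry: dict) -> pd.DataFrame:
    rows = []
    for context in CONTEXTS:
        tables = entry["tables"][context]
        comps = entry["comparisons"][context]
        for pat in PATTERN_ORDER:
            rows.append(
                {
                    "context": context,
                    "pattern": pat.value,
                    "ai_count": int(tables["ai"].loc[pat.value, "count"]),
                    "ai_percent": float(tables["ai"].loc[pat.value, "percent"]),
                    "reader_count": int(tables["reader"].loc[pat.value, "count"]),
                    "reader_percent": float(tables["reader"].loc[pat.value, "percent"]),
                    "difference_pp": comps[pat.value].difference_pp,
                    "p_value": comps[pat.value].test.p_value,
                }
            )
    return pd.DataFrame(rows)


def _density_distribution(cohort: Cohort) -> tuple[pd.DataFrame, dict]:
    pairs = exam_level_pairs(cohort)
    n = len(pairs)
    frame = pd.DataFrame(pairs, columns=["ai", "reader"])
    rows = []
    for code, label in enumerate("abcd"):
        ai_n = int((frame["ai"] == code).sum())
        rd_n = int((frame["reader"] == code).sum())
        rows.append(
            {
                "category": label,
                "ai_count": ai_n,
                "ai_percent": percent(ai_n, n),
                "reader_count": rd_n,
                "reader_percent": percent(rd_n, n),
            }
        )
    try:
        mh = marginal_homogeneity(pairs).to_dict()
    except DegenerateTableError as exc:
        mh = {"error": str(exc)}
    return pd.DataFrame(rows), {"n_exams": n, "marginal_homogeneity": mh}


def run_analysis(config: AnalysisConfig, cohort: Cohort | None = None) -> dict:
    """Run the full pipeline and write the report bundle to ``output_dir``.

    ``cohort`` may be passed directly (e.g. fresh from the simulator);
    otherwise it is read from ``config.input_path``.  Returns the nested
    report produced by :func:`densitraj.subgroups.run_all` plus the
    density-distribution summary.
    """
    out = Path(config.output_dir)
    out.mkdir(parents=True, exist_ok=True)
    handler = logging.FileHandler(out / "run.log", mode="w")
    handler.setFormatter(logging.Formatter("%(asctime)s %(levelname)s %(message)s"))
    logger.addHandler(handler)
    logger.setLevel(logging.INFO)
    try:
        if cohort is None:
            cohort = read_cohort(config.input_path, strict=config.strict)
        prov = cohort.provenance
        logger.info(
            "cohort loaded: %d rows, %d women included, %d excluded (<3 exams), "
            "%d excluded (duplicate dates), %d malformed rows",
            prov.n_rows,
            prov.n_women_included,
            prov.n_women_excluded_short,
            prov.n_women_excluded_duplicate_dates,
            prov.n_rows_malformed,
        )
        if config.bmi_proxy_path is not None:
            model = BmiProxyModel.from_json(config.bmi_proxy_path)
            cohort = fill_missing_bmi(cohort, model)
            logger.info("missing BMI filled via image-based proxy")

        dist_frame, dist_meta = _density_distribution(cohort)
        dist_frame.to_csv(out / "density_distribution.csv", index=False)
        (out / "density_distribution.json").write_text(
            json.dumps(dist_meta, indent=2, sort_keys=True)
        )

        report = run_all(
            cohort,
            age_threshold=config.age_threshold,
            bmi_rel_threshold=config.bmi_rel_threshold,
            mcnemar_method=config.mcnemar_method,
        )
        results_json: dict = {"alpha": config.alpha, "subgroups": {}}
        for name, entry in report.items():
            results_json["subgroups"][name] = {
                "n_women": entry["n_women"],
                "comparisons": {
                    context: {
                        trait: comp.to_dict() for trait, comp in comps.items()
                    }
                    for context, comps in entry["comparisons"].items()
                },
            }
            if entry["n_women"] == 0:
                logger.info("subgroup %s is empty", name)
                continue
            _subgroup_table_frame(entry).to_csv(out / f"patterns_{name}.csv", index=False)
            logger.info("subgroup %s: n=%d", name, entry["n_women"])

        for context in CONTEXTS:
            paired_pattern_table(cohort, context).counts.to_csv(
                out / f"crosstab_{context}.csv"
            )
        for rater in ("ai", "reader"):
            write_sankey_csv(transition_table(cohort, rater), out / f"sankey_{rater}.csv")

        (out / "results.json").write_text(
            json.dumps(results_json, indent=2, sort_keys=True)
        )
        report["density_distribution"] = dist_meta
        return report
    finally:
        logger.removeHandler(handler)
        handler.close()
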