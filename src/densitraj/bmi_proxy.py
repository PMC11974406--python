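"""Image-based BMI proxy.

Measured BMI is often missing from screening records.  When it is, BMI can
be approximated from two quantities available on every mammogram: an
image-based breast-fat fraction and the compressed breast thickness.  The
estimator here is an ordinary least-squares linear model

    BMI ~ beta0 + beta_thickness * thickness_mm + beta_fat * fat_fraction

with predictions clamped to the physiologic range (10, 80) kg/m^2.
Coefficients are JSON-serialisable so an externally validated formula can be
dropped in without refitting.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, replace
from pathlib import Path
from typing import Sequence

import numpy as np
import statsmodels.api as sm

from .cohort import Cohort, WomanTimeline

BMI_CLAMP = (10.0, 80.0)
MIN_FIT_RECORDS = 10


class ProxyFitError(ValueError):
    """Degenerate design or too few records to fit the proxy."""


@dataclass(frozen=True)
class BmiProxyModel:
    intercept: float  # kg/m^2
    beta_thickness: float  # kg/m^2 per mm
    beta_fat: float  # kg/m^2 per unit fat fraction
    residual_sd: float = 0.0

    def __post_init__(self) -> None:
        vals = (self.intercept, self.beta_thickness, self.beta_fat, self.residual_sd)
        if not all(np.isfinite(vals)):
            raise ValueError("coefficients must be finite")

    def to_json(self, path: str | Path) -> Path:
        path = Path(path)
        path.write_text(
            json.dumps(
                {
                    "intercept": self.intercept,
                    "beta_thickness": self.beta_thickness,
                    "beta_fat": self.beta_fat,
                    "residual_sd": self.residual_sd,
                },
                indent=2,
                sort_keys=True,
            )
        )
        return path

    @classmethod
    def from_json(cls, path: str | Path) -> "BmiProxyModel":
        d = json.loads(Path(path).read_text())
        return cls(
            intercept=float(d["intercept"]),
            beta_thickness=float(d["beta_thickness"]),
            beta_fat=float(d["beta_fat"]),
            residual_sd=float(d.get("residual_sd", 0.0)),
        )


def fit_proxy(
    records: Sequence[tuple[float, float, float]]
) -> BmiProxyModel:
    """Fit the proxy by OLS on (fat_fraction, thickness_mm, measured_bmi) triples."""
    if len(records) < MIN_FIT_RECORDS:
        raise ProxyFitError(
            f"need at least {MIN_FIT_RECORDS} complete records, got {len(records)}"
        )
    arr = np.asarray(records, dtype=float)
    fat, thick, bmi = arr[:, 0], arr[:, 1], arr[:, 2]
    if np.ptp(fat) == 0 or np.ptp(thick) == 0:
        raise ProxyFitError("constant feature: design matrix is rank deficient")
    design = sm.add_constant(np.column_stack([thick, fat]))
    fit = sm.OLS(bmi, design).fit()
    resid_sd = float(np.std(fit.resid, ddof=3))  # 3 fitted parameters
    return BmiProxyModel(
        intercept=float(fit.params[0]),
        beta_thickness=float(fit.params[1]),
        beta_fat=float(fit.params[2]),
        residual_sd=resid_sd,
    )


def estimate_bmi(
    model: BmiProxyModel, fat_measure: float, thickness_mm: float
) -> float:
    """Linear prediction clamped to (10, 80) kg/m^2."""
    pred = (
        model.intercept
        + model.beta_thickness * thickness_mm
        + model.beta_fat * fat_measure
    )
    return float(np.clip(pred, *BMI_CLAMP))


def fill_missing_bmi(cohort: Cohort, model: BmiProxyModel) -> Cohort:
    """Replace missing BMI with the proxy estimate wherever both image
    features are available; exams with neither BMI nor features stay missing."""
    timelines = []
    for t in cohort:
        exams = []
        for e in t.exams:
            if e.bmi is None and e.fat_measure is not None and e.thickness_mm is not None:
                e = replace(e, bmi=estimate_bmi(model, e.fat_measure, e.thickness_mm))
            exams.append(e)
        timelines.append(WomanTimeline(t.woman_id, tuple(exams)))
    return Cohort(tuple(timelines), cohort.provenance)
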