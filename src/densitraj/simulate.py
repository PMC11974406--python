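"""Seeded synthetic screening-cohort generator.

The generator emulates the statistical structure of a multi-year screening
cohort assessed by two raters.  Each woman carries a latent continuous
density z on a standard-normal scale.  Over successive visits z drifts
slowly downward (density declines with age) and responds to BMI change
(weight gain lowers density).  Fixed thresholds tau_a < tau_b < tau_c cut
the latent scale into the four ordinal categories.  Each rater observes the
category of a noise-shifted latent value:

    radiologist: category(z + bias_reader + eps),  eps ~ N(0, reader_noise_sd)
    AI:          category(z + eps),                eps ~ N(0, ai_noise_sd)

Reader bias is drawn once per radiologist (between-reader variability);
noise is fresh per examination (within-reader variability).  Because noise
acts in latent space, misclassifications are ordinal and concentrated in
adjacent categories, as real density disagreements are.  Everything is
deterministic given the seed.
"""

from __future__ import annotations

import datetime as _dt
import json
from dataclasses import dataclass, asdict
from pathlib import Path
from typing import Sequence

import numpy as np
import pandas as pd
from scipy import stats as sps

from .cohort import Cohort, ExamRecord, Provenance, WomanTimeline, density_label

EXAM_COUNTS = (3, 4, 5, 6)

#: Radiologist exam-level category distribution used as the default latent
#: marginal: a 9.0%, b 45.1%, c 38.1%, d 7.7%.
DEFAULT_MARGINAL = (0.090, 0.451, 0.381, 0.077)

#: Women with 3/4/5/6 exams; the 5-or-6 block (10.5%) is split evenly.
DEFAULT_EXAM_COUNT_PROBS = (0.607, 0.288, 0.0525, 0.0525)


@dataclass(frozen=True)
class SimulationConfig:
    """Full parameterisation of the synthetic cohort."""

    n_women: int = 1000
    seed: int = 0
    exam_count_probs: tuple[float, float, float, float] = DEFAULT_EXAM_COUNT_PROBS
    age_mean: float = 55.6  # years
    age_sd: float = 10.3
    age_bounds: tuple[float, float] = (35.0, 90.0)
    bmi_mean: float = 28.3  # kg/m^2
    bmi_sd: float = 4.9
    bmi_bounds: tuple[float, float] = (15.0, 60.0)
    bmi_walk_sd: float = 3.0  # kg/m^2 per year of image-based BMI variation
    latent_density_marginal: tuple[float, float, float, float] = DEFAULT_MARGINAL
    annual_drift: float = -0.02  # latent units per year, <= 0
    bmi_coupling: float = -0.02  # latent units per kg/m^2 of BMI change
    thresholds: tuple[float, float, float] | None = None  # None -> calibrated
    reader_noise_sd: float = 0.30  # latent units, within-reader
    ai_noise_sd: float = 0.12
    reader_bias_sd: float = 0.25  # between-reader
    n_readers: int = 39
    fellowship_prob: float = 0.36
    reader_continuity: float = 0.75  # chance a visit is read by the home reader
    intervisit_years: float = 1.0
    start_date: _dt.date = _dt.date(2016, 1, 1)

    def __post_init__(self) -> None:
        if self.n_women < 1:
            raise ValueError("n_women must be positive")
        probs = np.asarray(self.exam_count_probs, dtype=float)
        if probs.shape != (4,) or (probs < 0).any() or abs(probs.sum() - 1) > 1e-9:
            raise ValueError("exam_count_probs must be 4 non-negative values summing to 1")
        marg = np.asarray(self.latent_density_marginal, dtype=float)
        # printed-table marginals may sum to 0.999 from rounding; normalised on use
        if marg.shape != (4,) or (marg <= 0).any() or abs(marg.sum() - 1) > 5e-3:
            raise ValueError("latent_density_marginal must be 4 positive values summing to 1")
        for name in ("reader_noise_sd", "ai_noise_sd", "reader_bias_sd", "bmi_walk_sd"):
            if getattr(self, name) < 0:
                raise ValueError(f"{name} must be >= 0")
        if self.thresholds is not None:
            t = tuple(self.thresholds)
            if len(t) != 3 or not (t[0] < t[1] < t[2]):
                raise ValueError("thresholds must be 3 strictly increasing values")
        if not 0 <= self.fellowship_prob <= 1 or not 0 <= self.reader_continuity <= 1:
            raise ValueError("probabilities must be in [0, 1]")
        if self.n_readers < 1 or self.intervisit_years <= 0:
            raise ValueError("n_readers and intervisit_years must be positive")

    def to_dict(self) -> dict:
        d = asdict(self)
        d["start_date"] = self.start_date.isoformat()
        return d

    @classmethod
    def from_dict(cls, d: dict) -> "SimulationConfig":
        d = dict(d)
        if "start_date" in d and isinstance(d["start_date"], str):
            d["start_date"] = _dt.date.fromisoformat(d["start_date"])
        for key in ("exam_count_probs", "latent_density_marginal", "thresholds",
                    "age_bounds", "bmi_bounds"):
            if key in d and d[key] is not None:
                d[key] = tuple(d[key])
        return cls(**d)


def calibrate_thresholds(
    target_marginal: Sequence[float], latent_distribution=None
) -> tuple[float, float, float]:
    """Category thresholds as latent-distribution quantiles of the cumulative
    target probabilities; applying them to a large latent sample reproduces
    the targets up to Monte-Carlo error."""
    targets = np.asarray(target_marginal, dtype=float)
    if (targets <= 0).any():
        raise ValueError("every category needs positive target probability")
    if abs(targets.sum() - 1) > 5e-3:
        raise ValueError("target probabilities must sum to 1")
    targets = targets / targets.sum()
    dist = latent_distribution if latent_distribution is not None else sps.norm()
    cum = np.cumsum(targets)[:3]
    t = tuple(float(dist.ppf(p)) for p in cum)
    return t


def mean_visit_offset_years(
    exam_count_probs: Sequence[float] = DEFAULT_EXAM_COUNT_PROBS,
    intervisit_years: float = 1.0,
) -> float:
    """Expected years elapsed since a woman's first exam, averaged over all
    exams of the cohort ((n - 1) / 2 visits for an n-exam woman)."""
    probs = np.asarray(exam_count_probs, dtype=float)
    counts = np.asarray(EXAM_COUNTS, dtype=float)
    # exam-level average: an n-exam woman contributes n exams at mean index (n-1)/2
    return float(
        intervisit_years
        * np.sum(probs * counts * (counts - 1) / 2)
        / np.sum(probs * counts)
    )


def default_thresholds(config: "SimulationConfig") -> tuple[float, float, float]:
    """Thresholds calibrated so the exam-level category distribution matches
    the configured marginal: quantiles of the latent distribution at the
    cohort's mean visit offset, where drift has shifted the mean."""
    shift = config.annual_drift * mean_visit_offset_years(
        config.exam_count_probs, config.intervisit_years
    )
    return calibrate_thresholds(
        config.latent_density_marginal, sps.norm(loc=shift, scale=1.0)
    )


def categorize(z: float, thresholds: Sequence[float]) -> int:
    """Ordinal category of a latent value under strictly increasing thresholds."""
    return int(np.searchsorted(np.asarray(thresholds), z, side="left"))


def expected_misclassification_rate(
    thresholds: Sequence[float],
    noise_sd: float,
    latent_mean: float = 0.0,
    latent_sd: float = 1.0,
) -> float:
    """P(category(z + eps) != category(z)) for z ~ N(latent_mean, latent_sd^2)
    and eps ~ N(0, noise_sd^2), by numerical integration."""
    if noise_sd == 0:
        return 0.0
    taus = np.asarray(thresholds, dtype=float)
    z = np.linspace(latent_mean - 8 * latent_sd, latent_mean + 8 * latent_sd, 40001)
    fz = sps.norm.pdf(z, latent_mean, latent_sd)
    edges = np.concatenate([[-np.inf], taus, [np.inf]])
    cat = np.searchsorted(taus, z, side="left")
    lo = edges[cat]
    hi = edges[cat + 1]
    p_same = sps.norm.cdf((hi - z) / noise_sd) - sps.norm.cdf((lo - z) / noise_sd)
    return float(1.0 - np.trapezoid(p_same * fz, z))


def _truncated_normal(rng, mean, sd, bounds, size):
    a, b = (bounds[0] - mean) / sd, (bounds[1] - mean) / sd
    return sps.truncnorm.rvs(a, b, loc=mean, scale=sd, size=size, random_state=rng)


def generate(config: SimulationConfig) -> tuple[Cohort, pd.DataFrame]:
    """Generate a cohort and its hidden-truth sidecar.

    Returns ``(cohort, truth)`` where ``truth`` has one row per examination
    with the latent density, the true category, both observed categories and
    the assigned reader — for testing and calibration only, never an input
    to the analysis.
    """
    cfg = config
    rng = np.random.default_rng(cfg.seed)
    thresholds = (
        cfg.thresholds if cfg.thresholds is not None else default_thresholds(cfg)
    )

    fellowship = rng.random(cfg.n_readers) < cfg.fellowship_prob
    reader_bias = (
        rng.normal(0.0, cfg.reader_bias_sd, cfg.n_readers)
        if cfg.reader_bias_sd > 0
        else np.zeros(cfg.n_readers)
    )
    reader_ids = [f"R{i:02d}" for i in range(cfg.n_readers)]

    exam_counts = rng.choice(EXAM_COUNTS, size=cfg.n_women, p=cfg.exam_count_probs)
    ages0 = _truncated_normal(rng, cfg.age_mean, cfg.age_sd, cfg.age_bounds, cfg.n_women)
    bmis0 = _truncated_normal(rng, cfg.bmi_mean, cfg.bmi_sd, cfg.bmi_bounds, cfg.n_women)
    z0 = rng.standard_normal(cfg.n_women)
    home_readers = rng.integers(0, cfg.n_readers, cfg.n_women)
    start_offsets = rng.integers(0, 365, cfg.n_women)

    dt = cfg.intervisit_years
    step_days = max(1, round(dt * 365.25))
    timelines: list[WomanTimeline] = []
    truth_rows: list[dict] = []
    for w in range(cfg.n_women):
        wid = f"W{w:06d}"
        n_exams = int(exam_counts[w])
        z = float(z0[w])
        bmi = float(bmis0[w])
        date0 = cfg.start_date + _dt.timedelta(days=int(start_offsets[w]))
        exams = []
        for t in range(n_exams):
            if t > 0:
                new_bmi = bmi + rng.normal(0.0, cfg.bmi_walk_sd * np.sqrt(dt))
                new_bmi = float(np.clip(new_bmi, *cfg.bmi_bounds))
                z += cfg.annual_drift * dt + cfg.bmi_coupling * (new_bmi - bmi)
                bmi = new_bmi
            true_cat = categorize(z, thresholds)
            if cfg.reader_continuity >= 1 or rng.random() < cfg.reader_continuity:
                r = int(home_readers[w])
            else:
                r = int(rng.integers(0, cfg.n_readers))
            reader_cat = categorize(
                z + reader_bias[r] + rng.normal(0.0, cfg.reader_noise_sd)
                if cfg.reader_noise_sd > 0
                else z + reader_bias[r],
                thresholds,
            )
            ai_cat = categorize(
                z + rng.normal(0.0, cfg.ai_noise_sd) if cfg.ai_noise_sd > 0 else z,
                thresholds,
            )
            thickness = float(np.clip(20 + 1.5 * (bmi - 20) + rng.normal(0, 4), 10, 150))
            fat = float(np.clip(0.25 + 0.012 * (bmi - 20) + rng.normal(0, 0.05), 0.01, 0.99))
            exam_date = date0 + _dt.timedelta(days=t * step_days)
            exams.append(
                ExamRecord(
                    woman_id=wid,
                    exam_date=exam_date,
                    reader_id=reader_ids[r],
                    reader_fellowship=bool(fellowship[r]),
                    reader_density=reader_cat,
                    ai_density=ai_cat,
                    age_years=round(float(ages0[w]) + t * dt, 2),
                    bmi=round(bmi, 3),
                    fat_measure=round(fat, 4),
                    thickness_mm=round(thickness, 2),
                )
            )
            truth_rows.append(
                {
                    "woman_id": wid,
                    "exam_index": t,
                    "exam_date": exam_date.isoformat(),
                    "latent": z,
                    "true_category": density_label(true_cat),
                    "ai_category": density_label(ai_cat),
                    "reader_category": density_label(reader_cat),
                    "reader_id": reader_ids[r],
                }
            )
        timelines.append(WomanTimeline(wid, tuple(exams)))

    prov = Provenance(
        source=f"simulated(seed={cfg.seed}, n_women={cfg.n_women})",
        n_rows=int(exam_counts.sum()),
        n_women_seen=cfg.n_women,
        n_women_included=cfg.n_women,
    )
    cohort = Cohort(tuple(timelines), prov)
    truth = pd.DataFrame(truth_rows)
    return cohort, truth


def write_config(config: SimulationConfig, path: str | Path) -> Path:
    path = Path(path)
    path.write_text(json.dumps(config.to_dict(), indent=2, sort_keys=True))
    return path
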