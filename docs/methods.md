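# Methods

## Pattern taxonomy

A woman's ordered density sequence (≥ 3 exams) is summarised from the signs
of its consecutive differences d_i = sign(x_{i+1} − x_i): constant if no
d_i is nonzero, ascending if some d_i > 0 and none < 0, descending
symmetrically, bi-directional if both signs occur. Two choices were
genuinely open and are fixed as follows:

* **Plateaus do not break monotonicity.** (b, b, c) is ascending. "Constant"
  means literally all assessments equal. This is the minimal reading under
  which the four labels partition all sequences; over all 64 length-3
  quaternary sequences the census is 4 constant / 16 ascending /
  16 descending / 28 bi-directional, which the suite checks against an
  independent sorted-copy oracle.
* **Consecutive differences, not first-vs-last.** Bi-directionality is
  undefined under a first-vs-last comparison; transition tables (first exam
  → last exam) are kept as a separate, deliberately coarser view.

Binary-density patterns are computed by classifying the binarized sequence
({a,b}→0, {c,d}→1), not by collapsing the 4-category label: the binary
collapse is order-preserving, so a 4-category constant stays constant and an
ascending sequence can only become constant or ascending (a property test).

## Paired tests

McNemar is implemented with the exact two-sided binomial on the discordant
counts (b, c); default policy is exact below b + c = 25 and the
continuity-corrected χ² above (the correction is applied even at b = c,
following the R/statsmodels convention). The exact p depends on the
discordant pairs only; concordant-pair invariance and rater-exchange
antisymmetry are tested. Under a simulated exchangeable-rater null the
exact test rejects at ≤ 5.5% (it is conservative; observed ≈ 3–4%).

The exam-level category distributions of the two raters are compared with
the Stuart–Maxwell marginal-homogeneity statistic d'S⁻¹d on the first k−1
marginal differences (S_hh = row_h + col_h − 2n_hh, S_hj = −(n_hj + n_jh)),
df = k − 1. The data are paired, so an unpaired χ² would be wrong. With
identical marginals the statistic is 0 and p = 1 even when S is singular;
a table with all mass in one category raises a degenerate-table error
rather than returning NaN. At k = 2 the statistic equals the uncorrected
McNemar χ² to machine precision (tested), and the implementation is
cross-checked against statsmodels' `SquareTable.homogeneity` on random
tables.

Reported percentages are rounded half-up to one decimal and headline
differences are differences of the *rounded* percentages, matching how such
tables are printed (e.g. 81.0 − 56.8 = 24.2 where the unrounded difference
is 24.25). Raw proportions are kept at full precision in `results.json`.
No multiplicity correction is applied across traits × contexts × subgroups.

## Subgroups

* Post-menopausal: first-exam age strictly > 55 years (an age proxy only).
* Stable BMI: |ΔBMI|/BMI < 5% for **every consecutive pair** of exams —
  the stricter reading of "between examinations", consistent with
  "stable". Women with any missing BMI are excluded from this subgroup;
  the image-based proxy can fill gaps first.
* Same reader / fellowship: **all** of a woman's exams must qualify, since
  the longitudinal label is a property of the whole sequence.

Filters are idempotent and commute; each subgroup is a subset of the full
cohort (property tests).

## BMI proxy

BMI is approximated by OLS on compressed breast thickness (mm) and
image-based fat fraction, clamped to (10, 80) kg/m². The two-feature
linear form is a pluggable stand-in: coefficients are JSON round-trippable
so an externally validated estimator can replace the fitted one without
touching the pipeline. Parameter recovery on data generated from a known
linear model is within 1% at noise sd 0.01, and the proxy correlates
> 0.9 with true BMI when residual noise is ≤ 1 kg/m².

## Synthetic cohort

The generator emulates the statistical structure of a multi-site screening
cohort, not its images. Per woman: exam count ∈ {3,4,5,6} with
probabilities (0.607, 0.288, 0.0525, 0.0525) — the published 3- and 4-exam
fractions, with the pooled 10.5% "5 or 6" block split evenly; age at first
exam ~ N(55.6, 10.3²) truncated to [35, 90]; BMI ~ N(28.3, 4.9²) truncated
to (15, 60). A latent density z₀ ~ N(0,1) evolves as
z_{t+1} = z_t + drift·Δt + coupling·ΔBMI with defaults drift = −0.02/yr
(small decline, as longitudinal density studies report) and coupling =
−0.02 per kg/m² (weight gain lowers percent density). Thresholds are the
latent quantiles of the target category marginal — by default the
radiologists' exam-level distribution (9.0/45.1/38.1/7.7%) — evaluated at
the cohort's mean visit offset so the *exam-level* truth marginal, not just
the baseline one, matches the target (realized error ≲ 0.7 pp at
n = 20 000).

Rater observation: radiologist = category(z + bias_r + ε),
ε ~ N(0, 0.30); bias_r ~ N(0, 0.25) drawn once per radiologist (39
readers, 36% fellowship-trained). AI = category(z + ε), ε ~ N(0, 0.12),
no bias. Putting at least as much radiologist variability between readers
as within reflects the literature on BI-RADS density agreement and makes
the same-reader subgroup behave as observed: radiologists become more
self-consistent when the reader is fixed, yet remain less consistent than
the AI. Women have a "home" reader who reads each visit with probability
0.75, giving ≈ 35% of women a single reader throughout. The BMI walk sd
(3 kg/m²/yr) represents variation of the *image-based* BMI measure, not
physiologic weight change; it is set so that only a small minority of
women (≈ 10%) meet the < 5% stability criterion, as in screening cohorts
where stable-BMI subgroups are small. Noise in latent space guarantees
ordinal, adjacent-category-heavy errors; an arbitrary confusion matrix
cannot.

The generator is deterministic given the seed (byte-identical CSVs,
tested). Its truth sidecar (latent values, true categories, reader
assignment) exists for testing and calibration only.

**What passing tests do and do not show.** The simulator reproduces the
qualitative headline (AI more constant, fewer bi-directional, p < .05 at
n = 5000) and realistic marginals, but it does not model race, site
effects, acquisition format (DM vs SM), hormonal exposures, or secular
drift in reader behaviour; agreement magnitudes on real cohorts are a
claim the synthetic tests cannot make.

## Numerical and degenerate-input choices

* Exams are ordered by date; same-date exams for a woman are invalid input
  (excluded and tallied), since screening is at most annual.
* Lenient CSV reading drops and tallies malformed rows; strict mode aborts.
  Exclusion tallies always reconcile with the distinct women seen.
* Density codes are integers 0–3 internally; letters only at I/O.
* Exact-binomial doubling is capped at 1; b = c = 0 returns p = 1.
* Problem sizes in the routine checks (800–20 000 simulated women,
  2000 null replicates of 300 pairs) keep every stage to seconds while
  leaving Monte-Carlo error well inside the asserted tolerances.

## Known limitations

* The true image-based BMI formula used in practice is proprietary to each
  site; the linear proxy is a structural stand-in.
* The stable-BMI narrowing seen in real data partly reflects selection
  effects (who returns, who stays stable) that the random-walk model does
  not capture.
* Pattern labels ignore inter-exam spacing; a 6-month recall and a 2-year
  gap count equally.
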