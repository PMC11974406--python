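"""Generate a synthetic screening cohort and look at its composition.

Each woman gets 3-6 annual exams; a latent density declines slowly and is
observed through two noisy raters (AI and radiologist).  The printed counts
show the exam-count mix and the exam-level density marginals for each rater.
"""

import pandas as pd

from densitraj import SimulationConfig, generate

cfg = SimulationConfig(n_women=2000, seed=7)
cohort, truth = generate(cfg)

frame = cohort.to_frame()
print(f"women: {cohort.n_women}   exams: {cohort.n_exams}")
exam_counts = pd.Series([len(t) for t in cohort]).value_counts(normalize=True)
print("exam-count mix (fraction of women):")
print(exam_counts.sort_index().round(3).to_string())
print("\nexam-level density marginals (%):")
print(
    pd.DataFrame(
        {
            "ai": frame["ai_density"].value_counts(normalize=True) * 100,
            "radiologist": frame["reader_density"].value_counts(normalize=True) * 100,
            "truth": truth["true_category"].value_counts(normalize=True) * 100,
        }
    )
    .sort_index()
    .round(1)
)
# the radiologist column is wider in the tails than the AI column: the
# larger radiologist noise spreads observed categories away from the truth
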