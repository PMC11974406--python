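"""Classify longitudinal density patterns and cross-tabulate the two raters.

A sequence is constant / ascending / descending / bi-directional according to
the signs of its consecutive changes.  Bi-directional trajectories over a
short window are implausible physiologically, so their frequency measures
assessment variability rather than biology.
"""

from densitraj import (
    SimulationConfig,
    classify_pattern,
    generate,
    paired_pattern_table,
    pattern_table,
)

print("worked single sequences (0=a .. 3=d):")
for seq in [(2, 2, 2), (1, 2, 3), (1, 0, 1), (1, 1, 2)]:
    print(f"  {seq} -> {classify_pattern(seq).value}")

cohort, _ = generate(SimulationConfig(n_women=3000, seed=5))
for rater in ("ai", "reader"):
    print(f"\n{rater} pattern table (4-category):")
    print(pattern_table(cohort, rater, "four_category"))

print("\nAI (rows) vs radiologist (columns) pattern confusion matrix:")
print(paired_pattern_table(cohort, "four_category").counts)
# most disagreements sit in the 'constant' row: the AI calls the sequence
# stable while the radiologists' assessments wander
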