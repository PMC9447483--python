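"""Refugium and toxicity statistics for retroelements across chromosome classes.

Simulates a repeat landscape with a W-enriched ERV-like family, computes the
Refugium Index (observed vs length-proportional expected repeat bp) per
class with a chi-square uniformity test, and evaluates the Toxicity Index on
full-length-element counts.
"""

from zwtools.refugium import (
    ChromClassTotals,
    fl_ltr_summary,
    refugium_index,
    toxicity_index,
)
from zwtools.simulate import (
    GenomeLayout,
    RepeatFamily,
    RepeatSimParams,
    simulate_repeat_annotation,
)

layout = GenomeLayout(
    [("a1", "autosome", 4_000_000), ("z", "Z", 500_000), ("w", "W", 300_000)],
    window_size=10_000,
)
families = [RepeatFamily("ERV", 0.03, {"autosome": 1.0, "Z": 2.0, "W": 8.0},
                         mean_length=300)]
annotation, truth = simulate_repeat_annotation(
    layout, RepeatSimParams(families, seed=2), with_sequences=False
)

totals = ChromClassTotals(
    ungapped_bp={"autosome": 4_000_000, "Z": 500_000, "W": 300_000},
    observed={"ERV": truth.groupby("class")["repeat_bp"].sum().to_dict()},
)
res = refugium_index(totals, "ERV")
for cls in ("autosome", "Z", "W"):
    print(f"{cls:>9}: observed {res.observed[cls]:>9.0f} bp, "
          f"expected {res.expected[cls]:>9.0f} bp, RI = {res.ri[cls]:+.3f}")
print(f"chi2 = {res.chi2:.0f}, df = {res.df}, p = {res.p:.3g}")

# Toxicity Index on genome-wide full-length LTR counts at a realistic
# snake-genome class-length split: near zero = no strong sex bias in
# diploid fl-LTR load.
counts = {"autosome": 13603, "Z": 1786, "W": 572}
genome_scale = ChromClassTotals({"autosome": 940e6, "Z": 40e6, "W": 20e6})
print(fl_ltr_summary(counts, genome_scale).round(3).to_string())
print(f"toxicity index = {toxicity_index(counts).index:+.4f}")

# RI > 0 on Z and W with autosomal depletion is the refugium signature: the
# sex chromosomes hold more ERV bp than their length share predicts.
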