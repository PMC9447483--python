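"""W-linked gene evolution: copy number, decay rates, translocation, expression.

Estimates gene copy number from simulated female read depth (a single-copy
W gene sits at half the diploid autosomal median), computes per-stratum gene
decay rates and stratum enrichment, classifies candidate autosome-to-W
translocations, and applies the raw-count expression-detection rules.
"""

import pandas as pd

from zwtools.gene_content import (
    classify_translocation,
    copy_number_table,
    decay_rate,
    expression_flags,
    stratum_enrichment,
)
from zwtools.simulate import CoverageSimParams, simulate_expression_counts, simulate_gene_depths

# --- copy number from depth (true copy numbers 1, 1, 2, 6, 94) ---
truth = [1, 1, 2, 6, 94]
depths = simulate_gene_depths(truth, CoverageSimParams(mean_depth=30, dispersion=10.0, seed=4))
medians = {s: 30.0 for s in depths["sample"].unique()}
cn = copy_number_table(depths, medians)
cn["true"] = truth
print(cn.round(2).to_string(index=False))

# --- decay rates per stratum (constructed Z/W gene counts) ---
recent = decay_rate(300, 100, 40e6, stratum="recent")
older = decay_rate(700, 220, 90e6, stratum="older")
for d in (recent, older):
    print(f"{d.stratum}: ({d.n_z_genes} Z - {d.n_w_genes} W) / {d.time_years/1e6:.0f} Myr "
          f"= {d.rate:.2e} genes lost/year")

# --- stratum gene enrichment (W vs Z genes inside the recent stratum) ---
fisher = stratum_enrichment(100, 100, 120, 480)
print(f"recent-stratum enrichment: OR = {fisher['odds_ratio']:.2f}, p = {fisher['p']:.2e}")

# --- translocation calls ---
for gene, has_z, chrom in (("RBM14", False, "2"), ("LMTK3", True, "6"), ("novel", False, None)):
    print(f"{gene}: {classify_translocation(has_z, chrom)}")

# --- expression detection: female-specific genes ---
counts = simulate_expression_counts(200, female_mean=2.0, male_mean=0.05, n_per_sex=3, seed=4)
sex_map = {c: ("female" if c.startswith("female") else "male") for c in counts.columns}
flags = expression_flags(counts, sex_map)
print(f"detected in females: {flags['detected_female'].sum()} / 200; "
      f"female-specific: {flags['female_specific'].sum()}")

# Copy-number estimates track the truth including the highly amplified gene;
# the recent stratum decays more slowly per year than the older stratum here
# only if its (Z - W) deficit per unit time is smaller.
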