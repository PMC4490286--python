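"""Run the full SNP quality-control chain on a structured synthetic cohort.

The cohort carries two Balding–Nichols subpopulations (Fst = 0.1) plus
a pair of duplicated subjects and high-LD SNP probes, so every filter
has something real to remove.
"""

import warnings

import numpy as np

from paraica import CohortConfig, generate_cohort
from paraica.qc import (
    ld_prune,
    sample_qc,
    snp_filters,
    stratification_adjust,
    univariate_prefilter,
)

warnings.filterwarnings("ignore")

config = CohortConfig(
    n_per_group=(60, 90, 90),
    n_snps=1500,
    fst=0.05,  # hidden two-population structure
    group_shift=(0.0, 0.0, 0.0),
    snp_effect_size=0.0,  # null scan: lambda_GC should sit near 1
    n_duplicate_subjects=2,
    n_duplicate_snps=20,
    missing_rate=0.01,
    seed=11,
)
table, _, truth = generate_cohort(config)
print(f"input: {table.n_subjects} subjects x {table.n_snps} SNPs")

table, rep1 = sample_qc(table, seed=0)
table, rep2 = snp_filters(table)
table, rep3 = ld_prune(table)
for step in rep1.steps + rep2.steps + rep3.steps:
    print(f"  {step['name']:<24} removed {step['removed']:>4}  remaining {step['remaining']}")

adjusted, rep4 = stratification_adjust(table)
flagged = rep4.stratification["adjusted_components"]
print(f"ancestry-associated PCs regressed out: {flagged}")

selected, stats_table, diag = univariate_prefilter(table, adjusted)
for contrast, d in diag["contrasts"].items():
    print(f"  {contrast}: lambda_GC = {d['lambda_gc']:.3f}")
print(f"prefilter union (P < 0.025 in either contrast): {len(selected)} SNPs")

# The duplicated subjects fall to the relatedness gate, the LD probes to
# the pruning step, and the ancestry axis is detected and residualized;
# lambda_GC near 1 confirms the adjusted scan is not inflated.
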