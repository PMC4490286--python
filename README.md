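# paraica

Parallel ICA fusion of SNP genotypes and EEG spectral features — a
library for multivariate genotype–phenotype association in cohorts
where each subject carries both a genome-wide dosage vector and a set
of spatio-spectral EEG weights.

Univariate GWAS treats every SNP alone against a unitary phenotype and
pays for it in multiple-testing burden; psychiatric phenotypes such as
resting-state EEG oscillations are instead thought to be driven by many
interacting variants of small effect. Parallel ICA (para-ICA)
addresses this by decomposing both data matrices at once,

X_snp = A_snp · S_snp,    X_eeg = A_eeg · S_eeg,

with Infomax ICA maximizing source independence on each side while an
extra objective term maximizes the correlation between paired columns
of the loading matrices A (the per-subject loading coefficients, LC).
A significant loading correlation links a *network* of SNPs (the rows
of S_snp thresholded at |Z| ≥ 2) to a *pattern* of EEG frequency
activity, with far fewer tests than SNP-by-SNP scans: significance is
Bonferroni-corrected only over the k_eeg × k_snp component grid.

The package provides every stage as an importable API:

| module | what it does |
| --- | --- |
| `paraica.synth` | three-group synthetic cohorts with designed cross-modal coupling and known ground truth |
| `paraica.qc` | additive coding, sample QC (missingness / heterozygosity / relatedness), SNP filters (MAF, call rate, exact HWE in controls, differential missingness), LD pruning, eigenstrat-style stratification adjustment, per-SNP logistic prefilter with λ_GC / q–q diagnostics |
| `paraica.spectra` | Hamming-window amplitude spectra (bins < 1.5 Hz dropped) and group spectral ICA to per-subject channel × component weights |
| `paraica.order` | model-order selection: Wax–Kailath MDL and ICASSO-style run-to-run stability |
| `paraica.parallel` | Infomax ICA and the coupled two-modality decomposition; |Z| ≥ 2 feature selection with relative weights |
| `paraica.assoc` | partial-correlation association with age/sex/ethnicity/site adjustment, Bonferroni correction, group and clinical comparisons |
| `paraica.reliability` | Hungarian component matching and leave-one-out reliability |
| `paraica.pipeline` / CLI `paraica` | end-to-end orchestration with per-stage artifacts and a run manifest |
| `paraica.plinkio` / `paraica.h5io` | PLINK BED/BIM/FAM and dosage-text I/O; HDF5 serialization |

## Worked example

`examples/` contains one short script per capability. The core loop —
generate a coupled cohort, decompose, test — looks like this
(condensed from `examples/04_parallel_ica.py` and
`examples/05_reliability.py`):

```python
from paraica import (CohortConfig, generate_cohort, para_ica,
                     build_covariate_design, partial_association_matrix,
                     loo_reliability)
from paraica.qc import impute_standardize

cfg = CohortConfig(n_per_group=(12, 24, 24), n_snps=500, n_channels=16,
                   n_freq_components=8, k_geno=3, k_eeg=3,
                   coupled_pairs=((0, 0, 0.5),), group_shift=(0, 0, 0),
                   snp_effect_size=2.0, noise_sd=0.2, missing_rate=0.0,
                   seed=42)
table, features, truth = generate_cohort(cfg)
x = impute_standardize(table.dosages)

result = para_ica(x, features.weights, k_snp=3, k_eeg=3, seed=7)
print(result.max_pair())

report = loo_reliability(x, features.weights, result,
                         [result.max_pair()[:2]], seed=7)
print(report.pair_reliability)
```

Output:

```
(2, 2, 0.4665935566682898)
{(2, 2): {'eeg': 0.9997710952099548, 'snp': 0.9920497333623424}}
```

The strongest loading-correlation pair is EEG component 3 with SNP
component 3 at r = +0.467 — the designed r = 0.5 coupling recovered
from the observed data up to sampling and estimation error. The
leave-one-out reliability indices (mean |correlation| between each
rerun's best-matching component and the original, across all 60
drop-one-subject reruns) are 1.000 on the EEG side and 0.992 on the SNP
side: no single subject drives the pair.

The same analysis runs from the shell on files
(PLINK trio + HDF5 features):

```sh
paraica synth --seed 7 --out run/
paraica run-all --genotypes run/cohort --features run/features.h5 \
        --seed 7 --out run/out
```

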