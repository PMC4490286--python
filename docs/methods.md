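# Methods

`paraica` implements a multivariate genotype–phenotype association
workflow for cohorts carrying both SNP genotypes and EEG spectral
features: quality-controlled additive dosages and group-ICA-compressed
spatio-spectral weights are decomposed jointly by a parallel ICA whose
objective couples the two modalities, followed by covariate-adjusted
association testing, component feature selection, group comparisons and
leave-one-out reliability. This note records the models, the defaults
and why they are what they are, and the choices made where the design
was genuinely open.

## Synthetic cohorts

The generator (`paraica.synth`) emulates a three-group case/case/control
design. Its latent model is additive on both sides:

* Subject loadings for `k_geno` genetic and `k_eeg` EEG components are
  standard normal; designated pairs are drawn from a bivariate normal
  at a designed Pearson `r`, standardized, and then shifted per group
  by `group_shift` (s.d. units). The designed `r` is therefore the
  **within-group** correlation; the pooled correlation also carries the
  shared diagnosis shift, as in real case/control data.
* Genotypes: each SNP has an ancestral MAF drawn uniformly from
  `maf_range` (default (0.05, 0.5]). With `fst > 0`, two Balding–Nichols
  subpopulations perturb the allele frequency through a
  Beta(p(1−F)/F, (1−p)(1−F)/F) draw, and self-reported ethnicity is
  tied to the subpopulation so stratification adjustment is testable.
  Latent genetic signal enters on the logit scale — the per-allele
  success probability of the Binomial(2, p) draw is shifted by
  `snp_effect_size ×` (loading × sparse component map) — so dosages
  remain legal {0, 1, 2} and null SNPs are exactly in Hardy–Weinberg
  equilibrium. Missing calls are injected completely at random.
* EEG features: a noisy linear mixture of sparse Laplace
  (super-Gaussian, hence ICA-identifiable) spatio-spectral maps,
  `n_channels × n_freq_components` columns laid out channel-major.
* Demographics (age, sex, site, ethnicity distributions per group, and
  clinical scores for the case groups) default to the margins of a
  306-subject multisite psychosis cohort (56/105/145 controls/cases);
  they are generated independently of the latent loadings unless the
  `confound_strength` knob leaks standardized age into every loading,
  which is how the partial-correlation stage is tested under a
  confounded regime.

What the generator does **not** emulate: linkage-disequilibrium
haplotype structure (only optional near-duplicate SNP probes for the
pruning test), pedigrees (only duplicate-subject probes), genotyping
batch effects, non-random missingness, and any realistic SNP-to-EEG
effect architecture — the additive latent-component model is an
assumption of the artifact, chosen for testability, not a claim about
biology. Passing recovery tests therefore show the algorithms work
under a known additive ground truth, not that real cohorts behave this
way.

## SNP quality control

The chain follows standard GWAS practice with these thresholds:
subject missing rate > 3%, heterozygosity beyond 3 s.d. of the cohort
mean, pairwise relatedness > 0.1875 (the member with higher missingness
is dropped); SNP MAF < 5%, call rate < 98%, HWE exact P < 1e-5 computed
in controls only, case/control differential missingness (Fisher exact)
P < 1e-5, autosomes only; LD pruning at r² > 0.8 within closed 10 kb
windows (positions 1-based as in BIM files), dropping the later SNP,
ties by lower MAF.

* **HWE** uses the exact conditional (Levene–Haldane) test via the
  numerically stable heterozygote-count recurrence, not the chi-square
  approximation: at thresholds like 1e-5 the exact tail is the only
  defensible choice, and it admits an independent enumeration oracle
  that the tests sweep exhaustively for all configurations with n ≤ 50.
* **Relatedness** is the method-of-moments standardized-genotype
  covariance (a PI-HAT analogue under no inbreeding): ≈1 for
  duplicates, 0.5 for full sibs, 0 for unrelated. Like PLINK's
  estimator it uses pooled allele frequencies and therefore inflates
  under strong population structure; with continental-scale Fst ≥ 0.1
  same-ancestry pairs can cross the 0.1875 gate. A structure-robust
  estimator (KING-style) is a known alternative and out of scope.
* **Stratification** is eigenstrat-style: PCA on standardized
  mean-imputed dosages, one-way ANOVA of each of the top 10 subject
  score vectors against self-reported ethnicity, and OLS
  residualization of every flagged (P < 0.05) component out of the
  dosage matrix. Residualization is idempotent and the report records
  the post-adjustment ANOVA and the case–control comparison of scores.
* **Univariate prefilter**: per-SNP logistic regression of case status
  on dosage, run separately for each case group against controls; the
  union of SNPs with uncorrected P < 0.025 in either contrast feeds the
  multivariate stage. The solver is a vectorized two-parameter Newton
  iteration (intercept + dosage for all SNPs simultaneously) with a
  Rao score-test fallback under separation and P = 1 for zero-variance
  dosages; it is cross-checked against `statsmodels.Logit` in the
  tests. No covariates enter this regression — stratification has
  already been residualized out of the dosages, which the pipeline
  order enforces. Genomic inflation λ_GC (median χ² over 0.4549) and a
  q–q table are emitted per contrast.
* Missing dosages are mean-imputed for PCA, correlation and LD
  computations and casewise-deleted in the logistic scan. A
  sex-discordance check is not implemented (it needs X-chromosome
  intensity data outside the dosage model) and is noted in the report.

## EEG spectra and group compression

`spectral_transform` returns the square root of the one-sided,
window-power-normalized (mean-detrended) Hamming periodogram, with bins
below 1.5 Hz removed by default (slow eye-movement guard). The
normalization makes a Parseval identity exact, which the tests exploit
as an oracle. `group_spectral_ica` stacks every (subject, epoch,
channel) spectrum into one matrix, reduces it by PCA to `n_components`
(default 8) and unmixes with Infomax; per-row weights are averaged over
epochs within subject, giving one weight per subject, channel and
component, flattened channel-major (64 channels × 8 components = 512
columns). Component spectra are unit-normalized with their peak forced
positive; subject weights carry the magnitude. The stacking axis and
epoch-averaging back-reconstruction are artifact choices — they are
the simplest scheme producing the per-subject channel × component
weight layout; group-ICA literature contains several variants. Raw-EEG
preprocessing (artifact rejection, re-referencing, filtering) is out of
scope; the pipeline accepts a precomputed feature matrix and skips this
stage.

## Model-order selection

* **MDL**: Wax–Kailath form on the eigenvalues of the feature
  covariance, computed through the subject-space Gram matrix, so
  m = min(subjects − 1, features) eigenvalues with the i.i.d. sample
  count equal to the number of subjects. MDL(k) =
  −N(m−k)·log(geometric/arithmetic mean of the trailing eigenvalues)
  + ½k(2m−k+1)·log N, minimized over k. Constant data returns 0.
* **Stability (consistency)**: for each candidate k the data are
  decomposed `n_runs` times on random 90% subject subsamples with
  fresh initializations; components are matched between every run pair
  by Hungarian assignment on |correlation| of source maps and the
  score is the mean matched |correlation|. The maximizing k wins, ties
  to the smaller k; a flat/low profile (< 0.7) is flagged
  low-confidence.

## Infomax and the parallel decomposition

The ICA model is X = A·S for (subjects × features) data: feature
columns are the i.i.d. samples, the subject dimension is PCA-whitened
to k, and a square unmixing matrix W is learned by natural-gradient
Infomax with the logistic nonlinearity (batch updates over shuffled
sample blocks of ≈√p, capped at 512). Numerical choices:

* Initial learning rate 0.01/log k, chosen by simulation calibration —
  at desk-scale sample counts smaller classic rates stall far from
  separation within the epoch budget.
* Annealing: ×0.95 whenever the angle between successive epoch updates
  exceeds 60°; weight blow-up (max |W| > 1e8) resets W and halves the
  rate. Additionally the rate decays ×0.97/epoch over the second half
  of the budget: on near-converged data the logistic score admits a
  slow scale drift of W that successive-update angles cannot detect
  (updates stay nearly collinear), and the scheduled decay guarantees
  the stopping rule (squared update norm < 1e-6) is reachable.
* Basin selection: the objective is multimodal in practice, so each
  run starts with three short (48-epoch) pilots from independent
  random orthonormal inits and continues from the one with the highest
  Infomax log-likelihood (log|det W| + E log g′(Wy)). The pilots are
  driven by the run's own seeded generator, so results remain exactly
  reproducible.
* Components are ordered by explained variance with the sign fixed so
  each source map's largest-|value| entry is positive; Z-maps are the
  source rows standardized per component (zero mean, unit s.d. across
  features).

`para_ica` trains one such side per modality in alternation. After each
epoch the Pearson correlations between all loading-column pairs are
computed; pairs with |r| above an entry threshold (0.3), made disjoint
greedily by |r| so no component receives competing gradients, get an
extra gradient-ascent step on the squared loading correlation applied
to the whitened mixing columns. The coupling weight λ ramps linearly
from 0 to 0.5 over the first half of training and each coupling step is
capped at half the norm of that side's latest Infomax update, keeping
independence the dominant objective. Convergence requires both sides'
update norms below tolerance and the cross-correlation matrix stable to
1e-4; a side that has converged is frozen and only re-opened by an
above-tolerance coupling perturbation. With λ_max = 0 the routine is
bit-identical to two independent `infomax_ica` runs with the same
derived seeds — the decoupled-limit contract the tests verify.

**Small-sample caveat.** The 0.3 entry threshold presumes cohorts large
enough that null loading correlations rarely cross it (at n ≈ 300 the
null crossing probability is ~1e-7). At n ≲ 100 the coupling term can
chase chance correlations and inflate the familywise error of the
downstream association test; the null-calibration suite therefore runs
at n = 150, where the measured familywise error equals the nominal 5%
with full coupling. Users fusing very small cohorts should raise the
entry threshold or set λ_max = 0.

## Association, selection, reliability

Partial correlation residualizes both loading columns on [1,
covariates] (age linear; sex, ethnicity, site as full-rank dummy
contrasts, aliased columns dropped with a warning) and correlates the
residuals; the two-sided P uses the t distribution with n − 2 − q
degrees of freedom. Both raw and partial r/P are reported because
adjusted and unadjusted inference can disagree on borderline pairs; the
significance flag applies the Bonferroni threshold α/(k_eeg·k_snp) to
the partial P. Group comparisons are pairwise two-sided t-tests
preceded by Shapiro–Wilk (α = 0.05) with a flagged Mann–Whitney
fallback; clinical correlations are Pearson on non-missing scores; both
are reported uncorrected, as post-hoc analyses, with groups under 3
subjects skipped.

`zscore_select` thresholds each component's Z-map at |Z| ≥ 2, ranks by
|Z| and reports the relative weight |Z|/max|Z| (top feature = 1).

Leave-one-out reliability reruns `para_ica` once per subject on the
n − 1 remaining subjects with the original seeds and coupling (so each
rerun differs from the original only by the left-out subject), matches
each modality's components to the original by Hungarian assignment on
|correlation|, and averages the matched |correlation| per significant
pair. Matching uses source maps by default because their feature space
is invariant to removing a subject; loading-based matching (dropping
the left-out reference row) is available and the report records which
was used. Non-convergent reruns are excluded from the averages and
counted. Reruns are independent and may run in parallel (`n_jobs`);
the per-run records are ordered by left-out subject index.

## Problem sizes in the shipped checks

The statistical suites run at desk scale, chosen so each check has
adequate power while the whole suite stays quick: HWE enumeration is
exhaustive to n = 50; LD pruning uses a 200-SNP two-chromosome fixture
with planted blocks; Infomax recovery uses 20 seeds of 4-source
mixtures at SNR 10; coupling recovery uses 20 replicate cohorts of 306
subjects × 1000 SNPs × 512 features at designed r = 0.5; the global
null uses 200 replicate cohorts of 150 subjects; leave-one-out
reliability uses a 60-subject coupled cohort (500 SNPs, 128 features).
`scripts/acceptance.py` regenerates the order-selection and reliability
quantities from scratch at 306 × 512, 300 × 2000 and 60-subject scales
respectively.

## Known limitations

* The coupling schedule's constants (entry threshold, λ ramp, step
  cap) are package defaults exposed in `CouplingConfig`; other parallel
  ICA implementations use different, unpublished schedules, so
  numerical agreement with them is not a goal — recovery of designed
  ground truth is.
* Standard (logistic) Infomax only; an extended variant for
  sub-Gaussian sources is not implemented. Sparse super-Gaussian
  component maps dominate both modalities here.
* Two modalities only; no GPU; no reference-panel imputation, no
  X/Y/mitochondrial handling, no gene annotation, no enrichment
  analysis.
* The relatedness estimator inflates under strong structure (above);
  the logistic Wald P is slightly anticonservative below ~100 subjects
  per contrast, visible as λ_GC noise on small null panels.
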