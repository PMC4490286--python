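"""SNP-side quality control and univariate case–control prefiltering.

The chain mirrors standard GWAS practice: additive minor-allele coding,
per-sample filters (missingness, heterozygosity outliers, relatedness),
per-SNP filters (MAF, call rate, HWE in controls, differential
missingness), LD pruning in physical windows, eigenstrat-style
stratification adjustment, and a per-SNP logistic prefilter whose union
across case-group contrasts feeds the multivariate decomposition.

Default thresholds: sample missing rate 3%, heterozygosity ±3 s.d.,
relatedness (PI-HAT analogue) 0.1875; SNP MAF 5%, call rate 98%, HWE
exact P 1e-5 in controls, differential-missingness Fisher P 1e-5; LD
r² 0.8 within 10 kb; prefilter α 0.025 per contrast.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats

from .datasets import GenotypeTable
from .hwe import hwe_exact_test

__all__ = [
    "QcReport",
    "code_additive",
    "sample_qc",
    "snp_filters",
    "ld_prune",
    "stratification_adjust",
    "residualize_components",
    "impute_standardize",
    "univariate_prefilter",
    "relatedness_matrix",
    "logistic_scan",
    "genomic_inflation",
]

MISSING = "00"  # conventional PLINK missing genotype call


@dataclass
class QcReport:
    """Ordered record of QC steps with per-item statistics."""

    steps: list[dict] = field(default_factory=list)
    snp_stats: pd.DataFrame | None = None
    subject_stats: pd.DataFrame | None = None
    stratification: dict | None = None
    inflation: dict | None = None
    notes: list[str] = field(default_factory=list)

    def add_step(self, name: str, threshold, removed: int, remaining: int) -> None:
        if self.steps and remaining > self.steps[-1]["remaining"]:
            raise ValueError("remaining count increased across QC steps")
        self.steps.append(
            {
                "name": name,
                "threshold": threshold,
                "removed": int(removed),
                "remaining": int(remaining),
            }
        )

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(self.steps)


def code_additive(call: str, allele_a: str, allele_b: str) -> float:
    """Additive minor-allele dosage of a two-character genotype call.

    ``allele_b`` is the minor allele: AA → 0, AB/BA → 1, BB → 2.  The
    PLINK missing call ``"00"`` (or ``"--"``/``"NN"``) maps to ``nan``.
    """
    if call in (MISSING, "--", "NN", "", None):
        return np.nan
    if len(call) != 2:
        raise ValueError(f"genotype call must be two alleles, got {call!r}")
    dose = 0
    for allele in call:
        if allele == allele_b:
            dose += 1
        elif allele != allele_a:
            raise ValueError(
                f"allele {allele!r} not in SNP allele set {{{allele_a}, {allele_b}}}"
            )
    return float(dose)


# ---------------------------------------------------------------------------
# sample-level QC


def _heterozygosity(dosages: np.ndarray) -> np.ndarray:
    """Observed per-subject heterozygote fraction over called genotypes."""
    called = np.isfinite(dosages)
    n_called = called.sum(axis=1)
    n_het = np.nansum(dosages == 1.0, axis=1)
    with np.errstate(invalid="ignore", divide="ignore"):
        return np.where(n_called > 0, n_het / n_called, np.nan)


def relatedness_matrix(
    dosages: np.ndarray, max_snps: int = 20000, seed: int = 0
) -> np.ndarray:
    """Method-of-moments pairwise relatedness (PI-HAT analogue).

    The standardized genotype covariance ``mean_m (x_i - 2p)(x_j - 2p) /
    (2 p (1-p))`` estimates twice the kinship coefficient: ≈1 for
    duplicates/MZ twins, 0.5 full sibs, 0 unrelated.  Missing entries
    contribute nothing (pairwise-complete average).  A random SNP subset
    caps the cost on dense panels; callers pass LD-thinned data when
    available.
    """
    n, m = dosages.shape
    if m > max_snps:
        rng = np.random.default_rng(seed)
        dosages = dosages[:, rng.choice(m, size=max_snps, replace=False)]
        m = max_snps
    p = np.nanmean(dosages, axis=0) / 2.0
    ok = (p > 0) & (p < 1)
    dosages, p = dosages[:, ok], p[ok]
    denom = np.sqrt(2.0 * p * (1.0 - p))
    z = (dosages - 2.0 * p) / denom
    called = np.isfinite(z)
    z0 = np.where(called, z, 0.0)
    num = z0 @ z0.T
    counts = called.astype(float) @ called.astype(float).T
    with np.errstate(invalid="ignore", divide="ignore"):
        return np.where(counts > 0, num / counts, 0.0)


def sample_qc(
    table: GenotypeTable,
    missing_max: float = 0.03,
    het_sd: float = 3.0,
    ibd_max: float = 0.1875,
    seed: int = 0,
) -> tuple[GenotypeTable, QcReport]:
    """Remove subjects with poor genotyping quality or hidden relatedness.

    Order: missing rate > ``missing_max``; heterozygosity beyond
    ``het_sd`` s.d. of the cohort mean; then for each remaining pair
    with relatedness > ``ibd_max``, drop the member with the higher
    missing rate.  A sex-discordance check is not performed (it needs
    X-chromosome intensity data outside this table's model) and is
    noted in the report.
    """
    if table.n_subjects < 2:
        raise ValueError("sample QC needs at least 2 subjects")
    report = QcReport()
    report.notes.append("sex-discordance check not performed (no X/intensity data)")
    n0 = table.n_subjects

    miss = table.subject_missing_rate()
    keep = miss <= missing_max
    report.add_step("subject_missing_rate", missing_max, (~keep).sum(), keep.sum())
    table = table.take_subjects(keep)
    miss = miss[keep]

    het = _heterozygosity(table.dosages)
    mu, sd = het.mean(), het.std(ddof=1)
    keep = np.abs(het - mu) <= het_sd * sd if sd > 0 else np.ones(het.size, bool)
    report.add_step("subject_heterozygosity_sd", het_sd, (~keep).sum(), keep.sum())
    table = table.take_subjects(keep)
    miss = miss[keep]

    rel = relatedness_matrix(table.dosages, seed=seed)
    np.fill_diagonal(rel, 0.0)
    drop: set[int] = set()
    pairs = np.argwhere(np.triu(rel > ibd_max, k=1))
    # resolve highest-relatedness pairs first
    for i, j in sorted(pairs, key=lambda ij: -rel[ij[0], ij[1]]):
        if i in drop or j in drop:
            continue
        drop.add(i if miss[i] >= miss[j] else j)
    keep = np.array([i not in drop for i in range(table.n_subjects)])
    report.add_step("subject_relatedness", ibd_max, len(drop), keep.sum())
    table = table.take_subjects(keep)

    report.subject_stats = pd.DataFrame(
        {
            "subject_id": table.subjects["subject_id"],
            "missing_rate": miss[keep],
            "heterozygosity": _heterozygosity(table.dosages),
        }
    )
    assert report.steps[-1]["remaining"] == table.n_subjects <= n0
    return table, report


# ---------------------------------------------------------------------------
# SNP-level filters


def _diff_missingness_p(dosages: np.ndarray, is_case: np.ndarray) -> np.ndarray:
    """Fisher exact P of called/missing × case/control per SNP."""
    called = np.isfinite(dosages)
    n_case, n_ctrl = is_case.sum(), (~is_case).sum()
    called_case = called[is_case].sum(axis=0)
    called_ctrl = called[~is_case].sum(axis=0)
    out = np.ones(dosages.shape[1])
    # skip the all-called fast path (P=1)
    todo = np.flatnonzero((called_case < n_case) | (called_ctrl < n_ctrl))
    for j in todo:
        tab = [
            [called_case[j], n_case - called_case[j]],
            [called_ctrl[j], n_ctrl - called_ctrl[j]],
        ]
        out[j] = stats.fisher_exact(tab)[1]
    return out


def snp_filters(
    table: GenotypeTable,
    maf_min: float = 0.05,
    call_min: float = 0.98,
    hwe_alpha: float = 1e-5,
    diffmiss_alpha: float = 1e-5,
    autosomes_only: bool = True,
) -> tuple[GenotypeTable, QcReport]:
    """Exclude SNPs by MAF, call rate, HWE in controls, differential missingness.

    HWE is tested in control subjects only (exact conditional test).
    Differential missingness compares all cases pooled against controls.
    """
    report = QcReport()
    is_ctrl = (table.subjects["group"] == "control").to_numpy()
    is_case = ~is_ctrl
    if hwe_alpha is not None and not is_ctrl.any():
        raise ValueError("HWE filter requires control subjects")

    if autosomes_only:
        chrom = table.snps["chrom"].astype(str)
        keep = chrom.str.fullmatch(r"(chr)?([1-9]|1[0-9]|2[0-2])").to_numpy()
        report.add_step("autosomes_only", None, (~keep).sum(), keep.sum())
        table = table.take_snps(keep)

    maf = table.maf()
    call = table.call_rate()

    ctrl_dos = table.dosages[is_ctrl]
    hwe_p = np.ones(table.n_snps)
    for j in range(table.n_snps):
        d = ctrl_dos[:, j]
        d = d[np.isfinite(d)]
        if d.size:
            hwe_p[j] = hwe_exact_test((d == 0).sum(), (d == 1).sum(), (d == 2).sum())

    dm_p = (
        _diff_missingness_p(table.dosages, is_case)
        if is_case.any() and is_ctrl.any()
        else np.ones(table.n_snps)
    )

    report.snp_stats = pd.DataFrame(
        {
            "snp_id": table.snps["snp_id"],
            "maf": maf,
            "call_rate": call,
            "hwe_p_controls": hwe_p,
            "diff_missing_p": dm_p,
        }
    )

    stats_arrays = {"maf": maf, "call": call, "hwe": hwe_p, "dm": dm_p}
    gates = [
        ("snp_maf", "maf", maf_min),
        ("snp_call_rate", "call", call_min),
        ("snp_hwe_controls", "hwe", hwe_alpha),
        ("snp_diff_missingness", "dm", diffmiss_alpha),
    ]
    for name, key, thr in gates:
        keep = stats_arrays[key] >= thr
        report.add_step(name, thr, (~keep).sum(), keep.sum())
        table = table.take_snps(keep)
        stats_arrays = {k: a[keep] for k, a in stats_arrays.items()}
    return table, report


def impute_standardize(dosages: np.ndarray) -> np.ndarray:
    """Mean-impute missing calls, then z-score each SNP column.

    The standard preprocessing for PCA, LD and the multivariate
    decomposition; the logistic prefilter instead deletes missing
    calls casewise.
    """
    col_mean = np.nanmean(dosages, axis=0)
    x = np.where(np.isfinite(dosages), dosages, col_mean)
    sd = x.std(axis=0)
    sd[sd == 0] = 1.0
    return (x - x.mean(axis=0)) / sd


def ld_prune(
    table: GenotypeTable, r2_max: float = 0.8, window_bp: int = 10_000
) -> tuple[GenotypeTable, QcReport]:
    """Greedy LD pruning: drop the later SNP of any high-LD pair in a window.

    Scans each chromosome left to right; a SNP is dropped when its
    dosage correlation with any *retained* SNP within ``window_bp``
    (closed interval on position) satisfies r² > ``r2_max``.  Position
    ties are broken by dropping the lower-MAF copy (sort order places
    it later).  Input is sorted internally if needed, with a warning.
    """
    snps = table.snps
    maf = table.maf()
    chrom_codes = pd.factorize(snps["chrom"])[0]  # first-appearance order
    order = np.lexsort((-maf, snps["pos"].to_numpy(), chrom_codes))
    pos_sorted_within_chrom = all(
        g["pos"].is_monotonic_increasing for _, g in snps.groupby("chrom", sort=False)
    )
    if not pos_sorted_within_chrom:
        warnings.warn("SNPs not sorted by chromosome/position; sorting internally")
    x = impute_standardize(table.dosages)[:, order]
    pos = snps["pos"].to_numpy()[order]
    chrom = snps["chrom"].astype(str).to_numpy()[order]
    n = table.n_subjects

    keep_sorted: list[int] = []
    kept_by_chrom: dict[str, list[int]] = {}
    for idx in range(len(order)):
        kept = kept_by_chrom.setdefault(chrom[idx], [])
        # retained SNPs within the closed window [pos-window, pos]
        recent = [k for k in kept if pos[idx] - pos[k] <= window_bp]
        drop = False
        for k in recent:
            r = (x[:, idx] @ x[:, k]) / n
            if r * r > r2_max:
                drop = True
                break
        if not drop:
            kept.append(idx)
            keep_sorted.append(idx)

    keep_mask = np.zeros(len(order), dtype=bool)
    keep_mask[np.asarray(order)[keep_sorted]] = True
    report = QcReport()
    report.add_step(
        "ld_prune", {"r2_max": r2_max, "window_bp": window_bp},
        (~keep_mask).sum(), keep_mask.sum(),
    )
    return table.take_snps(keep_mask), report


# ---------------------------------------------------------------------------
# stratification adjustment (eigenstrat-style residualization)


def residualize_components(x: np.ndarray, scores: np.ndarray) -> np.ndarray:
    """Residual of every column of ``x`` on [1, scores] (OLS projection)."""
    design = np.column_stack([np.ones(x.shape[0]), scores])
    beta, *_ = np.linalg.lstsq(design, x, rcond=None)
    return x - design @ beta


def stratification_adjust(
    table: GenotypeTable,
    n_components_scan: int = 10,
    assoc_alpha: float = 0.05,
) -> tuple[np.ndarray, QcReport]:
    """Regress ethnicity-associated genotype PCs out of every SNP.

    PCA runs on standardized mean-imputed dosages; each of the top
    ``n_components_scan`` subject-score vectors is tested against
    self-reported ethnicity by one-way ANOVA, and components with
    P < ``assoc_alpha`` are residualized out of the dosage matrix.
    Returns the adjusted (now continuous) dosage matrix and a report
    that also records the case–control comparison of adjusted scores.
    """
    report = QcReport()
    eth = table.subjects["ethnicity"].astype(str).to_numpy()
    levels = np.unique(eth)
    x = impute_standardize(table.dosages)
    n_comp = min(n_components_scan, table.n_subjects - 1, table.n_snps)

    # subject scores from the left singular vectors
    u, s, _ = np.linalg.svd(x, full_matrices=False)
    scores = u[:, :n_comp] * s[:n_comp]

    flagged: list[int] = []
    pvals: list[float] = []
    if levels.size < 2:
        report.notes.append("single ethnicity category: no components adjustable")
    else:
        for c in range(n_comp):
            groups = [scores[eth == lev, c] for lev in levels]
            p = stats.f_oneway(*groups)[1]
            pvals.append(float(p))
            if p < assoc_alpha:
                flagged.append(c)

    adjusted = residualize_components(x, scores[:, flagged]) if flagged else x.copy()

    # diagnostic: the top PCs of the adjusted matrix should no longer
    # separate ethnicity groups
    post_p = []
    if flagged and levels.size >= 2:
        u2, s2, _ = np.linalg.svd(adjusted, full_matrices=False)
        post_p = [
            float(stats.f_oneway(*[(u2[:, c] * s2[c])[eth == lev] for lev in levels])[1])
            for c in range(min(len(flagged), u2.shape[1]))
        ]

    is_ctrl = (table.subjects["group"] == "control").to_numpy()
    cc_p = []
    if is_ctrl.any() and (~is_ctrl).any():
        for c in range(n_comp):
            cc_p.append(float(stats.ttest_ind(scores[is_ctrl, c], scores[~is_ctrl, c])[1]))

    report.stratification = {
        "n_components_scanned": n_comp,
        "ethnicity_anova_p": pvals,
        "adjusted_components": flagged,
        "post_adjustment_anova_p": post_p,
        "case_control_score_p": cc_p,
    }
    report.add_step(
        "stratification_adjust", assoc_alpha, 0, table.n_snps
    )
    return adjusted, report


# ---------------------------------------------------------------------------
# univariate logistic prefilter


def logistic_scan(
    dosages: np.ndarray, y: np.ndarray, max_iter: int = 40, tol: float = 1e-10
) -> pd.DataFrame:
    """Per-SNP logistic regression of case status on dosage (vectorized Newton).

    Fits intercept + dosage for every SNP simultaneously, casewise
    deleting missing dosages.  Returns Wald z, two-sided P and a flag
    for SNPs that hit the separation guard, whose P comes from the Rao
    score test instead.
    """
    n, m = dosages.shape
    y = y.astype(float)
    called = np.isfinite(dosages)
    x = np.where(called, dosages, 0.0)
    w_obs = called.astype(float)

    # zero-variance columns get P=1 outright
    with np.errstate(invalid="ignore"):
        mean_x = (x * w_obs).sum(0) / w_obs.sum(0)
        var_x = ((x - mean_x) ** 2 * w_obs).sum(0) / w_obs.sum(0)
    degenerate = var_x <= 0

    b0 = np.zeros(m)  # intercept
    b1 = np.zeros(m)  # dosage effect
    for _ in range(max_iter):
        eta = b0[None, :] + b1[None, :] * x
        mu = 1.0 / (1.0 + np.exp(-eta))
        w = mu * (1.0 - mu) * w_obs
        r = (y[:, None] - mu) * w_obs
        g0, g1 = r.sum(0), (r * x).sum(0)
        h00, h01, h11 = w.sum(0), (w * x).sum(0), (w * x * x).sum(0)
        det = h00 * h11 - h01 * h01
        det = np.where(np.abs(det) < 1e-300, np.nan, det)
        d0 = (h11 * g0 - h01 * g1) / det
        d1 = (h00 * g1 - h01 * g0) / det
        d0, d1 = np.nan_to_num(d0), np.nan_to_num(d1)
        b0 += d0
        b1 += d1
        if max(np.abs(d0).max(initial=0), np.abs(d1).max(initial=0)) < tol:
            break

    eta = b0[None, :] + b1[None, :] * x
    mu = 1.0 / (1.0 + np.exp(-eta))
    w = mu * (1.0 - mu) * w_obs
    h00, h01, h11 = w.sum(0), (w * x).sum(0), (w * x * x).sum(0)
    det = h00 * h11 - h01 * h01
    with np.errstate(invalid="ignore", divide="ignore"):
        se1 = np.sqrt(h00 / det)
        z = b1 / se1
    wald_p = 2.0 * stats.norm.sf(np.abs(z))

    separated = (~np.isfinite(wald_p)) | (np.abs(b1) > 15)
    # Rao score test at beta=0 as fallback (and for degenerate columns)
    pbar = (y[:, None] * w_obs).sum(0) / w_obs.sum(0)
    score = ((y[:, None] - pbar) * x * w_obs).sum(0)
    sx2 = (w_obs * (x - mean_x) ** 2).sum(0)
    with np.errstate(invalid="ignore", divide="ignore"):
        score_var = pbar * (1 - pbar) * sx2
        score_chi = np.where(score_var > 0, score**2 / score_var, 0.0)
    score_p = stats.chi2.sf(score_chi, df=1)

    p = np.where(separated, score_p, wald_p)
    p = np.where(degenerate, 1.0, p)
    return pd.DataFrame(
        {
            "beta": b1,
            "z": z,
            "p": p,
            "score_chi2": score_chi,
            "separation_flag": separated & ~degenerate,
        }
    )


def genomic_inflation(p: np.ndarray) -> float:
    """Genomic-control λ: median association χ² over its null median."""
    chi = stats.chi2.isf(np.clip(p, 1e-300, 1.0), df=1)
    return float(np.median(chi) / stats.chi2.isf(0.5, df=1))


def univariate_prefilter(
    table: GenotypeTable,
    adjusted: np.ndarray | None = None,
    alpha: float = 0.025,
) -> tuple[list[str], pd.DataFrame, dict]:
    """Case-vs-control logistic scan per group; union of P < alpha SNP sets.

    Each case group is contrasted against controls separately; the
    selected set is the union over contrasts of SNPs with uncorrected
    P below ``alpha``.  Returns (selected snp ids, per-contrast
    statistics table, diagnostics with λ_GC and a q–q table per
    contrast).

    When ``adjusted`` dosages (stratification-residualized, continuous)
    are supplied the regression runs on those; otherwise on raw
    dosages with casewise deletion of missing calls.
    """
    groups = table.subjects["group"].to_numpy()
    case_groups = [g for g in ("case1", "case2") if (groups == g).any()]
    if not (groups == "control").any() or not case_groups:
        raise ValueError("prefilter requires controls and at least one case group")

    x_all = adjusted if adjusted is not None else table.dosages
    frames = []
    diagnostics = {"contrasts": {}}
    selected: set[str] = set()
    for g in case_groups:
        mask = (groups == "control") | (groups == g)
        y = (groups[mask] == g).astype(float)
        res = logistic_scan(np.asarray(x_all)[mask], y)
        res.insert(0, "snp_id", table.snps["snp_id"].to_numpy())
        res.insert(0, "contrast", f"{g}_vs_control")
        frames.append(res)
        selected |= set(res.loc[res["p"] < alpha, "snp_id"])

        p = res["p"].to_numpy()
        order = np.argsort(p)
        n = p.size
        qq = pd.DataFrame(
            {
                "expected_neglog10": -np.log10((np.arange(1, n + 1) - 0.5) / n),
                "observed_neglog10": -np.log10(np.clip(p[order], 1e-300, 1.0)),
            }
        )
        diagnostics["contrasts"][f"{g}_vs_control"] = {
            "lambda_gc": genomic_inflation(p),
            "qq": qq,
        }

    stats_table = pd.concat(frames, ignore_index=True)
    ordered = [s for s in table.snps["snp_id"] if s in selected]
    return ordered, stats_table, diagnostics
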