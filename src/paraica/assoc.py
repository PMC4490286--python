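"""Component-pair association testing and group/clinical comparisons.

Loading coefficients (LCs) — each subject's weight on an independent
component — are correlated across modalities.  Because case/control
cohorts are rarely balanced on age, sex, race or site, those factors
are removed by partial correlation (residualize both LC columns on the
covariate design, correlate the residuals) and significance is
Bonferroni-corrected across all component pairs (α / (k_eeg · k_snp)).
"""

from __future__ import annotations

import warnings

import numpy as np
import pandas as pd
from scipy import stats

__all__ = [
    "build_covariate_design",
    "partial_correlation",
    "partial_association_matrix",
    "bonferroni_threshold",
    "group_and_clinical_tests",
]


def build_covariate_design(
    subjects: pd.DataFrame,
    numeric: tuple[str, ...] = ("age",),
    categorical: tuple[str, ...] = ("sex", "ethnicity", "site"),
) -> np.ndarray:
    """Covariate matrix: linear terms plus full-rank indicator contrasts.

    Categorical factors are dummy-coded dropping the first level;
    aliased (collinear) columns are removed with a warning so the
    design is always full rank.  The intercept is implicit (handled by
    centering inside the partial correlation).
    """
    cols = []
    for name in numeric:
        if name in subjects:
            cols.append(subjects[name].to_numpy(dtype=float)[:, None])
    for name in categorical:
        if name not in subjects:
            continue
        dummies = pd.get_dummies(subjects[name].astype(str), drop_first=True)
        if dummies.shape[1]:
            cols.append(dummies.to_numpy(dtype=float))
    if not cols:
        return np.empty((len(subjects), 0))
    design = np.column_stack(cols)

    # drop aliased columns
    q, r = np.linalg.qr(np.column_stack([np.ones(len(design)), design]))
    diag = np.abs(np.diag(r))[1:]
    keep = diag > 1e-8 * max(diag.max(), 1.0)
    if not keep.all():
        warnings.warn(f"dropping {int((~keep).sum())} aliased covariate column(s)")
        design = design[:, keep]
    return design


def partial_correlation(
    u: np.ndarray, v: np.ndarray, covariates: np.ndarray | None = None
) -> tuple[float, float]:
    """Partial Pearson r of ``u`` and ``v`` given covariates, with its P.

    Both vectors are residualized on ``[1, covariates]`` by OLS and the
    residuals correlated; the two-sided P comes from the t distribution
    with ``n - 2 - q`` degrees of freedom (q covariate columns).  An
    empty covariate set gives the plain Pearson correlation.
    """
    u = np.asarray(u, dtype=float)
    v = np.asarray(v, dtype=float)
    n = u.size
    q = 0 if covariates is None or covariates.size == 0 else covariates.shape[1]
    if q:
        design = np.column_stack([np.ones(n), covariates])
        u = u - design @ np.linalg.lstsq(design, u, rcond=None)[0]
        v = v - design @ np.linalg.lstsq(design, v, rcond=None)[0]
    uc = u - u.mean()
    vc = v - v.mean()
    denom = np.linalg.norm(uc) * np.linalg.norm(vc)
    if denom == 0:
        return 0.0, 1.0
    r = float(np.clip(uc @ vc / denom, -1.0, 1.0))
    df = n - 2 - q
    if df <= 0:
        return r, 1.0
    with np.errstate(divide="ignore"):
        t = r * np.sqrt(df / max(1.0 - r * r, 1e-300))
    p = float(2.0 * stats.t.sf(abs(t), df))
    return r, p


def bonferroni_threshold(alpha: float, k_eeg: int, k_snp: int) -> tuple[float, int]:
    """Per-pair significance threshold α / (k_eeg · k_snp) and the pair count."""
    if not 0 < alpha < 1:
        raise ValueError("alpha must be in (0, 1)")
    if k_eeg < 1 or k_snp < 1:
        raise ValueError("component counts must be >= 1")
    n_pairs = k_eeg * k_snp
    return alpha / n_pairs, n_pairs


def partial_association_matrix(
    eeg_loadings: np.ndarray,
    snp_loadings: np.ndarray,
    covariates: np.ndarray | None = None,
    alpha: float = 0.05,
) -> pd.DataFrame:
    """Raw and covariate-adjusted correlation for every component pair.

    One row per (eeg component, snp component) with raw Pearson r/P,
    partial r/P given the covariate design, and a significance flag at
    the Bonferroni-corrected threshold applied to the partial P.
    Both P variants are reported because adjusted and unadjusted
    inference can disagree on borderline pairs.
    """
    eeg_loadings = np.asarray(eeg_loadings, dtype=float)
    snp_loadings = np.asarray(snp_loadings, dtype=float)
    if eeg_loadings.shape[0] != snp_loadings.shape[0]:
        raise ValueError("subject counts differ between modalities")
    k_eeg, k_snp = eeg_loadings.shape[1], snp_loadings.shape[1]
    threshold, n_pairs = bonferroni_threshold(alpha, k_eeg, k_snp)

    rows = []
    for i in range(k_eeg):
        for j in range(k_snp):
            r_raw, p_raw = partial_correlation(eeg_loadings[:, i], snp_loadings[:, j])
            r_part, p_part = partial_correlation(
                eeg_loadings[:, i], snp_loadings[:, j], covariates
            )
            rows.append(
                {
                    "eeg_component": i,
                    "snp_component": j,
                    "r_raw": r_raw,
                    "p_raw": p_raw,
                    "r_partial": r_part,
                    "p_partial": p_part,
                    "significant": p_part < threshold,
                }
            )
    out = pd.DataFrame(rows)
    out.attrs["alpha"] = alpha
    out.attrs["threshold"] = threshold
    out.attrs["n_pairs"] = n_pairs
    out.attrs["n_covariates"] = 0 if covariates is None else covariates.shape[1]
    return out


def group_and_clinical_tests(
    loadings: np.ndarray,
    groups: np.ndarray,
    clinical: pd.DataFrame | None = None,
    component_ids: list | None = None,
    normality_alpha: float = 0.05,
) -> dict:
    """Pairwise group comparisons and clinical-score correlations of LCs.

    For every loading column, each pair of groups is compared with a
    two-sided t-test after a Shapiro–Wilk normality check; when either
    group fails the check the Mann–Whitney rank-sum test is used and
    flagged.  Groups with fewer than 3 subjects are skipped with a
    warning.  Clinical scores are correlated (Pearson) on subjects with
    non-missing values.  Results are uncorrected, matching post-hoc use.
    """
    loadings = np.atleast_2d(np.asarray(loadings, dtype=float))
    if loadings.shape[0] != len(groups):
        loadings = loadings.T
    groups = np.asarray(groups)
    labels = [g for g in pd.unique(groups)]
    if len(labels) < 2:
        raise ValueError("need at least 2 groups")
    ids = component_ids or list(range(loadings.shape[1]))

    group_rows, clinical_rows = [], []
    for c, cid in enumerate(ids):
        col = loadings[:, c]
        for a in range(len(labels)):
            for b in range(a + 1, len(labels)):
                ga, gb = col[groups == labels[a]], col[groups == labels[b]]
                if min(ga.size, gb.size) < 3:
                    warnings.warn(
                        f"group comparison {labels[a]} vs {labels[b]} skipped (<3 subjects)"
                    )
                    continue
                normal = (
                    stats.shapiro(ga)[1] >= normality_alpha
                    and stats.shapiro(gb)[1] >= normality_alpha
                )
                if normal:
                    stat, p = stats.ttest_ind(ga, gb)
                    test = "t"
                else:
                    stat, p = stats.mannwhitneyu(ga, gb, alternative="two-sided")
                    test = "mannwhitney"
                group_rows.append(
                    {
                        "component": cid,
                        "group_a": labels[a],
                        "group_b": labels[b],
                        "test": test,
                        "statistic": float(stat),
                        "p": float(p),
                        "mean_a": float(ga.mean()),
                        "mean_b": float(gb.mean()),
                    }
                )
        if clinical is not None:
            for score in clinical.columns:
                vals = clinical[score].to_numpy(dtype=float)
                ok = np.isfinite(vals)
                if ok.sum() < 3 or np.std(vals[ok]) == 0 or np.std(col[ok]) == 0:
                    continue
                r, p = stats.pearsonr(col[ok], vals[ok])
                clinical_rows.append(
                    {
                        "component": cid,
                        "score": score,
                        "n": int(ok.sum()),
                        "r": float(r),
                        "p": float(p),
                    }
                )
    return {
        "group_tests": pd.DataFrame(group_rows),
        "clinical_correlations": pd.DataFrame(clinical_rows),
    }
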