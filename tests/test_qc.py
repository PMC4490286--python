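"""SNP and sample QC: coding, filters, pruning, stratification, prefilter."""

import numpy as np
import pandas as pd
import pytest

from paraica.datasets import GenotypeTable
from paraica.qc import (
    code_additive,
    genomic_inflation,
    ld_prune,
    logistic_scan,
    relatedness_matrix,
    residualize_components,
    sample_qc,
    snp_filters,
    stratification_adjust,
    univariate_prefilter,
)
from paraica.synth import CohortConfig, generate_cohort


def _table(dosages, groups=None, chrom=None, pos=None, ethnicity=None):
    n, m = dosages.shape
    snps = pd.DataFrame(
        {
            "snp_id": [f"s{j}" for j in range(m)],
            "chrom": chrom if chrom is not None else np.ones(m, dtype=int),
            "pos": pos if pos is not None else 10_000 + 5_000 * np.arange(m),
            "allele_a": "A",
            "allele_b": "B",
        }
    )
    subjects = pd.DataFrame(
        {
            "subject_id": [f"S{i}" for i in range(n)],
            "group": groups if groups is not None else ["control"] * n,
            "age": 30.0,
            "sex": "F",
            "site": "one",
            "ethnicity": ethnicity if ethnicity is not None else ["x"] * n,
        }
    )
    return GenotypeTable(np.asarray(dosages, dtype=float), snps, subjects)


class TestAdditiveCoding:
    @pytest.mark.parametrize(
        "call,expected", [("BB", 2.0), ("AA", 0.0), ("AB", 1.0), ("BA", 1.0)]
    )
    def test_minor_allele_count(self, call, expected):
        assert code_additive(call, "A", "B") == expected

    def test_missing_call(self):
        assert np.isnan(code_additive("00", "A", "B"))

    def test_foreign_allele_rejected(self):
        with pytest.raises(ValueError, match="allele"):
            code_additive("AC", "A", "B")


class TestSampleQc:
    def test_high_missingness_removed(self):
        rng = np.random.default_rng(0)
        d = rng.binomial(2, 0.3, size=(40, 200)).astype(float)
        d[0, : int(200 * 0.05)] = np.nan  # subject 0: 5% missing
        table = _table(d)
        out, report = sample_qc(table, seed=1)
        assert "S0" not in set(out.subjects["subject_id"])
        assert report.steps[0]["name"] == "subject_missing_rate"
        assert report.steps[0]["removed"] >= 1

    def test_duplicate_subject_pair_resolved(self):
        rng = np.random.default_rng(1)
        d = rng.binomial(2, rng.uniform(0.1, 0.5, 300), size=(30, 300)).astype(float)
        d[1] = d[0]  # duplicated genotypes -> relatedness ~ 1
        rel = relatedness_matrix(d)
        assert rel[0, 1] > 0.8
        out, report = sample_qc(_table(d), seed=1)
        ids = set(out.subjects["subject_id"])
        assert ("S0" in ids) != ("S1" in ids)  # exactly one of the pair kept

    def test_clean_cohort_essentially_no_removals(self):
        """Unrelated HWE subjects: only the ~0.3%/subject false-positive
        rate of the 3-s.d. heterozygosity gate is tolerated."""
        rng = np.random.default_rng(7)
        d = rng.binomial(2, rng.uniform(0.2, 0.5, 400), size=(50, 400)).astype(float)
        out, report = sample_qc(_table(d), seed=2)
        assert out.n_subjects >= 49
        by_name = {s["name"]: s for s in report.steps}
        assert by_name["subject_missing_rate"]["removed"] == 0
        assert by_name["subject_relatedness"]["removed"] == 0

    def test_monotone_remaining_counts(self):
        rng = np.random.default_rng(3)
        d = rng.binomial(2, 0.3, size=(25, 150)).astype(float)
        _, report = sample_qc(_table(d), seed=0)
        remaining = [s["remaining"] for s in report.steps]
        assert remaining == sorted(remaining, reverse=True)


class TestSnpFilters:
    def test_constructed_panel_hand_enumeration(self):
        """Six SNPs, one failing each gate, one passing all -> 2 retained."""
        rng = np.random.default_rng(5)
        n = 200
        groups = ["control"] * 100 + ["case1"] * 100
        cols = {}
        cols["pass1"] = rng.binomial(2, 0.3, n)
        cols["low_maf"] = rng.binomial(2, 0.02, n)
        cols["low_call"] = rng.binomial(2, 0.3, n).astype(float)
        cols["hwe_fail"] = np.ones(n)  # all heterozygous: extreme HWE violation
        cols["diffmiss"] = rng.binomial(2, 0.3, n).astype(float)
        cols["pass2"] = rng.binomial(2, 0.4, n)
        d = np.column_stack([np.asarray(c, dtype=float) for c in cols.values()])
        d[: int(n * 0.05), list(cols).index("low_call")] = np.nan
        d[100:140, list(cols).index("diffmiss")] = np.nan  # cases only
        table = _table(d, groups=groups)
        out, report = snp_filters(table)
        kept = list(out.snps["snp_id"])
        names = list(cols)
        assert kept == [f"s{names.index('pass1')}", f"s{names.index('pass2')}"]

    def test_retained_snp_passes_all_gates(self):
        rng = np.random.default_rng(6)
        d = rng.binomial(2, 0.25, size=(120, 1)).astype(float)
        out, _ = snp_filters(_table(d, groups=["control"] * 60 + ["case1"] * 60))
        assert out.n_snps == 1

    def test_hwe_computed_in_controls_only(self):
        """A SNP violating HWE only in cases survives the control-based gate."""
        rng = np.random.default_rng(8)
        ctrl = rng.binomial(2, 0.3, size=(100, 1)).astype(float)
        cases = np.ones((100, 1))  # all het in cases
        d = np.vstack([ctrl, cases])
        table = _table(d, groups=["control"] * 100 + ["case1"] * 100)
        out, _ = snp_filters(table, diffmiss_alpha=1e-300)
        assert out.n_snps == 1

    def test_no_controls_rejected(self):
        d = np.ones((10, 2))
        with pytest.raises(ValueError, match="control"):
            snp_filters(_table(d, groups=["case1"] * 10))

    def test_non_autosomes_dropped(self):
        rng = np.random.default_rng(9)
        d = rng.binomial(2, 0.3, size=(80, 3)).astype(float)
        table = _table(d, chrom=np.array([1, 23, 22]))
        out, _ = snp_filters(table)
        assert set(out.snps["chrom"]) <= set(range(1, 23))


def brute_force_prune(dosages, pos, chrom, maf, r2_max, window_bp):
    """Reference pruning: explicit scan checking every retained pair."""
    m = dosages.shape[1]
    col_mean = np.nanmean(dosages, axis=0)
    x = np.where(np.isfinite(dosages), dosages, col_mean)
    x = (x - x.mean(0)) / np.where(x.std(0) == 0, 1, x.std(0))
    order = sorted(range(m), key=lambda j: (str(chrom[j]), pos[j], -maf[j]))
    kept = []
    for j in order:
        ok = True
        for k in kept:
            if str(chrom[k]) == str(chrom[j]) and abs(pos[j] - pos[k]) <= window_bp:
                r = float(x[:, j] @ x[:, k]) / x.shape[0]
                if r * r > r2_max:
                    ok = False
                    break
        if ok:
            kept.append(j)
    return sorted(kept)


class TestLdPrune:
    def test_exact_duplicate_dropped(self):
        rng = np.random.default_rng(0)
        a = rng.binomial(2, 0.4, 100).astype(float)
        d = np.column_stack([a, a, rng.binomial(2, 0.4, 100)])
        table = _table(d, pos=np.array([1000, 1100, 50_000]))
        out, report = ld_prune(table)
        assert list(out.snps["snp_id"]) == ["s0", "s2"]
        assert report.steps[0]["removed"] == 1

    def test_independent_snps_all_retained(self):
        rng = np.random.default_rng(1)
        d = rng.binomial(2, 0.3, size=(200, 10)).astype(float)
        out, _ = ld_prune(_table(d, pos=1000 * np.arange(10) + 1000))
        assert out.n_snps == 10

    def test_constructed_block_matches_bruteforce(self):
        rng = np.random.default_rng(2)
        n = 300
        base = rng.binomial(2, 0.4, n).astype(float)
        cols = [base]
        for noise in (0.02, 0.4, 0.05, 0.6):  # mixed-LD 5-SNP block
            c = base.copy()
            flip = rng.random(n) < noise
            c[flip] = rng.binomial(2, 0.4, int(flip.sum()))
            cols.append(c)
        d = np.column_stack(cols)
        pos = np.array([1000, 2000, 3000, 4000, 5000])
        table = _table(d, pos=pos)
        out, _ = ld_prune(table)
        expected = brute_force_prune(
            d, pos, np.ones(5), table.maf(), 0.8, 10_000
        )
        assert sorted(int(s[1:]) for s in out.snps["snp_id"]) == expected

    def test_window_limits_comparisons(self):
        """Identical SNPs farther apart than the window are both kept."""
        rng = np.random.default_rng(3)
        a = rng.binomial(2, 0.4, 100).astype(float)
        d = np.column_stack([a, a])
        out, _ = ld_prune(_table(d, pos=np.array([1000, 20_000])))
        assert out.n_snps == 2


class TestStratification:
    def test_structured_cohort_flagged_and_corrected(self):
        cfg = CohortConfig(
            n_per_group=(40, 40, 40), n_snps=800, k_geno=2, k_eeg=2,
            coupled_pairs=(), group_shift=(0, 0, 0), snp_effect_size=0.0,
            fst=0.1, missing_rate=0.0, seed=4,
        )
        table, _, truth = generate_cohort(cfg)
        adjusted, report = stratification_adjust(table)
        flagged = report.stratification["adjusted_components"]
        assert len(flagged) >= 1
        assert all(p > 0.05 for p in report.stratification["post_adjustment_anova_p"])

    def test_pca_separates_subpopulations(self):
        cfg = CohortConfig(
            n_per_group=(50, 50, 50), n_snps=1000, k_geno=2, k_eeg=2,
            coupled_pairs=(), group_shift=(0, 0, 0), snp_effect_size=0.0,
            fst=0.1, missing_rate=0.0, seed=5,
        )
        table, _, truth = generate_cohort(cfg)
        from paraica.qc import impute_standardize

        x = impute_standardize(table.dosages)
        u, s, _ = np.linalg.svd(x, full_matrices=False)
        pc1 = u[:, 0]
        lab = truth.subpop_labels.astype(float)
        r = np.corrcoef(pc1, lab)[0, 1]
        assert abs(r) > 0.5

    def test_unstructured_cohort_few_flags(self):
        cfg = CohortConfig(
            n_per_group=(40, 40, 40), n_snps=600, k_geno=2, k_eeg=2,
            coupled_pairs=(), group_shift=(0, 0, 0), snp_effect_size=0.0,
            fst=0.0, missing_rate=0.0, seed=6,
        )
        table, _, _ = generate_cohort(cfg)
        _, report = stratification_adjust(table)
        # null expectation: alpha * n_components_scan = 0.5 flags
        assert len(report.stratification["adjusted_components"]) <= 3

    def test_residualization_idempotent(self):
        rng = np.random.default_rng(7)
        x = rng.standard_normal((50, 30))
        scores = rng.standard_normal((50, 3))
        once = residualize_components(x, scores)
        twice = residualize_components(once, scores)
        assert np.allclose(once, twice, atol=1e-10)

    def test_single_ethnicity_noted(self):
        rng = np.random.default_rng(8)
        d = rng.binomial(2, 0.3, size=(30, 100)).astype(float)
        _, report = stratification_adjust(_table(d))
        assert report.stratification["adjusted_components"] == []
        assert any("single ethnicity" in n for n in report.notes)


class TestPrefilter:
    def test_logistic_scan_matches_statsmodels(self):
        import statsmodels.api as sm

        rng = np.random.default_rng(0)
        n = 150
        d = rng.binomial(2, 0.3, size=(n, 5)).astype(float)
        y = rng.binomial(1, 1 / (1 + np.exp(-(d[:, 0] - 0.6))))
        res = logistic_scan(d, y)
        for j in range(5):
            fit = sm.Logit(y, sm.add_constant(d[:, j])).fit(disp=0)
            assert res["beta"][j] == pytest.approx(fit.params[1], abs=1e-6)
            assert res["p"][j] == pytest.approx(fit.pvalues[1], rel=1e-4)

    def test_constant_dosage_p_is_one(self):
        y = np.array([0, 1] * 25)
        d = np.full((50, 1), 2.0)
        res = logistic_scan(d, y)
        assert res["p"][0] == 1.0

    def test_union_semantics(self, null_cohort):
        cfg, table, feats, truth = null_cohort
        selected, stats_table, diag = univariate_prefilter(table, alpha=0.025)
        per_contrast = {
            c: set(g.loc[g["p"] < 0.025, "snp_id"])
            for c, g in stats_table.groupby("contrast")
        }
        union = set().union(*per_contrast.values())
        assert set(selected) == union
        assert len(per_contrast) == 2

    def test_lambda_gc_null_near_one(self, null_cohort):
        cfg, table, feats, truth = null_cohort
        _, stats_table, diag = univariate_prefilter(table, alpha=0.025)
        for c, d in diag["contrasts"].items():
            assert 0.9 < d["lambda_gc"] < 1.1

    def test_genomic_inflation_uniform_p(self):
        rng = np.random.default_rng(1)
        p = rng.uniform(size=20_000)
        assert genomic_inflation(p) == pytest.approx(1.0, abs=0.05)
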