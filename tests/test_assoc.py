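"""Association statistics: partial correlation, correction, group tests."""

import numpy as np
import pandas as pd
import pytest
from scipy import stats

from paraica.assoc import (
    bonferroni_threshold,
    build_covariate_design,
    group_and_clinical_tests,
    partial_association_matrix,
    partial_correlation,
)


class TestPartialCorrelation:
    def test_matches_residual_regression_oracle(self):
        """Two-step OLS oracle: residualize on covariates, correlate."""
        import statsmodels.api as sm

        rng = np.random.default_rng(0)
        n = 80
        cov = rng.standard_normal((n, 3))
        u = rng.standard_normal(n)
        v = rng.standard_normal(n)
        r, p = partial_correlation(u, v, cov)
        design = sm.add_constant(cov)
        ru = sm.OLS(u, design).fit().resid
        rv = sm.OLS(v, design).fit().resid
        r_oracle = np.corrcoef(ru, rv)[0, 1]
        assert abs(r - r_oracle) < 1e-12

    def test_matches_pingouin(self):
        pg = pytest.importorskip("pingouin")
        rng = np.random.default_rng(1)
        n = 60
        df = pd.DataFrame(
            {
                "u": rng.standard_normal(n),
                "v": rng.standard_normal(n),
                "c1": rng.standard_normal(n),
                "c2": rng.standard_normal(n),
            }
        )
        df["u"] += 0.5 * df["c1"]
        df["v"] += 0.5 * df["c1"]
        r, p = partial_correlation(
            df["u"].to_numpy(), df["v"].to_numpy(), df[["c1", "c2"]].to_numpy()
        )
        ref = pg.partial_corr(df, x="u", y="v", covar=["c1", "c2"])
        assert r == pytest.approx(float(ref["r"].iloc[0]), abs=1e-10)
        assert p == pytest.approx(float(ref["p_val"].iloc[0]), rel=1e-6)

    def test_empty_covariates_equal_plain_pearson(self):
        rng = np.random.default_rng(2)
        u, v = rng.standard_normal(50), rng.standard_normal(50)
        r, p = partial_correlation(u, v)
        r_ref, p_ref = stats.pearsonr(u, v)
        assert r == pytest.approx(r_ref, abs=1e-14)
        assert p == pytest.approx(p_ref, rel=1e-10)

    def test_zero_variance_covariate_no_effect(self):
        rng = np.random.default_rng(3)
        u, v = rng.standard_normal(40), rng.standard_normal(40)
        r_plain, _ = partial_correlation(u, v)
        r_cov, _ = partial_correlation(u, v, np.ones((40, 1)))
        assert r_cov == pytest.approx(r_plain, abs=1e-12)

    def test_confounder_removed(self):
        rng = np.random.default_rng(4)
        n = 10_000
        c = rng.standard_normal(n)
        u = c + 0.5 * rng.standard_normal(n)
        v = c + 0.5 * rng.standard_normal(n)
        r_raw, _ = partial_correlation(u, v)
        r_part, _ = partial_correlation(u, v, c[:, None])
        assert r_raw > 0.5
        assert abs(r_part) < 0.05


class TestBonferroni:
    def test_five_by_nine_pairs(self):
        thr, n_pairs = bonferroni_threshold(0.05, 5, 9)
        assert n_pairs == 45
        assert thr == pytest.approx(0.05 / 45)

    def test_single_pair_unchanged(self):
        assert bonferroni_threshold(0.05, 1, 1)[0] == 0.05

    def test_arbitrary_counts(self):
        assert bonferroni_threshold(0.01, 3, 4)[0] == pytest.approx(8.333e-4, rel=1e-3)

    def test_invalid_alpha(self):
        with pytest.raises(ValueError):
            bonferroni_threshold(0.0, 2, 2)


class TestAssociationMatrix:
    def test_row_count_and_symmetry(self):
        rng = np.random.default_rng(5)
        eeg = rng.standard_normal((60, 3))
        snp = rng.standard_normal((60, 4))
        a = partial_association_matrix(eeg, snp)
        assert len(a) == 12
        b = partial_association_matrix(snp, eeg)
        m_a = a.pivot(index="eeg_component", columns="snp_component", values="r_raw")
        m_b = b.pivot(index="eeg_component", columns="snp_component", values="r_raw")
        assert np.array_equal(m_a.to_numpy(), m_b.to_numpy().T)

    def test_significance_flag_arithmetic(self):
        rng = np.random.default_rng(6)
        eeg = rng.standard_normal((80, 2))
        snp = np.column_stack([eeg[:, 0] + 0.1 * rng.standard_normal(80),
                               rng.standard_normal(80)])
        a = partial_association_matrix(eeg, snp, alpha=0.05)
        thr = a.attrs["threshold"]
        assert (a["significant"] == (a["p_partial"] < thr)).all()
        assert a.loc[(a.eeg_component == 0) & (a.snp_component == 0),
                     "significant"].item()

    def test_aliased_covariates_dropped_with_warning(self):
        subjects = pd.DataFrame(
            {"age": [30.0] * 10, "sex": ["F"] * 10, "ethnicity": ["x"] * 10,
             "site": ["a"] * 5 + ["b"] * 5}
        )
        subjects["age"] = np.arange(10, dtype=float)
        dup = subjects.copy()
        dup["site"] = dup["site"]
        design = build_covariate_design(subjects)
        # duplicating age as a fake numeric covariate forces aliasing
        with pytest.warns(UserWarning, match="aliased"):
            aliased = build_covariate_design(
                subjects, numeric=("age", "age"), categorical=("site",)
            )
        assert aliased.shape[1] == design.shape[1]


class TestGroupClinical:
    def test_designed_shift_detected(self):
        rng = np.random.default_rng(7)
        lc = np.concatenate([rng.standard_normal(50), 1.0 + rng.standard_normal(50)])
        groups = np.array(["control"] * 50 + ["case1"] * 50)
        rep = group_and_clinical_tests(lc[:, None], groups)
        assert rep["group_tests"]["p"].iloc[0] < 0.01

    def test_null_rejection_rate_calibrated(self):
        """Identical group distributions: ~alpha of replicates reject."""
        rng = np.random.default_rng(8)
        rejections = 0
        n_rep = 400
        for _ in range(n_rep):
            lc = rng.standard_normal(60)
            groups = np.array(["control"] * 30 + ["case1"] * 30)
            rep = group_and_clinical_tests(lc[:, None], groups)
            rejections += int(rep["group_tests"]["p"].iloc[0] < 0.05)
        rate = rejections / n_rep
        assert rate == pytest.approx(0.05, abs=3 * np.sqrt(0.05 * 0.95 / n_rep))

    def test_nonnormal_falls_back_to_ranksum(self):
        rng = np.random.default_rng(9)
        lc = np.concatenate([np.exp(3 * rng.standard_normal(40)),
                             np.exp(3 * rng.standard_normal(40))])
        groups = np.array(["control"] * 40 + ["case1"] * 40)
        rep = group_and_clinical_tests(lc[:, None], groups)
        assert rep["group_tests"]["test"].iloc[0] == "mannwhitney"

    def test_perfect_clinical_correlation(self):
        rng = np.random.default_rng(10)
        lc = rng.standard_normal(50)
        clinical = pd.DataFrame({"score": lc})
        groups = np.array(["control"] * 25 + ["case1"] * 25)
        rep = group_and_clinical_tests(lc[:, None], groups, clinical)
        row = rep["clinical_correlations"].iloc[0]
        assert row["r"] == pytest.approx(1.0)
        assert row["p"] < 1e-20

    def test_tiny_group_skipped_with_warning(self):
        lc = np.arange(12, dtype=float)
        groups = np.array(["control"] * 10 + ["case1"] * 2)
        with pytest.warns(UserWarning, match="skipped"):
            rep = group_and_clinical_tests(lc[:, None], groups)
        assert rep["group_tests"].empty
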