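"""Component matching and leave-one-out reliability."""

import numpy as np
import pytest

from paraica.infomax import IcaDecomposition
from paraica.parallel import para_ica
from paraica.qc import impute_standardize
from paraica.reliability import loo_reliability, match_components
from paraica.synth import CohortConfig, generate_cohort


def _decomp_from_sources(sources, loadings=None):
    sources = np.asarray(sources, dtype=float)
    k, p = sources.shape
    n = 5 if loadings is None else loadings.shape[0]
    return IcaDecomposition(
        loadings=loadings if loadings is not None else np.zeros((n, k)),
        sources=sources,
        z_maps=sources,
        unmixing=np.eye(k),
        whitening=np.zeros((k, n)),
        dewhitening=np.zeros((n, k)),
        k=k,
        converged=True,
        n_iter=1,
    )


class TestMatchComponents:
    def test_permutation_and_sign_identity(self):
        rng = np.random.default_rng(0)
        src = rng.standard_normal((4, 200))
        perm = [2, 0, 3, 1]
        flip = np.array([1, -1, -1, 1])[:, None]
        cand = src[perm] * flip
        m = match_components(_decomp_from_sources(src), _decomp_from_sources(cand))
        assert np.allclose(m.correlation, 1.0)
        assert list(m.candidate[np.argsort(m.reference)]) == [1, 3, 0, 2]

    def test_noise_candidate_matches_permutation_null(self):
        """Independent noise: matched |corr| sits at the null maximum level,
        estimated by a label-permutation oracle."""
        rng = np.random.default_rng(1)
        p = 300
        ref = rng.standard_normal((3, p))
        cand = rng.standard_normal((3, p))
        m = match_components(_decomp_from_sources(ref), _decomp_from_sources(cand))
        null_max = []
        for _ in range(200):
            perm = rng.permutation(p)
            c = np.abs(np.corrcoef(ref[0], cand[0, perm])[0, 1])
            null_max.append(c)
        # matched |corr| of k=3 Hungarian vs null scale ~ sqrt(1/p); generous band
        assert m.correlation.mean() < 10 * np.mean(null_max)
        assert m.correlation.mean() < 0.5

    def test_hungarian_beats_greedy_on_trap(self):
        """Constructed correlation matrix where row-wise greedy is trapped."""
        rng = np.random.default_rng(2)
        p = 400
        basis = np.linalg.qr(rng.standard_normal((p, 3)))[0].T
        basis -= basis.mean(axis=1, keepdims=True)
        basis /= np.linalg.norm(basis, axis=1, keepdims=True)
        ref = basis[:2]
        # candidate columns engineered: corr(ref_i, cand_j) ~ M[i, j]
        m_target = np.array([[0.6, 0.55], [0.5, 0.1]])
        cand = []
        for j in range(2):
            vec = m_target[0, j] * ref[0] + m_target[1, j] * ref[1]
            resid = basis[2] * np.sqrt(max(0, 1 - (m_target[:, j] ** 2).sum()))
            cand.append(vec + resid)
        cand = np.array(cand)
        m = match_components(_decomp_from_sources(ref), _decomp_from_sources(cand))
        hungarian_total = m.correlation.sum()
        greedy_total = 0.6 + 0.1  # greedy takes (0,0) first, stuck with (1,1)
        assert hungarian_total > greedy_total + 0.2

    def test_rectangular_reports_unmatched(self):
        rng = np.random.default_rng(3)
        ref = rng.standard_normal((4, 100))
        cand = ref[:2] + 0.01 * rng.standard_normal((2, 100))
        m = match_components(_decomp_from_sources(ref), _decomp_from_sources(cand))
        assert len(m.unmatched_reference) == 2
        assert m.unmatched_candidate == []

    def test_loadings_matching_drops_left_out_row(self):
        rng = np.random.default_rng(4)
        load_ref = rng.standard_normal((20, 3))
        load_cand = np.delete(load_ref, 7, axis=0)
        m = match_components(
            _decomp_from_sources(np.zeros((3, 10)), load_ref),
            _decomp_from_sources(np.zeros((3, 10)), load_cand),
            on="loadings",
            drop_reference_rows=np.array([7]),
        )
        assert np.allclose(m.correlation, 1.0)


class TestLooReliability:
    @pytest.fixture(scope="class")
    def coupled(self):
        cfg = CohortConfig(
            n_per_group=(6, 7, 7), n_snps=200, n_channels=8, n_freq_components=8,
            k_geno=2, k_eeg=2, coupled_pairs=((0, 0, 0.6),), group_shift=(0, 0, 0),
            snp_effect_size=2.5, noise_sd=0.15, missing_rate=0.0, seed=21,
        )
        table, feats, _ = generate_cohort(cfg)
        x = impute_standardize(table.dosages)
        res = para_ica(x, feats.weights, 2, 2, seed=3, max_iter=384)
        return x, feats.weights, res

    def test_run_count_equals_subject_count(self, coupled):
        x, w, res = coupled
        pair = res.max_pair()[:2]
        rep = loo_reliability(x, w, res, [pair], seed=3, max_iter=384)
        assert rep.n_runs == x.shape[0]
        assert len(rep.per_run) == x.shape[0]

    def test_strong_structure_high_reliability(self, coupled):
        x, w, res = coupled
        pair = res.max_pair()[:2]
        rep = loo_reliability(x, w, res, [pair], seed=3, max_iter=384)
        vals = rep.pair_reliability[pair]
        assert vals["eeg"] > 0.9
        assert vals["snp"] > 0.9

    def test_invariant_to_component_relabeling(self, coupled):
        """Permuting/sign-flipping the original's components leaves the
        matched correlations unchanged (matching is assignment-based)."""
        x, w, res = coupled
        pair = res.max_pair()[:2]
        rep = loo_reliability(x, w, res, [pair], seed=3, max_iter=384)

        flipped = IcaDecomposition(
            loadings=res.snp.loadings[:, ::-1] * -1,
            sources=res.snp.sources[::-1] * -1,
            z_maps=res.snp.z_maps[::-1] * -1,
            unmixing=res.snp.unmixing,
            whitening=res.snp.whitening,
            dewhitening=res.snp.dewhitening,
            k=res.snp.k, converged=True, n_iter=res.snp.n_iter,
        )
        from paraica.parallel import ParaIcaResult

        relabeled = ParaIcaResult(
            snp=flipped, eeg=res.eeg, cross_corr=res.cross_corr[:, ::-1],
            trace=res.trace, converged=res.converged, n_iter=res.n_iter,
        )
        new_pair = (pair[0], res.snp.k - 1 - pair[1])
        rep2 = loo_reliability(x, w, relabeled, [new_pair], seed=3, max_iter=384)
        a = rep.pair_reliability[pair]
        b = rep2.pair_reliability[new_pair]
        assert a["snp"] == pytest.approx(b["snp"], abs=1e-10)
        assert a["eeg"] == pytest.approx(b["eeg"], abs=1e-10)

    def test_reliability_decreases_with_noise(self):
        """Mean reliability is not worse at low noise than at high noise."""
        means = {}
        for noise in (2.0, 6.0):
            vals = []
            for seed in range(3):
                cfg = CohortConfig(
                    n_per_group=(8, 8, 8), n_snps=150, n_channels=8,
                    n_freq_components=8, k_geno=2, k_eeg=2,
                    coupled_pairs=((0, 0, 0.6),), group_shift=(0, 0, 0),
                    snp_effect_size=2.5, noise_sd=noise, missing_rate=0.0,
                    seed=50 + seed,
                )
                table, feats, _ = generate_cohort(cfg)
                x = impute_standardize(table.dosages)
                res = para_ica(x, feats.weights, 2, 2, seed=4, max_iter=256)
                pair = res.max_pair()[:2]
                rep = loo_reliability(x, feats.weights, res, [pair], seed=4,
                                      max_iter=256)
                v = rep.pair_reliability[pair]
                vals.append((v["eeg"] + v["snp"]) / 2)
            means[noise] = np.mean(vals)
        assert means[2.0] >= means[6.0] - 0.02
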