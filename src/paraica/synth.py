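"""Synthetic three-group cohorts with coupled SNP and EEG-spectral structure.

The generator emulates a case/case/control imaging-genetics design:
subjects carry latent component loadings in two modalities; designated
pairs of loadings are drawn from a bivariate normal with a designed
cross-modal correlation, and case groups receive a standardized mean
shift.  Genotypes are sampled under Hardy–Weinberg equilibrium within
(optionally Balding–Nichols-structured) subpopulations, with the latent
genetic signal entering through a logistic shift of the per-allele
success probability so dosages stay legal {0,1,2}.  EEG spatio-spectral
features are a noisy linear mixture of sparse super-Gaussian maps.

Default cohort sizes (56 controls, 105 + 145 cases) and default matrix
shapes (306 × 2000 dosages, 306 × 512 spectral weights from a
64-channel montage) mirror a realistic multisite psychosis cohort at
desk scale.
"""

from __future__ import annotations

import json
from dataclasses import asdict, dataclass, field

import numpy as np
import pandas as pd
from scipy.special import expit, logit

from .datasets import GROUPS, GenotypeTable, SpectralFeatureMatrix

__all__ = [
    "CohortConfig",
    "TruthBundle",
    "generate_cohort",
    "simulate_genotypes",
    "simulate_coupled_loadings",
]

# demographic defaults for (control, case1, case2): multisite psychosis cohort
_AGE_MEAN = (37.07, 31.20, 34.29)
_AGE_SD = (11.28, 11.08, 12.05)
_MALE_FRAC = (22 / 56, 79 / 105, 60 / 145)
_SITES = ("Baltimore", "Boston", "Chicago", "Dallas", "Detroit", "Hartford")
_SITE_COUNTS = {
    "control": (11, 3, 1, 0, 11, 30),
    "case1": (36, 5, 8, 1, 13, 42),
    "case2": (41, 3, 31, 5, 10, 55),
}
_ETHNICITIES = ("Caucasian", "African-American", "Hispanic", "Asian", "Mixed")
_ETH_COUNTS = {
    "control": (30, 18, 2, 3, 3),
    "case1": (57, 30, 10, 1, 7),
    "case2": (95, 27, 17, 1, 5),
}
# clinical score (mean, sd) for (case1, case2); controls get nan
_CLINICAL = {
    "panss_positive": ((15.09, 5.28), (14.04, 5.56)),
    "panss_negative": ((16.21, 5.73), (12.84, 4.68)),
    "panss_general": ((30.43, 8.73), (29.41, 8.51)),
    "schizo_bipolar_scale": ((7.52, 1.34), (2.09, 1.73)),
    "cpz_equivalent": ((542.01, 410.71), (383.31, 339.3)),
}


@dataclass
class CohortConfig:
    """Design of a synthetic coupled cohort.

    ``coupled_pairs`` lists ``(geno_component, eeg_component, r)`` with
    the designed Pearson correlation between the two subject-loading
    columns.  ``group_shift`` is the standardized mean shift added to
    every latent loading for (control, case1, case2) subjects.
    ``fst`` > 0 splits the cohort into two Balding–Nichols
    subpopulations tied to self-reported ethnicity.
    """

    n_per_group: tuple[int, int, int] = (56, 105, 145)
    n_snps: int = 2000
    n_channels: int = 64
    n_freq_components: int = 8
    k_geno: int = 9
    k_eeg: int = 5
    coupled_pairs: tuple[tuple[int, int, float], ...] = ((0, 3, -0.34), (2, 1, 0.31))
    group_shift: tuple[float, float, float] = (0.0, 0.5, 0.5)
    maf_range: tuple[float, float] = (0.05, 0.5)
    fst: float = 0.0
    subpop_fractions: tuple[float, float] = (0.5, 0.5)
    snp_effect_size: float = 1.0
    snp_support_frac: float = 0.05
    noise_sd: float = 0.5
    missing_rate: float = 0.01
    confound_strength: float = 0.0  # age leakage into latent loadings
    n_duplicate_subjects: int = 0  # relatedness-QC probes (near-copies)
    n_duplicate_snps: int = 0  # adjacent high-LD copies for prune tests
    seed: int = 0

    @property
    def n_features(self) -> int:
        return self.n_channels * self.n_freq_components

    @property
    def n_subjects(self) -> int:
        return int(sum(self.n_per_group))

    def validate(self) -> None:
        for name in ("n_snps", "n_channels", "n_freq_components", "k_geno", "k_eeg"):
            if getattr(self, name) <= 0:
                raise ValueError(f"{name} must be positive, got {getattr(self, name)}")
        if any(n < 0 for n in self.n_per_group) or sum(self.n_per_group) < 2:
            raise ValueError(f"n_per_group invalid: {self.n_per_group}")
        for g, e, r in self.coupled_pairs:
            if not (0 <= g < self.k_geno and 0 <= e < self.k_eeg):
                raise ValueError(f"coupled pair ({g},{e}) out of component range")
            if abs(r) > 1:
                raise ValueError(f"designed r={r} outside [-1, 1]")
        lo, hi = self.maf_range
        if not (0 < lo <= hi <= 0.5):
            raise ValueError(f"maf_range must lie in (0, 0.5], got {self.maf_range}")
        if self.fst < 0:
            raise ValueError(f"fst must be >= 0, got {self.fst}")
        if not 0 <= self.missing_rate < 1:
            raise ValueError(f"missing_rate must be in [0,1), got {self.missing_rate}")
        if self.noise_sd < 0:
            raise ValueError(f"noise_sd must be >= 0, got {self.noise_sd}")

    def to_json(self) -> str:
        return json.dumps(asdict(self), indent=2)

    @classmethod
    def from_json(cls, text: str) -> "CohortConfig":
        raw = json.loads(text)
        for key in ("n_per_group", "group_shift", "maf_range", "subpop_fractions"):
            if key in raw:
                raw[key] = tuple(raw[key])
        if "coupled_pairs" in raw:
            raw["coupled_pairs"] = tuple(tuple(p) for p in raw["coupled_pairs"])
        return cls(**raw)


@dataclass
class TruthBundle:
    """Ground truth of a generated cohort, for recovery tests."""

    geno_loadings: np.ndarray  # (n, k_geno)
    eeg_loadings: np.ndarray  # (n, k_eeg)
    geno_maps: np.ndarray  # (k_geno, n_snps)
    eeg_maps: np.ndarray  # (k_eeg, n_features)
    designed_r: tuple[tuple[int, int, float], ...]
    group_labels: np.ndarray
    subpop_labels: np.ndarray
    config: CohortConfig = field(repr=False, default=None)


def simulate_coupled_loadings(
    config: CohortConfig, rng: np.random.Generator | None = None
) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """Latent subject loadings for both modalities plus group labels.

    Coupled pairs are drawn from a bivariate normal at the designed r;
    every column is standardized before the per-group mean shifts are
    added, so ``group_shift`` is in s.d. units.
    """
    config.validate()
    rng = rng if rng is not None else np.random.default_rng(config.seed)
    n = config.n_subjects
    groups = np.repeat(np.arange(3), config.n_per_group)

    geno = rng.standard_normal((n, config.k_geno))
    eeg = rng.standard_normal((n, config.k_eeg))
    for g, e, r in config.coupled_pairs:
        shared = geno[:, g]
        eeg[:, e] = r * shared + np.sqrt(max(0.0, 1.0 - r * r)) * rng.standard_normal(n)

    def _standardize(m: np.ndarray) -> np.ndarray:
        sd = m.std(axis=0, ddof=0)
        sd[sd == 0] = 1.0
        return (m - m.mean(axis=0)) / sd

    geno, eeg = _standardize(geno), _standardize(eeg)
    shift = np.asarray(config.group_shift)[groups]
    geno = geno + shift[:, None]
    eeg = eeg + shift[:, None]
    group_labels = np.asarray(GROUPS)[groups]
    return geno, eeg, group_labels


def simulate_genotypes(
    maf: np.ndarray,
    subjects: int,
    fst: float = 0.0,
    subpop_fractions: tuple[float, ...] = (0.5, 0.5),
    truth_effects: np.ndarray | None = None,
    rng: np.random.Generator | None = None,
    return_subpops: bool = False,
):
    """HWE genotype dosages with optional population structure and effects.

    Each SNP's ancestral minor-allele frequency ``maf`` is perturbed per
    subpopulation with a Balding–Nichols Beta draw when ``fst > 0``.
    ``truth_effects`` (subjects × snps, logit scale) shifts the binomial
    allele probability, so component-member dosages track the latent
    genetic loadings while remaining valid genotype counts.
    """
    maf = np.asarray(maf, dtype=float)
    if ((maf <= 0) | (maf > 0.5)).any():
        raise ValueError("all MAF values must lie in (0, 0.5]")
    if fst < 0:
        raise ValueError("fst must be >= 0")
    rng = rng if rng is not None else np.random.default_rng()
    m = maf.size

    if fst > 0:
        fractions = np.asarray(subpop_fractions, dtype=float)
        fractions = fractions / fractions.sum()
        subpops = rng.choice(fractions.size, size=subjects, p=fractions)
        a = maf * (1.0 - fst) / fst
        b = (1.0 - maf) * (1.0 - fst) / fst
        # per-subpopulation allele frequencies
        pop_freq = np.stack(
            [np.clip(rng.beta(a, b), 1e-4, 1 - 1e-4) for _ in range(fractions.size)]
        )
        p = pop_freq[subpops]  # (subjects, snps)
    else:
        subpops = np.zeros(subjects, dtype=int)
        p = np.broadcast_to(maf, (subjects, m)).copy()

    if truth_effects is not None:
        p = expit(logit(p) + np.asarray(truth_effects))

    dosage = rng.binomial(2, p).astype(float)
    if return_subpops:
        return dosage, subpops
    return dosage


def _sparse_maps(k: int, p: int, support_frac: float, rng) -> np.ndarray:
    """Sparse super-Gaussian source maps with disjoint-leaning support."""
    maps = np.zeros((k, p))
    support = max(int(round(support_frac * p)), 2)
    for i in range(k):
        idx = rng.choice(p, size=support, replace=False)
        maps[i, idx] = rng.laplace(size=support)
    return maps


def _categorical(counts: tuple, labels: tuple, size: int, rng) -> np.ndarray:
    probs = np.asarray(counts, dtype=float)
    probs = probs / probs.sum()
    return rng.choice(labels, size=size, p=probs)


def generate_cohort(
    config: CohortConfig,
) -> tuple[GenotypeTable, SpectralFeatureMatrix, TruthBundle]:
    """Generate one cohort: dosages, spectral weights and the ground truth.

    Identical config (including seed) yields bit-identical outputs.
    """
    config.validate()
    rng = np.random.default_rng(config.seed)
    n = config.n_subjects

    geno_load, eeg_load, group_labels = simulate_coupled_loadings(config, rng)

    # subject metadata
    groups_idx = np.repeat(np.arange(3), config.n_per_group)
    age = np.empty(n)
    sex = np.empty(n, dtype=object)
    site = np.empty(n, dtype=object)
    eth = np.empty(n, dtype=object)
    clinical = {name: np.full(n, np.nan) for name in _CLINICAL}
    for gi, gname in enumerate(GROUPS):
        mask = groups_idx == gi
        size = int(mask.sum())
        age[mask] = rng.normal(_AGE_MEAN[gi], _AGE_SD[gi], size=size)
        sex[mask] = np.where(rng.random(size) < _MALE_FRAC[gi], "M", "F")
        site[mask] = _categorical(_SITE_COUNTS[gname], _SITES, size, rng)
        eth[mask] = _categorical(_ETH_COUNTS[gname], _ETHNICITIES, size, rng)
        if gname != "control":
            ci = gi - 1
            for name, params in _CLINICAL.items():
                mu, sd = params[ci]
                clinical[name][mask] = rng.normal(mu, sd, size=size)

    if config.confound_strength > 0:
        # optional confounding: age leaks into every latent loading
        age_z = (age - age.mean()) / age.std()
        geno_load = geno_load + config.confound_strength * age_z[:, None]
        eeg_load = eeg_load + config.confound_strength * age_z[:, None]

    # genotype side
    maf = rng.uniform(*config.maf_range, size=config.n_snps)
    geno_maps = _sparse_maps(config.k_geno, config.n_snps, config.snp_support_frac, rng)
    effects = config.snp_effect_size * (geno_load @ geno_maps)
    dosage, subpops = simulate_genotypes(
        maf,
        n,
        fst=config.fst,
        subpop_fractions=config.subpop_fractions,
        truth_effects=effects,
        rng=rng,
        return_subpops=True,
    )
    if config.fst > 0:
        # tie self-reported ethnicity to ancestry so stratification is testable
        eth = np.asarray([f"pop{s}" for s in subpops], dtype=object)

    # high-LD probes: SNPs 1, 3, 5, ... become near-copies of their left
    # neighbour (2% of entries redrawn, so r-squared is high but < 1)
    dup_snps = min(config.n_duplicate_snps, (config.n_snps - 1) // 2 + 1)
    for j in range(dup_snps):
        tgt, src = 2 * j + 1, 2 * j
        col = dosage[:, src].copy()
        redraw = rng.random(n) < 0.02
        col[redraw] = rng.binomial(2, maf[tgt], size=int(redraw.sum())).astype(float)
        dosage[:, tgt] = col

    # relatedness probes: tail subjects become copies of head subjects
    dup_subj = min(config.n_duplicate_subjects, n // 2)
    for i in range(dup_subj):
        dosage[n - 1 - i] = dosage[i]

    if config.missing_rate > 0:
        miss = rng.random(dosage.shape) < config.missing_rate
        dosage[miss] = np.nan

    # SNP metadata: 22 autosomes in contiguous blocks, 5 kb spacing, so
    # index-adjacent SNPs (including the LD probes) share a 10 kb window
    chrom = 1 + (np.arange(config.n_snps) * 22) // config.n_snps
    pos = np.empty(config.n_snps, dtype=int)
    for c in range(1, 23):
        mask = chrom == c
        pos[mask] = 10_000 + np.arange(mask.sum()) * 5_000
    snps = pd.DataFrame(
        {
            "snp_id": [f"snp{j:06d}" for j in range(config.n_snps)],
            "chrom": chrom,
            "pos": pos,
            "allele_a": "A",
            "allele_b": "B",
        }
    )

    subjects = pd.DataFrame(
        {
            "subject_id": [f"S{i:04d}" for i in range(n)],
            "group": group_labels,
            "age": np.round(age, 1),
            "sex": sex,
            "site": site,
            "ethnicity": eth,
            **clinical,
        }
    )
    table = GenotypeTable(dosage, snps, subjects)

    # EEG side: noisy mixture of sparse super-Gaussian spatio-spectral maps
    eeg_maps = _sparse_maps(config.k_eeg, config.n_features, 0.15, rng)
    weights = eeg_load @ eeg_maps + config.noise_sd * rng.standard_normal(
        (n, config.n_features)
    )
    features = SpectralFeatureMatrix(
        weights=weights,
        channel_names=[f"ch{c:02d}" for c in range(config.n_channels)],
        n_freq_components=config.n_freq_components,
        provenance="synthetic",
    )

    truth = TruthBundle(
        geno_loadings=geno_load,
        eeg_loadings=eeg_load,
        geno_maps=geno_maps,
        eeg_maps=eeg_maps,
        designed_r=config.coupled_pairs,
        group_labels=group_labels,
        subpop_labels=subpops,
        config=config,
    )
    return table, features, truth
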