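"""Shared fixtures and simulation helpers."""

from __future__ import annotations

import numpy as np
import pytest

from paraica.synth import CohortConfig, generate_cohort


def make_mixture(
    n: int, p: int, k: int, noise: float = 0.0, seed: int = 0, sparse: bool = False
):
    """Super-Gaussian linear mixture with known mixing (for recovery tests)."""
    rng = np.random.default_rng(seed)
    mixing = rng.standard_normal((n, k))
    if sparse:
        sources = np.zeros((k, p))
        support = max(p // 20, 2)
        for i in range(k):
            idx = rng.choice(p, size=support, replace=False)
            sources[i, idx] = rng.laplace(size=support) * 5.0
    else:
        sources = rng.laplace(size=(k, p))
    x = mixing @ sources
    if noise > 0:
        x = x + noise * rng.standard_normal((n, p))
    return x, mixing, sources


@pytest.fixture(scope="session")
def small_cohort():
    """60-subject coupled cohort used by several integration tests."""
    cfg = CohortConfig(
        n_per_group=(12, 24, 24),
        n_snps=400,
        n_channels=16,
        n_freq_components=8,
        k_geno=3,
        k_eeg=3,
        coupled_pairs=((0, 0, 0.6),),
        group_shift=(0.0, 0.5, 0.5),
        snp_effect_size=2.0,
        noise_sd=0.3,
        seed=20,
    )
    return cfg, *generate_cohort(cfg)


@pytest.fixture(scope="session")
def null_cohort():
    """Cohort with no genetic effects, coupling or group shifts."""
    cfg = CohortConfig(
        n_per_group=(40, 60, 60),
        n_snps=1000,
        n_channels=16,
        n_freq_components=8,
        k_geno=3,
        k_eeg=3,
        coupled_pairs=(),
        group_shift=(0.0, 0.0, 0.0),
        snp_effect_size=0.0,
        noise_sd=1.0,
        missing_rate=0.0,
        seed=33,
    )
    return cfg, *generate_cohort(cfg)
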