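"""Exact test of Hardy–Weinberg equilibrium.

The test conditions on the observed allele counts and asks whether the
observed heterozygote count is unusual under random mating (the
Levene–Haldane conditional distribution).  The two-sided P-value is the
sum of probabilities of all heterozygote counts whose conditional
probability does not exceed that of the observed count — the standard
"exact" SNP-HWE convention used by GWAS QC tools.
"""

from __future__ import annotations

import numpy as np

__all__ = ["hwe_exact_test"]


def hwe_exact_test(n_aa: int, n_ab: int, n_bb: int) -> float:
    """Two-sided exact HWE P-value from genotype counts.

    Parameters
    ----------
    n_aa, n_ab, n_bb
        Counts of major-homozygote, heterozygote and minor-homozygote
        genotypes.  Which homozygote is "minor" does not matter; the
        test is symmetric in the two alleles.

    Returns
    -------
    float
        P-value in (0, 1].  Monomorphic sites return 1.0.
    """
    n_aa, n_ab, n_bb = int(n_aa), int(n_ab), int(n_bb)
    if min(n_aa, n_ab, n_bb) < 0:
        raise ValueError("genotype counts must be non-negative")
    n = n_aa + n_ab + n_bb
    if n < 1:
        raise ValueError("at least one genotyped individual required")

    # rare-allele count; conditional distribution is over heterozygote
    # counts with the same parity as n_rare
    n_rare = min(2 * n_aa + n_ab, 2 * n_bb + n_ab)
    if n_rare == 0:
        return 1.0

    # probabilities up to a constant via the Wigginton recurrence:
    # P(h+2)/P(h) = (n_rare - h)(n_common - h) / ((h+2)(h+1)) where the
    # homozygote counts adjust accordingly; work from the mode outward.
    het_values = np.arange(n_rare % 2, n_rare + 1, 2)
    probs = np.empty(het_values.size, dtype=float)

    # unnormalized log-probabilities by recurrence from the smallest het
    n_common = 2 * n - n_rare
    probs[0] = 0.0  # log scale, relative
    for i in range(1, het_values.size):
        h = het_values[i - 1]
        # moving h -> h+2 converts one rare-homozygote and one
        # common-homozygote into two heterozygotes
        rare_hom = (n_rare - h) // 2
        common_hom = (n_common - h) // 2
        ratio = (4.0 * rare_hom * common_hom) / ((h + 2.0) * (h + 1.0))
        probs[i] = probs[i - 1] + np.log(ratio)

    probs -= probs.max()
    p = np.exp(probs)
    p /= p.sum()

    p_obs = p[het_values == n_ab]
    if p_obs.size == 0:
        raise ValueError(
            f"heterozygote count {n_ab} has wrong parity for {n_rare} rare alleles"
        )
    # 1e-12 relative slack guards against ties lost to rounding
    return float(min(1.0, p[p <= p_obs[0] * (1.0 + 1e-12)].sum()))
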