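"""Leave-one-out reliability of the coupled decomposition.

Each subject is dropped in turn, the parallel decomposition is rerun on
the remaining subjects with the original configuration and seeds, and
every rerun's components are matched to the original run (one-to-one
Hungarian assignment on |correlation|).  The reliability index of a
significant component pair is the mean matched |correlation| per
modality across all reruns — close to 1 when the decomposition does not
depend on any single subject.

Matching is computed on source maps by default: their feature space is
unchanged when a subject is removed.  Loading-based matching (dropping
the left-out row of the reference loadings) is available via
``match_on="loadings"`` and recorded in the report.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from joblib import Parallel, delayed
from scipy.optimize import linear_sum_assignment

from .infomax import IcaDecomposition
from .parallel import CouplingConfig, ParaIcaResult, para_ica

__all__ = ["ComponentMatch", "ReliabilityReport", "match_components", "loo_reliability"]


@dataclass
class ComponentMatch:
    """One-to-one assignment of candidate to reference components."""

    reference: np.ndarray  # reference component indices
    candidate: np.ndarray  # matched candidate indices
    correlation: np.ndarray  # |corr| per matched pair
    signs: np.ndarray  # sign to align each matched candidate
    unmatched_reference: list[int] = field(default_factory=list)
    unmatched_candidate: list[int] = field(default_factory=list)

    def corr_of_reference(self, ref_idx: int) -> float:
        pos = np.flatnonzero(self.reference == ref_idx)
        return float(self.correlation[pos[0]]) if pos.size else np.nan


@dataclass
class ReliabilityReport:
    n_runs: int
    matched_on: str
    pair_reliability: dict  # (eeg comp, snp comp) -> {"eeg": mean, "snp": mean}
    per_run: list[dict]
    n_nonconverged: int = 0


def _abs_corr(a: np.ndarray, b: np.ndarray) -> np.ndarray:
    ac = a - a.mean(axis=1, keepdims=True)
    bc = b - b.mean(axis=1, keepdims=True)
    ac /= np.linalg.norm(ac, axis=1, keepdims=True) + 1e-300
    bc /= np.linalg.norm(bc, axis=1, keepdims=True) + 1e-300
    return ac @ bc.T


def match_components(
    reference: IcaDecomposition,
    candidate: IcaDecomposition,
    on: str = "maps",
    drop_reference_rows: np.ndarray | None = None,
) -> ComponentMatch:
    """Best one-to-one component assignment maximizing total |correlation|.

    ``on="maps"`` correlates source feature maps (default);
    ``on="loadings"`` correlates loading columns, optionally dropping
    ``drop_reference_rows`` from the reference to align subject counts
    (the leave-one-out case).  Rectangular problems leave the surplus
    components unmatched and reported.
    """
    if on == "maps":
        ref, cand = reference.sources, candidate.sources
    elif on == "loadings":
        ref = reference.loadings.T
        if drop_reference_rows is not None:
            keep = np.ones(ref.shape[1], dtype=bool)
            keep[drop_reference_rows] = False
            ref = ref[:, keep]
        cand = candidate.loadings.T
    else:
        raise ValueError("on must be 'maps' or 'loadings'")
    if ref.shape[1] != cand.shape[1]:
        raise ValueError("feature spaces differ between reference and candidate")

    corr = _abs_corr(ref, cand)
    ri, ci = linear_sum_assignment(-np.abs(corr))
    signs = np.sign(corr[ri, ci])
    signs[signs == 0] = 1.0
    return ComponentMatch(
        reference=ri,
        candidate=ci,
        correlation=np.abs(corr[ri, ci]),
        signs=signs,
        unmatched_reference=sorted(set(range(ref.shape[0])) - set(ri)),
        unmatched_candidate=sorted(set(range(cand.shape[0])) - set(ci)),
    )


def loo_reliability(
    snp_data: np.ndarray,
    eeg_data: np.ndarray,
    original: ParaIcaResult,
    significant_pairs: list[tuple[int, int]],
    coupling: CouplingConfig | None = None,
    seed: int = 0,
    max_iter: int = 512,
    match_on: str = "maps",
    n_jobs: int = 1,
) -> ReliabilityReport:
    """Leave-one-out stability of each significant (eeg, snp) component pair.

    ``seed``, ``coupling`` and ``max_iter`` must be the values of the
    original run so each rerun differs from it only by the left-out
    subject.  Non-convergent reruns are excluded from the averages and
    counted.  Runs may execute in parallel (``n_jobs``); results are
    ordered by left-out subject index regardless of completion order.
    """
    snp_data = np.asarray(snp_data, dtype=float)
    eeg_data = np.asarray(eeg_data, dtype=float)
    n = snp_data.shape[0]
    if eeg_data.shape[0] != n:
        raise ValueError("subject mismatch between modalities")
    k_snp, k_eeg = original.snp.k, original.eeg.k

    def _one(left_out: int) -> dict:
        keep = np.ones(n, dtype=bool)
        keep[left_out] = False
        rerun = para_ica(
            snp_data[keep],
            eeg_data[keep],
            k_snp,
            k_eeg,
            coupling=coupling,
            seed=seed,
            max_iter=max_iter,
        )
        kwargs = (
            {"drop_reference_rows": np.array([left_out])}
            if match_on == "loadings"
            else {}
        )
        m_snp = match_components(original.snp, rerun.snp, on=match_on, **kwargs)
        m_eeg = match_components(original.eeg, rerun.eeg, on=match_on, **kwargs)
        return {
            "left_out": left_out,
            "converged": rerun.converged,
            "snp_match": {int(r): float(c) for r, c in zip(m_snp.reference, m_snp.correlation)},
            "eeg_match": {int(r): float(c) for r, c in zip(m_eeg.reference, m_eeg.correlation)},
        }

    if n_jobs == 1:
        runs = [_one(i) for i in range(n)]
    else:
        runs = Parallel(n_jobs=n_jobs)(delayed(_one)(i) for i in range(n))
        runs = sorted(runs, key=lambda r: r["left_out"])

    usable = [r for r in runs if r["converged"]]
    pair_rel = {}
    for e, s in significant_pairs:
        pair_rel[(int(e), int(s))] = {
            "eeg": float(np.mean([r["eeg_match"][e] for r in usable])) if usable else np.nan,
            "snp": float(np.mean([r["snp_match"][s] for r in usable])) if usable else np.nan,
        }
    return ReliabilityReport(
        n_runs=n,
        matched_on=match_on,
        pair_reliability=pair_rel,
        per_run=runs,
        n_nonconverged=n - len(usable),
    )
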