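"""Parallel (two-modality) ICA with cross-modal loading coupling.

Two Infomax decompositions — one per modality, sharing the subject
dimension — are trained in alternation.  After each epoch the Pearson
correlations between all pairs of loading columns are computed; for
pairs whose |r| exceeds an entry threshold the whitened mixing columns
of both modalities receive an extra gradient-ascent step on the squared
loading correlation, so genuinely linked components are drawn together
while source independence continues to be optimized on each side.

The coupling weight λ ramps linearly from 0 to ``lambda_max`` over the
first half of training and the coupling step is capped at half the norm
of the side's latest Infomax update, keeping the independence objective
dominant.  With ``lambda_max = 0`` the routine reproduces two
independent :func:`paraica.infomax.infomax_ica` runs bit for bit (same
seeds), which is the tested decoupled limit.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .infomax import IcaDecomposition, InfomaxSide

__all__ = ["CouplingConfig", "ParaIcaResult", "para_ica", "zscore_select"]


@dataclass
class CouplingConfig:
    """Strength and schedule of the cross-modal coupling term."""

    lambda_max: float = 0.5
    entry_threshold: float = 0.3  # |r| needed before a pair is enhanced
    cap_ratio: float = 0.5  # coupling step ≤ cap_ratio × infomax step norm

    def lam(self, epoch: int, max_iter: int) -> float:
        ramp = min(1.0, 2.0 * (epoch + 1) / max_iter)
        return self.lambda_max * ramp


@dataclass
class ParaIcaResult:
    snp: IcaDecomposition
    eeg: IcaDecomposition
    cross_corr: np.ndarray  # (k_eeg, k_snp) loading correlations
    trace: list[dict] = field(default_factory=list)
    converged: bool = False
    n_iter: int = 0

    def max_pair(self) -> tuple[int, int, float]:
        """(eeg component, snp component, r) of the strongest coupling."""
        i, j = np.unravel_index(np.abs(self.cross_corr).argmax(), self.cross_corr.shape)
        return int(i), int(j), float(self.cross_corr[i, j])


def _column_corr(a: np.ndarray, b: np.ndarray) -> np.ndarray:
    """Pearson correlation of every column of ``a`` with every column of ``b``."""
    ac = a - a.mean(axis=0, keepdims=True)
    bc = b - b.mean(axis=0, keepdims=True)
    ac = ac / (np.linalg.norm(ac, axis=0, keepdims=True) + 1e-300)
    bc = bc / (np.linalg.norm(bc, axis=0, keepdims=True) + 1e-300)
    return ac.T @ bc


def _greedy_disjoint_pairs(corr: np.ndarray, threshold: float) -> list[tuple[int, int]]:
    """Strongest pairs above threshold, each component used at most once."""
    pairs = []
    c = np.abs(corr).copy()
    while True:
        i, j = np.unravel_index(c.argmax(), c.shape)
        if c[i, j] <= threshold:
            break
        pairs.append((int(i), int(j)))
        c[i, :] = 0.0
        c[:, j] = 0.0
    return pairs


def _corr_gradients(u: np.ndarray, v: np.ndarray) -> tuple[float, np.ndarray, np.ndarray]:
    """r = corr(u, v) and ∂(r²)/∂u, ∂(r²)/∂v."""
    uc = u - u.mean()
    vc = v - v.mean()
    nu, nv = np.linalg.norm(uc), np.linalg.norm(vc)
    if nu == 0 or nv == 0:
        return 0.0, np.zeros_like(u), np.zeros_like(v)
    r = float(uc @ vc / (nu * nv))
    du = (vc / nv - r * uc / nu) / nu
    dv = (uc / nu - r * vc / nv) / nv
    du -= du.mean()
    dv -= dv.mean()
    return r, 2.0 * r * du, 2.0 * r * dv


def para_ica(
    snp_data: np.ndarray,
    eeg_data: np.ndarray,
    k_snp: int,
    k_eeg: int,
    coupling: CouplingConfig | None = None,
    seed: int = 0,
    max_iter: int = 512,
    tol: float = 1e-6,
    corr_tol: float = 1e-4,
) -> ParaIcaResult:
    """Jointly decompose SNP and EEG matrices sharing a subject dimension.

    Parameters
    ----------
    snp_data, eeg_data
        (subjects × snps) and (subjects × features); identical subject
        order is the caller's contract.
    k_snp, k_eeg
        Component counts per modality (≤ the respective data ranks).
    coupling
        Coupling schedule; ``None`` uses the defaults.  ``lambda_max=0``
        degenerates to two independent Infomax runs.
    seed
        Master seed; each side derives its own child seed, so the SNP
        side of a run is reproducible independently of the EEG side.
    """
    snp_data = np.asarray(snp_data, dtype=float)
    eeg_data = np.asarray(eeg_data, dtype=float)
    if snp_data.shape[0] != eeg_data.shape[0]:
        raise ValueError(
            f"subject mismatch: {snp_data.shape[0]} vs {eeg_data.shape[0]}"
        )
    coupling = coupling if coupling is not None else CouplingConfig()
    seeds = np.random.SeedSequence(seed).generate_state(2)
    snp_side = InfomaxSide(snp_data, k_snp, seed=int(seeds[0]), max_iter=max_iter, tol=tol)
    eeg_side = InfomaxSide(eeg_data, k_eeg, seed=int(seeds[1]), max_iter=max_iter, tol=tol)

    trace: list[dict] = []
    prev_corr = None
    for epoch in range(max_iter):
        snp_side.step()
        eeg_side.step()

        a_snp = snp_side.dewh @ snp_side.mixing_whitened()
        a_eeg = eeg_side.dewh @ eeg_side.mixing_whitened()
        corr = _column_corr(a_eeg, a_snp)  # (k_eeg, k_snp)

        lam = coupling.lam(epoch, max_iter)
        enhanced = []
        if lam > 0.0:
            pairs = _greedy_disjoint_pairs(corr, coupling.entry_threshold)
            if pairs:
                m_eeg = eeg_side.mixing_whitened()
                m_snp = snp_side.mixing_whitened()
                d_eeg = np.zeros_like(m_eeg)
                d_snp = np.zeros_like(m_snp)
                for i, j in pairs:
                    r, g_u, g_v = _corr_gradients(a_eeg[:, i], a_snp[:, j])
                    # pull loading gradients back to whitened mixing columns
                    d_eeg[:, i] += lam * (eeg_side.dewh.T @ g_u)
                    d_snp[:, j] += lam * (snp_side.dewh.T @ g_v)
                    enhanced.append((i, j, r))
                for side, delta in ((eeg_side, d_eeg), (snp_side, d_snp)):
                    step_norm = float(np.linalg.norm(delta))
                    cap = coupling.cap_ratio * max(side.last_update_norm, tol)
                    if np.isfinite(cap) and step_norm > cap > 0:
                        delta = delta * (cap / step_norm)
                    delta_norm2 = float((delta**2).sum())
                    if delta_norm2 > 0:
                        side.set_mixing_whitened(side.mixing_whitened() + delta)
                        # only a non-negligible perturbation re-opens the side
                        if delta_norm2 > tol:
                            side.converged = False
        trace.append(
            {
                "epoch": epoch,
                "lambda": lam,
                "enhanced_pairs": enhanced,
                "max_abs_corr": float(np.abs(corr).max()),
            }
        )

        corr_change = (
            np.inf if prev_corr is None else float(np.abs(corr - prev_corr).max())
        )
        prev_corr = corr
        if snp_side.converged and eeg_side.converged and corr_change < corr_tol:
            break

    snp_dec = snp_side.decomposition()
    eeg_dec = eeg_side.decomposition()
    cross = _column_corr(eeg_dec.loadings, snp_dec.loadings)
    return ParaIcaResult(
        snp=snp_dec,
        eeg=eeg_dec,
        cross_corr=cross,
        trace=trace,
        converged=snp_side.converged and eeg_side.converged,
        n_iter=len(trace),
    )


def zscore_select(
    decomposition: IcaDecomposition,
    z_threshold: float = 2.0,
    feature_ids: list[str] | None = None,
) -> list[pd.DataFrame]:
    """Features dominating each component: |Z| ≥ threshold, ranked by |Z|.

    Each returned table has columns ``feature``, ``z`` and ``relative_weight``
    (|Z| divided by the component's maximum |Z|, so the top feature scores 1).
    """
    out = []
    ids = (
        np.asarray(feature_ids)
        if feature_ids is not None
        else np.arange(decomposition.z_maps.shape[1])
    )
    for z in decomposition.z_maps:
        sel = np.flatnonzero(np.abs(z) >= z_threshold)
        sel = sel[np.argsort(-np.abs(z[sel]))]
        max_abs = np.abs(z).max() if z.size else 1.0
        out.append(
            pd.DataFrame(
                {
                    "feature": ids[sel],
                    "z": z[sel],
                    "relative_weight": np.abs(z[sel]) / (max_abs or 1.0),
                }
            )
        )
    return out
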