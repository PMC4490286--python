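"""Model-order selection: MDL on covariance eigenvalues and
ICASSO-style run-to-run stability.
"""

from __future__ import annotations

import warnings

import numpy as np
from scipy.optimize import linear_sum_assignment

from .infomax import infomax_ica

__all__ = ["estimate_order_mdl", "mdl_criterion", "estimate_order_stability"]


def mdl_criterion(data: np.ndarray) -> np.ndarray:
    """Wax–Kailath minimum-description-length curve over candidate orders.

    The rows of ``data`` (subjects) are the i.i.d. observations; the
    eigenvalue spectrum comes from the subject-space Gram matrix, so at
    most ``min(n_subjects - 1, n_features)`` eigenvalues are available.
    Returns MDL(k) for k = 0 .. m-1 where m is that eigenvalue count.
    """
    x = np.asarray(data, dtype=float)
    n, p = x.shape
    if n < 2 or p < 2:
        raise ValueError("need at least 2 subjects and 2 features")
    xc = x - x.mean(axis=0, keepdims=True)
    # eigenvalues of the feature covariance via the small Gram matrix
    gram = xc @ xc.T / n
    evals = np.linalg.eigvalsh(gram)[::-1]
    m = min(n - 1, p)
    evals = np.clip(evals[:m], 1e-300, None)

    n_obs = n  # finite-sample i.i.d. count
    log_ev = np.log(evals)
    mdl = np.empty(m)
    for k in range(m):
        tail = evals[k:]
        log_geo = log_ev[k:].mean()
        log_arith = np.log(tail.mean())
        mdl[k] = -n_obs * (m - k) * (log_geo - log_arith) + 0.5 * k * (
            2 * m - k + 1
        ) * np.log(n_obs)
    return mdl


def estimate_order_mdl(data: np.ndarray) -> int:
    """Number of signal components minimizing the MDL criterion.

    Constant (zero-variance) data returns 0.
    """
    x = np.asarray(data, dtype=float)
    if np.allclose(x, x.mean(axis=0, keepdims=True)):
        return 0
    return int(np.argmin(mdl_criterion(x)))


def _match_abs_corr(a: np.ndarray, b: np.ndarray) -> float:
    """Mean |corr| of Hungarian-matched rows of two source matrices."""
    ac = a - a.mean(axis=1, keepdims=True)
    bc = b - b.mean(axis=1, keepdims=True)
    ac /= np.linalg.norm(ac, axis=1, keepdims=True) + 1e-300
    bc /= np.linalg.norm(bc, axis=1, keepdims=True) + 1e-300
    corr = np.abs(ac @ bc.T)
    ri, ci = linear_sum_assignment(-corr)
    return float(corr[ri, ci].mean())


def estimate_order_stability(
    data: np.ndarray,
    k_candidates: list[int],
    n_runs: int = 10,
    subsample_frac: float = 0.9,
    seed: int = 0,
    max_iter: int = 256,
) -> tuple[int, dict]:
    """Pick the order whose components replicate best across repeated runs.

    For every candidate ``k`` the data are decomposed ``n_runs`` times
    on random subject subsamples with fresh initializations; components
    are matched between every pair of runs (Hungarian assignment on
    |correlation| of source maps) and the candidate's stability score
    is the mean matched |correlation|.  Returns ``(k_best, detail)``
    where ``detail`` maps each k to its score; ties go to the smaller k
    and a flat/low profile is flagged low-confidence.
    """
    k_candidates = sorted(set(int(k) for k in k_candidates))
    if not k_candidates:
        raise ValueError("k_candidates must be non-empty")
    if n_runs < 2:
        raise ValueError("stability needs at least 2 runs")
    x = np.asarray(data, dtype=float)
    n = x.shape[0]
    n_sub = max(int(round(subsample_frac * n)), max(k_candidates) + 1)
    root = np.random.SeedSequence(seed)
    scores: dict[int, float] = {}
    for k, ss in zip(k_candidates, root.spawn(len(k_candidates))):
        run_seeds = ss.generate_state(n_runs)
        sources = []
        for rs in run_seeds:
            rng = np.random.default_rng(rs)
            rows = rng.choice(n, size=n_sub, replace=False)
            dec = infomax_ica(
                x[rows], k, seed=int(rs % (2**31)), max_iter=max_iter
            )
            sources.append(dec.sources)
        sims = [
            _match_abs_corr(sources[i], sources[j])
            for i in range(n_runs)
            for j in range(i + 1, n_runs)
        ]
        scores[k] = float(np.mean(sims))
        if np.std(sims) == 0 and len(set(map(int, run_seeds))) < n_runs:
            warnings.warn("identical replicate seeds: stability is degenerate")

    best = max(k_candidates, key=lambda k: (scores[k], -k))
    detail = {"scores": scores, "low_confidence": max(scores.values()) < 0.7}
    if detail["low_confidence"]:
        warnings.warn("stability profile flat/low; order estimate is low-confidence")
    return best, detail
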