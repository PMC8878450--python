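"""Evaluation metrics: relative reconstruction error, L0 sparsity counts,
and an exact Mann-Whitney U test."""

from __future__ import annotations

from itertools import combinations

import numpy as np
from scipy import stats

__all__ = ["relative_error", "l0_norm", "mann_whitney_u"]


def relative_error(y: np.ndarray, ye: np.ndarray, sqrt: bool = False) -> float:
    """Relative reconstruction error re = ||y - ye||_2^2 / ||y||_2^2.

    ``sqrt=True`` returns the root of the ratio instead (both
    conventions appear in the literature for the same symbol).
    """
    y = np.asarray(y)
    ye = np.asarray(ye)
    if y.shape != ye.shape:
        raise ValueError("shapes do not match")
    denom = np.linalg.norm(y.ravel()) ** 2
    if denom == 0:
        raise ValueError("reference has zero norm")
    re = float(np.linalg.norm((y - ye).ravel()) ** 2 / denom)
    return float(np.sqrt(re)) if sqrt else re


def l0_norm(coeffs: np.ndarray, tol: float | None = None, relative: bool = True) -> int:
    """Count of coefficients with magnitude above ``tol``.

    By default ``tol`` is 1e-3 of the maximum magnitude (relative mode);
    pass ``relative=False`` for an absolute threshold.
    """
    mag = np.abs(np.asarray(coeffs))
    if tol is None:
        tol = 1e-3
    if tol < 0:
        raise ValueError("tol must be non-negative")
    thresh = tol * mag.max() if relative and mag.size else tol
    return int(np.count_nonzero(mag > thresh))


def _u_statistic(a: np.ndarray, b: np.ndarray) -> float:
    """Mann-Whitney U of sample a (midranks for ties)."""
    pooled = np.concatenate([a, b])
    ranks = stats.rankdata(pooled)
    ra = ranks[: len(a)].sum()
    return float(ra - len(a) * (len(a) + 1) / 2.0)


def mann_whitney_u(
    sample_a, sample_b, exact_max: int = 10
) -> tuple[float, float]:
    """Two-sided Mann-Whitney U test: returns (U of sample_a, p-value).

    For both sample sizes <= ``exact_max`` the p-value is computed by
    full enumeration of all C(na+nb, na) group labelings of the pooled
    values (midranks handle ties exactly); larger samples fall back to
    the tie-corrected normal approximation.
    """
    a = np.asarray(sample_a, dtype=float).ravel()
    b = np.asarray(sample_b, dtype=float).ravel()
    if a.size == 0 or b.size == 0:
        raise ValueError("samples must be nonempty")
    na, nb = a.size, b.size
    u_obs = _u_statistic(a, b)

    if na <= exact_max and nb <= exact_max:
        pooled = np.concatenate([a, b])
        ranks = stats.rankdata(pooled)
        offset = na * (na + 1) / 2.0
        u_lo = min(u_obs, na * nb - u_obs)
        n_total = 0
        n_extreme = 0
        for idx in combinations(range(na + nb), na):
            u = ranks[list(idx)].sum() - offset
            n_total += 1
            if u <= u_lo + 1e-9 or u >= na * nb - u_lo - 1e-9:
                n_extreme += 1
        p = min(1.0, n_extreme / n_total)
        return u_obs, p

    res = stats.mannwhitneyu(a, b, alternative="two-sided", method="asymptotic")
    return u_obs, float(res.pvalue)
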