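"""Kendall rank correlation (tau-b) with the tie-corrected normal approximation.

The environmental variable is constant within countries, so heavy ties in ``y`` are the
norm rather than the exception; tau-b divides the concordance excess by the geometric
mean of the tie-adjusted pair counts, and the p-value uses the normal approximation of
S = C - D with the full tie-corrected variance (Kendall 1970).  The approximation is
adequate for n > 10, which is why the scan filters SNPs with fewer usable populations.
"""

from __future__ import annotations

import numpy as np
from scipy.stats import norm

from .errors import ConstantInputError, DegenerateCovariateError

__all__ = ["kendall_tau_b", "partial_kendall"]


def _tie_moments(values: np.ndarray) -> tuple[float, float, float, float]:
    """(sum t(t-1)/2, sum t(t-1)(2t+5), sum t(t-1), sum t(t-1)(t-2)) over tie groups."""
    _, counts = np.unique(values, return_counts=True)
    t = counts.astype(float)
    tt1 = t * (t - 1.0)
    return 0.5 * tt1.sum(), (tt1 * (2.0 * t + 5.0)).sum(), tt1.sum(), (tt1 * (t - 2.0)).sum()


def _s_statistic(x: np.ndarray, y: np.ndarray) -> float:
    """S = C - D by pairwise sign products (O(n^2), n is small here)."""
    i, j = np.triu_indices(x.size, k=1)
    return float(np.sum(np.sign(x[i] - x[j]) * np.sign(y[i] - y[j])))


def _tau_p_from_stats(
    s: float,
    n: int,
    xm: tuple[float, float, float, float],
    ym: tuple[float, float, float, float],
) -> tuple[float, float]:
    n0 = n * (n - 1) / 2.0
    n1, vt, v1t, v2t = xm
    n2, vu, v1u, v2u = ym
    denom = np.sqrt((n0 - n1) * (n0 - n2))
    tau = s / denom
    v0 = n * (n - 1) * (2.0 * n + 5.0)
    var_s = (v0 - vt - vu) / 18.0
    var_s += (v1t * v1u) / (2.0 * n * (n - 1))
    if n > 2:
        var_s += (v2t * v2u) / (9.0 * n * (n - 1) * (n - 2))
    if var_s <= 0:
        # only possible when nearly everything is tied; treat as no evidence
        return tau, 1.0
    z = s / np.sqrt(var_s)
    p = 2.0 * norm.sf(abs(z))
    return tau, float(min(max(p, np.finfo(float).tiny), 1.0))


def kendall_tau_b(x, y) -> tuple[float, float]:
    """Kendall tau-b between two sequences, with a two-sided tie-corrected normal p.

    Pairs where either value is NaN are dropped first.  Raises
    :class:`ConstantInputError` when fewer than two distinct values remain on either
    side (the correlation is undefined).

    Returns
    -------
    (tau, p) : tuple of float
        tau-b in [-1, 1] and the two-sided p-value in (0, 1].
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.shape != y.shape or x.ndim != 1:
        raise ValueError("x and y must be one-dimensional and of equal length")
    keep = ~(np.isnan(x) | np.isnan(y))
    x, y = x[keep], y[keep]
    n = x.size
    if n < 2 or np.unique(x).size < 2 or np.unique(y).size < 2:
        raise ConstantInputError(
            "Kendall correlation undefined: fewer than two distinct values"
        )
    s = _s_statistic(x, y)
    return _tau_p_from_stats(s, n, _tie_moments(x), _tie_moments(y))


def partial_kendall(x, y, z) -> float:
    """Partial Kendall correlation of x and y given z.

    Closed form from the three pairwise tau-b values:
    tau_xy.z = (tau_xy - tau_xz * tau_yz) / sqrt((1 - tau_xz^2) (1 - tau_yz^2)).
    Raises :class:`DegenerateCovariateError` when |tau_xz| = 1 or |tau_yz| = 1.
    Significance, when needed, is assessed by plugging the partial tau into the same
    normal approximation used for plain tau -- a documented approximation.
    """
    t_xy, _ = kendall_tau_b(x, y)
    t_xz, _ = kendall_tau_b(x, z)
    t_yz, _ = kendall_tau_b(y, z)
    denom_sq = (1.0 - t_xz**2) * (1.0 - t_yz**2)
    if denom_sq <= 0:
        raise DegenerateCovariateError(
            "partial Kendall undefined: covariate perfectly correlated with x or y"
        )
    return float((t_xy - t_xz * t_yz) / np.sqrt(denom_sq))


# ---------------------------------------------------------------------------
# vectorised scan core
# ---------------------------------------------------------------------------


def tau_scan(X: np.ndarray, y: np.ndarray, min_n: int = 10):
    """tau-b and p for every row of ``X`` against the shared vector ``y``.

    Parameters
    ----------
    X : (n_snps, n_obs) array, NaN = missing per cell.
    y : (n_obs,) array, no NaNs expected (missing environments are a panel defect).
    min_n : minimum number of pairwise-complete observations per row.

    Returns
    -------
    tau, p : float arrays (NaN where skipped)
    n_used : int array of observations used per row
    skip : object array of reason codes (None where computed); codes are
        ``too_few_populations`` and ``constant_frequency``.
    """
    X = np.asarray(X, dtype=float)
    y = np.asarray(y, dtype=float)
    n_snps, n_obs = X.shape
    iu, ju = np.triu_indices(n_obs, k=1)
    sy_full = np.sign(y[iu] - y[ju])
    ym_full = _tie_moments(y)

    tau = np.full(n_snps, np.nan)
    p = np.full(n_snps, np.nan)
    n_used = np.zeros(n_snps, dtype=np.int64)
    skip = np.full(n_snps, None, dtype=object)

    nan_mask = np.isnan(X)
    any_nan = nan_mask.any(axis=1)

    for k in range(n_snps):
        row = X[k]
        if any_nan[k]:
            keep = ~nan_mask[k]
            xk, yk = row[keep], y[keep]
        else:
            xk, yk = row, y
        m = xk.size
        n_used[k] = m
        if m < min_n:
            skip[k] = "too_few_populations"
            continue
        if np.unique(xk).size < 2:
            skip[k] = "constant_frequency"
            continue
        if any_nan[k]:
            if np.unique(yk).size < 2:
                skip[k] = "constant_environment"
                continue
            s = _s_statistic(xk, yk)
            tau[k], p[k] = _tau_p_from_stats(s, m, _tie_moments(xk), _tie_moments(yk))
        else:
            sx = np.sign(xk[iu] - xk[ju])
            s = float(np.sum(sx * sy_full))
            if (sx == 0.0).any():
                xm = _tie_moments(xk)
            else:
                xm = (0.0, 0.0, 0.0, 0.0)
            tau[k], p[k] = _tau_p_from_stats(s, m, xm, ym_full)
    return tau, p, n_used, skip
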