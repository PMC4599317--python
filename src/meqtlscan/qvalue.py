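"""Storey q-values with smoother-based pi0 estimation.

The q-value of a test is the minimum false discovery rate at which it would
be called significant. With the null-proportion estimate pi0 fixed at 1 the
procedure reduces exactly to Benjamini-Hochberg adjusted p-values; the
smoother estimate of pi0 makes it less conservative when many tests are
non-null.
"""

from __future__ import annotations

import numpy as np

from .exceptions import DomainError

__all__ = ["estimate_pi0", "storey_qvalues"]

DEFAULT_LAMBDA_GRID = np.round(np.arange(0.05, 0.9001, 0.05), 2)


def estimate_pi0(p_values, lambda_grid=DEFAULT_LAMBDA_GRID) -> float:
    """Estimate the proportion of true nulls by the smoother method.

    pi0(lambda) = #{p > lambda} / (m * (1 - lambda)) is computed over the
    grid, a cubic smoothing spline is fit to the curve, and the smoothed
    value at the largest lambda is taken, clamped to (0, 1].
    """
    p = np.asarray(p_values, dtype=float).ravel()
    _check_p(p)
    m = p.size
    if m < 2:
        return 1.0
    lam = np.asarray(lambda_grid, dtype=float)
    pi0_lam = np.array([(p > l).sum() / (m * (1.0 - l)) for l in lam])
    from scipy.interpolate import UnivariateSpline

    spline = UnivariateSpline(lam, pi0_lam, k=3)
    pi0 = float(spline(lam.max()))
    return float(min(max(pi0, 1.0 / m), 1.0))


def storey_qvalues(p_values, lambda_grid=DEFAULT_LAMBDA_GRID, pi0: float | None = None):
    """q-values for a family of p-values.

    q_(i) = min_{j >= i} pi0 * m * p_(j) / j over the sorted p-values, which
    is monotone nondecreasing in p. ``pi0=None`` estimates pi0 by the
    smoother; ``pi0=1`` reproduces Benjamini-Hochberg exactly.

    Returns (q_values aligned to the input order, pi0 used).
    """
    p = np.asarray(p_values, dtype=float).ravel()
    _check_p(p)
    m = p.size
    if m == 0:
        return np.array([]), 1.0
    if pi0 is None:
        pi0 = estimate_pi0(p, lambda_grid)
    if not (0.0 < pi0 <= 1.0):
        raise DomainError(f"pi0 must be in (0, 1], got {pi0}")
    order = np.argsort(p, kind="mergesort")
    ranked = p[order] * pi0 * m / np.arange(1, m + 1)
    q_sorted = np.minimum.accumulate(ranked[::-1])[::-1]
    q_sorted = np.minimum(q_sorted, 1.0)
    q = np.empty(m)
    q[order] = q_sorted
    return q, float(pi0)


def _check_p(p: np.ndarray) -> None:
    if p.size and (np.any(~np.isfinite(p)) or p.min() < 0 or p.max() > 1):
        raise DomainError("p-values must be finite and in [0, 1]")
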