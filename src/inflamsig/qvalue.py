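"""Storey q-values for permutation p-values.

Implements the Storey-Tibshirani procedure: estimate the null proportion
pi0 from the p-value histogram over a lambda grid with a cubic smoother,
then convert p-values to q-values by the step-down transform

    q_(i) = min_{k >= i}  pi0 * m * p_(k) / k .

With pi0 = 1 this reduces exactly to Benjamini-Hochberg.  For small
feature sets (m < 50) the pi0 estimate is unstable, so pi0 is fixed to 1.
"""

from __future__ import annotations

import numpy as np

__all__ = ["estimate_pi0", "qvalues", "qvalue_select"]


def estimate_pi0(
    pvals: np.ndarray, lambdas: np.ndarray | None = None
) -> float:
    """Smoothed estimator of the proportion of true nulls.

    pi0(lambda) = #{p > lambda} / (m * (1 - lambda)) is computed on a grid
    and a cubic polynomial smoother is evaluated at the largest lambda.
    """
    pvals = np.asarray(pvals, dtype=float)
    m = pvals.size
    if lambdas is None:
        lambdas = np.arange(0.05, 0.95, 0.05)
    pi0_lam = np.array(
        [np.mean(pvals > lam) / (1.0 - lam) for lam in lambdas]
    )
    if np.all(pi0_lam == 0):
        return 1.0 / m  # all p-values tiny
    coeffs = np.polyfit(lambdas, pi0_lam, deg=3)
    pi0 = float(np.polyval(coeffs, lambdas.max()))
    return float(min(max(pi0, 1.0 / m), 1.0))


def qvalues(pvals, pi0: float | None = None) -> np.ndarray:
    """q-values for an array of p-values.

    ``pi0=None`` selects the smoothed Storey estimate when m >= 50 and the
    conservative pi0 = 1 (Benjamini-Hochberg) otherwise.
    """
    p = np.asarray(pvals, dtype=float)
    if p.size == 0:
        raise ValueError("no p-values supplied")
    if np.any((p < 0) | (p > 1) | ~np.isfinite(p)):
        raise ValueError("p-values must lie in [0, 1]")
    if pi0 is None:
        pi0 = estimate_pi0(p) if p.size >= 50 else 1.0
    m = p.size
    order = np.argsort(p, kind="stable")
    ranked = p[order]
    raw = pi0 * m * ranked / np.arange(1, m + 1)
    q_sorted = np.minimum.accumulate(raw[::-1])[::-1]
    q = np.empty(m)
    q[order] = np.minimum(q_sorted, 1.0)
    return q


def qvalue_select(pvals, fdr_threshold: float = 0.2, pi0: float | None = None):
    """q-values plus the boolean significance call at the FDR threshold."""
    q = qvalues(pvals, pi0=pi0)
    return q, q < fdr_threshold
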