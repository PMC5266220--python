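"""Storey q-values for false-discovery-rate control across trait scans."""

from __future__ import annotations

import numpy as np

__all__ = ["qvalues", "estimate_pi0"]


def estimate_pi0(p: np.ndarray, lambdas: np.ndarray | None = None) -> float:
    """Estimate the proportion of true nulls pi0 by the lambda-grid smoother.

    pi0(lam) = #{p > lam} / (m (1 - lam)) is computed on a grid and a cubic
    polynomial smoother is evaluated at the largest lambda. Falls back to 1
    (Benjamini-Hochberg behaviour) when the grid is degenerate.
    """
    p = np.asarray(p, dtype=float)
    m = p.size
    if lambdas is None:
        lambdas = np.arange(0.05, 0.96, 0.05)
    lambdas = np.asarray(lambdas, dtype=float)
    if m < 2 * lambdas.size or np.min(p) >= np.max(lambdas):
        return 1.0
    pi0_lam = np.array([np.mean(p > lam) / (1.0 - lam) for lam in lambdas])
    coef = np.polyfit(lambdas, pi0_lam, deg=3)
    pi0 = float(np.polyval(coef, np.max(lambdas)))
    return float(np.clip(pi0, 1.0 / m, 1.0))


def qvalues(p: np.ndarray, pi0: float | None = None) -> np.ndarray:
    """Storey q-values: q_i = min_{p_j >= p_i} pi0 * m * p_j / rank(p_j).

    With ``pi0=1`` this reduces exactly to Benjamini-Hochberg adjusted
    p-values. q-values are monotone non-decreasing in p and clipped to [0,1].
    """
    p = np.asarray(p, dtype=float)
    if p.size == 0:
        raise ValueError("empty p-value vector")
    if np.any((p < 0) | (p > 1)) or np.any(~np.isfinite(p)):
        raise ValueError("p-values must lie in [0, 1]")
    m = p.size
    if pi0 is None:
        pi0 = estimate_pi0(p)
    order = np.argsort(p, kind="stable")
    ranked = p[order]
    q = pi0 * m * ranked / np.arange(1, m + 1)
    q = np.minimum.accumulate(q[::-1])[::-1]  # enforce monotonicity from the top
    q = np.clip(q, 0.0, 1.0)
    out = np.empty(m)
    out[order] = q
    return out
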