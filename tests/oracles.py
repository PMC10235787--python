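"""Independent oracles used to cross-check the estimators.

Everything here deliberately avoids the code paths in ``mrmed`` — closed
forms, statsmodels regressions and naive scans — so each comparison is a
genuine dual-route check.
"""

from __future__ import annotations

import numpy as np
import statsmodels.api as sm
from scipy.stats import fisher_exact


def ivw_oracle(bx: np.ndarray, by: np.ndarray, sy: np.ndarray) -> tuple[float, float]:
    """IVW as intercept-free WLS of by on bx, weights 1/sy^2.

    Returns (theta, multiplicative-random-effects SE).  statsmodels reports
    bse = sqrt(scale * (X'WX)^-1) with scale = RSS_w/(J-1); the fixed-effect
    SE strips the scale and the multiplicative RE SE is the larger of the
    two.
    """
    fit = sm.WLS(by, bx[:, None], weights=sy**-2).fit()
    bse = float(fit.bse[0])
    fixed = bse / np.sqrt(fit.scale)
    return float(fit.params[0]), max(fixed, bse)


def egger_oracle(
    bx: np.ndarray, by: np.ndarray, sy: np.ndarray
) -> tuple[float, float, float, float]:
    """MR-Egger WLS with intercept after orienting bx >= 0.

    Returns (intercept, intercept SE, slope, slope SE) with SEs inflated by
    max(1, sqrt(RSS_w/(J-2))).
    """
    flip = np.where(bx < 0, -1.0, 1.0)
    bx, by = bx * flip, by * flip
    fit = sm.WLS(by, sm.add_constant(bx), weights=sy**-2).fit()
    fixed = fit.bse / np.sqrt(fit.scale)  # scale = RSS_w/(J-2)
    se = np.maximum(fixed, fit.bse)
    return float(fit.params[0]), float(se[0]), float(fit.params[1]), float(se[1])


def mvmr_oracle(
    x: np.ndarray, y: np.ndarray, sy: np.ndarray
) -> tuple[np.ndarray, np.ndarray]:
    """Multivariable WLS through the origin via explicit normal equations.

    Returns (coefficients, SEs inflated by max(1, sqrt(RSS_w/(J-k)))).
    """
    w = sy**-2
    xtwx = x.T @ np.diag(w) @ x
    coef = np.linalg.inv(xtwx) @ x.T @ np.diag(w) @ y
    resid = y - x @ coef
    rss = float(resid @ np.diag(w) @ resid)
    j, k = x.shape
    phi = max(1.0, np.sqrt(rss / (j - k)))
    ses = phi * np.sqrt(np.diag(np.linalg.inv(xtwx)))
    return coef, ses


def weighted_median_oracle(theta: np.ndarray, w: np.ndarray) -> float:
    """Explicit scan of the cumulative-weight function.

    Sorts the ratios, walks the cumulative weights until the midpoint-shifted
    cumulative probability brackets 0.5, and interpolates linearly between
    the bracketing ratio values.
    """
    order = np.argsort(theta, kind="stable")
    t = [float(theta[i]) for i in order]
    ww = [float(w[i]) for i in order]
    total = sum(ww)
    p = []
    running = 0.0
    for wi in ww:
        p.append((running + wi / 2.0) / total)
        running += wi
    if 0.5 <= p[0]:
        return t[0]
    for i in range(len(p) - 1):
        if p[i] <= 0.5 <= p[i + 1]:
            frac = (0.5 - p[i]) / (p[i + 1] - p[i])
            return t[i] + frac * (t[i + 1] - t[i])
    return t[-1]


def clump_oracle(
    pvals: dict[str, float], r2: dict[frozenset, float], threshold: float
) -> list[str]:
    """Naive set-based greedy clump: repeatedly take the best remaining
    variant (ties by variant_id) and purge everything in LD with it."""
    remaining = set(pvals)
    kept = []
    while remaining:
        best = min(remaining, key=lambda v: (pvals[v], v))
        kept.append(best)
        remaining = {
            v
            for v in remaining
            if v != best and r2.get(frozenset((best, v)), 0.0) < threshold
        }
    return kept


def fisher_oracle(k: int, K: int, n: int, N: int) -> float:
    """One-sided Fisher exact p for the over-representation 2x2 table."""
    table = [[k, n - k], [K - k, N - K - (n - k)]]
    return float(fisher_exact(table, alternative="greater")[1])
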