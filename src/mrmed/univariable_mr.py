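"""Univariable two-sample MR estimators.

All estimators consume a two-column :class:`~mrmed.summary_data.HarmonisedSet`
(exposure first, outcome last) and return :class:`MREstimate` records on the
outcome's link scale.  The main analysis is multiplicative random-effects IVW;
weighted median, MR-Egger and MR-PRESSO serve as sensitivity estimators.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
from scipy import stats as sps

from mrmed.exceptions import MethodUnavailableError
from mrmed.summary_data import HarmonisedSet

logger = logging.getLogger(__name__)

Z95 = 1.959963984540054  # two-sided 95% normal quantile

#: significance thresholds used for result labelling
BONFERRONI_P = 0.005
SUGGESTIVE_P = 0.05


@dataclass
class MREstimate:
    """A single estimator's causal-effect estimate.

    ``theta`` is on the outcome's link scale (log-odds for binary outcomes)
    per unit of exposure; ``or_scale()`` exponentiates for binary outcomes.
    Heterogeneity fields (``q``, ``q_df``, ``q_pval``) are populated where the
    estimator defines them.
    """

    method: str
    theta: float
    se: float
    pval: float
    n_snps: int
    q: float | None = None
    q_df: int | None = None
    q_pval: float | None = None
    ci_low: float = field(init=False)
    ci_high: float = field(init=False)

    def __post_init__(self) -> None:
        self.ci_low = self.theta - Z95 * self.se
        self.ci_high = self.theta + Z95 * self.se

    def or_scale(self) -> tuple[float, float, float]:
        """(OR, CI low, CI high) by exponentiating the estimate."""
        return (np.exp(self.theta), np.exp(self.ci_low), np.exp(self.ci_high))

    @property
    def significance(self) -> str:
        if self.pval < BONFERRONI_P:
            return "significant"
        if self.pval < SUGGESTIVE_P:
            return "suggestive"
        return "ns"


@dataclass
class PressoResult:
    """MR-PRESSO global test, per-variant outlier flags and corrected IVW."""

    global_rss_p: float
    outlier_flags: np.ndarray
    outlier_pvals: np.ndarray
    raw: MREstimate
    corrected: MREstimate
    distortion_p: float | None


def _check_two_cols(h: HarmonisedSet) -> tuple[np.ndarray, np.ndarray, np.ndarray, np.ndarray]:
    if h.beta.shape[1] != 2:
        raise ValueError(
            f"expected exactly one exposure and one outcome column, got {h.beta.shape[1]} traits"
        )
    return h.beta[:, 0], h.se[:, 0], h.beta[:, 1], h.se[:, 1]


def ratio_estimates(h: HarmonisedSet) -> tuple[np.ndarray, np.ndarray]:
    """Per-variant Wald ratios theta_j = bY_j/bX_j with first-order SEs.

    Variants with a zero exposure beta are dropped with a warning.
    """
    bx, _, by, sy = _check_two_cols(h)
    nonzero = bx != 0
    if not nonzero.all():
        logger.warning(
            "ratio_estimates: dropped %d variants with zero exposure beta",
            int((~nonzero).sum()),
        )
    bx, by, sy = bx[nonzero], by[nonzero], sy[nonzero]
    return by / bx, sy / np.abs(bx)


def _ivw_core(theta_j: np.ndarray, se_j: np.ndarray, model: str) -> MREstimate:
    w = se_j**-2
    theta = float(np.sum(w * theta_j) / np.sum(w))
    se_fixed = float(np.sum(w) ** -0.5)
    j = len(theta_j)
    q = float(np.sum(w * (theta_j - theta) ** 2))
    q_df = j - 1
    q_pval = float(sps.chi2.sf(q, q_df)) if q_df > 0 else float("nan")
    if model == "random":
        se = se_fixed * max(1.0, np.sqrt(q / q_df)) if q_df > 0 else se_fixed
    elif model == "fixed":
        se = se_fixed
    else:
        raise ValueError(f"unknown IVW model {model!r}")
    pval = float(2.0 * sps.norm.sf(abs(theta) / se))
    return MREstimate(
        method="ivw", theta=theta, se=se, pval=pval, n_snps=j,
        q=q, q_df=q_df, q_pval=q_pval,
    )


def ivw(h: HarmonisedSet, model: str = "random") -> MREstimate:
    """Inverse-variance-weighted estimate (multiplicative random effects).

    Equivalent to weighted least squares of outcome betas on exposure betas
    through the origin with weights 1/seY^2.  With ``model="random"`` the
    fixed-effect SE is inflated by ``max(1, sqrt(Q/(J-1)))``.  A single
    variant degrades to its Wald ratio (method tag ``wald_ratio``).
    """
    theta_j, se_j = ratio_estimates(h)
    if len(theta_j) == 0:
        raise MethodUnavailableError("ivw: no usable variants")
    if len(theta_j) == 1:
        logger.warning("ivw: single variant — returning its Wald ratio")
        theta, se = float(theta_j[0]), float(se_j[0])
        return MREstimate(
            method="wald_ratio", theta=theta, se=se,
            pval=float(2.0 * sps.norm.sf(abs(theta) / se)), n_snps=1,
        )
    return _ivw_core(theta_j, se_j, model)


def _weighted_median_point(theta_j: np.ndarray, w: np.ndarray) -> float:
    order = np.argsort(theta_j, kind="stable")
    t = theta_j[order]
    ww = w[order]
    p = (np.cumsum(ww) - 0.5 * ww) / np.sum(ww)
    return float(np.interp(0.5, p, t))


def weighted_median(
    h: HarmonisedSet, n_boot: int = 1000, seed: int | None = None
) -> MREstimate:
    """Weighted-median estimator with parametric-bootstrap SE.

    Per-variant ratios are ordered and the inverse-variance-weighted median
    is interpolated at cumulative weight 0.5.  The SE resamples exposure and
    outcome betas from their normal sampling distributions ``n_boot`` times.
    Requires at least three variants.
    """
    if h.n_variants < 3:
        raise MethodUnavailableError("weighted_median requires >= 3 variants")
    bx, sx, by, sy = _check_two_cols(h)
    theta_j = by / bx
    w = (sy / np.abs(bx)) ** -2
    theta = _weighted_median_point(theta_j, w)

    rng = np.random.default_rng(seed)
    j = len(bx)
    bx_b = rng.normal(bx, sx, size=(n_boot, j))
    by_b = rng.normal(by, sy, size=(n_boot, j))
    boots = np.empty(n_boot)
    for b in range(n_boot):
        tb = by_b[b] / bx_b[b]
        wb = (sy / np.abs(bx_b[b])) ** -2
        boots[b] = _weighted_median_point(tb, wb)
    se = float(np.std(boots, ddof=1))
    pval = float(2.0 * sps.norm.sf(abs(theta) / se)) if se > 0 else float(theta == 0.0)
    return MREstimate(
        method="weighted_median", theta=theta, se=se, pval=pval, n_snps=j
    )


def mr_egger(h: HarmonisedSet) -> tuple[MREstimate, MREstimate]:
    """MR-Egger regression: returns (slope estimate, intercept estimate).

    Each variant is oriented so its exposure beta is non-negative, then
    outcome betas are regressed on exposure betas by weighted least squares
    (weights 1/seY^2) with a free intercept.  SEs are inflated by
    ``max(1, sqrt(RSS_w/(J-2)))``; the intercept p-value is the directional
    pleiotropy test.
    """
    if h.n_variants < 3:
        raise MethodUnavailableError("mr_egger requires >= 3 variants")
    bx, _, by, sy = _check_two_cols(h)
    flip = np.sign(bx)
    flip[flip == 0] = 1.0
    bx, by = bx * flip, by * flip
    w = sy**-2

    x = np.column_stack([np.ones_like(bx), bx])
    xtw = x.T * w
    coef = np.linalg.solve(xtw @ x, xtw @ by)
    resid = by - x @ coef
    j = len(bx)
    rss_w = float(np.sum(w * resid**2))
    phi = max(1.0, np.sqrt(rss_w / (j - 2)))
    cov = np.linalg.inv(xtw @ x)
    se_a, se_t = phi * np.sqrt(np.diag(cov))
    alpha, theta = coef

    def _p(est: float, se: float) -> float:
        return float(2.0 * sps.t.sf(abs(est) / se, j - 2))

    q_pval = float(sps.chi2.sf(rss_w, j - 2))
    slope = MREstimate(
        method="egger_slope", theta=float(theta), se=float(se_t),
        pval=_p(theta, se_t), n_snps=j, q=rss_w, q_df=j - 2, q_pval=q_pval,
    )
    intercept = MREstimate(
        method="egger_intercept", theta=float(alpha), se=float(se_a),
        pval=_p(alpha, se_a), n_snps=j,
    )
    return slope, intercept


def _origin_slope(bx: np.ndarray, by: np.ndarray, w: np.ndarray) -> float:
    return float(np.sum(w * bx * by) / np.sum(w * bx**2))


def mr_presso(
    h: HarmonisedSet,
    n_sim: int = 1000,
    outlier_p: float = 0.05,
    seed: int | None = None,
) -> PressoResult:
    """MR-PRESSO: global pleiotropy test, outlier removal, corrected IVW.

    The observed leave-one-out residual sum of squares is compared with its
    distribution under ``n_sim`` datasets simulated from the fitted
    no-pleiotropy model; per-variant outliers are flagged when their
    simulation p falls below the Bonferroni-corrected ``outlier_p``; the
    corrected estimate is random-effects IVW on the unflagged variants; the
    distortion p compares the raw-vs-corrected shift against removals of
    random non-outlier subsets of the same size.
    """
    if h.n_variants < 4:
        raise MethodUnavailableError("mr_presso requires >= 4 variants")
    bx, sx, by, sy = _check_two_cols(h)
    j = len(bx)
    w = sy**-2
    rng = np.random.default_rng(seed)

    # leave-one-out slopes: theta_{-i} through the origin
    sxy = np.sum(w * bx * by)
    sxx = np.sum(w * bx**2)
    loo_slopes = (sxy - w * bx * by) / (sxx - w * bx**2)
    obs_res2 = w * (by - loo_slopes * bx) ** 2
    obs_rss = float(np.sum(obs_res2))

    # simulate under the no-pleiotropy model with expected betas bX, theta*bX
    bx_sim = rng.normal(bx, sx, size=(n_sim, j))
    by_sim = rng.normal(loo_slopes * bx, sy, size=(n_sim, j))
    w_row = w[None, :]
    sxy_s = np.sum(w_row * bx_sim * by_sim, axis=1, keepdims=True)
    sxx_s = np.sum(w_row * bx_sim**2, axis=1, keepdims=True)
    loo_s = (sxy_s - w_row * bx_sim * by_sim) / (sxx_s - w_row * bx_sim**2)
    sim_res2 = w_row * (by_sim - loo_s * bx_sim) ** 2
    sim_rss = np.sum(sim_res2, axis=1)

    global_p = float((np.sum(sim_rss >= obs_rss) + 1) / (n_sim + 1))
    outlier_pvals = (np.sum(sim_res2 >= obs_res2[None, :], axis=0) + 1) / (n_sim + 1)
    flags = outlier_pvals < outlier_p / j

    raw = ivw(h)
    keep_ids = [v for v, f in zip(h.variant_ids, flags) if not f]
    if flags.any() and len(keep_ids) >= 2:
        corrected = ivw(h.subset(keep_ids))
        corrected.method = "presso_corrected"
        # distortion: removals of random non-outlier subsets of the same size
        n_out = int(flags.sum())
        non_out = np.where(~flags)[0]
        obs_d = raw.theta - corrected.theta
        diffs = np.empty(n_sim)
        for b in range(n_sim):
            drop = rng.choice(non_out, size=n_out, replace=False)
            mask = np.ones(j, dtype=bool)
            mask[drop] = False
            diffs[b] = raw.theta - _origin_slope(bx[mask], by[mask], w[mask])
        distortion_p = float((np.sum(np.abs(diffs) >= abs(obs_d)) + 1) / (n_sim + 1))
    else:
        corrected = MREstimate(
            method="presso_corrected", theta=raw.theta, se=raw.se,
            pval=raw.pval, n_snps=raw.n_snps, q=raw.q, q_df=raw.q_df,
            q_pval=raw.q_pval,
        )
        distortion_p = None

    raw.method = "presso_raw"
    return PressoResult(
        global_rss_p=global_p,
        outlier_flags=flags,
        outlier_pvals=outlier_pvals,
        raw=raw,
        corrected=corrected,
        distortion_p=distortion_p,
    )
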