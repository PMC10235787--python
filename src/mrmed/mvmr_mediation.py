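"""Multivariable MR and mediation decomposition by the difference method.

The direct effect of an exposure conditional on a mediator comes from
weighted regression of outcome betas on both exposures' betas with the
intercept fixed to zero; the indirect effect is total minus direct; SEs are
combined by propagation of error (zero covariance between the total and
direct estimates, which use different instrument sets).
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats as sps

from mrmed.exceptions import (
    CollinearityError,
    EmptyInstrumentError,
    EmptyInputError,
    MRError,
    UnderdeterminedError,
)
from mrmed.summary_data import (
    HarmonisedSet,
    LDInfo,
    SummaryStats,
    pool_for_mvmr,
    select_instruments,
)
from mrmed.univariable_mr import Z95, MREstimate, ivw

logger = logging.getLogger(__name__)


@dataclass
class MediationResult:
    """Total/direct/indirect decomposition for one (exposure, mediator) pair.

    All effects are on the outcome's link scale.  ``proportion_mediated`` is
    indirect/total with a delta-method SE; its CI may legitimately fall
    outside [0, 1].
    """

    exposure_id: str
    mediator_id: str
    outcome_id: str
    total: MREstimate
    direct: MREstimate
    indirect_theta: float
    indirect_se: float
    indirect_ci: tuple[float, float]
    proportion_mediated: float
    proportion_se: float
    proportion_ci: tuple[float, float]
    unit_scaling: float = 1.0


def mvmr_fit(h: HarmonisedSet) -> dict[str, MREstimate]:
    """Multivariable MR: per-exposure direct effects conditional on the rest.

    Regresses outcome betas on the k exposure-beta columns with no intercept
    and weights 1/seY^2.  Coefficient SEs are inflated by
    ``max(1, sqrt(RSS_w/(J-k)))``.  Conditional instrument-strength F
    statistics are attached to each estimate's ``q`` slot's companion field
    via the returned mapping order (see ``conditional_f``).
    """
    k = h.beta.shape[1] - 1
    if k < 2:
        raise ValueError("mvmr_fit needs >= 2 exposures plus an outcome")
    j = h.n_variants
    if j <= k:
        raise UnderdeterminedError(f"{j} variants for {k} exposures")
    y = h.beta[:, k]
    sy = h.se[:, k]
    w = sy**-2

    # all-zero exposure columns contribute nothing: fit without them and
    # report a zero coefficient (degenerate-MVMR = univariable behaviour)
    active = [c for c in range(k) if np.any(h.beta[:, c] != 0.0)]
    x = h.beta[:, active]

    xtwx = (x.T * w) @ x
    if np.linalg.cond(xtwx) > 1e12:
        corr = np.corrcoef(x, rowvar=False)
        off = np.abs(corr - np.eye(len(active)))
        i, jj = divmod(int(np.argmax(off)), len(active))
        raise CollinearityError((h.traits[active[i]], h.traits[active[jj]]))
    coef = np.linalg.solve(xtwx, (x.T * w) @ y)
    resid = y - x @ coef
    rss_w = float(np.sum(w * resid**2))
    phi = max(1.0, np.sqrt(rss_w / (j - k)))
    cov = np.linalg.inv(xtwx)
    ses = phi * np.sqrt(np.diag(cov))
    q_pval = float(sps.chi2.sf(rss_w, j - k))

    out: dict[str, MREstimate] = {}
    for i, trait in enumerate(h.traits[:k]):
        if i in active:
            a = active.index(i)
            theta, se = float(coef[a]), float(ses[a])
            pval = float(2.0 * sps.norm.sf(abs(theta) / se))
        else:
            theta, se, pval = 0.0, float("nan"), float("nan")
        out[trait] = MREstimate(
            method="mvmr",
            theta=theta,
            se=se,
            pval=pval,
            n_snps=j,
            q=rss_w,
            q_df=j - k,
            q_pval=q_pval,
        )
    return out


def conditional_f(h: HarmonisedSet) -> dict[str, float]:
    """Per-exposure conditional instrument-strength diagnostic.

    For each exposure, its betas are regressed on the remaining exposures'
    betas (weights = that exposure's 1/se^2, no intercept); the weighted
    residual Q over its degrees of freedom approximates the conditional F.
    """
    k = h.beta.shape[1] - 1
    j = h.n_variants
    out: dict[str, float] = {}
    for i in range(k):
        target = h.beta[:, i]
        w = h.se[:, i] ** -2
        others = [c for c in range(k) if c != i]
        if others:
            xo = h.beta[:, others]
            coef = np.linalg.lstsq(xo * np.sqrt(w)[:, None], target * np.sqrt(w), rcond=None)[0]
            resid = target - xo @ coef
            df = j - len(others)
        else:
            resid = target
            df = j
        out[h.traits[i]] = float(np.sum(w * resid**2) / df)
    return out


def decompose(
    total: MREstimate,
    direct: MREstimate,
    exposure_id: str = "exposure",
    mediator_id: str = "mediator",
    outcome_id: str = "outcome",
    unit_scaling: float = 1.0,
) -> MediationResult:
    """Difference-method decomposition with propagation-of-error intervals.

    indirect = total - direct; SE_indirect = sqrt(SE_total^2 + SE_direct^2);
    proportion mediated = indirect/total with a ratio delta-method SE.  The
    covariance between total and direct is taken as zero (they are estimated
    from different instrument sets).
    """
    if abs(total.theta) < 1e-10:
        raise MRError("total effect is ~0: proportion mediated undefined")
    ind = total.theta - direct.theta
    ind_se = float(np.hypot(total.se, direct.se))
    prop = ind / total.theta
    if ind != 0.0:
        prop_se = abs(prop) * float(
            np.hypot(ind_se / ind, total.se / total.theta)
        )
    else:
        prop_se = ind_se / abs(total.theta)
    return MediationResult(
        exposure_id=exposure_id,
        mediator_id=mediator_id,
        outcome_id=outcome_id,
        total=total,
        direct=direct,
        indirect_theta=ind,
        indirect_se=ind_se,
        indirect_ci=(ind - Z95 * ind_se, ind + Z95 * ind_se),
        proportion_mediated=prop,
        proportion_se=prop_se,
        proportion_ci=(prop - Z95 * prop_se, prop + Z95 * prop_se),
        unit_scaling=unit_scaling,
    )


def rescale(est: MREstimate, multiplier: float) -> MREstimate:
    """Re-express an estimate per ``multiplier`` exposure units.

    Both theta and SE are multiplied before any exponentiation, so e.g. a
    per-mmHg log-odds estimate becomes per-10-mmHg with ``multiplier=10``.
    Proportions mediated are invariant to this rescaling.
    """
    if multiplier <= 0:
        raise ValueError("multiplier must be positive")
    return MREstimate(
        method=est.method,
        theta=est.theta * multiplier,
        se=est.se * multiplier,
        pval=est.pval,
        n_snps=est.n_snps,
        q=est.q,
        q_df=est.q_df,
        q_pval=est.q_pval,
    )


def mediate_pair(
    exposure: SummaryStats,
    mediator: SummaryStats,
    outcome: SummaryStats,
    ld: LDInfo,
    p_threshold: float = 5e-8,
    r2_threshold: float = 0.001,
    unit_scaling: float = 1.0,
) -> MediationResult:
    """End-to-end mediation analysis for one (exposure, mediator) pair.

    The total effect uses the exposure's own clumped instruments via
    univariable IVW; the direct effect uses pooled-then-clumped instruments
    across exposure and mediator via MVMR with the intercept fixed to zero.
    """
    from mrmed.summary_data import harmonise  # local import avoids cycle at module load

    own = select_instruments(exposure, ld, p_threshold, r2_threshold)
    h_total = harmonise([exposure.subset(own.variant_ids), outcome])
    total = ivw(h_total)

    pooled = pool_for_mvmr([exposure, mediator], ld, p_threshold, r2_threshold)
    h_mvmr = harmonise(
        [
            exposure.subset(pooled.variant_ids),
            mediator.subset(pooled.variant_ids),
            outcome.subset(pooled.variant_ids),
        ]
    )
    direct = mvmr_fit(h_mvmr)[exposure.trait_id]

    if unit_scaling != 1.0:
        total = rescale(total, unit_scaling)
        direct = rescale(direct, unit_scaling)
    return decompose(
        total,
        direct,
        exposure_id=exposure.trait_id,
        mediator_id=mediator.trait_id,
        outcome_id=outcome.trait_id,
        unit_scaling=unit_scaling,
    )


def mediation_grid(
    risk_factors: list[SummaryStats],
    outcome: SummaryStats,
    ld: LDInfo,
    p_threshold: float = 5e-8,
    r2_threshold: float = 0.001,
    unit_scalings: dict[str, float] | None = None,
) -> pd.DataFrame:
    """All ordered (exposure, mediator) pairs as a tidy long-format table.

    Per-pair failures (e.g. a mediator with no genome-wide-significant
    variants) are logged and recorded as missing cells, never fatal.
    """
    if len(risk_factors) < 2:
        raise ValueError("mediation_grid needs >= 2 risk factors")
    unit_scalings = unit_scalings or {}
    rows = []
    for exposure in risk_factors:
        for mediator in risk_factors:
            if mediator.trait_id == exposure.trait_id:
                continue
            row: dict[str, object] = {
                "exposure": exposure.trait_id,
                "mediator": mediator.trait_id,
                "outcome": outcome.trait_id,
            }
            try:
                res = mediate_pair(
                    exposure,
                    mediator,
                    outcome,
                    ld,
                    p_threshold,
                    r2_threshold,
                    unit_scaling=unit_scalings.get(exposure.trait_id, 1.0),
                )
            except (MRError, EmptyInstrumentError, EmptyInputError, ValueError) as exc:
                logger.warning(
                    "mediation cell (%s, %s) failed: %s",
                    exposure.trait_id,
                    mediator.trait_id,
                    exc,
                )
                row["status"] = f"failed: {exc}"
                rows.append(row)
                continue
            tor, tlo, thi = res.total.or_scale()
            dor, dlo, dhi = res.direct.or_scale()
            row.update(
                status="ok",
                total_or=tor,
                total_ci_low=tlo,
                total_ci_high=thi,
                direct_or=dor,
                direct_ci_low=dlo,
                direct_ci_high=dhi,
                indirect=res.indirect_theta,
                indirect_se=res.indirect_se,
                proportion_mediated=res.proportion_mediated,
                pm_ci_low=res.proportion_ci[0],
                pm_ci_high=res.proportion_ci[1],
                n_snps_total=res.total.n_snps,
                n_snps_mvmr=res.direct.n_snps,
            )
            rows.append(row)
    return pd.DataFrame(rows)
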