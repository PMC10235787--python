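"""Synthetic two-sample GWAS summary statistics with known causal structure.

The generator follows a mediation DAG — exposure -> mediator -> binary
outcome on the log-odds scale, plus a direct exposure -> outcome path — and
emits three :class:`~mrmed.summary_data.SummaryStats` tables drawn from
non-overlapping samples (independent noise), an LD table with configurable
block structure, and a per-variant truth table for parameter-recovery tests.

Pleiotropy modes mirror the standard taxonomy: ``balanced`` and
``directional`` draw variant-outcome effects independent of the
variant-exposure effects (InSIDE holds); ``correlated`` draws them
proportional to the exposure effects plus noise (InSIDE violated).
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from pathlib import Path

import numpy as np
import pandas as pd
from scipy import stats as sps

from mrmed.exceptions import ConfigurationError
from mrmed.summary_data import LDInfo, SummaryStats

__all__ = ["TruthConfig", "SyntheticStudy", "simulate", "scenario_suite", "write_study"]


@dataclass(frozen=True)
class TruthConfig:
    """Ground-truth causal parameters for one synthetic study.

    ``gamma_dist`` describes per-variant instrument effects: ``("normal",
    sd)`` draws mean-zero effects; ``("signed_uniform", lo, hi)`` draws
    magnitudes uniformly in [lo, hi] with random sign (useful to guarantee
    genome-wide significance of every instrument).  ``mediator_frac`` is the
    fraction of variants acting as mediator-specific instruments (needed for
    MVMR identifiability); the rest are exposure instruments.
    """

    J: int = 50
    maf_range: tuple[float, float] = (0.1, 0.5)
    gamma_dist: tuple = ("signed_uniform", 0.03, 0.08)
    theta_xm: float = 0.0  # exposure -> mediator
    theta_my: float = 0.0  # mediator -> outcome (log-odds)
    theta_direct: float = 0.0  # exposure -> outcome, not via mediator
    pleiotropy_mode: str = "none"  # none|balanced|directional|correlated
    alpha_dist: tuple = ("normal", 0.0, 0.0)  # (kind, mean, sd)
    pleiotropy_fraction: float = 0.0
    mediator_frac: float = 0.3
    n_exp: int = 200_000
    n_med: int = 200_000
    n_out: int = 200_000
    n_outliers: int = 0
    outlier_offset: float = 0.0  # in units of outcome SE
    ld_block_size: int = 1
    ld_r2_within: float = 0.0
    seed: int = 0

    @property
    def implied_proportion_mediated(self) -> float:
        """theta_xm*theta_my / (theta_xm*theta_my + theta_direct)."""
        denom = self.theta_xm * self.theta_my + self.theta_direct
        if denom == 0:
            return float("nan")
        return self.theta_xm * self.theta_my / denom


@dataclass
class SyntheticStudy:
    """Generator output: one SummaryStats per trait plus LD and truth."""

    exposure: SummaryStats
    mediator: SummaryStats
    outcome: SummaryStats
    ld: LDInfo
    truth: pd.DataFrame  # variant_id, gamma, delta, alpha, outlier, true betas
    config: TruthConfig


def _draw_gamma(rng: np.random.Generator, dist: tuple, size: int) -> np.ndarray:
    kind = dist[0]
    if kind == "normal":
        return rng.normal(0.0, dist[1], size)
    if kind == "signed_uniform":
        mag = rng.uniform(dist[1], dist[2], size)
        sign = rng.choice([-1.0, 1.0], size)
        return mag * sign
    if kind == "uniform":
        # all-positive effects: keeps a directional pleiotropy mean
        # directional after MR-Egger's orientation step
        return rng.uniform(dist[1], dist[2], size)
    raise ConfigurationError(f"unknown gamma_dist kind {kind!r}")


def _pvals(beta: np.ndarray, se: np.ndarray) -> np.ndarray:
    p = 2.0 * sps.norm.sf(np.abs(beta / se))
    return np.clip(p, 1e-300, 1.0)


def _stats(
    trait_id: str,
    ids: list[str],
    pos: np.ndarray,
    maf: np.ndarray,
    beta: np.ndarray,
    se: np.ndarray,
    n: int,
    trait_type: str,
    unit: str,
) -> SummaryStats:
    df = pd.DataFrame(
        {
            "variant_id": ids,
            "chrom": "1",
            "pos": pos,
            "effect_allele": "A",
            "other_allele": "G",
            "eaf": maf,
            "beta": beta,
            "se": se,
            "pval": _pvals(beta, se),
            "n": n,
        }
    )
    return SummaryStats(trait_id=trait_id, variants=df, trait_type=trait_type, unit_label=unit)


def simulate(cfg: TruthConfig) -> SyntheticStudy:
    """Draw one synthetic three-trait study from ``cfg`` (seeded).

    Per variant j: an instrument effect gamma_j on the exposure (or, for the
    mediator-instrument subset, delta_j on the mediator directly); true
    mediator effect ``theta_xm*gamma_j + delta_j``; true outcome effect
    ``theta_direct*gamma_j + theta_my*betaM_j + alpha_j`` with alpha the
    pleiotropy term.  Observed betas add independent normal noise per study
    with SE = 1/sqrt(2*maf*(1-maf)*n).
    """
    lo, hi = cfg.maf_range
    if not (0.0 < lo <= hi < 1.0):
        raise ConfigurationError(f"degenerate maf_range {cfg.maf_range}")
    rng = np.random.default_rng(cfg.seed)
    J = cfg.J
    ids = [f"rs{j + 1:05d}" for j in range(J)]
    pos = np.arange(1, J + 1) * 1000
    maf = rng.uniform(lo, hi, J)

    n_med_inst = int(round(cfg.mediator_frac * J))
    is_med_inst = np.zeros(J, dtype=bool)
    if n_med_inst:
        is_med_inst[rng.choice(J, n_med_inst, replace=False)] = True

    effects = _draw_gamma(rng, cfg.gamma_dist, J)
    gamma = np.where(is_med_inst, 0.0, effects)
    delta = np.where(is_med_inst, effects, 0.0)

    alpha = np.zeros(J)
    if cfg.pleiotropy_mode != "none" and cfg.pleiotropy_fraction > 0:
        n_pl = int(round(cfg.pleiotropy_fraction * J))
        which = rng.choice(J, n_pl, replace=False)
        kind, mean, sd = cfg.alpha_dist
        if kind != "normal":
            raise ConfigurationError(f"unknown alpha_dist kind {kind!r}")
        if cfg.pleiotropy_mode == "balanced":
            alpha[which] = rng.normal(0.0, sd, n_pl)
        elif cfg.pleiotropy_mode == "directional":
            alpha[which] = rng.normal(mean, sd, n_pl)
        elif cfg.pleiotropy_mode == "correlated":
            # alpha proportional to the instrument effect plus noise: InSIDE broken
            alpha[which] = mean * effects[which] + rng.normal(0.0, sd, n_pl)
        else:
            raise ConfigurationError(
                f"unknown pleiotropy_mode {cfg.pleiotropy_mode!r}"
            )

    beta_x = gamma
    beta_m = cfg.theta_xm * gamma + delta
    beta_y = cfg.theta_direct * gamma + cfg.theta_my * beta_m + alpha

    var_g = 2.0 * maf * (1.0 - maf)
    se_x = 1.0 / np.sqrt(var_g * cfg.n_exp)
    se_m = 1.0 / np.sqrt(var_g * cfg.n_med)
    se_y = 1.0 / np.sqrt(var_g * cfg.n_out)

    outlier = np.zeros(J, dtype=bool)
    if cfg.n_outliers:
        chosen = rng.choice(J, cfg.n_outliers, replace=False)
        outlier[chosen] = True
        beta_y = beta_y + outlier * cfg.outlier_offset * se_y

    obs_x = beta_x + rng.normal(0.0, se_x)
    obs_m = beta_m + rng.normal(0.0, se_m)
    obs_y = beta_y + rng.normal(0.0, se_y)

    ld = LDInfo()
    if cfg.ld_block_size > 1 and cfg.ld_r2_within > 0:
        for start in range(0, J, cfg.ld_block_size):
            block = ids[start : start + cfg.ld_block_size]
            for i in range(len(block)):
                for k in range(i + 1, len(block)):
                    ld.add(block[i], block[k], cfg.ld_r2_within)

    truth = pd.DataFrame(
        {
            "variant_id": ids,
            "maf": maf,
            "gamma": gamma,
            "delta": delta,
            "alpha": alpha,
            "outlier": outlier,
            "beta_x_true": beta_x,
            "beta_m_true": beta_m,
            "beta_y_true": beta_y,
        }
    )
    return SyntheticStudy(
        exposure=_stats("exposure", ids, pos, maf, obs_x, se_x, cfg.n_exp, "quantitative", "SD"),
        mediator=_stats("mediator", ids, pos, maf, obs_m, se_m, cfg.n_med, "quantitative", "SD"),
        outcome=_stats("outcome", ids, pos, maf, obs_y, se_y, cfg.n_out, "binary", "logOR"),
        ld=ld,
        truth=truth,
        config=cfg,
    )


def scenario_suite(seed: int = 0) -> dict[str, TruthConfig]:
    """Named generator configurations used throughout the test suite."""
    base = TruthConfig(seed=seed)
    return {
        "null": replace(base, theta_xm=0.0, theta_my=0.0, theta_direct=0.0),
        "causal": replace(base, theta_direct=0.2),
        "mediation_half": replace(
            base, theta_xm=0.5, theta_my=0.4, theta_direct=0.2
        ),
        "balanced_pleiotropy": replace(
            base,
            theta_direct=0.2,
            pleiotropy_mode="balanced",
            alpha_dist=("normal", 0.0, 0.01),
            pleiotropy_fraction=0.5,
        ),
        "directional_pleiotropy": replace(
            base,
            theta_direct=0.2,
            gamma_dist=("uniform", 0.03, 0.08),
            pleiotropy_mode="directional",
            alpha_dist=("normal", 0.01, 0.003),
            pleiotropy_fraction=1.0,
        ),
        "correlated_pleiotropy": replace(
            base,
            theta_direct=0.2,
            pleiotropy_mode="correlated",
            alpha_dist=("normal", 0.3, 0.003),
            pleiotropy_fraction=1.0,
        ),
        "one_outlier": replace(
            base, theta_direct=0.2, n_outliers=1, outlier_offset=10.0
        ),
        "weak_instruments": replace(
            base,
            gamma_dist=("signed_uniform", 0.001, 0.01),
            n_exp=5_000,
            n_med=5_000,
            n_out=5_000,
        ),
    }


def write_study(study: SyntheticStudy, outdir: str | Path) -> dict[str, Path]:
    """Write the three trait TSVs, the LD table and truth.tsv to ``outdir``."""
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    paths = {
        "exposure": outdir / "exposure.tsv",
        "mediator": outdir / "mediator.tsv",
        "outcome": outdir / "outcome.tsv",
        "ld": outdir / "ld.tsv",
        "truth": outdir / "truth.tsv",
    }
    study.exposure.to_tsv(paths["exposure"])
    study.mediator.to_tsv(paths["mediator"])
    study.outcome.to_tsv(paths["outcome"])
    study.ld.to_table(paths["ld"])
    study.truth.to_csv(paths["truth"], sep="\t", index=False)
    return paths
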