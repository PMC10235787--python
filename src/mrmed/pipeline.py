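"""End-to-end orchestration: total effects, mediation grid, enrichment.

A :class:`RunConfig` (loadable from YAML) names the trait files, LD source,
thresholds, methods and seeds; :func:`run_full` executes instrument
selection, univariable estimators, the mediation grid and (optionally)
pathway enrichment, writing tidy TSV tables plus a JSON manifest.  Reruns
with the same config and seed reproduce byte-identical tables.
"""

from __future__ import annotations

import json
import logging
from dataclasses import dataclass, field as dfield
from pathlib import Path
from typing import Any

import pandas as pd
import yaml

from mrmed.exceptions import ConfigurationError, MRError
from mrmed.summary_data import (
    HarmonisedSet,
    LDInfo,
    SummaryStats,
    harmonise,
    read_gwas,
    select_instruments,
)
from mrmed.univariable_mr import (
    MREstimate,
    ivw,
    mr_egger,
    mr_presso,
    weighted_median,
)
from mrmed.mvmr_mediation import mediation_grid, rescale
from mrmed.enrichment import (
    EqtlTable,
    PathwayDB,
    annotate_drugs,
    map_eqtl_genes,
    ora,
    results_frame,
)

logger = logging.getLogger(__name__)

KNOWN_METHODS = ("ivw", "median", "egger", "presso")


@dataclass
class RunConfig:
    """Validated run configuration.

    ``exposures`` maps trait_id -> file path; ``column_maps``, ``trait_types``,
    ``unit_labels`` and ``unit_scalings`` are optional per-trait overrides.
    All thresholds must lie in (0, 1); every referenced path must exist at
    validation time.
    """

    exposures: dict[str, str]
    outcome: str
    outcome_id: str = "outcome"
    ld: str | None = None
    column_maps: dict[str, dict[str, str]] = dfield(default_factory=dict)
    trait_types: dict[str, str] = dfield(default_factory=dict)
    unit_labels: dict[str, str] = dfield(default_factory=dict)
    unit_scalings: dict[str, float] = dfield(default_factory=dict)
    p_select: float = 5e-8
    r2_threshold: float = 0.001
    bonferroni: float = 0.005
    fdr: float = 0.05
    methods: tuple[str, ...] = ("ivw", "median", "egger", "presso")
    seed: int = 0
    out_dir: str = "results"
    eqtl: str | None = None
    gmt: str | None = None
    drugs: str | None = None

    def __post_init__(self) -> None:
        if not self.methods:
            raise ConfigurationError("methods list is empty")
        unknown = set(self.methods) - set(KNOWN_METHODS)
        if unknown:
            raise ConfigurationError(f"unknown methods: {sorted(unknown)}")
        for name, val in (
            ("p_select", self.p_select),
            ("r2_threshold", self.r2_threshold),
            ("bonferroni", self.bonferroni),
            ("fdr", self.fdr),
        ):
            if not 0.0 < val < 1.0:
                raise ConfigurationError(f"{name} = {val} outside (0, 1)")
        for label, path in self._paths():
            if not Path(path).exists():
                raise ConfigurationError(f"{label}: file not found: {path}")

    def _paths(self) -> list[tuple[str, str]]:
        out = [(tid, p) for tid, p in self.exposures.items()]
        out.append((self.outcome_id, self.outcome))
        for label, p in (("ld", self.ld), ("eqtl", self.eqtl), ("gmt", self.gmt), ("drugs", self.drugs)):
            if p is not None:
                out.append((label, p))
        return out

    @classmethod
    def from_yaml(cls, path: str | Path) -> "RunConfig":
        raw = yaml.safe_load(Path(path).read_text())
        if not isinstance(raw, dict):
            raise ConfigurationError(f"{path}: config must be a mapping")
        if "methods" in raw:
            raw["methods"] = tuple(raw["methods"])
        try:
            return cls(**raw)
        except TypeError as exc:
            raise ConfigurationError(f"{path}: {exc}") from None

    def to_dict(self) -> dict[str, Any]:
        d = dict(self.__dict__)
        d["methods"] = list(self.methods)
        return d

    def load_traits(self) -> tuple[list[SummaryStats], SummaryStats, LDInfo]:
        exposures = [
            read_gwas(
                path,
                column_map=self.column_maps.get(tid),
                trait_id=tid,
                trait_type=self.trait_types.get(tid, "quantitative"),
                unit_label=self.unit_labels.get(tid, ""),
            )
            for tid, path in self.exposures.items()
        ]
        outcome = read_gwas(
            self.outcome,
            column_map=self.column_maps.get(self.outcome_id),
            trait_id=self.outcome_id,
            trait_type=self.trait_types.get(self.outcome_id, "binary"),
            unit_label=self.unit_labels.get(self.outcome_id, "logOR"),
        )
        ld = LDInfo.from_table(self.ld) if self.ld else LDInfo()
        return exposures, outcome, ld


def _estimate_rows(
    exposure_id: str,
    h: HarmonisedSet,
    methods: tuple[str, ...],
    seed: int,
    bonferroni: float,
    scaling: float,
) -> list[dict[str, Any]]:
    estimates: list[MREstimate] = []
    extra: dict[str, Any] = {}
    if "ivw" in methods:
        estimates.append(ivw(h))
    if "median" in methods:
        estimates.append(weighted_median(h, seed=seed))
    if "egger" in methods:
        slope, intercept = mr_egger(h)
        estimates.extend([slope, intercept])
    if "presso" in methods:
        pres = mr_presso(h, seed=seed)
        estimates.extend([pres.raw, pres.corrected])
        extra = {
            "presso_global_p": pres.global_rss_p,
            "presso_n_outliers": int(pres.outlier_flags.sum()),
            "presso_distortion_p": pres.distortion_p,
        }
    rows = []
    for est in estimates:
        scaled = rescale(est, scaling) if scaling != 1.0 else est
        orv, lo, hi = scaled.or_scale()
        label = (
            "significant"
            if est.pval < bonferroni
            else ("suggestive" if est.pval < 0.05 else "ns")
        )
        rows.append(
            {
                "exposure": exposure_id,
                "method": est.method,
                "theta": scaled.theta,
                "se": scaled.se,
                "ci_low": scaled.ci_low,
                "ci_high": scaled.ci_high,
                "pval": est.pval,
                "or": orv,
                "or_ci_low": lo,
                "or_ci_high": hi,
                "n_snps": est.n_snps,
                "q": est.q,
                "q_pval": est.q_pval,
                "significance": label,
                "unit_scaling": scaling,
                **(extra if est.method.startswith("presso") else {}),
            }
        )
    return rows


def run_total_effects(
    cfg: RunConfig,
    exposures: list[SummaryStats] | None = None,
    outcome: SummaryStats | None = None,
    ld: LDInfo | None = None,
) -> pd.DataFrame:
    """Univariable estimates for every exposure against the outcome.

    Per-exposure failures are isolated: the failing trait contributes an
    error row and the run continues.
    """
    if exposures is None or outcome is None or ld is None:
        exposures, outcome, ld = cfg.load_traits()
    rows: list[dict[str, Any]] = []
    for exp in exposures:
        try:
            inst = select_instruments(exp, ld, cfg.p_select, cfg.r2_threshold)
            h = harmonise([exp.subset(inst.variant_ids), outcome])
            scaling = cfg.unit_scalings.get(exp.trait_id, 1.0)
            rows.extend(
                _estimate_rows(exp.trait_id, h, cfg.methods, cfg.seed, cfg.bonferroni, scaling)
            )
        except MRError as exc:
            logger.warning("total-effects failed for %s: %s", exp.trait_id, exc)
            rows.append({"exposure": exp.trait_id, "method": "error", "note": str(exc)})
    return pd.DataFrame(rows)


def run_full(cfg: RunConfig) -> Path:
    """Execute the whole pipeline and write result tables plus a manifest.

    Writes ``total_effects.tsv``, ``mediation_grid.tsv``, optionally
    ``enrichment.tsv``, and ``manifest.json`` into ``cfg.out_dir``.  A stage
    failure is recorded in the manifest and the process exits non-zero via
    the CLI wrapper; completed stages are kept.
    """
    out_dir = Path(cfg.out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    exposures, outcome, ld = cfg.load_traits()
    manifest: dict[str, Any] = {
        "config": cfg.to_dict(),
        "seed": cfg.seed,
        "version": _version(),
        "stages": {},
    }

    failed = False
    try:
        totals = run_total_effects(cfg, exposures, outcome, ld)
        totals.to_csv(out_dir / "total_effects.tsv", sep="\t", index=False)
        manifest["stages"]["total_effects"] = {"rows": len(totals)}
    except Exception as exc:  # pragma: no cover - defensive
        manifest["stages"]["total_effects"] = {"error": str(exc)}
        failed = True

    if len(exposures) >= 2:
        try:
            grid = mediation_grid(
                exposures, outcome, ld, cfg.p_select, cfg.r2_threshold, cfg.unit_scalings
            )
            grid.to_csv(out_dir / "mediation_grid.tsv", sep="\t", index=False)
            manifest["stages"]["mediation_grid"] = {"rows": len(grid)}
        except Exception as exc:
            manifest["stages"]["mediation_grid"] = {"error": str(exc)}
            failed = True

    if cfg.eqtl and cfg.gmt:
        try:
            eqtl = EqtlTable.from_tsv(cfg.eqtl)
            db = PathwayDB.from_gmt(cfg.gmt)
            all_inst: list[str] = []
            for exp in exposures:
                try:
                    inst = select_instruments(exp, ld, cfg.p_select, cfg.r2_threshold)
                    all_inst.extend(inst.variant_ids)
                except MRError:
                    continue
            genes, _ = map_eqtl_genes(sorted(set(all_inst)), eqtl)
            results = ora(genes, db, cfg.fdr)
            if cfg.drugs:
                drug_map = pd.read_csv(cfg.drugs, sep="\t")
                results = annotate_drugs(results, drug_map, cfg.fdr)
            results_frame(results).to_csv(out_dir / "enrichment.tsv", sep="\t", index=False)
            manifest["stages"]["enrichment"] = {"rows": len(results)}
        except Exception as exc:
            manifest["stages"]["enrichment"] = {"error": str(exc)}
            failed = True

    manifest["status"] = "failed" if failed else "ok"
    (out_dir / "manifest.json").write_text(json.dumps(manifest, indent=2, default=str))
    if failed:
        raise MRError(f"one or more stages failed; see {out_dir / 'manifest.json'}")
    return out_dir


def _version() -> str:
    from mrmed import __version__

    return __version__
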