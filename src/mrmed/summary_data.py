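"""GWAS summary-statistics I/O, harmonisation and instrument selection.

A :class:`SummaryStats` is a validated per-variant association table for one
trait.  Harmonisation aligns two or more tables to a shared effect allele per
variant (sign-flipping swapped orientations, keeping palindromic variants, and
dropping variants whose allele pair matches neither orientation).  Instrument
selection applies a p-value threshold followed by greedy LD clumping, and
attaches per-variant strength diagnostics (F statistic and variance
explained).
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd

from mrmed.exceptions import (
    ConfigurationError,
    EmptyInputError,
    EmptyInstrumentError,
)

logger = logging.getLogger(__name__)

VALID_ALLELES = frozenset("ACGT")

#: canonical column names of a SummaryStats variant table
VARIANT_COLUMNS = [
    "variant_id",
    "chrom",
    "pos",
    "effect_allele",
    "other_allele",
    "eaf",
    "beta",
    "se",
    "pval",
    "n",
]

_REQUIRED_KEYS = ("variant_id", "effect_allele", "other_allele", "beta", "se", "pval")
_OPTIONAL_KEYS = ("chrom", "pos", "eaf", "n")


@dataclass
class SummaryStats:
    """Per-variant association estimates for a single trait.

    Parameters
    ----------
    trait_id : str
        Label identifying the trait.
    variants : pandas.DataFrame
        One row per variant with columns ``variant_id, chrom, pos,
        effect_allele, other_allele, eaf, beta, se, pval, n`` (``chrom``,
        ``pos``, ``eaf`` and ``n`` may be NaN).
    trait_type : {"quantitative", "binary"}
        Binary traits carry betas in log-odds units.
    unit_label : str
        Free-text unit of the beta column (e.g. ``"mmHg"``, ``"SD"``,
        ``"logOR"``).
    """

    trait_id: str
    variants: pd.DataFrame
    trait_type: str = "quantitative"
    unit_label: str = ""

    def __post_init__(self) -> None:
        if self.trait_type not in ("quantitative", "binary"):
            raise ConfigurationError(
                f"trait_type must be 'quantitative' or 'binary', got {self.trait_type!r}"
            )
        self.variants = _validate_variants(self.variants, self.trait_id)

    def __len__(self) -> int:
        return len(self.variants)

    @property
    def variant_ids(self) -> list[str]:
        return self.variants["variant_id"].tolist()

    def subset(self, variant_ids: Iterable[str]) -> "SummaryStats":
        """Return a copy restricted to ``variant_ids`` (original order kept)."""
        wanted = set(variant_ids)
        sub = self.variants[self.variants["variant_id"].isin(wanted)].reset_index(
            drop=True
        )
        out = object.__new__(SummaryStats)
        out.trait_id = self.trait_id
        out.variants = sub
        out.trait_type = self.trait_type
        out.unit_label = self.unit_label
        return out

    def to_tsv(self, path: str | Path) -> None:
        self.variants.to_csv(path, sep="\t", index=False)


def _validate_variants(df: pd.DataFrame, trait_id: str) -> pd.DataFrame:
    df = df.copy()
    for col in VARIANT_COLUMNS:
        if col not in df.columns:
            if col in _REQUIRED_KEYS:
                raise ConfigurationError(
                    f"trait {trait_id!r}: missing required column {col!r}"
                )
            df[col] = np.nan
    df = df[VARIANT_COLUMNS]
    n0 = len(df)

    df["variant_id"] = df["variant_id"].astype(str)
    for col in ("effect_allele", "other_allele"):
        df[col] = df[col].astype(str).str.upper().str.strip()
    for col in ("eaf", "beta", "se", "pval", "n", "pos"):
        df[col] = pd.to_numeric(df[col], errors="coerce")

    bad_allele = ~(
        df["effect_allele"].isin(VALID_ALLELES)
        & df["other_allele"].isin(VALID_ALLELES)
        & (df["effect_allele"] != df["other_allele"])
    )
    bad_se = ~(df["se"] > 0)
    bad_beta = df["beta"].isna()
    bad_p = ~((df["pval"] > 0) & (df["pval"] <= 1))
    dup = df["variant_id"].duplicated(keep=False)
    drop = bad_allele | bad_se | bad_beta | bad_p | dup
    if drop.any():
        logger.warning(
            "trait %s: dropped %d/%d rows (alleles=%d, se=%d, beta=%d, pval=%d, dup=%d)",
            trait_id,
            int(drop.sum()),
            n0,
            int(bad_allele.sum()),
            int(bad_se.sum()),
            int(bad_beta.sum()),
            int(bad_p.sum()),
            int(dup.sum()),
        )
        df = df[~drop]
    if df.empty:
        raise EmptyInputError(f"trait {trait_id!r}: zero valid rows after validation")
    return df.reset_index(drop=True)


def read_gwas(
    path: str | Path,
    column_map: Mapping[str, str] | None = None,
    trait_id: str | None = None,
    trait_type: str = "quantitative",
    unit_label: str = "",
) -> SummaryStats:
    """Read a GWAS summary-statistics file into a :class:`SummaryStats`.

    The file must be tab- or comma-separated with a header.  ``column_map``
    maps canonical field names (``variant_id``, ``effect_allele``,
    ``other_allele``, ``beta``, ``se``, ``pval``; optionally ``chrom``,
    ``pos``, ``eaf``, ``n``) to the column names used in the file; canonical
    names present verbatim in the header need no mapping.  Rows with
    non-positive SE, invalid alleles or duplicate variant IDs are dropped
    with a logged count.  Gzipped files are accepted.
    """
    path = Path(path)
    sep = "," if path.name.removesuffix(".gz").endswith(".csv") else "\t"
    raw = pd.read_csv(path, sep=sep)
    column_map = dict(column_map or {})

    rename: dict[str, str] = {}
    for key in _REQUIRED_KEYS + _OPTIONAL_KEYS:
        src = column_map.get(key, key)
        if src in raw.columns:
            rename[src] = key
        elif key in _REQUIRED_KEYS:
            raise ConfigurationError(
                f"{path.name}: cannot resolve required column {key!r} "
                f"(mapped to {src!r}; header has {list(raw.columns)})"
            )
    df = raw.rename(columns=rename)
    return SummaryStats(
        trait_id=trait_id or path.stem.removesuffix(".tsv"),
        variants=df,
        trait_type=trait_type,
        unit_label=unit_label,
    )


class LDInfo:
    """Sparse symmetric table of pairwise LD r-squared values.

    Pairs absent from the table are treated as :math:`r^2 = 0` (variants on
    different chromosomes or outside each other's clumping window).
    """

    def __init__(self, pairs: Mapping[tuple[str, str], float] | None = None):
        self._r2: dict[frozenset[str], float] = {}
        if pairs:
            for (a, b), r2 in pairs.items():
                self.add(a, b, r2)

    def add(self, a: str, b: str, r2: float) -> None:
        if not 0.0 <= r2 <= 1.0:
            raise ConfigurationError(f"r2({a},{b}) = {r2} outside [0, 1]")
        if a == b:
            return
        self._r2[frozenset((a, b))] = float(r2)

    def r2(self, a: str, b: str) -> float:
        if a == b:
            return 1.0
        return self._r2.get(frozenset((a, b)), 0.0)

    def __len__(self) -> int:
        return len(self._r2)

    @classmethod
    def from_table(cls, path: str | Path) -> "LDInfo":
        """Read LD from a long-format TSV (``id_a``, ``id_b``, ``r2``) or a
        dense square matrix with a header row of variant IDs."""
        path = Path(path)
        df = pd.read_csv(path, sep="\t")
        cols_lower = [c.lower() for c in df.columns]
        obj = cls()
        if len(df.columns) == 3 and "r2" in cols_lower:
            df.columns = cols_lower
            a_col, b_col = [c for c in cols_lower if c != "r2"]
            for a, b, r2 in zip(df[a_col], df[b_col], df["r2"]):
                obj.add(str(a), str(b), float(r2))
        else:
            # dense matrix: first column is the row index of IDs
            ids = df.iloc[:, 0].astype(str).tolist()
            mat = df.iloc[:, 1:].to_numpy(dtype=float)
            if mat.shape != (len(ids), len(ids)):
                raise ConfigurationError(
                    f"{path.name}: dense LD matrix is not square over its IDs"
                )
            for i, a in enumerate(ids):
                for j in range(i + 1, len(ids)):
                    if mat[i, j] > 0:
                        obj.add(a, ids[j], mat[i, j])
        return obj

    def to_table(self, path: str | Path) -> None:
        rows = [
            {"id_a": min(k), "id_b": max(k), "r2": v} for k, v in self._r2.items()
        ]
        pd.DataFrame(rows, columns=["id_a", "id_b", "r2"]).sort_values(
            ["id_a", "id_b"]
        ).to_csv(path, sep="\t", index=False)


@dataclass
class HarmonisedSet:
    """Variants aligned to a shared effect allele across two or more traits.

    ``beta`` and ``se`` are ``(J, T)`` arrays over ``variant_ids`` x
    ``traits``; the last trait is by convention the outcome.  No cell is
    missing: variants lacking an estimate in any trait are excluded before
    construction.
    """

    traits: list[str]
    variant_ids: list[str]
    beta: np.ndarray
    se: np.ndarray
    effect_alleles: list[str] = field(default_factory=list)
    other_alleles: list[str] = field(default_factory=list)

    def __post_init__(self) -> None:
        self.beta = np.asarray(self.beta, dtype=float)
        self.se = np.asarray(self.se, dtype=float)
        J, T = self.beta.shape
        if self.se.shape != (J, T):
            raise ValueError("beta and se shapes differ")
        if len(self.traits) != T or len(self.variant_ids) != J:
            raise ValueError("label lengths inconsistent with matrix shape")
        if not np.all(self.se > 0):
            raise ValueError("all standard errors must be positive")

    @property
    def n_variants(self) -> int:
        return len(self.variant_ids)

    def subset(self, variant_ids: Sequence[str]) -> "HarmonisedSet":
        idx = [self.variant_ids.index(v) for v in variant_ids]
        return HarmonisedSet(
            traits=list(self.traits),
            variant_ids=[self.variant_ids[i] for i in idx],
            beta=self.beta[idx],
            se=self.se[idx],
            effect_alleles=[self.effect_alleles[i] for i in idx]
            if self.effect_alleles
            else [],
            other_alleles=[self.other_alleles[i] for i in idx]
            if self.other_alleles
            else [],
        )

    def columns(self, traits: Sequence[str]) -> "HarmonisedSet":
        """Project onto a subset of traits (order as given)."""
        idx = [self.traits.index(t) for t in traits]
        return HarmonisedSet(
            traits=[self.traits[i] for i in idx],
            variant_ids=list(self.variant_ids),
            beta=self.beta[:, idx],
            se=self.se[:, idx],
            effect_alleles=list(self.effect_alleles),
            other_alleles=list(self.other_alleles),
        )

    def to_frame(self) -> pd.DataFrame:
        data: dict[str, object] = {"variant_id": self.variant_ids}
        if self.effect_alleles:
            data["effect_allele"] = self.effect_alleles
            data["other_allele"] = self.other_alleles
        for t_i, t in enumerate(self.traits):
            data[f"beta_{t}"] = self.beta[:, t_i]
            data[f"se_{t}"] = self.se[:, t_i]
        return pd.DataFrame(data)


def harmonise(tables: Sequence[SummaryStats]) -> HarmonisedSet:
    """Align effect alleles across tables and intersect variants.

    The first table defines the reference effect allele per variant.  For
    every other table a variant is kept as-is when its (effect, other)
    alleles match the reference orientation, sign-flipped when they are
    swapped, and dropped (with a log entry) otherwise.  Palindromic variants
    (A/T, C/G) are aligned by allele letters exactly like any other variant —
    no frequency check, no exclusion.  No proxies are used for variants
    missing from any table: only the intersection survives.
    """
    if len(tables) < 2:
        raise ConfigurationError("harmonise requires at least two trait tables")

    ref = tables[0].variants.set_index("variant_id")
    common = set(ref.index)
    for t in tables[1:]:
        common &= set(t.variants["variant_id"])
    if not common:
        raise EmptyInputError("no variant shared by all trait tables")

    order = [v for v in tables[0].variant_ids if v in common]
    ref_ea = ref.loc[order, "effect_allele"]
    ref_oa = ref.loc[order, "other_allele"]

    betas = [ref.loc[order, "beta"].to_numpy(dtype=float)]
    ses = [ref.loc[order, "se"].to_numpy(dtype=float)]
    keep = pd.Series(True, index=order)
    aligned: list[tuple[np.ndarray, np.ndarray]] = []

    for t in tables[1:]:
        tv = t.variants.set_index("variant_id").loc[order]
        same = (tv["effect_allele"] == ref_ea) & (tv["other_allele"] == ref_oa)
        swap = (tv["effect_allele"] == ref_oa) & (tv["other_allele"] == ref_ea)
        beta = np.where(swap, -tv["beta"], tv["beta"]).astype(float)
        mismatch = ~(same | swap)
        if mismatch.any():
            logger.warning(
                "harmonise: dropped %d variants with incompatible alleles vs trait %s",
                int(mismatch.sum()),
                t.trait_id,
            )
        keep &= ~mismatch
        aligned.append((beta, tv["se"].to_numpy(dtype=float)))

    mask = keep.to_numpy()
    if not mask.any():
        raise EmptyInputError("no variant with compatible alleles across all tables")
    for beta, se in aligned:
        betas.append(beta[mask])
        ses.append(se[mask])
    betas[0] = betas[0][mask]
    ses[0] = ses[0][mask]
    kept_ids = [v for v, k in zip(order, mask) if k]

    return HarmonisedSet(
        traits=[t.trait_id for t in tables],
        variant_ids=kept_ids,
        beta=np.column_stack(betas),
        se=np.column_stack(ses),
        effect_alleles=ref_ea[mask].tolist(),
        other_alleles=ref_oa[mask].tolist(),
    )


@dataclass
class InstrumentSet:
    """Clumped genome-wide-significant instruments with strength diagnostics.

    ``table`` has one row per surviving variant: ``variant_id``, ``pval``,
    ``F``, ``r2`` (per-variant variance explained), ``weak`` (F <= 10 flag)
    and ``r2_formula`` naming the variance-explained formula used.
    """

    trait_id: str
    table: pd.DataFrame
    total_r2: float
    mean_f: float

    def __len__(self) -> int:
        return len(self.table)

    @property
    def variant_ids(self) -> list[str]:
        return self.table["variant_id"].tolist()

    def to_tsv(self, path: str | Path) -> None:
        self.table.to_csv(path, sep="\t", index=False)


def greedy_clump(
    candidates: pd.DataFrame, ld: LDInfo, r2_threshold: float
) -> list[str]:
    """Greedy p-ordered clumping; ties broken by ascending variant_id.

    ``candidates`` needs ``variant_id`` and ``pval`` columns.  Repeatedly
    keeps the most significant remaining variant and discards every other
    variant in LD (r^2 >= threshold) with it.
    """
    ranked = candidates.sort_values(
        ["pval", "variant_id"], kind="mergesort"
    )["variant_id"].tolist()
    kept: list[str] = []
    while ranked:
        best = ranked.pop(0)
        kept.append(best)
        ranked = [v for v in ranked if ld.r2(best, v) < r2_threshold]
    return kept


def instrument_strength(
    variant_ids: Sequence[str], stats: SummaryStats
) -> pd.DataFrame:
    """Per-variant F statistic and variance explained for chosen instruments.

    F uses the single-variant approximation ``(beta/se)^2``.  Variance
    explained defaults to ``2*eaf*(1-eaf)*beta^2`` (trait assumed
    variance-standardised); when ``eaf`` is missing it falls back to
    ``F/(F + n - 2)``, and when both ``eaf`` and ``n`` are missing only F is
    reported (r2 = NaN) with a warning.
    """
    sub = stats.variants.set_index("variant_id").loc[list(variant_ids)]
    f_stat = (sub["beta"] / sub["se"]) ** 2
    eaf = sub["eaf"]
    n = sub["n"]
    r2_eaf = 2.0 * eaf * (1.0 - eaf) * sub["beta"] ** 2
    r2_f = f_stat / (f_stat + n - 2.0)
    r2 = r2_eaf.where(eaf.notna(), r2_f)
    formula = np.where(
        eaf.notna(), "2p(1-p)b^2", np.where(n.notna(), "F/(F+n-2)", "unavailable")
    )
    if (formula == "unavailable").any():
        logger.warning(
            "trait %s: eaf and n both missing for %d instruments; F only",
            stats.trait_id,
            int((formula == "unavailable").sum()),
        )
    out = pd.DataFrame(
        {
            "variant_id": list(variant_ids),
            "pval": sub["pval"].to_numpy(),
            "F": f_stat.to_numpy(),
            "r2": r2.to_numpy(),
            "r2_formula": formula,
        }
    )
    out["weak"] = out["F"] <= 10.0
    if out["weak"].any():
        logger.warning(
            "trait %s: %d instruments with F <= 10 (flagged, not dropped)",
            stats.trait_id,
            int(out["weak"].sum()),
        )
    return out


def select_instruments(
    stats: SummaryStats,
    ld: LDInfo,
    p_threshold: float = 5e-8,
    r2_threshold: float = 0.001,
) -> InstrumentSet:
    """Select genome-wide-significant, LD-independent instruments.

    Variants with ``pval < p_threshold`` are greedily clumped at
    ``r2_threshold`` (best p kept first) and returned with per-variant F and
    variance-explained diagnostics.
    """
    passing = stats.variants[stats.variants["pval"] < p_threshold]
    if passing.empty:
        raise EmptyInstrumentError(stats.trait_id, p_threshold)
    kept = greedy_clump(passing[["variant_id", "pval"]], ld, r2_threshold)
    table = instrument_strength(kept, stats)
    return InstrumentSet(
        trait_id=stats.trait_id,
        table=table,
        total_r2=float(np.nansum(table["r2"].to_numpy())),
        mean_f=float(table["F"].mean()),
    )


def pool_for_mvmr(
    exposure_tables: Sequence[SummaryStats],
    ld: LDInfo,
    p_threshold: float = 5e-8,
    r2_threshold: float = 0.001,
) -> InstrumentSet:
    """Pool-then-clump instruments across several exposures for MVMR.

    Variants genome-wide significant in *any* exposure are pooled; each
    variant's clumping rank is its minimum p across exposures; greedy
    clumping then proceeds as in :func:`select_instruments`.  Strength
    diagnostics are computed against the first exposure table.
    """
    if len(exposure_tables) < 2:
        raise ConfigurationError("pool_for_mvmr requires >= 2 exposure tables")
    min_p: dict[str, float] = {}
    for t in exposure_tables:
        passing = t.variants[t.variants["pval"] < p_threshold]
        for vid, p in zip(passing["variant_id"], passing["pval"]):
            if vid not in min_p or p < min_p[vid]:
                min_p[vid] = float(p)
    if not min_p:
        raise EmptyInstrumentError(
            "+".join(t.trait_id for t in exposure_tables), p_threshold
        )
    pooled = pd.DataFrame(
        {"variant_id": list(min_p.keys()), "pval": list(min_p.values())}
    )
    kept = greedy_clump(pooled, ld, r2_threshold)

    primary = exposure_tables[0]
    in_primary = [v for v in kept if v in set(primary.variant_ids)]
    table = instrument_strength(in_primary, primary) if in_primary else pd.DataFrame(
        columns=["variant_id", "pval", "F", "r2", "r2_formula", "weak"]
    )
    missing = [v for v in kept if v not in set(in_primary)]
    if missing:
        extra = pd.DataFrame(
            {
                "variant_id": missing,
                "pval": [min_p[v] for v in missing],
                "F": np.nan,
                "r2": np.nan,
                "r2_formula": "unavailable",
                "weak": False,
            }
        )
        table = pd.concat([table, extra], ignore_index=True)
    order = {v: i for i, v in enumerate(kept)}
    table = table.sort_values("variant_id", key=lambda s: s.map(order)).reset_index(
        drop=True
    )
    return InstrumentSet(
        trait_id="+".join(t.trait_id for t in exposure_tables),
        table=table,
        total_r2=float(np.nansum(table["r2"].to_numpy())),
        mean_f=float(table["F"].mean()),
    )
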