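"""cis-eQTL gene mapping, pathway over-representation, drug annotation.

Instruments are mapped to genes through a file-based cis-eQTL table
(q-value threshold, any-tissue rule by default); the resulting gene set is
tested for over-representation against GMT gene sets with a one-sided
hypergeometric test and Benjamini-Hochberg FDR control; FDR-significant
pathways are joined to a pathway-to-drug/ATC annotation table.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from pathlib import Path

import pandas as pd
from scipy.stats import hypergeom
from statsmodels.stats.multitest import multipletests

logger = logging.getLogger(__name__)


@dataclass
class EqtlTable:
    """Variant-to-gene cis-eQTL records with per-record q-values."""

    records: pd.DataFrame  # variant_id, gene_id, tissue, qval

    def __post_init__(self) -> None:
        need = {"variant_id", "gene_id", "tissue", "qval"}
        missing = need - set(self.records.columns)
        if missing:
            raise ValueError(f"eQTL table missing columns: {sorted(missing)}")
        dup = self.records.duplicated(["variant_id", "gene_id", "tissue"])
        if dup.any():
            logger.warning("eQTL table: %d duplicate records dropped", int(dup.sum()))
            self.records = self.records[~dup].reset_index(drop=True)

    @classmethod
    def from_tsv(cls, path: str | Path) -> "EqtlTable":
        return cls(pd.read_csv(path, sep="\t"))


@dataclass
class PathwayDB:
    """Flat pathway gene sets; the universe is the union of all sets."""

    pathways: dict[str, tuple[str, frozenset[str]]]  # id -> (name, genes)
    universe: frozenset[str] = field(init=False)

    def __post_init__(self) -> None:
        for pid, (_, genes) in self.pathways.items():
            if not genes:
                raise ValueError(f"pathway {pid!r} has an empty gene set")
        self.universe = frozenset().union(
            *(genes for _, genes in self.pathways.values())
        )

    @classmethod
    def from_gmt(cls, path: str | Path) -> "PathwayDB":
        """Read GMT: one pathway per line — id, description, member genes."""
        pathways: dict[str, tuple[str, frozenset[str]]] = {}
        for line in Path(path).read_text().splitlines():
            if not line.strip():
                continue
            parts = line.rstrip("\n").split("\t")
            if len(parts) < 3:
                raise ValueError(f"malformed GMT line: {line[:80]!r}")
            pathways[parts[0]] = (parts[1], frozenset(g for g in parts[2:] if g))
        return cls(pathways)


@dataclass
class EnrichmentResult:
    pathway_id: str
    name: str
    k: int  # overlap
    K: int  # pathway size
    n: int  # query size
    N: int  # universe size
    pval: float
    fdr: float = float("nan")
    drugs: list[tuple[str, str]] = field(default_factory=list)


def map_eqtl_genes(
    variant_ids: list[str],
    eqtl: EqtlTable,
    q_threshold: float = 0.05,
    tissue: str | None = None,
) -> tuple[set[str], pd.DataFrame]:
    """Genes with a significant cis-eQTL for any instrument variant.

    Returns the unique gene set (any-tissue rule unless ``tissue`` is given)
    plus the provenance rows (which variant, which tissue) behind it.
    """
    rec = eqtl.records
    hit = rec["variant_id"].isin(set(variant_ids)) & (rec["qval"] < q_threshold)
    if tissue is not None:
        hit &= rec["tissue"] == tissue
    prov = rec[hit].reset_index(drop=True)
    genes = set(prov["gene_id"])
    if not genes:
        logger.warning("map_eqtl_genes: no instrument maps to any eQTL gene")
    return genes, prov


def ora(
    genes: set[str],
    db: PathwayDB,
    fdr_threshold: float = 0.05,
    include_zero_overlap: bool = False,
) -> list[EnrichmentResult]:
    """One-sided hypergeometric over-representation with BH adjustment.

    The query is intersected with the DB universe before testing.  Each
    pathway's p is P(X >= k) for X ~ Hypergeom(N, K, n); BH is applied
    across all tested pathways.  Pathways with zero overlap are reported
    (p = 1) only when ``include_zero_overlap`` is set.
    """
    query = genes & db.universe
    if not query:
        logger.warning("ora: empty query after universe intersection")
        return []
    n = len(query)
    N = len(db.universe)
    results: list[EnrichmentResult] = []
    for pid, (name, members) in db.pathways.items():
        k = len(query & members)
        if k == 0 and not include_zero_overlap:
            continue
        K = len(members)
        p = float(hypergeom.sf(k - 1, N, K, n))
        results.append(
            EnrichmentResult(pathway_id=pid, name=name, k=k, K=K, n=n, N=N, pval=min(p, 1.0))
        )
    if results:
        fdr = multipletests([r.pval for r in results], method="fdr_bh")[1]
        for r, q in zip(results, fdr):
            r.fdr = float(q)
    results.sort(key=lambda r: (r.pval, r.pathway_id))
    _ = fdr_threshold  # significance is decided downstream
    return results


def annotate_drugs(
    results: list[EnrichmentResult],
    drug_map: pd.DataFrame,
    fdr_threshold: float = 0.05,
) -> list[EnrichmentResult]:
    """Attach (drug, ATC class) pairs to FDR-significant pathways only.

    ``drug_map`` columns: ``pathway_id``, ``drug``, ``atc_code``.  Rows whose
    pathway is absent from the results are logged and skipped.
    """
    known = {r.pathway_id for r in results}
    unknown = set(drug_map["pathway_id"]) - known
    if unknown:
        logger.info("annotate_drugs: %d drug-map pathways not in results", len(unknown))
    by_pathway: dict[str, list[tuple[str, str]]] = {}
    for row in drug_map.itertuples(index=False):
        by_pathway.setdefault(row.pathway_id, []).append((row.drug, row.atc_code))
    for r in results:
        if r.fdr < fdr_threshold:
            r.drugs = sorted(by_pathway.get(r.pathway_id, []))
        else:
            r.drugs = []
    return results


def results_frame(results: list[EnrichmentResult]) -> pd.DataFrame:
    """Tidy table of enrichment results (one row per pathway)."""
    return pd.DataFrame(
        [
            {
                "pathway_id": r.pathway_id,
                "name": r.name,
                "k": r.k,
                "K": r.K,
                "n": r.n,
                "N": r.N,
                "pval": r.pval,
                "fdr": r.fdr,
                "drugs": ";".join(f"{d}[{a}]" for d, a in r.drugs),
            }
            for r in results
        ]
    )
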