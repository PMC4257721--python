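"""Candidate-gene screening from precomputed homology hits.

Two steps: (i) restrict the DEG set to genes with at least one hit at or
below an e-value ceiling (inclusive, default 1e-5), decorating each kept
gene with its best hit; (ii) a per-catalogue-entry expression report that
compares the two libraries by RPKM fold change.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from fractions import Fraction
from pathlib import Path

from dgepair.io import (
    CATEGORIES,
    FloweringCatalogEntry,
    GeneCount,
    HomologyHit,
    LibraryPair,
)
from dgepair.stats import DiffExprRecord, TestConfig, compute_rpkm, log2_fold_change


@dataclass(frozen=True)
class CandidateRecord:
    gene_id: str
    best_hit: HomologyHit
    diff: DiffExprRecord
    category: str | None = None


@dataclass(frozen=True)
class ReportRow:
    """One catalogue entry's expression comparison (or a not-quantified stub)."""

    category: str
    gene_id: str
    homolog_name: str
    homolog_accession: str
    quantified: bool
    length_bp: int | None = None
    reads_L: int | None = None
    reads_S: int | None = None
    log2_ratio: float | None = None
    fold: float | None = None  # raw reads_S/reads_L, truncated to one decimal


def best_hit(hits: list[HomologyHit]) -> HomologyHit:
    """Lowest e-value; ties broken by highest bit score, then accession."""
    if not hits:
        raise ValueError("no hits to choose from")
    return min(hits, key=lambda h: (h.e_value, -h.bit_score, h.subject_accession))


def screen_flowering_related(
    degs: list[DiffExprRecord],
    hits: list[HomologyHit],
    e_max: float = 1e-5,
    catalog: list[FloweringCatalogEntry] | None = None,
) -> list[CandidateRecord]:
    """Keep DEGs with >= 1 hit at e-value <= e_max; one record per gene.

    The kept set is exactly {DEGs} intersected with {genes having a
    qualifying hit}; the best hit only decorates the record.
    """
    by_gene: dict[str, list[HomologyHit]] = {}
    for hit in hits:
        by_gene.setdefault(hit.query_gene_id, []).append(hit)
    categories = {e.gene_id: e.category for e in catalog} if catalog else {}

    candidates = []
    for record in degs:
        if not record.is_deg:
            continue
        qualifying = [h for h in by_gene.get(record.gene_id, []) if h.e_value <= e_max]
        if not qualifying:
            continue
        candidates.append(
            CandidateRecord(
                gene_id=record.gene_id,
                best_hit=best_hit(qualifying),
                diff=record,
                category=categories.get(record.gene_id),
            )
        )
    return candidates


def truncate_fold(reads_L: int, reads_S: int) -> float:
    """Raw reads_S/reads_L truncated (not rounded) to one decimal.

    inf when reads_L is zero and reads_S positive; exact rational arithmetic
    avoids float truncation artifacts.
    """
    if reads_L == 0:
        return math.inf if reads_S > 0 else math.nan
    return math.floor(Fraction(reads_S, reads_L) * 10) / 10


def flowering_time_report(
    catalog: list[FloweringCatalogEntry],
    counts: list[GeneCount],
    libs: LibraryPair,
    config: TestConfig = TestConfig(),
) -> list[ReportRow]:
    """One row per catalogue entry, grouped by category in catalogue order.

    Entries absent from the counts table yield a not-quantified stub row
    rather than an error.
    """
    by_gene = {c.gene_id: c for c in counts}
    rows: list[ReportRow] = []
    order = {cat: i for i, cat in enumerate(CATEGORIES)}
    for entry in sorted(catalog, key=lambda e: order[e.category]):
        gene = by_gene.get(entry.gene_id)
        if gene is None:
            rows.append(
                ReportRow(
                    category=entry.category,
                    gene_id=entry.gene_id,
                    homolog_name=entry.homolog_name,
                    homolog_accession=entry.homolog_accession,
                    quantified=False,
                )
            )
            continue
        rpkm_l = compute_rpkm(
            gene.reads_L, gene.length_bp, libs.total_reads_L, scale=config.rpkm_scale
        )
        rpkm_s = compute_rpkm(
            gene.reads_S, gene.length_bp, libs.total_reads_S, scale=config.rpkm_scale
        )
        rows.append(
            ReportRow(
                category=entry.category,
                gene_id=entry.gene_id,
                homolog_name=entry.homolog_name,
                homolog_accession=entry.homolog_accession,
                quantified=True,
                length_bp=gene.length_bp,
                reads_L=gene.reads_L,
                reads_S=gene.reads_S,
                log2_ratio=log2_fold_change(rpkm_l, rpkm_s, config.zero_substitute),
                fold=truncate_fold(gene.reads_L, gene.reads_S),
            )
        )
    return rows


CANDIDATE_COLUMNS = (
    "gene_id",
    "category",
    "subject_accession",
    "percent_identity",
    "e_value",
    "bit_score",
    "log2_ratio",
    "fdr",
    "direction",
)

REPORT_COLUMNS = (
    "category",
    "gene_id",
    "length_bp",
    "reads_L",
    "reads_S",
    "log2_ratio",
    "fold",
    "homolog_name",
    "homolog_accession",
    "status",
)


def write_candidates(candidates: list[CandidateRecord], path) -> None:
    with Path(path).open("w", newline="") as fh:
        fh.write("\t".join(CANDIDATE_COLUMNS) + "\n")
        for c in candidates:
            fh.write(
                "\t".join(
                    [
                        c.gene_id,
                        c.category or "NA",
                        c.best_hit.subject_accession,
                        f"{c.best_hit.percent_identity:.1f}",
                        f"{c.best_hit.e_value:.4g}",
                        f"{c.best_hit.bit_score:.1f}",
                        f"{c.diff.log2_ratio:.4f}",
                        f"{c.diff.fdr:.4g}",
                        c.diff.direction,
                    ]
                )
                + "\n"
            )


def _fmt_fold(fold: float | None) -> str:
    if fold is None or (isinstance(fold, float) and math.isnan(fold)):
        return "NA"
    if math.isinf(fold):
        return "inf"
    return f"{fold:.1f}"


def format_report(rows: list[ReportRow]) -> str:
    lines = ["\t".join(REPORT_COLUMNS)]
    for r in rows:
        if r.quantified:
            fields = [
                r.category,
                r.gene_id,
                str(r.length_bp),
                str(r.reads_L),
                str(r.reads_S),
                f"{r.log2_ratio:.4f}",
                _fmt_fold(r.fold),
                r.homolog_name,
                r.homolog_accession,
                "ok",
            ]
        else:
            fields = [
                r.category,
                r.gene_id,
                "NA",
                "NA",
                "NA",
                "NA",
                "NA",
                r.homolog_name,
                r.homolog_accession,
                "not quantified",
            ]
        lines.append("\t".join(fields))
    return "\n".join(lines) + "\n"


def write_report(rows: list[ReportRow], path) -> None:
    Path(path).write_text(format_report(rows))
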