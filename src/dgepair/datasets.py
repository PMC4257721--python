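"""Bundled reference dataset: a 107-entry flowering-time gene catalogue with
published per-gene read counts, gene lengths, log2 RPKM ratios, and homology
hit metadata, plus the two libraries' total clean-read counts.

Recomputing the log2 ratios from these counts with the bundled clean-read
totals reproduces every published value up to a shared constant offset of
about +0.051 (the original computation evidently used slightly smaller,
unpublished library totals). See the candidate-screen tests for the
constant-offset property.
"""

from __future__ import annotations

import csv
from dataclasses import dataclass
from importlib import resources

from dgepair.io import FloweringCatalogEntry, GeneCount, HomologyHit, LibraryPair

#: Total clean reads of the two libraries the reference counts came from.
REFERENCE_TOTAL_L = 25_603_968
REFERENCE_TOTAL_S = 27_723_240


def reference_library_pair() -> LibraryPair:
    return LibraryPair("L", "S", REFERENCE_TOTAL_L, REFERENCE_TOTAL_S)


@dataclass(frozen=True)
class ReferenceRow:
    category: str
    gene_id: str
    length_bp: int
    reads_L: int
    reads_S: int
    log2_printed: float
    accession: str
    identity_pct: float
    e_value: float
    homolog_name: str


def load_reference_rows() -> list[ReferenceRow]:
    text = (
        resources.files("dgepair.data")
        .joinpath("flowering_time_reference.tsv")
        .read_text()
    )
    rows = []
    reader = csv.DictReader(text.splitlines(), delimiter="\t")
    for rec in reader:
        rows.append(
            ReferenceRow(
                category=rec["category"],
                gene_id=rec["gene_id"],
                length_bp=int(rec["length_bp"]),
                reads_L=int(rec["reads_L"]),
                reads_S=int(rec["reads_S"]),
                log2_printed=float(rec["log2_printed"].replace("−", "-")),
                accession=rec["accession"],
                identity_pct=float(rec["identity_pct"]),
                e_value=float(rec["e_value"]),
                homolog_name=rec["homolog_name"],
            )
        )
    return rows


def reference_counts() -> tuple[list[GeneCount], LibraryPair]:
    counts = [
        GeneCount(r.gene_id, r.length_bp, r.reads_L, r.reads_S)
        for r in load_reference_rows()
    ]
    return counts, reference_library_pair()


def reference_catalog() -> list[FloweringCatalogEntry]:
    return [
        FloweringCatalogEntry(
            gene_id=r.gene_id,
            category=r.category,
            homolog_name=r.homolog_name,
            homolog_accession=r.accession,
        )
        for r in load_reference_rows()
    ]


def reference_hits() -> list[HomologyHit]:
    """The catalogue's hit metadata as homology-hit records (alignment
    coordinates are not published and default to zero)."""
    return [
        HomologyHit(
            query_gene_id=r.gene_id,
            subject_accession=r.accession,
            percent_identity=r.identity_pct,
            alignment_length=0,
            e_value=r.e_value,
            bit_score=0.0,
            subject_description=r.homolog_name,
        )
        for r in load_reference_rows()
    ]


def reference_printed_log2() -> dict[str, float]:
    return {r.gene_id: r.log2_printed for r in load_reference_rows()}
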