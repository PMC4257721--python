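"""Typed tabular I/O for two-library count experiments.

All on-disk formats are plain TSV. Counts tables carry their library totals
either in ``#total_L=`` / ``#total_S=`` header comment lines or via explicit
arguments (arguments win). Homology hits use the conventional 12-column
tabular alignment dialect (qseqid sseqid pident length mismatch gapopen
qstart qend sstart send evalue bitscore).

Real numbers are serialized with four decimals (p-values with four
significant digits); full precision is retained in memory. The U+2212 minus
sign occasionally found in published tables is normalized to ASCII ``-`` on
input.
"""

from __future__ import annotations

import csv
import dataclasses
import math
from dataclasses import dataclass
from pathlib import Path
from typing import Iterable, Sequence

NAMESPACES = (
    "biological_process",
    "cellular_component",
    "molecular_function",
    "pathway",
)

#: The six functional categories of the flowering-time catalogue, in report order.
CATEGORIES = (
    "circadian clock & photoperiod",
    "vernalization",
    "autonomous",
    "GA",
    "age-related",
    "floral pathway integrator",
)

COUNT_COLUMNS = ("gene_id", "length_bp", "reads_L", "reads_S")
ANNOTATION_COLUMNS = ("gene_id", "term_id", "term_name", "namespace")
CATALOG_COLUMNS = ("gene_id", "category", "homolog_name", "homolog_accession")
RESULT_COLUMNS = (
    "gene_id",
    "length_bp",
    "reads_L",
    "reads_S",
    "rpkm_L",
    "rpkm_S",
    "log2_ratio",
    "p_value",
    "fdr",
    "direction",
    "is_deg",
)


class ParseError(ValueError):
    """Raised on malformed input; carries the file and 1-based line number."""

    def __init__(self, path, line: int, message: str):
        self.path = str(path)
        self.line = line
        super().__init__(f"{path}:{line}: {message}")


def _normalize(token: str) -> str:
    # U+2212 (minus sign) -> ASCII hyphen-minus
    return token.strip().replace("−", "-")


def _parse_int(token: str, *, path, line, field, minimum=None) -> int:
    token = _normalize(token)
    try:
        value = int(token)
    except ValueError:
        raise ParseError(path, line, f"field {field!r}: {token!r} is not an integer")
    if minimum is not None and value < minimum:
        raise ParseError(path, line, f"field {field!r}: {value} < {minimum}")
    return value


def _parse_float(token: str, *, path, line, field, minimum=None) -> float:
    token = _normalize(token)
    try:
        value = float(token)
    except ValueError:
        raise ParseError(path, line, f"field {field!r}: {token!r} is not a number")
    if minimum is not None and value < minimum:
        raise ParseError(path, line, f"field {field!r}: {value} < {minimum}")
    return value


# ---------------------------------------------------------------------------
# Domain types
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class LibraryPair:
    """The two libraries being compared and their total read counts (N1, N2)."""

    label_L: str
    label_S: str
    total_reads_L: int
    total_reads_S: int

    def __post_init__(self):
        if not self.label_L or not self.label_S:
            raise ValueError("library labels must be non-empty")
        if self.label_L == self.label_S:
            raise ValueError("library labels must be distinct")
        if self.total_reads_L < 1 or self.total_reads_S < 1:
            raise ValueError("library totals must be >= 1")


@dataclass(frozen=True)
class GeneCount:
    """One gene's length and its read counts in the two libraries (x, y)."""

    gene_id: str
    length_bp: int
    reads_L: int
    reads_S: int

    def __post_init__(self):
        if not self.gene_id:
            raise ValueError("gene_id must be non-empty")
        if self.length_bp < 1:
            raise ValueError(f"{self.gene_id}: length_bp must be >= 1")
        if self.reads_L < 0 or self.reads_S < 0:
            raise ValueError(f"{self.gene_id}: read counts must be >= 0")


@dataclass(frozen=True)
class TermInfo:
    term_id: str
    name: str
    namespace: str

    def __post_init__(self):
        if self.namespace not in NAMESPACES:
            raise ValueError(f"unknown namespace {self.namespace!r}")


@dataclass
class AnnotationMap:
    """gene -> set of term ids, plus metadata for every term."""

    gene_terms: dict[str, frozenset[str]]
    terms: dict[str, TermInfo]

    def __post_init__(self):
        for gene, terms in self.gene_terms.items():
            for term in terms:
                if term not in self.terms:
                    raise ValueError(f"term {term!r} (gene {gene!r}) has no metadata")

    def annotated_genes(self) -> set[str]:
        return {g for g, t in self.gene_terms.items() if t}

    def terms_for(self, gene_id: str) -> frozenset[str]:
        return self.gene_terms.get(gene_id, frozenset())

    def genes_for_term(self, term_id: str) -> set[str]:
        return {g for g, t in self.gene_terms.items() if term_id in t}

    def __len__(self) -> int:
        return len(self.gene_terms)


@dataclass(frozen=True)
class HomologyHit:
    """One row of a 12-column tabular alignment file."""

    query_gene_id: str
    subject_accession: str
    percent_identity: float
    alignment_length: int
    mismatches: int = 0
    gap_opens: int = 0
    q_start: int = 0
    q_end: int = 0
    s_start: int = 0
    s_end: int = 0
    e_value: float = 0.0
    bit_score: float = 0.0
    subject_description: str = ""

    def __post_init__(self):
        if self.e_value < 0:
            raise ValueError("e_value must be >= 0")
        if not 0.0 <= self.percent_identity <= 100.0:
            raise ValueError("percent_identity must be in [0, 100]")


@dataclass(frozen=True)
class FloweringCatalogEntry:
    """A catalogued homologue of a known floral regulator."""

    gene_id: str
    category: str
    homolog_name: str
    homolog_accession: str

    def __post_init__(self):
        if self.category not in CATEGORIES:
            raise ValueError(
                f"category {self.category!r} not one of {CATEGORIES}"
            )


# ---------------------------------------------------------------------------
# Counts
# ---------------------------------------------------------------------------


def read_counts(
    path,
    *,
    total_L: int | None = None,
    total_S: int | None = None,
    label_L: str = "L",
    label_S: str = "S",
) -> tuple[list[GeneCount], LibraryPair]:
    """Read a counts TSV; returns the rows in file order plus the library pair.

    Totals come from ``#total_L=`` / ``#total_S=`` header comments unless
    overridden by the keyword arguments (which win).
    """
    path = Path(path)
    header_totals: dict[str, int] = {}
    counts: list[GeneCount] = []
    seen: set[str] = set()
    columns = None
    with path.open(newline="") as fh:
        for lineno, raw in enumerate(fh, start=1):
            line = raw.rstrip("\n")
            if not line:
                continue
            if line.startswith("#"):
                body = line[1:].strip()
                if "=" in body:
                    key, _, value = body.partition("=")
                    key = key.strip()
                    if key in ("total_L", "total_S"):
                        header_totals[key] = _parse_int(
                            value, path=path, line=lineno, field=key, minimum=1
                        )
                continue
            fields = line.split("\t")
            if columns is None:
                columns = fields
                missing = [c for c in COUNT_COLUMNS if c not in columns]
                if missing:
                    raise ParseError(path, lineno, f"missing columns: {missing}")
                idx = {c: columns.index(c) for c in COUNT_COLUMNS}
                continue
            if len(fields) != len(columns):
                raise ParseError(
                    path, lineno, f"expected {len(columns)} columns, got {len(fields)}"
                )
            gene_id = fields[idx["gene_id"]].strip()
            if gene_id in seen:
                raise ParseError(path, lineno, f"duplicate gene_id {gene_id!r}")
            seen.add(gene_id)
            try:
                record = GeneCount(
                    gene_id=gene_id,
                    length_bp=_parse_int(
                        fields[idx["length_bp"]],
                        path=path, line=lineno, field="length_bp", minimum=1,
                    ),
                    reads_L=_parse_int(
                        fields[idx["reads_L"]],
                        path=path, line=lineno, field="reads_L", minimum=0,
                    ),
                    reads_S=_parse_int(
                        fields[idx["reads_S"]],
                        path=path, line=lineno, field="reads_S", minimum=0,
                    ),
                )
            except ParseError:
                raise
            except ValueError as exc:
                raise ParseError(path, lineno, str(exc))
            counts.append(record)
    if columns is None:
        raise ParseError(path, 0, "empty counts file (no header)")
    n1 = total_L if total_L is not None else header_totals.get("total_L")
    n2 = total_S if total_S is not None else header_totals.get("total_S")
    if n1 is None or n2 is None:
        raise ParseError(
            path, 0, "library totals missing: supply #total_L=/#total_S= or arguments"
        )
    return counts, LibraryPair(label_L, label_S, n1, n2)


def write_counts(counts: Sequence[GeneCount], libs: LibraryPair, path) -> None:
    path = Path(path)
    with path.open("w", newline="") as fh:
        fh.write(f"#total_L={libs.total_reads_L}\n")
        fh.write(f"#total_S={libs.total_reads_S}\n")
        fh.write("\t".join(COUNT_COLUMNS) + "\n")
        for c in counts:
            fh.write(f"{c.gene_id}\t{c.length_bp}\t{c.reads_L}\t{c.reads_S}\n")


# ---------------------------------------------------------------------------
# Annotations
# ---------------------------------------------------------------------------


def read_annotations(path) -> AnnotationMap:
    """Read a gene_id/term_id/term_name/namespace TSV into an AnnotationMap.

    Duplicate (gene, term) rows collapse to a single membership.
    """
    path = Path(path)
    gene_terms: dict[str, set[str]] = {}
    terms: dict[str, TermInfo] = {}
    with path.open(newline="") as fh:
        reader = csv.reader(fh, delimiter="\t")
        header = None
        for lineno, fields in enumerate(reader, start=1):
            if not fields or (len(fields) == 1 and not fields[0].strip()):
                continue
            if fields[0].startswith("#"):
                continue
            if header is None:
                header = fields
                missing = [c for c in ANNOTATION_COLUMNS if c not in header]
                if missing:
                    raise ParseError(path, lineno, f"missing columns: {missing}")
                idx = {c: header.index(c) for c in ANNOTATION_COLUMNS}
                continue
            if len(fields) != len(header):
                raise ParseError(
                    path, lineno, f"expected {len(header)} columns, got {len(fields)}"
                )
            gene = fields[idx["gene_id"]].strip()
            term = fields[idx["term_id"]].strip()
            name = fields[idx["term_name"]].strip()
            namespace = fields[idx["namespace"]].strip()
            if namespace not in NAMESPACES:
                raise ParseError(
                    path, lineno,
                    f"unknown namespace {namespace!r}; expected one of {NAMESPACES}",
                )
            terms.setdefault(term, TermInfo(term, name, namespace))
            gene_terms.setdefault(gene, set()).add(term)
    if header is None:
        raise ParseError(path, 0, "empty annotation file (no header)")
    return AnnotationMap(
        gene_terms={g: frozenset(t) for g, t in gene_terms.items()},
        terms=terms,
    )


def write_annotations(annotations: AnnotationMap, path) -> None:
    path = Path(path)
    with path.open("w", newline="") as fh:
        fh.write("\t".join(ANNOTATION_COLUMNS) + "\n")
        for gene in sorted(annotations.gene_terms):
            for term in sorted(annotations.gene_terms[gene]):
                info = annotations.terms[term]
                fh.write(f"{gene}\t{term}\t{info.name}\t{info.namespace}\n")


# ---------------------------------------------------------------------------
# Homology hits (12-column tabular alignment dialect)
# ---------------------------------------------------------------------------


def read_hits(path) -> list[HomologyHit]:
    """Read 12-column tab-separated alignment rows (no header)."""
    path = Path(path)
    hits: list[HomologyHit] = []
    with path.open(newline="") as fh:
        for lineno, raw in enumerate(fh, start=1):
            line = raw.rstrip("\n")
            if not line or line.startswith("#"):
                continue
            fields = line.split("\t")
            if len(fields) != 12:
                raise ParseError(
                    path, lineno, f"expected 12 columns, got {len(fields)}"
                )
            try:
                hit = HomologyHit(
                    query_gene_id=fields[0].strip(),
                    subject_accession=fields[1].strip(),
                    percent_identity=_parse_float(
                        fields[2], path=path, line=lineno, field="pident", minimum=0
                    ),
                    alignment_length=_parse_int(
                        fields[3], path=path, line=lineno, field="length", minimum=0
                    ),
                    mismatches=_parse_int(
                        fields[4], path=path, line=lineno, field="mismatch", minimum=0
                    ),
                    gap_opens=_parse_int(
                        fields[5], path=path, line=lineno, field="gapopen", minimum=0
                    ),
                    q_start=_parse_int(fields[6], path=path, line=lineno, field="qstart"),
                    q_end=_parse_int(fields[7], path=path, line=lineno, field="qend"),
                    s_start=_parse_int(fields[8], path=path, line=lineno, field="sstart"),
                    s_end=_parse_int(fields[9], path=path, line=lineno, field="send"),
                    e_value=_parse_float(
                        fields[10], path=path, line=lineno, field="evalue", minimum=0
                    ),
                    bit_score=_parse_float(
                        fields[11], path=path, line=lineno, field="bitscore"
                    ),
                )
            except ParseError:
                raise
            except ValueError as exc:
                raise ParseError(path, lineno, str(exc))
            hits.append(hit)
    return hits


def write_hits(hits: Iterable[HomologyHit], path) -> None:
    path = Path(path)
    with path.open("w", newline="") as fh:
        for h in hits:
            fh.write(
                "\t".join(
                    [
                        h.query_gene_id,
                        h.subject_accession,
                        _fmt_float(h.percent_identity),
                        str(h.alignment_length),
                        str(h.mismatches),
                        str(h.gap_opens),
                        str(h.q_start),
                        str(h.q_end),
                        str(h.s_start),
                        str(h.s_end),
                        _fmt_pvalue(h.e_value),
                        _fmt_float(h.bit_score),
                    ]
                )
                + "\n"
            )


# ---------------------------------------------------------------------------
# Flowering catalogue
# ---------------------------------------------------------------------------


def read_catalog(path) -> list[FloweringCatalogEntry]:
    path = Path(path)
    entries: list[FloweringCatalogEntry] = []
    with path.open(newline="") as fh:
        reader = csv.reader(fh, delimiter="\t")
        header = None
        for lineno, fields in enumerate(reader, start=1):
            if not fields or fields[0].startswith("#"):
                continue
            if header is None:
                header = fields
                missing = [c for c in CATALOG_COLUMNS if c not in header]
                if missing:
                    raise ParseError(path, lineno, f"missing columns: {missing}")
                idx = {c: header.index(c) for c in CATALOG_COLUMNS}
                continue
            if len(fields) != len(header):
                raise ParseError(
                    path, lineno, f"expected {len(header)} columns, got {len(fields)}"
                )
            try:
                entries.append(
                    FloweringCatalogEntry(
                        gene_id=fields[idx["gene_id"]].strip(),
                        category=fields[idx["category"]].strip(),
                        homolog_name=fields[idx["homolog_name"]].strip(),
                        homolog_accession=fields[idx["homolog_accession"]].strip(),
                    )
                )
            except ValueError as exc:
                raise ParseError(path, lineno, str(exc))
    if header is None:
        raise ParseError(path, 0, "empty catalogue file (no header)")
    return entries


def write_catalog(entries: Iterable[FloweringCatalogEntry], path) -> None:
    path = Path(path)
    with path.open("w", newline="") as fh:
        fh.write("\t".join(CATALOG_COLUMNS) + "\n")
        for e in entries:
            fh.write(
                f"{e.gene_id}\t{e.category}\t{e.homolog_name}\t{e.homolog_accession}\n"
            )


# ---------------------------------------------------------------------------
# Differential-expression results
# ---------------------------------------------------------------------------


def _fmt_float(value: float) -> str:
    """Fixed-point rendering with 4 decimals (half-even not needed; round-half-away
    via printf is what the published tables use)."""
    if math.isinf(value):
        return "inf" if value > 0 else "-inf"
    return f"{value:.4f}"


def _fmt_pvalue(value: float) -> str:
    # p-values / e-values span many decades; 4 significant digits instead of
    # 4 decimals so small probabilities survive a round trip
    return f"{value:.4g}"


def write_results(records, path) -> None:
    """Write DiffExprRecords as a TSV; reals at 4 decimals, p/fdr at 4 sig. digits."""
    path = Path(path)
    with path.open("w", newline="") as fh:
        fh.write("\t".join(RESULT_COLUMNS) + "\n")
        for r in records:
            fh.write(
                "\t".join(
                    [
                        r.gene_id,
                        str(r.length_bp),
                        str(r.reads_L),
                        str(r.reads_S),
                        _fmt_float(r.rpkm_L),
                        _fmt_float(r.rpkm_S),
                        _fmt_float(r.log2_ratio),
                        _fmt_pvalue(r.p_value),
                        _fmt_pvalue(r.fdr),
                        r.direction,
                        "true" if r.is_deg else "false",
                    ]
                )
                + "\n"
            )


def read_results(path):
    """Read a results TSV written by :func:`write_results`."""
    from dgepair.stats import DiffExprRecord  # deferred: avoids import cycle

    path = Path(path)
    records = []
    with path.open(newline="") as fh:
        header = None
        for lineno, raw in enumerate(fh, start=1):
            line = raw.rstrip("\n")
            if not line or line.startswith("#"):
                continue
            fields = line.split("\t")
            if header is None:
                header = fields
                missing = [c for c in RESULT_COLUMNS if c not in header]
                if missing:
                    raise ParseError(path, lineno, f"missing columns: {missing}")
                idx = {c: header.index(c) for c in RESULT_COLUMNS}
                continue
            if len(fields) != len(header):
                raise ParseError(
                    path, lineno, f"expected {len(header)} columns, got {len(fields)}"
                )
            direction = fields[idx["direction"]].strip()
            if direction not in ("up", "down", "none"):
                raise ParseError(path, lineno, f"bad direction {direction!r}")
            flag = fields[idx["is_deg"]].strip().lower()
            if flag not in ("true", "false"):
                raise ParseError(path, lineno, f"bad is_deg flag {flag!r}")
            try:
                records.append(
                    DiffExprRecord(
                        gene_id=fields[idx["gene_id"]].strip(),
                        length_bp=_parse_int(
                            fields[idx["length_bp"]],
                            path=path, line=lineno, field="length_bp", minimum=1,
                        ),
                        reads_L=_parse_int(
                            fields[idx["reads_L"]],
                            path=path, line=lineno, field="reads_L", minimum=0,
                        ),
                        reads_S=_parse_int(
                            fields[idx["reads_S"]],
                            path=path, line=lineno, field="reads_S", minimum=0,
                        ),
                        rpkm_L=_parse_float(
                            fields[idx["rpkm_L"]],
                            path=path, line=lineno, field="rpkm_L", minimum=0,
                        ),
                        rpkm_S=_parse_float(
                            fields[idx["rpkm_S"]],
                            path=path, line=lineno, field="rpkm_S", minimum=0,
                        ),
                        log2_ratio=_parse_float(
                            fields[idx["log2_ratio"]],
                            path=path, line=lineno, field="log2_ratio",
                        ),
                        p_value=_parse_float(
                            fields[idx["p_value"]],
                            path=path, line=lineno, field="p_value", minimum=0,
                        ),
                        fdr=_parse_float(
                            fields[idx["fdr"]],
                            path=path, line=lineno, field="fdr", minimum=0,
                        ),
                        direction=direction,
                        is_deg=(flag == "true"),
                    )
                )
            except ParseError:
                raise
            except ValueError as exc:
                raise ParseError(path, lineno, str(exc))
    if header is None:
        raise ParseError(path, 0, "empty results file (no header)")
    return records


def round_tripped(record):
    """The record as it would read back after serialization (reals at rendered
    precision). Useful for round-trip assertions."""
    return dataclasses.replace(
        record,
        rpkm_L=float(_fmt_float(record.rpkm_L)),
        rpkm_S=float(_fmt_float(record.rpkm_S)),
        log2_ratio=float(_fmt_float(record.log2_ratio)),
        p_value=float(_fmt_pvalue(record.p_value)),
        fdr=float(_fmt_pvalue(record.fdr)),
    )
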