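"""Term over-representation of a DEG set against an annotated background.

The per-term p-value is the upper tail of the hypergeometric distribution:
the probability that at least the observed number of DEGs carry the term,
given the term's background frequency. Adjustment is Benjamini–Hochberg or
Bonferroni across the tested terms.
"""

from __future__ import annotations

from dataclasses import dataclass

from scipy.stats import hypergeom

from dgepair.io import AnnotationMap
from dgepair.stats import bh_fdr

CORRECTIONS = ("bh", "bonferroni")


@dataclass(frozen=True)
class EnrichmentRecord:
    term_id: str
    term_name: str
    namespace: str
    m: int  # DEGs annotated to the term
    n: int  # DEGs with any annotation
    M: int  # background genes annotated to the term
    N: int  # background genes with any annotation
    p_value: float
    adjusted_p: float
    enriched: bool

    def __post_init__(self):
        if not (0 <= self.m <= min(self.n, self.M)):
            raise ValueError("require 0 <= m <= min(n, M)")
        if self.n > self.N or self.M > self.N:
            raise ValueError("require n <= N and M <= N")
        if self.adjusted_p < self.p_value - 1e-12:
            raise ValueError("adjusted_p must be >= p_value")


def hypergeom_enrichment_p(m: int, n: int, M: int, N: int) -> float:
    """P(X >= m) for X hypergeometric with population N, M marked, n drawn."""
    if not (0 <= m <= min(n, M) and 0 <= n <= N and 0 <= M <= N):
        raise ValueError(f"invalid hypergeometric counts m={m} n={n} M={M} N={N}")
    if m == 0:
        return 1.0
    return float(hypergeom.sf(m - 1, N, M, n))


def enrich_terms(
    degs: set[str],
    annotations: AnnotationMap,
    background: set[str] | None = None,
    namespace: str | None = None,
    correction: str = "bh",
    alpha: float = 0.05,
) -> list[EnrichmentRecord]:
    """Score every term present in the annotated background.

    ``background`` defaults to all annotated genes; both it and the DEG set
    are restricted to genes carrying at least one annotation. Records are
    sorted by adjusted p (ties by term id); ``enriched`` means
    ``adjusted_p <= alpha``.
    """
    if correction not in CORRECTIONS:
        raise ValueError(f"correction must be one of {CORRECTIONS}")
    annotated = annotations.annotated_genes()
    bg = annotated if background is None else (set(background) & annotated)
    if not bg:
        raise ValueError("background contains no annotated genes")
    deg_bg = set(degs) & bg

    term_genes: dict[str, set[str]] = {}
    for gene in bg:
        for term in annotations.terms_for(gene):
            info = annotations.terms[term]
            if namespace is not None and info.namespace != namespace:
                continue
            term_genes.setdefault(term, set()).add(gene)

    if not term_genes:
        return []

    N = len(bg)
    n = len(deg_bg)
    term_ids = sorted(term_genes)
    raw = []
    for term in term_ids:
        members = term_genes[term]
        raw.append(hypergeom_enrichment_p(len(members & deg_bg), n, len(members), N))

    if correction == "bh":
        adjusted = bh_fdr(raw)
    else:
        k = len(raw)
        adjusted = [min(1.0, p * k) for p in raw]

    records = []
    for term, p, q in zip(term_ids, raw, adjusted):
        info = annotations.terms[term]
        members = term_genes[term]
        records.append(
            EnrichmentRecord(
                term_id=term,
                term_name=info.name,
                namespace=info.namespace,
                m=len(members & deg_bg),
                n=n,
                M=len(members),
                N=N,
                p_value=float(p),
                adjusted_p=float(q),
                enriched=bool(q <= alpha),
            )
        )
    records.sort(key=lambda r: (r.adjusted_p, r.term_id))
    return records


ENRICHMENT_COLUMNS = (
    "term_id",
    "term_name",
    "namespace",
    "m",
    "n",
    "M",
    "N",
    "p_value",
    "adjusted_p",
    "enriched",
)


def write_enrichment(records, path) -> None:
    from pathlib import Path

    with Path(path).open("w", newline="") as fh:
        fh.write("\t".join(ENRICHMENT_COLUMNS) + "\n")
        for r in records:
            fh.write(
                "\t".join(
                    [
                        r.term_id,
                        r.term_name,
                        r.namespace,
                        str(r.m),
                        str(r.n),
                        str(r.M),
                        str(r.N),
                        f"{r.p_value:.4g}",
                        f"{r.adjusted_p:.4g}",
                        "true" if r.enriched else "false",
                    ]
                )
                + "\n"
            )
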