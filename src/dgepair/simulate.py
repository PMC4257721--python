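"""Synthetic two-library count experiments with known ground truth.

Baseline gene abundances are log-normal (heavy-tailed, mimicking the spread
of real per-gene read counts), normalized to proportions. A configurable
fraction of genes receives a true log2 effect, split evenly between up- and
down-regulation (odd remainder goes up). Counts are Poisson at dispersion 0
and gamma-mixed Poisson (negative binomial, var = mu + d*mu^2) otherwise.
The same spec and seed always produce bit-identical tables.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np

from dgepair.io import (
    CATEGORIES,
    NAMESPACES,
    AnnotationMap,
    FloweringCatalogEntry,
    GeneCount,
    HomologyHit,
    LibraryPair,
    TermInfo,
)

_GO_NAMESPACES = ("biological_process", "cellular_component", "molecular_function")


@dataclass(frozen=True)
class SyntheticSpec:
    n_genes: int
    total_reads_L: int = 25_603_968
    total_reads_S: int = 27_723_240
    de_fraction: float = 0.0
    effect_log2: float = 2.0
    dispersion: float = 0.0
    length_range_bp: tuple[int, int] = (200, 3000)
    proportion_sigma: float = 1.0  # log-normal sd of baseline abundances
    up_fraction: float = 0.5
    n_terms: int = 0
    term_size_range: tuple[int, int] = (10, 100)
    planted_term_size: int = 0
    planted_odds_ratio: float = 1.0
    hit_fraction: float = 0.0
    n_catalog: int = 0
    seed: int = 0

    def __post_init__(self):
        if self.n_genes < 1:
            raise ValueError("n_genes must be >= 1")
        if self.total_reads_L < 1 or self.total_reads_S < 1:
            raise ValueError("library totals must be >= 1")
        if not 0.0 <= self.de_fraction < 1.0:
            raise ValueError("de_fraction must be in [0, 1)")
        if self.effect_log2 <= 0:
            raise ValueError("effect_log2 must be > 0")
        if self.dispersion < 0:
            raise ValueError("dispersion must be >= 0")
        lo, hi = self.length_range_bp
        if lo < 1 or hi < lo:
            raise ValueError("bad length_range_bp")
        if not 0.0 <= self.up_fraction <= 1.0:
            raise ValueError("up_fraction must be in [0, 1]")


@dataclass
class GroundTruth:
    gene_ids: list[str]
    effect_log2: np.ndarray
    is_de: np.ndarray
    baseline_proportion: np.ndarray

    def __post_init__(self):
        if not np.array_equal(self.is_de, self.effect_log2 != 0):
            raise ValueError("is_de must mark exactly the genes with nonzero effect")

    def de_genes(self) -> set[str]:
        return {g for g, flag in zip(self.gene_ids, self.is_de) if flag}


@dataclass(frozen=True)
class EnrichmentTruth:
    planted_term_id: str | None
    odds_ratio: float
    enriched: bool  # true iff a term was planted with odds ratio > 1


def _gene_ids(n: int) -> list[str]:
    width = max(5, len(str(n)))
    return [f"G{i:0{width}d}" for i in range(1, n + 1)]


def generate_counts(
    spec: SyntheticSpec,
) -> tuple[list[GeneCount], LibraryPair, GroundTruth]:
    rng = np.random.default_rng([spec.seed, 0])
    n = spec.n_genes

    baseline = rng.lognormal(mean=0.0, sigma=spec.proportion_sigma, size=n)
    proportions = baseline / baseline.sum()

    n_de = int(round(spec.de_fraction * n))
    n_up = math.ceil(n_de * spec.up_fraction)  # odd remainder goes up
    effects = np.zeros(n)
    de_idx = rng.choice(n, size=n_de, replace=False)
    effects[de_idx[:n_up]] = spec.effect_log2
    effects[de_idx[n_up:]] = -spec.effect_log2

    mu_L = proportions * spec.total_reads_L
    weight_S = proportions * np.exp2(effects)
    mu_S = weight_S / weight_S.sum() * spec.total_reads_S

    if spec.dispersion == 0:
        reads_L = rng.poisson(mu_L)
        reads_S = rng.poisson(mu_S)
    else:
        shape = 1.0 / spec.dispersion
        reads_L = rng.poisson(rng.gamma(shape, mu_L * spec.dispersion))
        reads_S = rng.poisson(rng.gamma(shape, mu_S * spec.dispersion))

    lo, hi = spec.length_range_bp
    lengths = rng.integers(lo, hi + 1, size=n)

    ids = _gene_ids(n)
    counts = [
        GeneCount(ids[i], int(lengths[i]), int(reads_L[i]), int(reads_S[i]))
        for i in range(n)
    ]
    libs = LibraryPair("L", "S", spec.total_reads_L, spec.total_reads_S)
    truth = GroundTruth(
        gene_ids=ids,
        effect_log2=effects,
        is_de=effects != 0,
        baseline_proportion=proportions,
    )
    return counts, libs, truth


def generate_annotations(
    gene_ids: list[str],
    spec: SyntheticSpec,
    truth: GroundTruth | None = None,
) -> tuple[AnnotationMap, EnrichmentTruth]:
    """Random term assignments, optionally with one term planted to be
    over-represented among the true-DE genes at the configured odds ratio."""
    if not gene_ids:
        raise ValueError("gene_ids must be non-empty")
    rng = np.random.default_rng([spec.seed, 1])
    n = len(gene_ids)
    lo, hi = spec.term_size_range
    if spec.n_terms > 0 and hi > n:
        raise ValueError("term sizes exceed the number of genes available")

    genes = np.asarray(gene_ids)
    gene_terms: dict[str, set[str]] = {g: set() for g in gene_ids}
    terms: dict[str, TermInfo] = {}

    for t in range(spec.n_terms):
        term_id = f"T{t + 1:04d}"
        size = int(rng.integers(lo, hi + 1))
        members = rng.choice(n, size=size, replace=False)
        namespace = _GO_NAMESPACES[t % len(_GO_NAMESPACES)]
        terms[term_id] = TermInfo(term_id, f"term {t + 1}", namespace)
        for i in members:
            gene_terms[genes[i]].add(term_id)

    planted_id = None
    plant = spec.planted_term_size > 0 and spec.planted_odds_ratio != 1.0
    if plant:
        if truth is None:
            raise ValueError("planting an enriched term requires ground truth")
        if spec.planted_term_size > n:
            raise ValueError("planted term larger than the gene universe")
        weights = np.where(truth.is_de, spec.planted_odds_ratio, 1.0)
        weights = weights / weights.sum()
        members = rng.choice(n, size=spec.planted_term_size, replace=False, p=weights)
        planted_id = "T_PLANTED"
        terms[planted_id] = TermInfo(planted_id, "planted term", "biological_process")
        for i in members:
            gene_terms[genes[i]].add(planted_id)

    annotations = AnnotationMap(
        gene_terms={g: frozenset(t) for g, t in gene_terms.items() if t},
        terms=terms,
    )
    return annotations, EnrichmentTruth(
        planted_term_id=planted_id,
        odds_ratio=spec.planted_odds_ratio if plant else 1.0,
        enriched=bool(plant and spec.planted_odds_ratio > 1.0),
    )


def generate_hits_and_catalog(
    gene_ids: list[str],
    spec: SyntheticSpec,
) -> tuple[list[HomologyHit], list[FloweringCatalogEntry]]:
    """Hits with log-uniform e-values straddling 1e-5 for a random subset of
    genes; a round-robin six-category catalogue for another subset."""
    if not gene_ids:
        raise ValueError("gene_ids must be non-empty")
    rng = np.random.default_rng([spec.seed, 2])
    n = len(gene_ids)
    genes = np.asarray(gene_ids)

    hits: list[HomologyHit] = []
    n_hit = int(round(spec.hit_fraction * n))
    if n_hit:
        chosen = rng.choice(n, size=n_hit, replace=False)
        for i in chosen:
            for _ in range(int(rng.integers(1, 4))):
                e_value = 10.0 ** rng.uniform(-10.0, 0.0)
                hits.append(
                    HomologyHit(
                        query_gene_id=str(genes[i]),
                        subject_accession=f"REF{int(rng.integers(0, 10000)):05d}.1",
                        percent_identity=float(np.round(rng.uniform(60, 100), 1)),
                        alignment_length=int(rng.integers(50, 2000)),
                        mismatches=int(rng.integers(0, 100)),
                        gap_opens=int(rng.integers(0, 10)),
                        q_start=1,
                        q_end=100,
                        s_start=1,
                        s_end=100,
                        e_value=float(e_value),
                        bit_score=float(np.round(50 - 2 * np.log10(e_value), 1)),
                    )
                )

    catalog: list[FloweringCatalogEntry] = []
    n_cat = min(spec.n_catalog, n)
    if n_cat:
        chosen = rng.choice(n, size=n_cat, replace=False)
        for j, i in enumerate(chosen):
            catalog.append(
                FloweringCatalogEntry(
                    gene_id=str(genes[i]),
                    category=CATEGORIES[j % len(CATEGORIES)],
                    homolog_name=f"HOM{j + 1}",
                    homolog_accession=f"REF{j + 1:05d}.1",
                )
            )
    return hits, catalog


def write_truth(truth: GroundTruth, path, planted_term_id: str | None = None) -> None:
    from pathlib import Path

    with Path(path).open("w", newline="") as fh:
        if planted_term_id:
            fh.write(f"#planted_term={planted_term_id}\n")
        fh.write("gene_id\teffect_log2\tis_de\tbaseline_proportion\n")
        for i, gene in enumerate(truth.gene_ids):
            fh.write(
                f"{gene}\t{truth.effect_log2[i]:.4f}\t"
                f"{'true' if truth.is_de[i] else 'false'}\t"
                f"{truth.baseline_proportion[i]:.6e}\n"
            )
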