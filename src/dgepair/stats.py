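"""Statistical core for two-library digital expression comparison.

Implements RPKM normalization, zero-substituted log2 fold change, the exact
conditional test for equal expression of a gene in two count libraries,
Benjamini–Hochberg FDR adjustment, and threshold-based DEG calling.

The equal-expression test conditions the count in the second library on the
count in the first. With library totals N1 and N2 and r = N2/N1, the
probability of observing y reads in the second library given x in the first
is::

    p(y | x) = r**y * (x + y)! / (x! * y! * (1 + r)**(x + y + 1))

which is a negative-binomial pmf in y with x + 1 "successes" and success
probability N1 / (N1 + N2). The point probability is evaluated in log space
via the log-gamma function; the tails use the regularized incomplete beta
through the negative-binomial CDF, with the upper tail taken as the
complement of the lower tail at y - 1 (no infinite summation). The reported
p-value is two-sided: twice the smaller tail, capped at 1.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
from scipy.special import gammaln
from scipy.stats import nbinom

from dgepair.io import GeneCount, LibraryPair

logger = logging.getLogger(__name__)

DIRECTIONS = ("up", "down", "none")


@dataclass(frozen=True)
class TestConfig:
    """Thresholds and constants for DEG calling (all inclusive)."""

    fdr_threshold: float = 0.001
    min_abs_log2: float = 1.0
    zero_substitute: float = 0.01
    rpkm_scale: float = 1e9

    def __post_init__(self):
        for field in ("fdr_threshold", "min_abs_log2", "zero_substitute", "rpkm_scale"):
            if getattr(self, field) <= 0:
                raise ValueError(f"{field} must be strictly positive")


@dataclass(frozen=True)
class DiffExprRecord:
    gene_id: str
    length_bp: int
    reads_L: int
    reads_S: int
    rpkm_L: float
    rpkm_S: float
    log2_ratio: float
    p_value: float
    fdr: float
    direction: str
    is_deg: bool

    def __post_init__(self):
        if self.direction not in DIRECTIONS:
            raise ValueError(f"direction must be one of {DIRECTIONS}")
        if not 0.0 <= self.p_value <= 1.0:
            raise ValueError("p_value must be in [0, 1]")
        if not 0.0 <= self.fdr <= 1.0:
            raise ValueError("fdr must be in [0, 1]")


def compute_rpkm(count, length_bp, library_total, scale: float = 1e9):
    """Reads per kilobase of transcript per million library reads.

    ``scale * count / (length_bp * library_total)``; zero iff count is zero.
    Accepts scalars or numpy arrays.
    """
    count = np.asarray(count, dtype=float)
    length_bp = np.asarray(length_bp, dtype=float)
    library_total = np.asarray(library_total, dtype=float)
    if np.any(count < 0):
        raise ValueError("count must be non-negative")
    if np.any(length_bp < 1):
        raise ValueError("length_bp must be >= 1")
    if np.any(library_total < 1):
        raise ValueError("library_total must be >= 1")
    out = scale * count / (length_bp * library_total)
    return float(out) if out.ndim == 0 else out


def log2_fold_change(rpkm_L, rpkm_S, zero_substitute: float = 0.01):
    """log2(rpkm_S / rpkm_L) with zero operands replaced by ``zero_substitute``."""
    if zero_substitute <= 0:
        raise ValueError("zero_substitute must be > 0")
    l = np.asarray(rpkm_L, dtype=float)
    s = np.asarray(rpkm_S, dtype=float)
    if np.any(l < 0) or np.any(s < 0):
        raise ValueError("RPKM values must be non-negative")
    l = np.where(l == 0, zero_substitute, l)
    s = np.where(s == 0, zero_substitute, s)
    out = np.log2(s / l)
    return float(out) if out.ndim == 0 else out


def _check_test_args(x, y, n1, n2):
    x = np.asarray(x)
    y = np.asarray(y)
    if np.any(x < 0) or np.any(y < 0):
        raise ValueError("counts must be non-negative")
    if np.any(np.asarray(n1) < 1) or np.any(np.asarray(n2) < 1):
        raise ValueError("library totals must be >= 1")
    return x.astype(float), y.astype(float)


def audic_pmf(x, y, n1, n2):
    """Probability of y reads in library 2 given x in library 1 under equal
    expression; evaluated in log space."""
    x, y = _check_test_args(x, y, n1, n2)
    log_r = np.log(n2) - np.log(n1)
    r = np.exp(log_r)
    logp = (
        y * log_r
        + gammaln(x + y + 1.0)
        - gammaln(x + 1.0)
        - gammaln(y + 1.0)
        - (x + y + 1.0) * np.log1p(r)
    )
    out = np.exp(logp)
    return float(out) if out.ndim == 0 else out


def audic_lower_tail(x, y, n1, n2):
    """P(Y <= y | x): the lower cumulative of :func:`audic_pmf`."""
    x, y = _check_test_args(x, y, n1, n2)
    p_success = n1 / (n1 + n2)
    out = nbinom.cdf(y, x + 1.0, p_success)
    return float(out) if np.ndim(out) == 0 else out


def audic_pvalue(x, y, n1, n2):
    """Two-sided equal-expression p-value: min(1, 2 * min(P(Y<=y), P(Y>=y))).

    The upper tail is the complement of the lower tail at y - 1.
    """
    x, y = _check_test_args(x, y, n1, n2)
    p_success = n1 / (n1 + n2)
    lower = nbinom.cdf(y, x + 1.0, p_success)
    upper = nbinom.sf(y - 1.0, x + 1.0, p_success)
    out = np.minimum(1.0, 2.0 * np.minimum(lower, upper))
    return float(out) if np.ndim(out) == 0 else out


def bh_fdr(p_values):
    """Benjamini–Hochberg step-up adjustment, input order preserved.

    q_(i) = min_{j >= i} p_(j) * m / j, capped at 1. Output is elementwise
    >= input.
    """
    p = np.asarray(p_values, dtype=float)
    if p.ndim != 1:
        raise ValueError("p_values must be one-dimensional")
    if p.size == 0:
        return p.copy()
    if np.any((p < 0) | (p > 1)) or np.any(np.isnan(p)):
        raise ValueError("p-values must lie in [0, 1]")
    m = p.size
    order = np.argsort(p, kind="stable")
    ranked = p[order] * m / np.arange(1, m + 1)
    q_sorted = np.minimum(1.0, np.minimum.accumulate(ranked[::-1])[::-1])
    q = np.empty(m)
    q[order] = q_sorted
    return q


def call_degs(
    counts: list[GeneCount],
    libs: LibraryPair,
    config: TestConfig = TestConfig(),
) -> list[DiffExprRecord]:
    """Score every testable gene and flag DEGs at the configured thresholds.

    Genes with zero reads in both libraries are untestable and are dropped
    (logged at INFO). Thresholds are inclusive: ``fdr <= fdr_threshold`` and
    ``|log2_ratio| >= min_abs_log2``.
    """
    if not counts:
        raise ValueError("counts must be non-empty")
    testable = [c for c in counts if c.reads_L > 0 or c.reads_S > 0]
    dropped = len(counts) - len(testable)
    if dropped:
        logger.info("dropped %d untestable genes (zero reads in both libraries)", dropped)
    if not testable:
        return []

    x = np.array([c.reads_L for c in testable], dtype=float)
    y = np.array([c.reads_S for c in testable], dtype=float)
    length = np.array([c.length_bp for c in testable], dtype=float)

    rpkm_l = compute_rpkm(x, length, libs.total_reads_L, scale=config.rpkm_scale)
    rpkm_s = compute_rpkm(y, length, libs.total_reads_S, scale=config.rpkm_scale)
    lfc = log2_fold_change(rpkm_l, rpkm_s, config.zero_substitute)
    pvals = audic_pvalue(x, y, libs.total_reads_L, libs.total_reads_S)
    fdrs = bh_fdr(pvals)

    records = []
    for i, gene in enumerate(testable):
        l2 = float(lfc[i])
        direction = "up" if l2 > 0 else ("down" if l2 < 0 else "none")
        records.append(
            DiffExprRecord(
                gene_id=gene.gene_id,
                length_bp=gene.length_bp,
                reads_L=gene.reads_L,
                reads_S=gene.reads_S,
                rpkm_L=float(rpkm_l[i]),
                rpkm_S=float(rpkm_s[i]),
                log2_ratio=l2,
                p_value=float(pvals[i]),
                fdr=float(fdrs[i]),
                direction=direction,
                is_deg=is_deg(l2, float(fdrs[i]), config),
            )
        )
    return records


def is_deg(log2_ratio: float, fdr: float, config: TestConfig = TestConfig()) -> bool:
    """Inclusive two-criterion DEG rule."""
    return fdr <= config.fdr_threshold and abs(log2_ratio) >= config.min_abs_log2


def summarize_degs(records: list[DiffExprRecord]) -> dict[str, int]:
    """Counts of tested genes and of up/down DEGs."""
    up = sum(1 for r in records if r.is_deg and r.direction == "up")
    down = sum(1 for r in records if r.is_deg and r.direction == "down")
    return {
        "genes_tested": len(records),
        "degs_up": up,
        "degs_down": down,
        "degs_total": up + down,
    }
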