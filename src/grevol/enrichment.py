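"""Locus-overlap enrichment of TE families near gene clusters.

The analysis asks whether copies of a transposable-element family co-occur
with a gene family's loci more often than with genic regions at large.  The
counting units are the merged "universe" regions (every gene expanded by a
flank, overlaps combined); the "query" subset are the regions built the same
way from the gene family of interest.  Each universe region is classified by
(query membership, >=1 bp TE overlap), giving a 2x2 table per TE family that
is tested with a one-sided Fisher's exact test, followed by
false-discovery-rate correction across families.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Mapping, Sequence

import numpy as np
from scipy import stats
from statsmodels.stats.multitest import multipletests

from .intervals import GenomicInterval, RegionSet, flank_and_merge, merge_intervals
from .records import TEAnnotation

DEFAULT_FLANK = 10_000


def build_query_regions(
    genes: Sequence[GenomicInterval],
    flank: int = DEFAULT_FLANK,
    scaffold_lengths: Mapping[str, int] | None = None,
) -> RegionSet:
    """Flank-and-merge regions around the gene family of interest."""
    rs = flank_and_merge(genes, flank, scaffold_lengths, label="query")
    rs.label = "query"
    return rs


def build_universe(
    all_genes: Sequence[GenomicInterval],
    flank: int = DEFAULT_FLANK,
    scaffold_lengths: Mapping[str, int] | None = None,
) -> RegionSet:
    """Flank-and-merge regions around every annotated gene (the universe)."""
    rs = flank_and_merge(all_genes, flank, scaffold_lengths, label="universe")
    rs.label = "universe"
    return rs


@dataclass(frozen=True)
class ContingencyTable:
    """Counts of universe regions by (query membership, TE-family overlap).

    a: query regions with >=1 family copy;   b: non-query regions with one;
    c: query regions without;                d: non-query regions without.
    """

    a: int
    b: int
    c: int
    d: int

    def __post_init__(self) -> None:
        if min(self.a, self.b, self.c, self.d) < 0:
            raise ValueError("contingency counts must be non-negative")

    @property
    def n(self) -> int:
        return self.a + self.b + self.c + self.d

    def as_array(self) -> np.ndarray:
        return np.array([[self.a, self.b], [self.c, self.d]])


def make_contingency(
    universe: RegionSet,
    query: RegionSet,
    te_family_intervals: Sequence[GenomicInterval],
) -> ContingencyTable:
    """Classify every universe region by query membership and TE overlap.

    A universe region is a query member when it shares >=1 bp with any query
    region; it "has" the family when any family copy overlaps it.  Every
    query region must fall inside the universe (queries are built from a
    subset of the universe's genes).
    """
    for q in query:
        if not universe.any_overlap(q):
            raise ValueError(
                f"query region {q} overlaps no universe region; "
                "build both sets from the same annotation"
            )
    te_merged = merge_intervals(te_family_intervals)
    a = b = c = d = 0
    for region in universe:
        is_query = query.any_overlap(region)
        has_te = te_merged.any_overlap(region)
        if is_query and has_te:
            a += 1
        elif has_te:
            b += 1
        elif is_query:
            c += 1
        else:
            d += 1
    return ContingencyTable(a, b, c, d)


def fisher_exact(
    table: ContingencyTable, alternative: str = "greater"
) -> tuple[float, float]:
    """One-sided Fisher's exact test; returns ``(p_value, odds_ratio)``.

    The p-value sums hypergeometric probabilities of tables at least as
    enriched given fixed margins; the odds ratio is the sample estimate
    ``ad/bc`` (infinite when ``bc = 0`` and ``ad > 0``).
    """
    res = stats.fisher_exact(table.as_array(), alternative=alternative)
    ad, bc = table.a * table.d, table.b * table.c
    if bc == 0:
        odds = np.inf if ad > 0 else np.nan
    else:
        odds = ad / bc
    return float(res.pvalue), float(odds)


def bh_fdr(p_values: Sequence[float]) -> np.ndarray:
    """Benjamini–Hochberg step-up adjusted p-values."""
    p = np.asarray(p_values, dtype=float)
    if p.size == 0:
        return p
    if np.any((p < 0) | (p > 1)):
        raise ValueError("p-values must lie in [0, 1]")
    return multipletests(p, method="fdr_bh")[1]


def storey_qvalue(p_values: Sequence[float], lam: float = 0.5) -> np.ndarray:
    """Storey q-values with a single-lambda pi0 estimate.

    ``pi0 = #{p > lam} / ((1 - lam) m)`` capped at 1; q-values are the
    monotone step-up of ``pi0 * m * p_(i) / i``.  Suited to large families
    of tests; with few tests, Benjamini–Hochberg is preferable.
    """
    p = np.asarray(p_values, dtype=float)
    if p.size == 0:
        return p
    if np.any((p < 0) | (p > 1)):
        raise ValueError("p-values must lie in [0, 1]")
    m = p.size
    pi0 = min(1.0, np.mean(p > lam) / (1.0 - lam)) if m else 1.0
    pi0 = max(pi0, 1.0 / m)  # guard against zero when all p are small
    order = np.argsort(p)
    q = np.empty(m)
    prev = 1.0
    for rank in range(m, 0, -1):
        i = order[rank - 1]
        prev = min(prev, pi0 * m * p[i] / rank)
        q[i] = prev
    return q


def compute_qvalues(p_values: Sequence[float], storey_min_tests: int = 100) -> np.ndarray:
    """BH for small test families, Storey (lambda=0.5) for large ones."""
    p = np.asarray(p_values, dtype=float)
    if p.size >= storey_min_tests:
        return storey_qvalue(p)
    return bh_fdr(p)


@dataclass
class EnrichmentResult:
    """One TE family's (or order's) enrichment near one gene family."""

    gene_family: str
    level: str  # "family" or "order"
    family_id: str
    order: str
    counts: ContingencyTable
    odds_ratio: float
    p_value: float
    q_value: float = float("nan")


def enrichment_scan(
    genes_by_family: Mapping[str, Sequence[GenomicInterval]],
    universe_genes: Sequence[GenomicInterval],
    te_annotations: Sequence[TEAnnotation],
    flank: int = DEFAULT_FLANK,
    scaffold_lengths: Mapping[str, int] | None = None,
    storey_min_tests: int = 100,
) -> list[EnrichmentResult]:
    """Test every TE consensus family (and every order, aggregated) for
    enrichment near each gene family; FDR-correct within each level;
    return results sorted by q-value."""
    if not universe_genes:
        raise ValueError("universe gene set is empty")
    if not te_annotations:
        return []
    universe = build_universe(universe_genes, flank, scaffold_lengths)
    by_family: dict[str, list] = {}
    by_order: dict[str, list] = {}
    order_of: dict[str, str] = {}
    for te in te_annotations:
        by_family.setdefault(te.family_id, []).append(te.interval)
        by_order.setdefault(te.order, []).append(te.interval)
        order_of[te.family_id] = te.order
    results: list[EnrichmentResult] = []
    for gene_family, genes in genes_by_family.items():
        query = build_query_regions(genes, flank, scaffold_lengths)
        for level, groups in (("family", by_family), ("order", by_order)):
            block: list[EnrichmentResult] = []
            for gid in sorted(groups):
                table = make_contingency(universe, query, groups[gid])
                p, odds = fisher_exact(table)
                block.append(
                    EnrichmentResult(
                        gene_family=gene_family,
                        level=level,
                        family_id=gid,
                        order=order_of.get(gid, gid),
                        counts=table,
                        odds_ratio=odds,
                        p_value=p,
                    )
                )
            qs = compute_qvalues([r.p_value for r in block], storey_min_tests)
            for r, q in zip(block, qs):
                r.q_value = float(q)
            results.extend(block)
    results.sort(key=lambda r: (r.gene_family, r.level, r.q_value, r.p_value, r.family_id))
    return results
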