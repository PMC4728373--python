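"""Genomic feature annotation of methylated sites.

Sites are partitioned into four exclusive categories with precedence
exon > intron > promoter > intergenic, where introns are the gene span
minus its exons and promoters are a fixed-width (default 2 kb)
strand-aware window immediately upstream of the gene start.
"""

from __future__ import annotations

from bisect import bisect_left, bisect_right
from dataclasses import dataclass
from typing import Iterable, Optional, Sequence

from intervaltree import IntervalTree

from .calling import CytosineCount
from .errors import ConfigurationError
from .simulate import GeneModel

CATEGORIES = ("exon", "intron", "promoter", "intergenic")


@dataclass
class FeatureIndex:
    """Per-contig interval trees for exons, introns and promoters."""

    exons: dict[str, IntervalTree]
    introns: dict[str, IntervalTree]
    promoters: dict[str, IntervalTree]
    promoter_len: int


def build_feature_index(
    genes: Sequence[GeneModel],
    promoter_len: int = 2000,
    contig_lengths: Optional[dict[str, int]] = None,
) -> FeatureIndex:
    """Derive exon/intron/promoter intervals from gene models.

    Introns are the parts of the gene span not covered by exons; promoters
    sit upstream of the 5' gene end on the gene's strand, clipped at
    position 0 and (when contig lengths are known) at the contig end.
    """
    if promoter_len < 0:
        raise ConfigurationError("promoter_len must be >= 0")
    exons: dict[str, IntervalTree] = {}
    introns: dict[str, IntervalTree] = {}
    promoters: dict[str, IntervalTree] = {}
    for g in genes:
        for s, e in g.exons:
            if s < g.start or e > g.end:
                raise ConfigurationError(
                    f"exon [{s},{e}) of {g.gene_id} outside gene span"
                )
            exons.setdefault(g.contig, IntervalTree()).addi(s, e, g.gene_id)
        cursor = g.start
        for s, e in g.exons:
            if s > cursor:
                introns.setdefault(g.contig, IntervalTree()).addi(cursor, s, g.gene_id)
            cursor = e
        if cursor < g.end:
            introns.setdefault(g.contig, IntervalTree()).addi(cursor, g.end, g.gene_id)
        if promoter_len > 0:
            if g.strand == "+":
                ps, pe = max(0, g.start - promoter_len), g.start
            else:
                ps, pe = g.end, g.end + promoter_len
                if contig_lengths is not None:
                    pe = min(pe, contig_lengths[g.contig])
            if pe > ps:
                promoters.setdefault(g.contig, IntervalTree()).addi(ps, pe, g.gene_id)
    return FeatureIndex(exons, introns, promoters, promoter_len)


def assign_feature(index: FeatureIndex, contig: str, pos: int) -> str:
    """Single exclusive category with precedence exon > intron > promoter."""
    for category, trees in (
        ("exon", index.exons),
        ("intron", index.introns),
        ("promoter", index.promoters),
    ):
        tree = trees.get(contig)
        if tree is not None and tree[pos]:
            return category
    return "intergenic"


def feature_fractions(
    sites: Sequence[tuple[str, int]], index: FeatureIndex
) -> dict[str, float]:
    """Fraction of sites per category; all four keys always present."""
    counts = dict.fromkeys(CATEGORIES, 0)
    for contig, pos in sites:
        counts[assign_feature(index, contig, pos)] += 1
    n = len(sites)
    if n == 0:
        return dict.fromkeys(CATEGORIES, 0.0)
    return {k: counts[k] / n for k in CATEGORIES}


def gene_cpg_coverage_summary(
    counts: Sequence[CytosineCount],
    genes: Sequence[GeneModel],
    thresholds: Sequence[int] = (5, 10),
) -> dict[int, int]:
    """Number of genes with at least k covered CpG sites, per threshold k."""
    if any(t <= 0 for t in thresholds):
        raise ConfigurationError("thresholds must be positive")
    covered: dict[str, list[int]] = {}
    for c in counts:
        if c.context == "CpG" and c.N >= 1:
            covered.setdefault(c.contig, []).append(c.pos)
    for positions in covered.values():
        positions.sort()
    per_gene = []
    for g in genes:
        positions = covered.get(g.contig, [])
        n = bisect_left(positions, g.end) - bisect_left(positions, g.start)
        per_gene.append(n)
    return {
        int(t): sum(1 for n in per_gene if n >= t) for t in thresholds
    }
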