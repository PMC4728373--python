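"""Differential methylation between photoperiod conditions.

For each CpG covered deeply enough in both the long-day (LD) and short-day
(SD) samples, the proportions of methylated reads are compared with a
two-sided Fisher's exact test on the 2x2 table

    [[K_LD, U_LD],
     [K_SD, U_SD]]

followed by Benjamini-Hochberg FDR control (5% by default). Significant
sites (DMCs) are classified hypo-LD or hyper-LD by comparing methylation
levels and mapped to genes via the gene span plus a strand-aware upstream
promoter window.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Optional, Sequence

import numpy as np
import pandas as pd
from intervaltree import IntervalTree
from scipy import stats

from .calling import CytosineCount, benjamini_hochberg
from .errors import ConfigurationError
from .simulate import GeneModel

# Relative tolerance for the "probability <= observed" two-sided rule,
# guarding against floating-point asymmetry between exactly tied tables.
_TWO_SIDED_RTOL = 1e-7


@dataclass(frozen=True)
class PairedSite:
    """One CpG with methylated/unmethylated counts in both conditions."""

    contig: str
    pos: int
    strand: str
    K_LD: int
    U_LD: int
    K_SD: int
    U_SD: int

    @property
    def N_LD(self) -> int:
        return self.K_LD + self.U_LD

    @property
    def N_SD(self) -> int:
        return self.K_SD + self.U_SD

    @property
    def level_LD(self) -> float:
        return 100.0 * self.K_LD / self.N_LD

    @property
    def level_SD(self) -> float:
        return 100.0 * self.K_SD / self.N_SD


@dataclass
class DMCRecord:
    site: PairedSite
    p_value: float
    q_value: float
    is_dmc: bool
    direction: str  # hyper_LD | hypo_LD | none
    gene_id: str = "intergenic"
    gene_ids: tuple[str, ...] = ()


def joint_coverage_filter(
    counts_LD: Sequence[CytosineCount],
    counts_SD: Sequence[CytosineCount],
    min_depth: int = 10,
) -> list[PairedSite]:
    """Pair sites covered at depth >= min_depth in BOTH samples."""
    if min_depth < 1:
        raise ConfigurationError("min_depth must be >= 1")
    by_key = {
        (c.contig, c.pos, c.strand): c for c in counts_SD if c.N >= min_depth
    }
    pairs = []
    for c in counts_LD:
        if c.N < min_depth:
            continue
        other = by_key.get((c.contig, c.pos, c.strand))
        if other is None:
            continue
        pairs.append(
            PairedSite(
                contig=c.contig,
                pos=c.pos,
                strand=c.strand,
                K_LD=c.K,
                U_LD=c.U,
                K_SD=other.K,
                U_SD=other.U,
            )
        )
    pairs.sort(key=lambda p: (p.contig, p.pos, p.strand))
    return pairs


def _fisher_two_sided(a: int, b: int, c: int, d: int) -> float:
    """Two-sided Fisher p via the hypergeometric distribution.

    Sums the probabilities of all tables sharing the observed margins whose
    probability does not exceed that of the observed table (up to a small
    relative tolerance for floating-point ties).
    """
    r1, c1, n = a + b, a + c, a + b + c + d
    support = np.arange(max(0, c1 - (c + d)), min(r1, c1) + 1)
    pmf = stats.hypergeom.pmf(support, n, r1, c1)
    p_obs = pmf[support == a][0]
    p = float(pmf[pmf <= p_obs * (1 + _TWO_SIDED_RTOL)].sum())
    return min(p, 1.0)


def fisher_exact_2x2(a: int, b: int, c: int, d: int) -> float:
    """Two-sided Fisher's exact test p-value for the table [[a,b],[c,d]]."""
    for x in (a, b, c, d):
        if x < 0 or int(x) != x:
            raise ConfigurationError("table entries must be non-negative integers")
    if a + b + c + d == 0:
        raise ConfigurationError("all-zero table has no Fisher p-value")
    return _fisher_two_sided(int(a), int(b), int(c), int(d))


def call_dmcs(pairs: Sequence[PairedSite], fdr: float = 0.05) -> list[DMCRecord]:
    """Fisher-test every paired site and flag DMCs at BH q <= fdr.

    Returns a record per tested site (``is_dmc`` marks the significant
    ones). Direction is hypo_LD when the LD level is below the SD level;
    equal levels yield direction "none" and are excluded from direction
    tallies.
    """
    if not pairs:
        raise ConfigurationError("no paired sites to test")
    p = np.array([
        _fisher_two_sided(s.K_LD, s.U_LD, s.K_SD, s.U_SD) for s in pairs
    ])
    q, flagged = benjamini_hochberg(p, alpha=fdr)
    records = []
    for s, pi, qi, fi in zip(pairs, p, q, flagged):
        if s.level_LD < s.level_SD:
            direction = "hypo_LD"
        elif s.level_LD > s.level_SD:
            direction = "hyper_LD"
        else:
            direction = "none"
        records.append(
            DMCRecord(
                site=s,
                p_value=float(pi),
                q_value=float(qi),
                is_dmc=bool(fi),
                direction=direction,
            )
        )
    return records


def map_dmcs_to_genes(
    dmcs: Sequence[DMCRecord],
    genes: Sequence[GeneModel],
    promoter_len: int = 2000,
) -> pd.DataFrame:
    """Map DMCs to genes (span + strand-aware upstream promoter window).

    A DMC falling in overlapping genes is assigned to each of them; DMCs
    hitting no gene are reported intergenic. Mutates each record's
    ``gene_id``/``gene_ids`` and returns a per-gene table with DMC and
    direction counts.
    """
    trees: dict[str, IntervalTree] = {}
    for g in genes:
        tree = trees.setdefault(g.contig, IntervalTree())
        tree.addi(g.start, g.end, g.gene_id)
        if promoter_len > 0:
            if g.strand == "+":
                ps, pe = max(0, g.start - promoter_len), g.start
            else:
                ps, pe = g.end, g.end + promoter_len
            if pe > ps:
                tree.addi(ps, pe, g.gene_id)

    tally: dict[str, dict[str, int]] = {}
    for rec in dmcs:
        tree = trees.get(rec.site.contig)
        hits = sorted({iv.data for iv in tree[rec.site.pos]}) if tree else []
        rec.gene_ids = tuple(hits)
        rec.gene_id = ";".join(hits) if hits else "intergenic"
        for gid in hits:
            row = tally.setdefault(gid, {"n_dmcs": 0, "n_hyper_LD": 0, "n_hypo_LD": 0})
            row["n_dmcs"] += 1
            if rec.direction == "hyper_LD":
                row["n_hyper_LD"] += 1
            elif rec.direction == "hypo_LD":
                row["n_hypo_LD"] += 1
    df = pd.DataFrame(
        [
            {"gene_id": gid, **row}
            for gid, row in sorted(tally.items())
        ],
        columns=["gene_id", "n_dmcs", "n_hyper_LD", "n_hypo_LD"],
    )
    return df
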