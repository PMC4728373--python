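"""Per-cytosine pileup, context classification and binomial methylation calls.

A cytosine with K methylated basecalls out of N covering reads is tested
against the conversion-error null: under no true methylation, each C
basecall arises with probability E (the estimated conversion-failure
rate), so the one-sided p-value is the binomial tail

    p = P(X >= K | N, E)

Benjamini-Hochberg correction over all tested sites controls the FDR
(1% by default); a site is called methylated when q <= fdr. The
methylation level of a site is the percentage of covering reads that
report C.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Optional, Sequence

import numpy as np
from scipy import stats
from statsmodels.stats.multitest import multipletests

from .errors import ConfigurationError
from .simulate import GenomeSequence, RRBSRead

_COMPLEMENT = str.maketrans("ACGT", "TGCA")


@dataclass(frozen=True)
class CytosineCount:
    """Methylated/unmethylated basecall counts at one cytosine."""

    contig: str
    pos: int
    strand: str
    context: str
    K: int  # C basecalls (methylated)
    U: int  # T basecalls (unmethylated)

    def __post_init__(self):
        if self.K < 0 or self.U < 0:
            raise ConfigurationError("counts must be non-negative")
        if self.context not in ("CpG", "CHG", "CHH"):
            raise ConfigurationError(f"bad context {self.context!r}")

    @property
    def N(self) -> int:
        return self.K + self.U


@dataclass(frozen=True)
class MethylationCall:
    site: CytosineCount
    p_value: float
    q_value: float
    is_methylated: bool

    @property
    def level(self) -> float:
        """Methylation level in percent: 100 * K / N."""
        return 100.0 * self.site.K / self.site.N


@dataclass(frozen=True)
class BimodalitySummary:
    frac_low: float
    frac_mid: float
    frac_high: float
    n_sites: int

    @property
    def is_empty(self) -> bool:
        return self.n_sites == 0

    def __iter__(self):
        return iter((self.frac_low, self.frac_mid, self.frac_high))


def classify_context(
    genome: GenomeSequence,
    contig: str,
    pos: int,
    strand: str = "+",
    with_flag: bool = False,
):
    """Classify a cytosine as CpG, CHG or CHH (H = A, C or T).

    On the minus strand the rule applies to the reverse complement read
    5'->3'. Cytosines within 2 bp of the contig end whose context is
    truncated are classified CHH; ``with_flag=True`` additionally returns
    whether truncation occurred.
    """
    seq = genome[contig]
    if strand == "+":
        base = seq[pos]
        nxt = seq[pos + 1] if pos + 1 < len(seq) else None
        nxt2 = seq[pos + 2] if pos + 2 < len(seq) else None
    elif strand == "-":
        base = seq[pos].translate(_COMPLEMENT)
        nxt = seq[pos - 1].translate(_COMPLEMENT) if pos - 1 >= 0 else None
        nxt2 = seq[pos - 2].translate(_COMPLEMENT) if pos - 2 >= 0 else None
    else:
        raise ConfigurationError(f"bad strand {strand!r}")
    if base != "C":
        raise ConfigurationError(
            f"{contig}:{pos}({strand}) is {base}, not C"
        )
    truncated = nxt is None or (nxt != "G" and nxt2 is None)
    if nxt == "G":
        ctx = "CpG"
    elif nxt2 == "G":
        ctx = "CHG"
    else:
        ctx = "CHH"
    return (ctx, truncated) if with_flag else ctx


def pileup(
    reads: Sequence[RRBSRead], genome: GenomeSequence
) -> list[CytosineCount]:
    """Count C (methylated) and T (unmethylated) basecalls per genomic C.

    Reads carry their origin coordinates, so no alignment is needed.
    Plus-strand cytosines only; adapter bases and the synthetic fill-in
    base are excluded; basecalls other than C/T at a C position are
    ignored. Returns counts in genomic order for covered cytosines.
    """
    acc: dict[tuple[str, int], list[int]] = {}
    for r in reads:
        contig, start, strand = r.origin
        if contig not in genome:
            raise ConfigurationError(f"read origin contig {contig!r} not in genome")
        seq = genome[contig]
        usable = len(r.sequence)
        if r.fillin_pos is not None:
            usable = min(usable, r.fillin_pos)
        if r.adapter_start is not None:
            usable = min(usable, r.adapter_start - 1)
        if start < 0 or start + usable > len(seq):
            raise ConfigurationError(
                f"read {r.read_id} origin outside genome bounds"
            )
        for i in range(usable):
            if seq[start + i] != "C":
                continue
            base = r.sequence[i]
            counts = acc.setdefault((contig, start + i), [0, 0])
            if base == "C":
                counts[0] += 1
            elif base == "T":
                counts[1] += 1
    out = []
    for (contig, pos) in sorted(acc):
        k, u = acc[(contig, pos)]
        out.append(
            CytosineCount(
                contig=contig,
                pos=pos,
                strand="+",
                context=classify_context(genome, contig, pos, "+"),
                K=k,
                U=u,
            )
        )
    return out


def benjamini_hochberg(
    p_values: Sequence[float], alpha: float = 0.05
) -> tuple[np.ndarray, np.ndarray]:
    """BH step-up q-values and rejection flags, in input order."""
    p = np.asarray(p_values, dtype=float)
    if p.size == 0:
        return np.array([]), np.array([], dtype=bool)
    if np.any((p < 0) | (p > 1)) or np.any(np.isnan(p)):
        raise ConfigurationError("p-values must lie in [0,1]")
    reject, q, _, _ = multipletests(p, alpha=alpha, method="fdr_bh")
    return q, reject


def call_methylation(
    counts: Sequence[CytosineCount],
    E: float,
    fdr: float = 0.01,
    min_depth: int = 5,
) -> list[MethylationCall]:
    """Binomial test of each covered cytosine against the conversion error E.

    Sites with depth below ``min_depth`` are not tested (uninformative and
    they inflate the multiple-testing family). All contexts enter a single
    BH family.
    """
    if not 0.0 <= E < 1.0:
        raise ConfigurationError("E must be in [0,1); E=1 is a degenerate null")
    if not 0.0 < fdr < 1.0:
        raise ConfigurationError("fdr must be in (0,1)")
    tested = [c for c in counts if c.N >= min_depth]
    if not tested:
        return []
    K = np.array([c.K for c in tested])
    N = np.array([c.N for c in tested])
    p = stats.binom.sf(K - 1, N, E)  # P(X >= K); K=0 -> 1 exactly
    p = np.minimum(p, 1.0)
    q, flagged = benjamini_hochberg(p, alpha=fdr)
    return [
        MethylationCall(site=c, p_value=float(pi), q_value=float(qi), is_methylated=bool(fi))
        for c, pi, qi, fi in zip(tested, p, q, flagged)
    ]


def bimodality_summary(
    calls: Sequence[MethylationCall],
    low_cut: float = 10.0,
    high_cut: float = 90.0,
) -> BimodalitySummary:
    """Fractions of sites with level below, between and above the cutoffs."""
    if not 0 <= low_cut < high_cut <= 100:
        raise ConfigurationError("require 0 <= low_cut < high_cut <= 100")
    if not calls:
        return BimodalitySummary(0.0, 0.0, 0.0, 0)
    levels = np.array([c.level for c in calls])
    n = len(levels)
    low = int(np.sum(levels < low_cut))
    high = int(np.sum(levels > high_cut))
    return BimodalitySummary(low / n, (n - low - high) / n, high / n, n)
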