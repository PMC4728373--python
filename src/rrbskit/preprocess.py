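"""Read-level QC filters and the bisulfite-conversion error estimator.

The conversion-failure rate E is estimated from the MspI fill-in position:
end repair of the CG overhang incorporates an unmethylated cytosine, so in
fully converted data that base always reads T. Reads that run into the
3' adapter with an overlap of at least ``min_overlap`` bases localize the
fill-in base (the base immediately preceding the adapter), and

    E = nCf / (nCf + nTf)

over the C and T basecalls observed there — incomplete conversion plus
residual T>C sequencing error.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Optional, Sequence

from .errors import ConfigurationError, NoAdapterReadsError
from .simulate import RRBSRead


@dataclass(frozen=True)
class ConversionErrorEstimate:
    """Conversion-failure rate estimate from fill-in basecalls."""

    E: float
    nCf: int
    nTf: int
    n_reads_used: int

    def __post_init__(self):
        total = self.nCf + self.nTf
        if total > 0 and abs(self.E - self.nCf / total) > 1e-12:
            raise ConfigurationError("E inconsistent with nCf/(nCf+nTf)")

    def as_dict(self) -> dict:
        return {
            "E": self.E,
            "nCf": self.nCf,
            "nTf": self.nTf,
            "n_reads_used": self.n_reads_used,
        }


def filter_quality(
    reads: Sequence[RRBSRead],
    phred_cutoff: int = 20,
    min_fraction_above: float = 0.9,
) -> list[RRBSRead]:
    """Keep reads where >= min_fraction_above of bases reach the Phred cutoff."""
    if not 0 <= phred_cutoff <= 41:
        raise ConfigurationError("phred_cutoff must be in [0, 41]")
    if not 0.0 <= min_fraction_above <= 1.0:
        raise ConfigurationError("min_fraction_above must be in [0,1]")
    kept = []
    for r in reads:
        n_good = sum(q >= phred_cutoff for q in r.qualities)
        if n_good >= min_fraction_above * len(r.qualities):
            kept.append(r)
    return kept


def filter_start_ygg(reads: Sequence[RRBSRead]) -> list[RRBSRead]:
    """Keep reads beginning CGG or TGG (YGG); shorter-than-3 reads drop out.

    Every genuine RRBS read starts at an MspI cut and therefore begins CGG
    (methylated, unconverted) or TGG (converted); anything else is noise.
    """
    return [r for r in reads if len(r.sequence) >= 3 and r.sequence[:3] in ("CGG", "TGG")]


def find_adapter(
    read: RRBSRead, adapter: str, min_overlap: int = 11
) -> Optional[int]:
    """Locate the 3' adapter in a read by exact suffix/prefix overlap.

    Returns the leftmost index at which a prefix of ``adapter`` of length
    >= ``min_overlap`` exactly matches the read suffix, or None. Leftmost
    match wins when an adapter prefix also occurs internally.
    """
    if min_overlap < 1:
        raise ConfigurationError("min_overlap must be >= 1")
    seq = read.sequence
    n = len(seq)
    for start in range(0, n - min_overlap + 1):
        overlap = n - start
        if overlap > len(adapter):
            continue
        if seq[start:] == adapter[:overlap]:
            return start
    return None


def estimate_conversion_error(
    reads: Sequence[RRBSRead], adapter: str, min_overlap: int = 11
) -> ConversionErrorEstimate:
    """Estimate E = nCf/(nCf+nTf) from fill-in basecalls in adapter reads.

    The fill-in base is the base immediately preceding the located adapter
    start. Basecalls other than C or T at that position are ignored.
    """
    nCf = nTf = used = 0
    for r in reads:
        start = find_adapter(r, adapter, min_overlap)
        if start is None or start < 1:
            continue
        used += 1
        base = r.sequence[start - 1]
        if base == "C":
            nCf += 1
        elif base == "T":
            nTf += 1
    if used == 0:
        raise NoAdapterReadsError(
            "no adapter-containing reads: cannot estimate conversion error"
        )
    total = nCf + nTf
    E = nCf / total if total else 0.0
    return ConversionErrorEstimate(E=E, nCf=nCf, nTf=nTf, n_reads_used=used)
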