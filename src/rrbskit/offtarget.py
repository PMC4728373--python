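"""dsRNA off-target prediction by exhaustive k-mer matching.

The dsRNA sequence is diced into every possible k-mer (19 by default, the
length of a Dicer product) and each k-mer is searched, exactly, against
every transcript and against its reverse complement — a k-mer matching the
antisense of a transcript would silence it just as well. Any transcript
other than the intended target that collects hits is a candidate
off-target.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Sequence

import pandas as pd

from .errors import ConfigurationError

_COMPLEMENT = str.maketrans("ACGT", "TGCA")

DEFAULT_K = 19


def reverse_complement(seq: str) -> str:
    return seq.translate(_COMPLEMENT)[::-1]


@dataclass(frozen=True)
class OffTargetHit:
    """One exact k-mer match within a transcript."""

    kmer: str
    transcript_id: str
    position: int  # 0-based offset of the matching window in the transcript
    matched_complement: bool


def _normalize(seq: str) -> str:
    return seq.upper().replace("U", "T")


def dice_kmers(sequence: str, k: int = DEFAULT_K) -> list[str]:
    """All len(sequence)-k+1 substrings of length k, in order."""
    if k < 1:
        raise ConfigurationError("k must be >= 1")
    seq = _normalize(sequence)
    return [seq[i : i + k] for i in range(len(seq) - k + 1)]


def scan_transcriptome(
    kmers: Sequence[str],
    transcriptome: dict[str, str],
    k: int = DEFAULT_K,
) -> list[OffTargetHit]:
    """Exact-match every k-mer against transcripts and their complements.

    A window matching a query k-mer directly is a sense hit; a window whose
    reverse complement is a query k-mer is reported at the same transcript
    coordinate with ``matched_complement=True``. Hits are sorted by
    (transcript, position, strand-of-match).
    """
    kset = {_normalize(km) for km in kmers if len(km) == k}
    hits: list[OffTargetHit] = []
    for tid in sorted(transcriptome):
        seq = _normalize(transcriptome[tid])
        for p in range(len(seq) - k + 1):
            w = seq[p : p + k]
            if w in kset:
                hits.append(OffTargetHit(w, tid, p, False))
            rw = reverse_complement(w)
            if rw in kset:
                hits.append(OffTargetHit(rw, tid, p, True))
    hits.sort(key=lambda h: (h.transcript_id, h.position, h.matched_complement))
    return hits


def hits_per_transcript(hits: Sequence[OffTargetHit]) -> pd.DataFrame:
    """Per-transcript hit counts (total / sense / antisense)."""
    rows: dict[str, dict[str, int]] = {}
    for h in hits:
        row = rows.setdefault(
            h.transcript_id, {"n_hits": 0, "n_sense": 0, "n_antisense": 0}
        )
        row["n_hits"] += 1
        row["n_antisense" if h.matched_complement else "n_sense"] += 1
    return pd.DataFrame(
        [{"transcript_id": t, **row} for t, row in sorted(rows.items())],
        columns=["transcript_id", "n_hits", "n_sense", "n_antisense"],
    )
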