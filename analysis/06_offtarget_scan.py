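#!/usr/bin/env python
"""Off-target check of a dsRNA construct against the simulated transcriptome.

Builds transcript sequences from the simulated gene models (spliced
exons), designs a dsRNA against the first gene, dices it into all 19-mers
and scans every transcript and its complement for exact matches. The
construct must self-hit its own transcript and should hit nothing else.
"""

import argparse
from pathlib import Path

import pandas as pd

from rrbskit import dice_kmers, hits_per_transcript, io, scan_transcriptome


def main():
    ap = argparse.ArgumentParser(description=__doc__)
    ap.add_argument("--studydir", type=Path, default=Path("results/study"))
    ap.add_argument("--dsrna-len", type=int, default=200)
    args = ap.parse_args()
    genome = io.read_genome(args.studydir / "genome.fa")
    genes = io.read_gff3(args.studydir / "genes.gff3")
    transcriptome = {
        g.gene_id: "".join(genome[g.contig][s:e] for s, e in g.exons) for g in genes
    }
    io.write_fasta(transcriptome, args.studydir / "transcriptome.fa")

    target = genes[0].gene_id
    dsrna = transcriptome[target][: args.dsrna_len]
    kmers = dice_kmers(dsrna, 19)
    hits = scan_transcriptome(kmers, transcriptome, 19)
    summary = hits_per_transcript(hits)
    summary.to_csv(args.studydir / "offtarget_summary.tsv", sep="\t", index=False)
    pd.DataFrame(
        [
            {"kmer": h.kmer, "transcript_id": h.transcript_id,
             "position0": h.position, "matched_complement": int(h.matched_complement)}
            for h in hits
        ]
    ).to_csv(args.studydir / "offtarget_hits.tsv", sep="\t", index=False)

    off = summary[summary.transcript_id != target]
    print(f"dsRNA against {target}: {len(kmers)} 19-mers, "
          f"{int(summary[summary.transcript_id == target].n_hits.iloc[0])} self-hits, "
          f"{len(off)} off-target transcripts")
    if len(off):
        print(off.to_string(index=False))


if __name__ == "__main__":
    main()
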