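#!/usr/bin/env python
"""Pile up per-cytosine counts and call methylated CpGs per condition.

Each covered cytosine with depth >= 5 is tested against the estimated
conversion error with the one-sided binomial tail, BH-corrected at 1% FDR.
Also reports the low/mid/high split of methylation levels, which should be
strongly bimodal for CpGs.
"""

import argparse
import json
from pathlib import Path

from rrbskit import bimodality_summary, call_methylation, io, pileup


def main():
    ap = argparse.ArgumentParser(description=__doc__)
    ap.add_argument("--studydir", type=Path, default=Path("results/study"))
    args = ap.parse_args()
    genome = io.read_genome(args.studydir / "genome.fa")
    for cond in ("LD", "SD"):
        reads = io.read_fastq(args.studydir / f"reads_{cond}.filtered.fastq")
        est = json.loads((args.studydir / f"conversion_error_{cond}.json").read_text())
        counts = pileup(reads, genome)
        calls = call_methylation(counts, est["E"], fdr=0.01)
        io.write_cytosine_report(counts, args.studydir / f"cytosine_report_{cond}.tsv")
        io.write_calls_tsv(calls, args.studydir / f"calls_{cond}.tsv")
        mc = [c for c in calls if c.is_methylated]
        io.write_bed([(c.site.contig, c.site.pos) for c in mc],
                     args.studydir / f"mc_{cond}.bed", name="mC")
        cpg_calls = [c for c in calls if c.site.context == "CpG"]
        split = bimodality_summary(cpg_calls, 10, 90)
        print(f"{cond}: {len(counts)} covered cytosines, {len(calls)} tested, "
              f"{len(mc)} called methylated at 1% FDR")
        print(f"  CpG level split <10% / mid / >90%: "
              f"{split.frac_low:.2f} / {split.frac_mid:.2f} / {split.frac_high:.2f}")


if __name__ == "__main__":
    main()
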