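#!/usr/bin/env python
"""Assign methylated CpGs to genomic features and summarize gene coverage.

Partitions mCpGs into exon/intron/promoter/intergenic (precedence in that
order, promoters = 2 kb strand-aware upstream) and counts genes with at
least 5 and at least 10 covered CpG sites.
"""

import argparse
from pathlib import Path

import pandas as pd

from rrbskit import build_feature_index, feature_fractions, gene_cpg_coverage_summary, io


def main():
    ap = argparse.ArgumentParser(description=__doc__)
    ap.add_argument("--studydir", type=Path, default=Path("results/study"))
    args = ap.parse_args()
    genome = io.read_genome(args.studydir / "genome.fa")
    genes = io.read_gff3(args.studydir / "genes.gff3")
    index = build_feature_index(genes, promoter_len=2000, contig_lengths=genome.lengths())

    rows = []
    for cond in ("LD", "SD"):
        sites = []
        with open(args.studydir / f"mc_{cond}.bed") as fh:
            for line in fh:
                parts = line.split("\t")
                sites.append((parts[0], int(parts[1])))
        fractions = feature_fractions(sites, index)
        rows.append({"condition": cond, "n_mc": len(sites), **fractions})
        print(f"{cond}: {len(sites)} mCpGs -> " + ", ".join(
            f"{k} {100 * v:.1f}%" for k, v in fractions.items()))

    counts_ld = io.read_cytosine_report(args.studydir / "cytosine_report_LD.tsv")
    coverage = gene_cpg_coverage_summary(counts_ld, genes, thresholds=(5, 10))
    print(f"genes with >=5 covered CpGs (LD): {coverage[5]}/{len(genes)}; "
          f">=10: {coverage[10]}/{len(genes)}")

    pd.DataFrame(rows).to_csv(args.studydir / "feature_fractions.tsv", sep="\t", index=False)


if __name__ == "__main__":
    main()
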