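#!/usr/bin/env python
"""Simulate the synthetic RRBS study: genome, methylomes, reads.

Generates a two-contig genome seeded with MspI sites, gene models, a
bimodal exon-concentrated CpG methylome with 50 planted differential CpGs
between long-day (LD) and short-day (SD) conditions, and bisulfite reads
from the MspI-digested, size-selected library for both conditions.
Everything lands under results/study/.
"""

import argparse
from pathlib import Path

from rrbskit import PipelineConfig, digest_mspi, generate_genome, generate_methylome, io, simulate_reads


def main():
    ap = argparse.ArgumentParser(description=__doc__)
    ap.add_argument("--seed", type=int, default=1)
    ap.add_argument("--outdir", type=Path, default=Path("results/study"))
    args = ap.parse_args()
    cfg = PipelineConfig(seed=args.seed)
    out = args.outdir
    out.mkdir(parents=True, exist_ok=True)

    genome, genes = generate_genome(
        n_contigs=cfg.n_contigs, contig_len=cfg.contig_len,
        gc_fraction=cfg.gc_fraction, gene_density=cfg.gene_density,
        seed=args.seed, ccgg_per_kb=cfg.ccgg_per_kb,
    )
    truth = generate_methylome(
        genome, genes, n_dmc=cfg.n_dmc, dmc_effect=cfg.dmc_effect,
        seed=args.seed + 1, conversion_failure_rate=cfg.conversion_failure_rate,
    )
    fragments = digest_mspi(genome, cfg.min_fragment_len, cfg.max_fragment_len)

    io.write_genome(genome, out / "genome.fa")
    io.write_gff3(genes, out / "genes.gff3")
    io.write_truth_tsv(truth, out / "truth.tsv")
    for ci, cond in enumerate(("LD", "SD")):
        reads = simulate_reads(
            fragments, truth, read_len=cfg.read_len, depth=cfg.depth,
            adapter=cfg.adapter, seq_error=cfg.seq_error,
            seed=args.seed + 2 + ci, condition=cond,
        )
        io.write_fastq(reads, out / f"reads_{cond}.fastq")
        print(f"{cond}: {len(reads)} reads of {cfg.read_len} bp")

    n_dmc = len(truth.planted_dmcs)
    print(f"genome: {sum(genome.lengths().values())} bp, {len(genes)} genes, "
          f"{len(truth.sites)} CpG sites ({n_dmc} planted DMCs)")
    print(f"library: {len(fragments)} MspI fragments retained "
          f"({cfg.min_fragment_len}-{cfg.max_fragment_len} bp)")


if __name__ == "__main__":
    main()
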