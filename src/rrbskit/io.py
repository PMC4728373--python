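"""Readers and writers for the pipeline's on-disk interfaces.

Standard formats go through Biopython (FASTA/FASTQ) and gffutils (GFF3);
tabular interchange uses pandas TSV. Genomic coordinates are 0-based
half-open in memory, GFF3 is written 1-based inclusive, and the cytosine
report uses a 1-based ``pos1`` column.
"""

from __future__ import annotations

import json
from pathlib import Path
from typing import Iterable, Optional, Sequence

import gffutils
import pandas as pd
from Bio import SeqIO
from Bio.Seq import Seq
from Bio.SeqRecord import SeqRecord

from .simulate import GeneModel, GenomeSequence, RRBSRead, SyntheticTruth, TruthSite


# ---------------------------------------------------------------- FASTA

def write_fasta(sequences: dict[str, str], path) -> None:
    records = [
        SeqRecord(Seq(seq), id=name, description="") for name, seq in sequences.items()
    ]
    SeqIO.write(records, str(path), "fasta")


def read_fasta(path) -> dict[str, str]:
    return {rec.id: str(rec.seq).upper() for rec in SeqIO.parse(str(path), "fasta")}


def write_genome(genome: GenomeSequence, path) -> None:
    write_fasta(genome.contigs, path)


def read_genome(path) -> GenomeSequence:
    return GenomeSequence(read_fasta(path))


# ---------------------------------------------------------------- GFF3

def write_gff3(genes: Sequence[GeneModel], path) -> None:
    """Write gene/exon models as GFF3 (1-based inclusive coordinates)."""
    with open(path, "w") as fh:
        fh.write("##gff-version 3\n")
        for g in genes:
            fh.write(
                f"{g.contig}\trrbskit\tgene\t{g.start + 1}\t{g.end}\t.\t"
                f"{g.strand}\t.\tID={g.gene_id}\n"
            )
            for xi, (s, e) in enumerate(g.exons):
                fh.write(
                    f"{g.contig}\trrbskit\texon\t{s + 1}\t{e}\t.\t{g.strand}\t.\t"
                    f"ID={g.gene_id}.e{xi + 1};Parent={g.gene_id}\n"
                )


def read_gff3(path) -> list[GeneModel]:
    """Parse gene/exon models written by :func:`write_gff3`."""
    db = gffutils.create_db(str(path), dbfn=":memory:", force=True, keep_order=True)
    genes = []
    for g in db.features_of_type("gene"):
        exons = tuple(
            sorted(
                (e.start - 1, e.end)
                for e in db.children(g, featuretype="exon")
            )
        )
        genes.append(
            GeneModel(
                gene_id=g.id,
                contig=g.seqid,
                strand=g.strand,
                start=g.start - 1,
                end=g.end,
                exons=exons,
            )
        )
    genes.sort(key=lambda g: (g.contig, g.start))
    return genes


# ---------------------------------------------------------------- FASTQ

def _read_description(read: RRBSRead) -> str:
    contig, pos, strand = read.origin
    parts = [
        f"origin={contig}:{pos}:{strand}",
        f"condition={read.condition}",
    ]
    if read.adapter_start is not None:
        parts.append(f"adapter_start={read.adapter_start}")
    if read.fillin_pos is not None:
        parts.append(f"fillin={read.fillin_pos}")
    return " ".join(parts)


def write_fastq(reads: Sequence[RRBSRead], path) -> None:
    """Write reads as Phred+33 FASTQ; origin metadata in the description."""
    records = []
    for r in reads:
        rec = SeqRecord(
            Seq(r.sequence), id=r.read_id, description=_read_description(r)
        )
        rec.letter_annotations["phred_quality"] = list(r.qualities)
        records.append(rec)
    SeqIO.write(records, str(path), "fastq")


def read_fastq(path) -> list[RRBSRead]:
    reads = []
    for rec in SeqIO.parse(str(path), "fastq"):
        fields = dict(
            kv.split("=", 1) for kv in rec.description.split()[1:] if "=" in kv
        )
        contig, pos, strand = fields["origin"].rsplit(":", 2)
        reads.append(
            RRBSRead(
                read_id=rec.id,
                sequence=str(rec.seq),
                qualities=tuple(rec.letter_annotations["phred_quality"]),
                origin=(contig, int(pos), strand),
                condition=fields.get("condition", "LD"),
                adapter_start=(
                    int(fields["adapter_start"]) if "adapter_start" in fields else None
                ),
                fillin_pos=int(fields["fillin"]) if "fillin" in fields else None,
            )
        )
    return reads


# ---------------------------------------------------------------- truth TSV

def write_truth_tsv(truth: SyntheticTruth, path) -> None:
    rows = [
        {
            "contig": s.contig,
            "pos0": s.pos,
            "strand": s.strand,
            "context": s.context,
            "p_meth_LD": s.p_meth_LD,
            "p_meth_SD": s.p_meth_SD,
            "is_dmc": int(s.is_planted_dmc),
            "dmc_direction": s.dmc_direction or ".",
        }
        for s in truth.sites.values()
    ]
    pd.DataFrame(
        rows,
        columns=[
            "contig", "pos0", "strand", "context",
            "p_meth_LD", "p_meth_SD", "is_dmc", "dmc_direction",
        ],
    ).to_csv(path, sep="\t", index=False)


def read_truth_tsv(path, conversion_failure_rate: float = 0.006, seed: int = 0) -> SyntheticTruth:
    df = pd.read_csv(path, sep="\t")
    sites = {}
    for row in df.itertuples(index=False):
        key = (row.contig, int(row.pos0), row.strand)
        sites[key] = TruthSite(
            contig=row.contig,
            pos=int(row.pos0),
            strand=row.strand,
            context=row.context,
            p_meth_LD=float(row.p_meth_LD),
            p_meth_SD=float(row.p_meth_SD),
            is_planted_dmc=bool(row.is_dmc),
            dmc_direction=None if row.dmc_direction == "." else row.dmc_direction,
        )
    return SyntheticTruth(sites, conversion_failure_rate, seed)


# ---------------------------------------------------------------- reports

CYTOSINE_REPORT_COLUMNS = [
    "contig", "pos1", "strand", "count_methylated", "count_unmethylated", "context",
]


def write_cytosine_report(counts, path) -> None:
    """Per-cytosine counts TSV with 1-based positions, header included."""
    rows = [
        {
            "contig": c.contig,
            "pos1": c.pos + 1,
            "strand": c.strand,
            "count_methylated": c.K,
            "count_unmethylated": c.U,
            "context": c.context,
        }
        for c in counts
    ]
    pd.DataFrame(rows, columns=CYTOSINE_REPORT_COLUMNS).to_csv(
        path, sep="\t", index=False
    )


def read_cytosine_report(path):
    from .calling import CytosineCount

    df = pd.read_csv(path, sep="\t")
    return [
        CytosineCount(
            contig=row.contig,
            pos=int(row.pos1) - 1,
            strand=row.strand,
            context=row.context,
            K=int(row.count_methylated),
            U=int(row.count_unmethylated),
        )
        for row in df.itertuples(index=False)
    ]


def write_calls_tsv(calls, path) -> None:
    rows = [
        {
            "contig": c.site.contig,
            "pos1": c.site.pos + 1,
            "strand": c.site.strand,
            "count_methylated": c.site.K,
            "count_unmethylated": c.site.U,
            "context": c.site.context,
            "p_value": c.p_value,
            "q_value": c.q_value,
            "is_methylated": int(c.is_methylated),
            "level_percent": c.level,
        }
        for c in calls
    ]
    pd.DataFrame(
        rows,
        columns=CYTOSINE_REPORT_COLUMNS[:3]
        + ["count_methylated", "count_unmethylated", "context",
           "p_value", "q_value", "is_methylated", "level_percent"],
    ).to_csv(path, sep="\t", index=False)


def write_bed(sites: Iterable[tuple[str, int]], path, name: str = ".") -> None:
    """0-based half-open single-base BED records."""
    with open(path, "w") as fh:
        for contig, pos in sites:
            fh.write(f"{contig}\t{pos}\t{pos + 1}\t{name}\n")


def write_dmc_tsv(records, path) -> None:
    rows = []
    for r in records:
        s = r.site
        rows.append(
            {
                "contig": s.contig,
                "pos1": s.pos + 1,
                "strand": s.strand,
                "K_LD": s.K_LD,
                "U_LD": s.U_LD,
                "K_SD": s.K_SD,
                "U_SD": s.U_SD,
                "level_LD_pct": s.level_LD,
                "level_SD_pct": s.level_SD,
                "p_value": r.p_value,
                "q_value": r.q_value,
                "direction": r.direction,
                "gene_id": r.gene_id,
            }
        )
    pd.DataFrame(
        rows,
        columns=[
            "contig", "pos1", "strand", "K_LD", "U_LD", "K_SD", "U_SD",
            "level_LD_pct", "level_SD_pct", "p_value", "q_value",
            "direction", "gene_id",
        ],
    ).to_csv(path, sep="\t", index=False)


def write_json(obj, path) -> None:
    Path(path).write_text(json.dumps(obj, indent=2, sort_keys=True) + "\n")
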