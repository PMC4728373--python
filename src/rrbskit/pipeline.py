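"""End-to-end orchestration: simulate -> preprocess -> call -> DMC -> annotate.

``run_pipeline`` executes the whole study on synthetic data for both
photoperiod conditions, writes every interface file under the configured
output directory, and returns (and writes) a manifest of record counts,
conversion-error estimates, methylation-call and DMC summaries, feature
fractions, and planted-DMC recovery statistics against the simulator's
ground-truth registry. Reruns with the same config are byte-identical.
"""

from __future__ import annotations

import dataclasses
import json
from dataclasses import dataclass, field
from pathlib import Path
from typing import Optional

import numpy as np
import yaml

from . import annotation, calling, differential, io, preprocess, simulate
from .errors import ConfigurationError, PipelineStageError

CONDITIONS = ("LD", "SD")


@dataclass
class PipelineConfig:
    """All tunables of the synthetic study and analysis thresholds."""

    seed: int = 0
    # genome / methylome
    n_contigs: int = 2
    contig_len: int = 50_000
    gc_fraction: float = 0.42
    gene_density: float = 1.0
    ccgg_per_kb: float = 4.0
    low_beta: tuple[float, float] = (1.0, 20.0)
    high_beta: tuple[float, float] = (20.0, 1.0)
    high_fraction_exon: float = 0.20
    high_fraction_other: float = 0.01
    n_dmc: int = 50
    dmc_effect: float = 0.6
    conversion_failure_rate: float = 0.006
    # library
    read_len: int = 50
    depth: int = 30
    adapter: str = simulate.DEFAULT_ADAPTER
    seq_error: float = 0.001
    # Lower bound below the nominal 40 bp gel window: real size selection
    # leaks short fragments, and only inserts shorter than
    # read_len - min_overlap - 1 read through into >= 11 adapter bases,
    # which is what the conversion-error estimator needs.
    min_fragment_len: int = 20
    max_fragment_len: int = 200
    # analysis thresholds (defaults follow the study)
    phred_cutoff: int = 20
    min_fraction_above: float = 0.9
    min_overlap: int = 11
    mc_fdr: float = 0.01
    dmc_fdr: float = 0.05
    min_depth: int = 10
    promoter_len: int = 2000
    k: int = 19
    output_dir: str = "results/pipeline"

    def validate(self) -> "PipelineConfig":
        checks = [
            (0 <= self.phred_cutoff <= 41, "phred_cutoff"),
            (0.0 <= self.min_fraction_above <= 1.0, "min_fraction_above"),
            (self.min_overlap >= 1, "min_overlap"),
            (0.0 < self.mc_fdr < 1.0, "mc_fdr"),
            (0.0 < self.dmc_fdr < 1.0, "dmc_fdr"),
            (self.min_depth >= 1, "min_depth"),
            (self.promoter_len >= 0, "promoter_len"),
            (self.k >= 1, "k"),
            (0.0 <= self.conversion_failure_rate <= 1.0, "conversion_failure_rate"),
            (0.0 <= self.seq_error < 1.0, "seq_error"),
            (self.read_len >= 3, "read_len"),
            (self.depth >= 1, "depth"),
            (0 <= self.min_fragment_len <= self.max_fragment_len, "min_fragment_len"),
            (self.seed >= 0, "seed"),
        ]
        for ok, name in checks:
            if not ok:
                raise ConfigurationError(f"config value out of range: {name}")
        return self


def validate_config(path) -> PipelineConfig:
    """Load a YAML config file; unknown keys and out-of-range values error."""
    raw = yaml.safe_load(Path(path).read_text()) or {}
    if not isinstance(raw, dict):
        raise ConfigurationError("config file must contain a mapping")
    known = {f.name for f in dataclasses.fields(PipelineConfig)}
    unknown = set(raw) - known
    if unknown:
        raise ConfigurationError(f"unknown config keys: {sorted(unknown)}")
    for key in ("low_beta", "high_beta"):
        if key in raw:
            raw[key] = tuple(raw[key])
    return PipelineConfig(**raw).validate()


def _child_seeds(seed: int, n: int) -> list[int]:
    rng = np.random.default_rng(seed)
    return [int(s) for s in rng.integers(0, 2**31 - 1, size=n)]


def run_pipeline(config: PipelineConfig) -> dict:
    """Run every stage for both conditions and write a reproducibility manifest."""
    config.validate()
    out = Path(config.output_dir)
    out.mkdir(parents=True, exist_ok=True)
    failed_marker = out / "FAILED"
    if failed_marker.exists():
        failed_marker.unlink()
    seeds = _child_seeds(config.seed, 4)
    manifest: dict = {"seed": config.seed, "config": _config_dict(config)}
    stage = "simulate"
    try:
        genome, genes = simulate.generate_genome(
            n_contigs=config.n_contigs,
            contig_len=config.contig_len,
            gc_fraction=config.gc_fraction,
            gene_density=config.gene_density,
            seed=seeds[0],
            ccgg_per_kb=config.ccgg_per_kb,
        )
        truth = simulate.generate_methylome(
            genome,
            genes,
            low_beta=config.low_beta,
            high_beta=config.high_beta,
            high_fraction_exon=config.high_fraction_exon,
            high_fraction_other=config.high_fraction_other,
            n_dmc=config.n_dmc,
            dmc_effect=config.dmc_effect,
            seed=seeds[1],
            conversion_failure_rate=config.conversion_failure_rate,
        )
        fragments = simulate.digest_mspi(
            genome, config.min_fragment_len, config.max_fragment_len
        )
        io.write_genome(genome, out / "genome.fa")
        io.write_gff3(genes, out / "genes.gff3")
        io.write_truth_tsv(truth, out / "truth.tsv")
        reads_by_cond = {}
        for ci, cond in enumerate(CONDITIONS):
            reads = simulate.simulate_reads(
                fragments,
                truth,
                read_len=config.read_len,
                depth=config.depth,
                adapter=config.adapter,
                seq_error=config.seq_error,
                seed=seeds[2 + ci],
                condition=cond,
            )
            io.write_fastq(reads, out / f"reads_{cond}.fastq")
            reads_by_cond[cond] = reads
        manifest["simulate"] = {
            "n_genes": len(genes),
            "n_cpg_sites": len(truth.sites),
            "n_planted_dmcs": len(truth.planted_dmcs),
            "n_fragments_retained": len(fragments),
            "reads": {c: len(r) for c, r in reads_by_cond.items()},
        }

        stage = "preprocess"
        counts_by_cond = {}
        calls_by_cond = {}
        estimates = {}
        filter_report = {}
        for cond in CONDITIONS:
            raw = reads_by_cond[cond]
            q_ok = preprocess.filter_quality(
                raw, config.phred_cutoff, config.min_fraction_above
            )
            ygg_ok = preprocess.filter_start_ygg(q_ok)
            est = preprocess.estimate_conversion_error(
                ygg_ok, config.adapter, config.min_overlap
            )
            estimates[cond] = est
            filter_report[cond] = {
                "reads_in": len(raw),
                "after_quality": len(q_ok),
                "after_ygg": len(ygg_ok),
            }
            io.write_fastq(ygg_ok, out / f"reads_{cond}.filtered.fastq")
            io.write_json(est.as_dict(), out / f"conversion_error_{cond}.json")

            stage = "call"
            counts = calling.pileup(ygg_ok, genome)
            io.write_cytosine_report(counts, out / f"cytosine_report_{cond}.tsv")
            calls = calling.call_methylation(counts, est.E, fdr=config.mc_fdr)
            io.write_calls_tsv(calls, out / f"calls_{cond}.tsv")
            mc = [c for c in calls if c.is_methylated]
            io.write_bed(
                [(c.site.contig, c.site.pos) for c in mc],
                out / f"mc_{cond}.bed",
                name="mC",
            )
            counts_by_cond[cond] = counts
            calls_by_cond[cond] = calls
            manifest.setdefault("calling", {})[cond] = {
                "covered_cytosines": len(counts),
                "tested_sites": len(calls),
                "mc_count": len(mc),
            }
            stage = "preprocess"
        manifest["preprocess"] = {
            "filters": filter_report,
            "conversion_error": {c: e.as_dict() for c, e in estimates.items()},
        }

        stage = "differential"
        pairs = differential.joint_coverage_filter(
            counts_by_cond["LD"], counts_by_cond["SD"], config.min_depth
        )
        cpg_pairs = [
            p
            for p in pairs
            if calling.classify_context(genome, p.contig, p.pos, p.strand) == "CpG"
        ]
        records = differential.call_dmcs(cpg_pairs, fdr=config.dmc_fdr)
        gene_table = differential.map_dmcs_to_genes(
            [r for r in records if r.is_dmc], genes, config.promoter_len
        )
        io.write_dmc_tsv([r for r in records if r.is_dmc], out / "dmcs.tsv")
        gene_table.to_csv(out / "dmc_genes.tsv", sep="\t", index=False)
        io.write_bed(
            [(r.site.contig, r.site.pos) for r in records if r.is_dmc],
            out / "dmcs.bed",
            name="DMC",
        )
        dmcs = [r for r in records if r.is_dmc]
        recovery = _dmc_recovery(dmcs, truth)
        manifest["differential"] = {
            "paired_cpg_sites": len(cpg_pairs),
            "dmc_count": len(dmcs),
            "n_hyper_LD": sum(r.direction == "hyper_LD" for r in dmcs),
            "n_hypo_LD": sum(r.direction == "hypo_LD" for r in dmcs),
            "unique_genes": int(len(gene_table)),
            "planted_recovery": recovery,
        }

        stage = "annotate"
        index = annotation.build_feature_index(
            genes, config.promoter_len, genome.lengths()
        )
        mc_ld = [
            (c.site.contig, c.site.pos)
            for c in calls_by_cond["LD"]
            if c.is_methylated
        ]
        fractions = annotation.feature_fractions(mc_ld, index) if mc_ld else {}
        coverage = annotation.gene_cpg_coverage_summary(
            counts_by_cond["LD"], genes, thresholds=(5, 10)
        )
        manifest["annotation"] = {
            "mc_feature_fractions_LD": fractions,
            "genes_with_covered_cpgs_LD": {str(k): v for k, v in coverage.items()},
        }
    except Exception as exc:  # noqa: BLE001 - annotate failures with the stage
        failed_marker.write_text(f"{stage}: {exc}\n")
        raise PipelineStageError(stage, str(exc)) from exc

    io.write_json(manifest, out / "manifest.json")
    return manifest


def _config_dict(config: PipelineConfig) -> dict:
    d = dataclasses.asdict(config)
    d["low_beta"] = list(d["low_beta"])
    d["high_beta"] = list(d["high_beta"])
    return d


def _dmc_recovery(dmcs, truth: simulate.SyntheticTruth) -> dict:
    """Compare called DMCs against the planted ground-truth registry."""
    planted = {
        (s.contig, s.pos, s.strand): s.dmc_direction for s in truth.planted_dmcs
    }
    called = {(r.site.contig, r.site.pos, r.site.strand): r.direction for r in dmcs}
    true_pos = set(called) & set(planted)
    direction_match = sum(
        1 for key in true_pos if called[key] == planted[key]
    )
    return {
        "n_planted": len(planted),
        "n_called": len(called),
        "n_true_positive": len(true_pos),
        "n_false_positive": len(called) - len(true_pos),
        "n_direction_match": direction_match,
    }
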