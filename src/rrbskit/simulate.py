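"""Synthetic RRBS study generator.

Builds everything the downstream stages consume, with known ground truth:
a random genome seeded with MspI sites (CCGG), simple gene models, a
bimodal CpG methylome with planted differentially methylated CpGs between
a long-day (LD) and a short-day (SD) condition, and bisulfite-converted
reads from an MspI-digested, size-selected library.

Chemistry emulated per read molecule:

* each CpG cytosine is methylated with its site's true probability for the
  read's condition; methylated C resists bisulfite conversion and reads C;
* unmethylated C (CpG or not) converts and reads T, except with the
  conversion-failure probability, in which case it still reads C;
* one always-unmethylated cytosine is filled in at the fragment 3' end
  during end repair of the CG overhang — its basecall is the handle the
  conversion-error estimator uses;
* fragments shorter than the read length read through into the adapter;
* a uniform substitution error is applied last.

Coordinates are 0-based half-open throughout; reads are simulated from the
plus strand only.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterable, Optional, Sequence

import numpy as np

from .errors import ConfigurationError

# Default adapter: Illumina TruSeq universal adapter prefix (33 bp).
DEFAULT_ADAPTER = "AGATCGGAAGAGCACACGTCTGAACTCCAGTCA"

_BASE_BYTES = np.frombuffer(b"ACGT", dtype=np.uint8)
_C, _G, _T = ord("C"), ord("G"), ord("T")
# base byte -> index in ACGT (255 = not a base)
_BASE_INDEX = np.full(256, 255, dtype=np.uint8)
for _i, _b in enumerate(b"ACGT"):
    _BASE_INDEX[_b] = _i


@dataclass(frozen=True)
class GenomeSequence:
    """Uppercase A/C/G/T contigs keyed by unique contig name."""

    contigs: dict[str, str]

    def __post_init__(self):
        if not self.contigs:
            raise ConfigurationError("genome must contain at least one contig")
        for name, seq in self.contigs.items():
            if set(seq) - set("ACGT"):
                raise ConfigurationError(
                    f"contig {name!r} contains non-ACGT characters"
                )

    def __getitem__(self, name: str) -> str:
        return self.contigs[name]

    def __contains__(self, name: str) -> bool:
        return name in self.contigs

    def lengths(self) -> dict[str, int]:
        return {name: len(seq) for name, seq in self.contigs.items()}


@dataclass(frozen=True)
class GeneModel:
    """A gene span with ordered, non-overlapping exons (0-based half-open)."""

    gene_id: str
    contig: str
    strand: str
    start: int
    end: int
    exons: tuple[tuple[int, int], ...]

    def __post_init__(self):
        if self.strand not in ("+", "-"):
            raise ConfigurationError(f"bad strand {self.strand!r}")
        if self.end <= self.start:
            raise ConfigurationError("gene end must exceed start")
        prev = self.start
        for s, e in self.exons:
            if s < prev or e <= s or e > self.end:
                raise ConfigurationError(
                    f"exons of {self.gene_id} not sorted/disjoint within span"
                )
            prev = e
        if not self.exons:
            raise ConfigurationError(f"gene {self.gene_id} has no exons")


@dataclass
class TruthSite:
    """Ground-truth record for one CpG cytosine (plus strand)."""

    contig: str
    pos: int
    strand: str
    context: str
    p_meth_LD: float
    p_meth_SD: float
    is_planted_dmc: bool = False
    dmc_direction: Optional[str] = None  # hyper_LD | hypo_LD

    def p_meth(self, condition: str) -> float:
        if condition == "LD":
            return self.p_meth_LD
        if condition == "SD":
            return self.p_meth_SD
        raise ConfigurationError(f"unknown condition {condition!r}")


@dataclass
class SyntheticTruth:
    """Registry of true per-site methylation probabilities per condition."""

    sites: dict[tuple[str, int, str], TruthSite]
    conversion_failure_rate: float
    seed: int

    def __post_init__(self):
        if not 0.0 <= self.conversion_failure_rate <= 1.0:
            raise ConfigurationError("conversion_failure_rate outside [0,1]")

    @property
    def planted_dmcs(self) -> list[TruthSite]:
        return [s for s in self.sites.values() if s.is_planted_dmc]

    def p_meth(self, contig: str, pos: int, condition: str) -> float:
        site = self.sites.get((contig, pos, "+"))
        return site.p_meth(condition) if site is not None else 0.0


@dataclass(frozen=True)
class Fragment:
    """An MspI restriction fragment; carries its sequence for convenience."""

    contig: str
    start: int
    end: int
    sequence: str

    def __len__(self) -> int:
        return self.end - self.start


@dataclass
class RRBSRead:
    """A simulated single-end bisulfite read with its ground-truth origin."""

    read_id: str
    sequence: str
    qualities: tuple[int, ...]
    origin: tuple[str, int, str]  # (contig, pos, strand) of the fragment 5' end
    condition: str
    adapter_start: Optional[int] = None
    fillin_pos: Optional[int] = None  # index of the synthetic fill-in base

    def __post_init__(self):
        if len(self.sequence) != len(self.qualities):
            raise ConfigurationError("sequence/quality length mismatch")
        if self.adapter_start is not None and self.adapter_start >= len(self.sequence):
            raise ConfigurationError("adapter_start beyond read end")


def generate_genome(
    n_contigs: int = 1,
    contig_len: int = 10_000,
    gc_fraction: float = 0.42,
    gene_density: float = 1.0,
    seed: int = 0,
    ccgg_per_kb: float = 2.0,
    gene_len_range: tuple[int, int] = (500, 1500),
    max_exons: int = 4,
) -> tuple[GenomeSequence, list[GeneModel]]:
    """Generate a random genome with seeded CCGG motifs and gene models.

    ``gene_density`` is genes per kb; genes are placed without overlap,
    strand-assigned at random, and split into 1..max_exons exons whose first
    and last exons abut the gene boundaries. Deterministic for a fixed seed.
    """
    if contig_len < 1000:
        raise ConfigurationError("contig_len must be >= 1000")
    if not 0.0 < gc_fraction < 1.0:
        raise ConfigurationError("gc_fraction must be in (0,1)")
    if n_contigs < 1:
        raise ConfigurationError("n_contigs must be >= 1")
    if gene_density < 0:
        raise ConfigurationError("gene_density must be >= 0")
    if ccgg_per_kb <= 0:
        raise ConfigurationError("ccgg_per_kb must be > 0")

    rng = np.random.default_rng(seed)
    probs = np.array(
        [(1 - gc_fraction) / 2, gc_fraction / 2, gc_fraction / 2, (1 - gc_fraction) / 2]
    )
    contigs: dict[str, str] = {}
    genes: list[GeneModel] = []
    for ci in range(n_contigs):
        name = f"contig{ci + 1}"
        arr = rng.choice(_BASE_BYTES, size=contig_len, p=probs)
        n_motif = max(1, round(ccgg_per_kb * contig_len / 1000))
        for pos in rng.integers(0, contig_len - 4, size=n_motif):
            arr[pos : pos + 4] = np.frombuffer(b"CCGG", dtype=np.uint8)
        contigs[name] = arr.tobytes().decode("ascii")

        n_genes = int(round(gene_density * contig_len / 1000))
        spans: list[tuple[int, int]] = []
        attempts = 0
        while len(spans) < n_genes and attempts < 50 * (n_genes + 1):
            attempts += 1
            lo, hi = gene_len_range
            length = int(rng.integers(lo, hi + 1))
            if length >= contig_len:
                continue
            s = int(rng.integers(0, contig_len - length))
            e = s + length
            if all(e <= gs or s >= ge for gs, ge in spans):
                spans.append((s, e))
        spans.sort()
        for gi, (s, e) in enumerate(spans):
            strand = "+" if rng.random() < 0.5 else "-"
            k = int(rng.integers(1, max_exons + 1))
            exons = _split_exons(rng, s, e, k)
            genes.append(
                GeneModel(
                    gene_id=f"{name}_g{gi + 1:03d}",
                    contig=name,
                    strand=strand,
                    start=s,
                    end=e,
                    exons=exons,
                )
            )
    return GenomeSequence(contigs), genes


def _split_exons(
    rng: np.random.Generator, start: int, end: int, k: int
) -> tuple[tuple[int, int], ...]:
    """Partition [start,end) into k exons separated by k-1 introns."""
    n_cuts = 2 * k - 2
    if n_cuts == 0 or end - start <= n_cuts + 1:
        return ((start, end),)
    cuts = np.sort(rng.choice(np.arange(start + 1, end), size=n_cuts, replace=False))
    bounds = [start, *cuts.tolist(), end]
    # segments alternate exon, intron, exon, ... starting and ending on exons
    return tuple(
        (bounds[i], bounds[i + 1]) for i in range(0, len(bounds) - 1, 2)
    )


def find_cpg_sites(genome: GenomeSequence) -> list[tuple[str, int]]:
    """All plus-strand CpG cytosine positions, in genomic order."""
    out: list[tuple[str, int]] = []
    for name in genome.contigs:
        arr = np.frombuffer(genome[name].encode("ascii"), dtype=np.uint8)
        hits = np.flatnonzero((arr[:-1] == _C) & (arr[1:] == _G))
        out.extend((name, int(p)) for p in hits)
    return out


def generate_methylome(
    genome: GenomeSequence,
    genes: Sequence[GeneModel],
    low_beta: tuple[float, float] = (1.0, 20.0),
    high_beta: tuple[float, float] = (20.0, 1.0),
    high_fraction_exon: float = 0.20,
    high_fraction_other: float = 0.01,
    n_dmc: int = 50,
    dmc_effect: float = 0.6,
    seed: int = 0,
    conversion_failure_rate: float = 0.006,
) -> SyntheticTruth:
    """Draw a bimodal CpG methylome and plant differential CpGs.

    Each plus-strand CpG draws its true level from a two-component beta
    mixture; exonic CpGs pick the high component with ``high_fraction_exon``,
    all others with ``high_fraction_other``, concentrating methylation in
    exons. Both conditions share the same level except at ``n_dmc`` planted
    sites where the two conditions are separated by at least ``dmc_effect``,
    half hypermethylated and half hypomethylated in LD.
    """
    for a, b in (low_beta, high_beta):
        if a <= 0 or b <= 0:
            raise ConfigurationError("beta parameters must be positive")
    for f in (high_fraction_exon, high_fraction_other):
        if not 0.0 <= f <= 1.0:
            raise ConfigurationError("high fractions must be in [0,1]")
    if not 0.0 < dmc_effect < 1.0:
        raise ConfigurationError("dmc_effect must be in (0,1)")

    sites = find_cpg_sites(genome)
    n = len(sites)
    if n_dmc > n:
        raise ConfigurationError(f"n_dmc={n_dmc} exceeds {n} CpG sites")

    exon_mask = _exonic_mask(genome, genes)
    rng = np.random.default_rng(seed)
    is_exonic = np.array([exon_mask[c][p] for c, p in sites], dtype=bool) if n else np.zeros(0, bool)
    p_high = np.where(is_exonic, high_fraction_exon, high_fraction_other)
    take_high = rng.random(n) < p_high
    low = rng.beta(low_beta[0], low_beta[1], size=n)
    high = rng.beta(high_beta[0], high_beta[1], size=n)
    levels = np.where(take_high, high, low)

    registry: dict[tuple[str, int, str], TruthSite] = {}
    for (contig, pos), lvl in zip(sites, levels):
        registry[(contig, pos, "+")] = TruthSite(
            contig=contig,
            pos=pos,
            strand="+",
            context="CpG",
            p_meth_LD=float(lvl),
            p_meth_SD=float(lvl),
        )

    if n_dmc > 0:
        idx = rng.choice(n, size=n_dmc, replace=False)
        hypo = np.zeros(n_dmc, dtype=bool)
        hypo[: n_dmc // 2] = True
        hypo = hypo[rng.permutation(n_dmc)]
        margin = min(0.02, (1.0 - dmc_effect) / 2)
        for i, site_i in enumerate(idx):
            contig, pos = sites[site_i]
            lo_max = max(margin, 1.0 - dmc_effect - margin)
            lo = float(rng.uniform(margin, lo_max))
            hi = min(1.0, lo + dmc_effect)
            site = registry[(contig, pos, "+")]
            site.is_planted_dmc = True
            if hypo[i]:
                site.dmc_direction = "hypo_LD"
                site.p_meth_LD, site.p_meth_SD = lo, hi
            else:
                site.dmc_direction = "hyper_LD"
                site.p_meth_LD, site.p_meth_SD = hi, lo

    return SyntheticTruth(
        sites=registry,
        conversion_failure_rate=conversion_failure_rate,
        seed=seed,
    )


def _exonic_mask(
    genome: GenomeSequence, genes: Sequence[GeneModel]
) -> dict[str, np.ndarray]:
    masks = {name: np.zeros(len(seq), dtype=bool) for name, seq in genome.contigs.items()}
    for g in genes:
        for s, e in g.exons:
            masks[g.contig][s:e] = True
    return masks


def digest_mspi(
    genome: GenomeSequence,
    min_len: int = 40,
    max_len: Optional[int] = 200,
) -> list[Fragment]:
    """In-silico MspI digestion (cut C^CGG) with fragment size selection.

    Cuts between the first and second base of every CCGG occurrence, so every
    internal fragment begins with "CGG" and ends in "...C". Fragments whose
    length falls outside [min_len, max_len] are discarded; pass ``min_len=0,
    max_len=None`` for the raw digest. Fragments come back in genomic order.
    """
    if max_len is not None and min_len > max_len:
        raise ConfigurationError("min_len must not exceed max_len")
    out: list[Fragment] = []
    for name, seq in genome.contigs.items():
        cuts = [0]
        i = seq.find("CCGG")
        while i != -1:
            cuts.append(i + 1)
            i = seq.find("CCGG", i + 1)
        cuts.append(len(seq))
        for s, e in zip(cuts, cuts[1:]):
            if e <= s:
                continue
            length = e - s
            if length < min_len or (max_len is not None and length > max_len):
                continue
            out.append(Fragment(name, s, e, seq[s:e]))
    return out


@dataclass
class _FragmentPlan:
    """Per-fragment cache used by the read simulator."""

    template: np.ndarray  # uint8 bases
    c_idx: np.ndarray  # indices of C bases
    p_meth_ld: np.ndarray
    p_meth_sd: np.ndarray


def simulate_reads(
    fragments: Sequence[Fragment],
    truth: SyntheticTruth,
    read_len: int = 50,
    depth: int = 30,
    adapter: str = DEFAULT_ADAPTER,
    seq_error: float = 0.001,
    seed: int = 0,
    condition: str = "LD",
    base_quality: int = 40,
) -> list[RRBSRead]:
    """Simulate single-end bisulfite reads from the fragment 5' ends.

    ``depth * n_fragments`` reads are drawn uniformly (with replacement)
    over the internal fragments (those beginning "CGG", so every read starts
    YGG after conversion unless a sequencing error hits base 0). Short
    fragments read through the fill-in base into the adapter.
    """
    if read_len < 3:
        raise ConfigurationError("read_len must be >= 3")
    if len(adapter) < 11:
        raise ConfigurationError("adapter must be >= 11 bases")
    if depth < 1:
        raise ConfigurationError("depth must be >= 1")
    if condition not in ("LD", "SD"):
        raise ConfigurationError(f"unknown condition {condition!r}")
    if not 0.0 <= seq_error < 1.0:
        raise ConfigurationError("seq_error must be in [0,1)")

    usable = [f for f in fragments if f.sequence.startswith("CGG")]
    if not usable:
        return []

    conv = truth.conversion_failure_rate
    adapter_bytes = np.frombuffer(adapter.encode("ascii"), dtype=np.uint8)
    rng = np.random.default_rng(seed)

    plans: list[_FragmentPlan] = []
    for f in usable:
        template = np.frombuffer(f.sequence.encode("ascii"), dtype=np.uint8).copy()
        c_idx = np.flatnonzero(template == _C)
        p_ld = np.empty(len(c_idx))
        p_sd = np.empty(len(c_idx))
        for j, ci in enumerate(c_idx):
            site = truth.sites.get((f.contig, f.start + int(ci), "+"))
            if site is None:
                p_ld[j] = p_sd[j] = 0.0
            else:
                p_ld[j], p_sd[j] = site.p_meth_LD, site.p_meth_SD
        plans.append(_FragmentPlan(template, c_idx, p_ld, p_sd))

    n_reads = depth * len(usable)
    picks = rng.integers(0, len(usable), size=n_reads)
    reads: list[RRBSRead] = []
    for serial, fi in enumerate(picks):
        frag = usable[fi]
        plan = plans[fi]
        p_meth = plan.p_meth_ld if condition == "LD" else plan.p_meth_sd

        arr = plan.template.copy()
        if len(plan.c_idx):
            methylated = rng.random(len(plan.c_idx)) < p_meth
            converted = rng.random(len(plan.c_idx)) < (1.0 - conv)
            to_t = plan.c_idx[~methylated & converted]
            arr[to_t] = _T
        fill_in = _T if rng.random() < (1.0 - conv) else _C

        frag_len = len(frag)
        pieces = [arr, np.array([fill_in], dtype=np.uint8)]
        adapter_start = None
        if frag_len + 1 < read_len:
            pieces.append(adapter_bytes)
            adapter_start = frag_len + 1
        seq = np.concatenate(pieces)[:read_len]
        fillin_pos = frag_len if frag_len < read_len else None
        if adapter_start is not None and adapter_start >= len(seq):
            adapter_start = None

        if seq_error > 0:
            hit = np.flatnonzero(rng.random(len(seq)) < seq_error)
            if len(hit):
                shift = rng.integers(1, 4, size=len(hit))
                seq[hit] = _BASE_BYTES[(_BASE_INDEX[seq[hit]] + shift) % 4]

        reads.append(
            RRBSRead(
                read_id=f"{condition}:{frag.contig}:{frag.start}-{frag.end}:{serial}",
                sequence=seq.tobytes().decode("ascii"),
                qualities=(base_quality,) * len(seq),
                origin=(frag.contig, frag.start, "+"),
                condition=condition,
                adapter_start=adapter_start,
                fillin_pos=fillin_pos,
            )
        )
    return reads
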