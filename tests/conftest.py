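import numpy as np
import pytest

from rrbskit import (
    GeneModel,
    GenomeSequence,
    RRBSRead,
    digest_mspi,
    generate_genome,
    generate_methylome,
    simulate_reads,
)


def make_read(
    sequence,
    qualities=None,
    read_id="r1",
    origin=("contig1", 0, "+"),
    condition="LD",
    adapter_start=None,
    fillin_pos=None,
):
    if qualities is None:
        qualities = (40,) * len(sequence)
    return RRBSRead(
        read_id=read_id,
        sequence=sequence,
        qualities=tuple(qualities),
        origin=origin,
        condition=condition,
        adapter_start=adapter_start,
        fillin_pos=fillin_pos,
    )


@pytest.fixture(scope="session")
def small_study():
    """A small but complete synthetic study shared across tests."""
    genome, genes = generate_genome(
        n_contigs=1, contig_len=20_000, gene_density=1.0, seed=11, ccgg_per_kb=6.0
    )
    truth = generate_methylome(
        genome, genes, n_dmc=20, dmc_effect=0.6, seed=12
    )
    fragments = digest_mspi(genome, 20, 200)
    reads = simulate_reads(fragments, truth, depth=20, seq_error=0.0, seed=13)
    return {
        "genome": genome,
        "genes": genes,
        "truth": truth,
        "fragments": fragments,
        "reads": reads,
    }


@pytest.fixture
def plus_gene():
    return GeneModel(
        gene_id="gA",
        contig="contig1",
        strand="+",
        start=5000,
        end=8000,
        exons=((5000, 5500), (7000, 8000)),
    )
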