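"""Generator contracts: determinism, digestion rules, bisulfite chemistry."""

import numpy as np
import pytest
from scipy import stats

from rrbskit import (
    ConfigurationError,
    GenomeSequence,
    digest_mspi,
    find_cpg_sites,
    generate_genome,
    generate_methylome,
    simulate_reads,
)


class TestGenerateGenome:
    def test_deterministic_and_seed_sensitive(self):
        g1, genes1 = generate_genome(1, 10_000, 0.42, 1.0, seed=7)
        g2, genes2 = generate_genome(1, 10_000, 0.42, 1.0, seed=7)
        g3, _ = generate_genome(1, 10_000, 0.42, 1.0, seed=8)
        assert g1.contigs == g2.contigs and genes1 == genes2
        assert g1.contigs != g3.contigs

    def test_gene_density_and_structure(self):
        g, genes = generate_genome(1, 10_000, 0.42, 1.0, seed=7)
        assert 7 <= len(genes) <= 10  # ~1 gene/kb, non-overlap permitting
        for gene in genes:
            assert gene.exons[0][0] == gene.start
            assert gene.exons[-1][1] == gene.end
        # ~1 CCGG per kb guaranteed by motif seeding
        assert g["contig1"].count("CCGG") >= 10

    def test_zero_gene_density(self):
        _, genes = generate_genome(1, 10_000, 0.42, 0.0, seed=7)
        assert genes == []

    @pytest.mark.parametrize(
        "kwargs",
        [dict(contig_len=500), dict(gc_fraction=0.0), dict(gc_fraction=1.0), dict(n_contigs=0)],
    )
    def test_invalid_parameters(self, kwargs):
        base = dict(n_contigs=1, contig_len=10_000, gc_fraction=0.42, gene_density=1.0, seed=0)
        base.update(kwargs)
        with pytest.raises(ConfigurationError):
            generate_genome(**base)


class TestDigestMspi:
    def test_cut_rule(self):
        g = GenomeSequence({"c": "AACCGGTT" + "A" * 992})
        frags = digest_mspi(g, 0, None)
        assert [f.sequence[:8] for f in frags][0] == "AAC"
        assert frags[0].sequence == "AAC"
        assert frags[1].sequence.startswith("CGGTT")

    def test_no_ccgg_gives_whole_contig(self):
        g = GenomeSequence({"c": "AT" * 600})
        frags = digest_mspi(g, 0, None)
        assert len(frags) == 1 and len(frags[0]) == 1200
        assert digest_mspi(g, 40, 200) == []

    def test_internal_fragments_begin_cgg_end_c(self, small_study):
        frags = digest_mspi(small_study["genome"], 0, None)
        internal = frags[1:-1]
        assert internal, "expected internal fragments"
        assert all(f.sequence.startswith("CGG") for f in internal)
        assert all(f.sequence.endswith("C") for f in internal)

    @pytest.mark.parametrize("seed", range(10))
    def test_concatenation_conserves_genome(self, seed):
        genome, _ = generate_genome(1, 2_000, 0.5, 0.0, seed=seed)
        frags = digest_mspi(genome, 0, None)
        assert "".join(f.sequence for f in frags) == genome["contig1"]

    def test_min_above_max_rejected(self, small_study):
        with pytest.raises(ConfigurationError):
            digest_mspi(small_study["genome"], 100, 50)


class TestGenerateMethylome:
    def test_null_methylome_all_low(self):
        genome, genes = generate_genome(1, 5_000, 0.5, 1.0, seed=1)
        truth = generate_methylome(
            genome, genes, high_fraction_exon=0.0, high_fraction_other=0.0,
            n_dmc=0, seed=2,
        )
        levels = [s.p_meth_LD for s in truth.sites.values()]
        # all levels from Beta(1,20): mean 1/21
        assert np.mean(levels) < 0.1

    def test_planted_dmc_bookkeeping(self):
        genome, genes = generate_genome(1, 10_000, 0.5, 1.0, seed=1)
        truth = generate_methylome(genome, genes, n_dmc=50, dmc_effect=0.6, seed=5)
        planted = truth.planted_dmcs
        assert len(planted) == 50
        hypo = sum(s.dmc_direction == "hypo_LD" for s in planted)
        assert hypo == 25
        for s in planted:
            assert abs(s.p_meth_LD - s.p_meth_SD) >= 0.6 - 1e-12
            expected = "hypo_LD" if s.p_meth_LD < s.p_meth_SD else "hyper_LD"
            assert s.dmc_direction == expected

    def test_bimodal_mixture_mass(self):
        """Mass in the mid range matches the analytic beta-mixture value."""
        analytic = 0.5 * (
            stats.beta.cdf(0.8, 1, 20) - stats.beta.cdf(0.2, 1, 20)
        ) + 0.5 * (stats.beta.cdf(0.8, 20, 1) - stats.beta.cdf(0.2, 20, 1))
        assert analytic < 0.10
        genome, genes = generate_genome(1, 20_000, 0.5, 1.0, seed=3, ccgg_per_kb=6.0)
        truth = generate_methylome(
            genome, genes, high_fraction_exon=0.5, high_fraction_other=0.5,
            n_dmc=0, seed=4,
        )
        levels = np.array([s.p_meth_LD for s in truth.sites.values()])
        mid = np.mean((levels >= 0.2) & (levels <= 0.8))
        sd = np.sqrt(analytic * (1 - analytic) / len(levels))
        assert mid < 0.10
        assert abs(mid - analytic) < 4 * sd + 1e-9

    def test_too_many_dmcs_rejected(self):
        genome, genes = generate_genome(1, 1_000, 0.5, 0.0, seed=1, ccgg_per_kb=1.0)
        n = len(find_cpg_sites(genome))
        with pytest.raises(ConfigurationError):
            generate_methylome(genome, genes, n_dmc=n + 1, seed=0)


class TestSimulateReads:
    def _study(self, **meth_kwargs):
        genome, genes = generate_genome(1, 20_000, 0.5, 1.0, seed=21, ccgg_per_kb=8.0)
        truth = generate_methylome(genome, genes, n_dmc=0, seed=22, **meth_kwargs)
        frags = digest_mspi(genome, 20, 200)
        return genome, truth, frags

    def test_perfect_conversion_all_unmethylated(self):
        genome, truth, frags = self._study(
            high_fraction_exon=0.0, high_fraction_other=0.0
        )
        for s in truth.sites.values():
            s.p_meth_LD = s.p_meth_SD = 0.0
        truth.conversion_failure_rate = 0.0
        reads = simulate_reads(frags, truth, depth=3, seq_error=0.0, seed=1)
        frag_by_start = {(f.contig, f.start): f for f in frags}
        for r in reads:
            frag = frag_by_start[r.origin[:2]]
            usable = min(len(r.sequence), r.fillin_pos or len(r.sequence))
            for i in range(usable):
                if frag.sequence[i] == "C":
                    assert r.sequence[i] == "T"

    def test_full_methylation_cpg_reads_c(self):
        genome, truth, frags = self._study()
        for s in truth.sites.values():
            s.p_meth_LD = s.p_meth_SD = 1.0
        truth.conversion_failure_rate = 0.0
        reads = simulate_reads(frags, truth, depth=3, seq_error=0.0, seed=2)
        cpg = set((c, p) for c, p in find_cpg_sites(genome))
        frag_by_start = {(f.contig, f.start): f for f in frags}
        for r in reads:
            frag = frag_by_start[r.origin[:2]]
            usable = min(len(r.sequence), r.fillin_pos or len(r.sequence))
            for i in range(usable):
                if frag.sequence[i] != "C":
                    continue
                gpos = frag.start + i
                expected = "C" if (frag.contig, gpos) in cpg else "T"
                assert r.sequence[i] == expected

    def test_short_fragment_contains_adapter_and_fillin(self):
        genome, truth, frags = self._study()
        short = [f for f in frags if len(f) + 1 < 50 - 11]
        assert short, "need read-through fragments"
        reads = simulate_reads(short, truth, read_len=50, depth=2, seq_error=0.0, seed=3)
        for r in reads:
            assert r.adapter_start is not None
            assert r.fillin_pos == r.adapter_start - 1
            overlap = len(r.sequence) - r.adapter_start
            assert overlap >= 11

    def test_fillin_t_fraction_tracks_conversion_failure(self):
        genome, truth, frags = self._study()
        truth.conversion_failure_rate = 0.05
        short = [f for f in frags if len(f) + 1 < 50]
        reads = simulate_reads(short, truth, depth=60, seq_error=0.0, seed=4)
        fills = [r.sequence[r.fillin_pos] for r in reads if r.fillin_pos is not None]
        frac_t = fills.count("T") / len(fills)
        sd = np.sqrt(0.05 * 0.95 / len(fills))
        assert abs(frac_t - 0.95) < 3 * sd

    def test_mean_methylation_converges_to_truth(self):
        """Law of large numbers: per-site C fraction approaches the truth."""
        genome, truth, frags = self._study(
            high_fraction_exon=0.5, high_fraction_other=0.5
        )
        truth.conversion_failure_rate = 0.0
        reads = simulate_reads(frags, truth, depth=500, seq_error=0.0, seed=5)
        counts: dict[tuple[str, int], list[int]] = {}
        frag_by_start = {(f.contig, f.start): f for f in frags}
        for r in reads:
            frag = frag_by_start[r.origin[:2]]
            usable = min(len(r.sequence), r.fillin_pos or len(r.sequence))
            for i in range(usable):
                if frag.sequence[i] == "C":
                    kc = counts.setdefault((frag.contig, frag.start + i), [0, 0])
                    kc[0] += r.sequence[i] == "C"
                    kc[1] += 1
        checked = 0
        for key, (k, n) in counts.items():
            site = truth.sites.get((key[0], key[1], "+"))
            if site is None or n < 200:
                continue
            p = site.p_meth_LD
            sd = np.sqrt(max(p * (1 - p), 1e-6) / n)
            assert abs(k / n - p) < max(3 * sd, 0.02)
            checked += 1
        assert checked > 20

    def test_reads_begin_ygg(self):
        genome, truth, frags = self._study()
        reads = simulate_reads(frags, truth, depth=2, seq_error=0.0, seed=6)
        assert all(r.sequence[:3] in ("CGG", "TGG") for r in reads)

    def test_fastq_byte_determinism(self, tmp_path, small_study):
        from rrbskit import io

        for run in ("a", "b"):
            reads = simulate_reads(
                small_study["fragments"], small_study["truth"], depth=5, seed=99
            )
            io.write_fastq(reads, tmp_path / f"{run}.fastq")
        assert (tmp_path / "a.fastq").read_bytes() == (tmp_path / "b.fastq").read_bytes()

    def test_read_len_too_short_rejected(self, small_study):
        with pytest.raises(ConfigurationError):
            simulate_reads(
                small_study["fragments"], small_study["truth"], read_len=2, seed=0
            )
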