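"""Context classification, pileup, and the binomial/error-rate caller."""

from fractions import Fraction
from math import comb

import numpy as np
import pytest

from rrbskit import (
    ConfigurationError,
    CytosineCount,
    GenomeSequence,
    MethylationCall,
    benjamini_hochberg,
    bimodality_summary,
    call_methylation,
    classify_context,
    pileup,
)
from conftest import make_read


def binomial_tail_oracle(K, N, E):
    """Exact-rational tail sum P(X >= K), independent of scipy."""
    e = Fraction(E).limit_denominator(10**9)
    return float(sum(comb(N, i) * e**i * (1 - e) ** (N - i) for i in range(K, N + 1)))


class TestClassifyContext:
    @pytest.mark.parametrize(
        "seq,pos,expected",
        [("ACGA" * 300, 1, "CpG"), ("ACAGA" * 240, 1, "CHG"), ("ACAAT" * 240, 1, "CHH")],
    )
    def test_plus_strand_rule(self, seq, pos, expected):
        g = GenomeSequence({"c": seq})
        assert classify_context(g, "c", pos, "+") == expected

    def test_minus_strand_reverse_complement_rule(self):
        # minus-strand C at a G position; context read 5'->3' on the minus strand
        g = GenomeSequence({"c": "ACGT" * 300})
        # pos 2 is G; its complement is C; next minus-strand base is complement
        # of pos 1 (C) = G -> CpG
        assert classify_context(g, "c", 2, "-") == "CpG"

    def test_truncated_context_flagged_chh(self):
        g = GenomeSequence({"c": "A" * 999 + "C"})
        ctx, truncated = classify_context(g, "c", 999, "+", with_flag=True)
        assert ctx == "CHH" and truncated

    def test_non_c_base_rejected(self):
        g = GenomeSequence({"c": "ACGT" * 300})
        with pytest.raises(ConfigurationError):
            classify_context(g, "c", 0, "+")


class TestPileup:
    @pytest.fixture
    def genome(self):
        return GenomeSequence({"c": "ACGTT" + "A" * 995})

    def test_counts_c_and_t(self, genome):
        reads = [
            make_read("ACGTT", origin=("c", 0, "+"), read_id="a"),
            make_read("ATGTT", origin=("c", 0, "+"), read_id="b"),
        ]
        counts = pileup(reads, genome)
        assert len(counts) == 1
        c = counts[0]
        assert (c.pos, c.K, c.U, c.N, c.context) == (1, 1, 1, 2, "CpG")

    def test_other_base_ignored(self, genome):
        reads = [
            make_read("ACGTT", origin=("c", 0, "+")),
            make_read("AGGTT", origin=("c", 0, "+")),
        ]
        counts = pileup(reads, genome)
        assert (counts[0].K, counts[0].U, counts[0].N) == (1, 0, 1)

    def test_empty_reads(self, genome):
        assert pileup([], genome) == []

    def test_fillin_and_adapter_excluded(self):
        g = GenomeSequence({"c": "ACGTC" + "CGG" + "A" * 992})
        # fragment covers [0,5); index 5 is the fill-in basecall, 6+ adapter.
        # The genomic C at pos 5 must not receive the fill-in T.
        read = make_read("ACGTT" + "T" + "AGATCGGAAG", origin=("c", 0, "+"),
                         adapter_start=6, fillin_pos=5)
        counts = {c.pos: c for c in pileup([read], g)}
        assert set(counts) == {1, 4}
        assert (counts[1].K, counts[1].U) == (1, 0)
        assert (counts[4].K, counts[4].U) == (0, 1)

    def test_origin_outside_genome_is_error(self, genome):
        read = make_read("ACGTT", origin=("c", 998, "+"))
        with pytest.raises(ConfigurationError):
            pileup([read], genome)


class TestCallMethylation:
    def test_zero_k_never_called(self):
        counts = [CytosineCount("c", 1, "+", "CpG", 0, 100)]
        calls = call_methylation(counts, 0.006, fdr=0.5)
        assert calls[0].p_value == 1.0 and not calls[0].is_methylated

    def test_fully_methylated_always_called(self):
        counts = [CytosineCount("c", 1, "+", "CpG", 50, 0)]
        calls = call_methylation(counts, 0.006, fdr=1e-6)
        assert calls[0].p_value < 1e-100 and calls[0].is_methylated

    @pytest.mark.parametrize(
        "K,N,E",
        [(3, 90, 0.0068), (1, 5, 0.006), (10, 90, 0.0062), (90, 90, 0.0068),
         (2, 200, 0.01), (7, 150, 0.005)],
    )
    def test_p_matches_exact_summation_oracle(self, K, N, E):
        counts = [CytosineCount("c", 1, "+", "CpG", K, N - K)]
        call = call_methylation(counts, E, fdr=0.01)[0]
        oracle = binomial_tail_oracle(K, N, E)
        assert call.p_value == pytest.approx(oracle, rel=1e-12)

    def test_min_depth_floor(self):
        counts = [CytosineCount("c", 1, "+", "CpG", 2, 2)]
        assert call_methylation(counts, 0.006, min_depth=5) == []
        assert len(call_methylation(counts, 0.006, min_depth=4)) == 1

    def test_degenerate_null_rejected(self):
        counts = [CytosineCount("c", 1, "+", "CpG", 2, 2)]
        with pytest.raises(ConfigurationError):
            call_methylation(counts, 1.0)

    def test_level_percent(self):
        counts = [CytosineCount("c", 1, "+", "CpG", 3, 7)]
        assert call_methylation(counts, 0.006)[0].level == pytest.approx(30.0)


class TestBenjaminiHochberg:
    def test_single_p(self):
        q, flags = benjamini_hochberg([0.01], 0.05)
        assert q[0] == pytest.approx(0.01) and flags[0]

    def test_stepup_arithmetic(self):
        q, _ = benjamini_hochberg([0.001, 0.02, 0.9], 0.05)
        assert np.allclose(q, [0.003, 0.03, 0.9])

    def test_ties(self):
        q, _ = benjamini_hochberg([0.02, 0.02], 0.05)
        assert np.allclose(q, [0.02, 0.02])

    def test_invariant_under_input_order(self):
        rng = np.random.default_rng(5)
        p = rng.uniform(size=200)
        perm = rng.permutation(200)
        q, _ = benjamini_hochberg(p, 0.05)
        qp, _ = benjamini_hochberg(p[perm], 0.05)
        assert np.allclose(q[perm], qp)

    def test_rejects_out_of_range(self):
        with pytest.raises(ConfigurationError):
            benjamini_hochberg([0.5, 1.5], 0.05)


class TestBimodalitySummary:
    def test_levels_split(self):
        calls = [
            MethylationCall(CytosineCount("c", i, "+", "CpG", k, 100 - k), 0.5, 0.5, False)
            for i, k in enumerate([1, 2, 95, 99])
        ]
        s = bimodality_summary(calls, 10, 90)
        assert tuple(s) == (0.5, 0.0, 0.5)

    def test_all_mid(self):
        calls = [
            MethylationCall(CytosineCount("c", i, "+", "CpG", 50, 50), 0.5, 0.5, False)
            for i in range(4)
        ]
        assert tuple(bimodality_summary(calls, 10, 90)) == (0.0, 1.0, 0.0)

    def test_empty_flag(self):
        s = bimodality_summary([], 10, 90)
        assert s.is_empty and tuple(s) == (0.0, 0.0, 0.0)

    def test_bimodal_methylome_at_depth(self):
        """Sampled levels from a (Beta(1,20), Beta(20,1)) methylome stay bimodal."""
        rng = np.random.default_rng(7)
        n = 4000
        high = rng.random(n) < 0.5
        p = np.where(high, rng.beta(20, 1, n), rng.beta(1, 20, n))
        depth = 200
        K = rng.binomial(depth, p)
        calls = [
            MethylationCall(
                CytosineCount("c", i, "+", "CpG", int(k), depth - int(k)), 0.5, 0.5, True
            )
            for i, k in enumerate(K)
        ]
        s = bimodality_summary(calls, 20, 80)
        assert s.frac_mid < 0.15
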