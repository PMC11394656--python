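"""Positional base biases and the ping-pong 5'-overlap signature."""

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

import pirnascape as pk
from pirnascape.signatures import AlignmentRecord, ping_pong_profile_naive


class TestPositionalBaseFrequencies:
    def test_shared_first_base_has_fraction_one(self):
        m = pk.positional_base_frequencies([("UAAA", 1), ("UGGG", 1)], 4)
        assert m.fraction(1, "U") == pytest.approx(1.0)
        assert m.fraction(2, "A") == pytest.approx(0.5)

    def test_uniform_random_sequences_are_near_quarter(self):
        rng = np.random.default_rng(0)
        seqs = [
            ("".join(rng.choice(list("ACGT"), size=30)), 1) for _ in range(10_000)
        ]
        m = pk.positional_base_frequencies(seqs, 30)
        for pos in range(1, 31):
            for base in "UAGC":
                assert abs(m.fraction(pos, base) - 0.25) < 0.02

    def test_short_sequences_only_cover_their_positions(self):
        m = pk.positional_base_frequencies([("AC", 1)], 5)
        assert 3 not in m.freq
        assert m.fraction(2, "C") == pytest.approx(1.0)

    def test_per_position_fractions_sum_to_one(self):
        m = pk.positional_base_frequencies([("ACGTT", 2), ("GGC", 3)], 5)
        for pos, fr in m.freq.items():
            assert sum(fr.values()) == pytest.approx(1.0, abs=1e-9)

    def test_empty_input_raises(self):
        with pytest.raises(ValueError):
            pk.positional_base_frequencies([], 5)

    def test_primary_first_base_bias_recovered(self):
        # realised 1U rate on simulated primary piRNAs matches q1U; a sparse
        # genome keeps first-write-wins dilution below the tolerance
        genome = pk.simulate_genome(10_000_000, 0.15, 0.01, seed=1)
        cfg = pk.GeneratorConfig(
            class_fractions={"BSB": {"piRNA": 1.0}}, pingpong_fraction=0.0,
            n_reads=50_000,
        )
        reads, _, _ = pk.simulate_library(cfg, genome, "BSB", seed=2)
        m = pk.positional_base_frequencies([(r.sequence, r.count) for r in reads], 1)
        assert m.fraction(1, "U") == pytest.approx(0.85, abs=0.01)


class TestPositionEnrichment:
    def test_homopolymer_is_flat(self):
        enr, _ = pk.position_enrichment([("AAAA", 1)] * 3, "A", 4)
        assert all(e == pytest.approx(1.0) for e in enr.values())

    def test_single_site_enrichment_is_inverse_frequency(self):
        enr, argmax = pk.position_enrichment([("GGGGGGGGGA", 1)], "A", 10)
        assert argmax == 10
        assert enr[10] == pytest.approx(10.0)

    def test_absent_base_raises(self):
        with pytest.raises(ValueError, match="never occurs"):
            pk.position_enrichment([("GGGG", 1)], "A", 4)


class TestFirstBaseByLength:
    def test_uniform_first_base(self):
        fbl = pk.first_base_by_length([("T" + "G" * 29, 1), ("T" + "C" * 29, 2)])
        assert fbl.fraction(30, "U") == pytest.approx(1.0)

    def test_known_mixture_fractions(self):
        seqs = [("T" + "G" * 28, 3), ("A" + "G" * 28, 1), ("C" + "G" * 29, 2)]
        fbl = pk.first_base_by_length(seqs)
        assert fbl.fraction(29, "U") == pytest.approx(0.75)
        assert fbl.fraction(29, "A") == pytest.approx(0.25)
        assert fbl.fraction(30, "C") == pytest.approx(1.0)

    def test_candidates_prefer_u_at_every_window_length(self, bsb_small):
        cands = pk.call_pirna_candidates(bsb_small[0])
        fbl = pk.first_base_by_length([(c.read.sequence, c.read.count) for c in cands])
        for length in range(27, 33):
            assert fbl.fraction(length, "U") >= 0.5


def _aln(rid, start, end, strand, chrom="chr1", count=1):
    return AlignmentRecord(rid, chrom, start, end, strand, count)


@st.composite
def alignment_sets(draw):
    n = draw(st.integers(1, 60))
    alns = []
    for i in range(n):
        start = draw(st.integers(0, 300))
        length = draw(st.integers(15, 35))
        strand = draw(st.sampled_from("+-"))
        chrom = draw(st.sampled_from(["chr1", "chr2"]))
        count = draw(st.integers(1, 3))
        alns.append(_aln(f"r{i}", start, start + length, strand, chrom, count))
    return alns


class TestPingPongProfile:
    def test_ten_nt_overlap_pair_lands_in_bin_ten(self):
        prof = pk.ping_pong_profile(
            [_aln("p", 100, 130, "+"), _aln("m", 91, 110, "-")]
        )
        assert prof.overlap_counts[10] == 1
        assert sum(prof.overlap_counts.values()) == 1

    def test_reads_on_different_chromosomes_never_pair(self):
        prof = pk.ping_pong_profile(
            [_aln("p", 100, 130, "+", "chr1"), _aln("m", 91, 110, "-", "chr2")]
        )
        assert all(v == 0 for v in prof.overlap_counts.values())
        assert prof.z10 == 0.0

    def test_no_pairs_gives_zero_profile(self):
        assert pk.ping_pong_profile([]).z10 == 0.0

    @given(alignment_sets())
    @settings(max_examples=60, deadline=None)
    def test_sweep_equals_all_pairs_oracle(self, alns):
        fast = pk.ping_pong_profile(alns)
        slow = ping_pong_profile_naive(alns)
        assert fast.overlap_counts == slow.overlap_counts
        assert fast.z10 == pytest.approx(slow.z10)

    @given(alignment_sets())
    @settings(max_examples=40, deadline=None)
    def test_symmetric_under_strand_relabel_and_reflection(self, alns):
        C = 1000
        mirrored = [
            _aln(a.read_id, C - a.end, C - a.start,
                 "-" if a.strand == "+" else "+", a.chrom, a.count)
            for a in alns
        ]
        assert (
            pk.ping_pong_profile(alns).overlap_counts
            == pk.ping_pong_profile(mirrored).overlap_counts
        )

    @given(alignment_sets(), alignment_sets())
    @settings(max_examples=40, deadline=None)
    def test_additive_over_disjoint_chromosomes(self, a, b):
        a = [_aln(x.read_id, x.start, x.end, x.strand, "cA", x.count) for x in a]
        b = [_aln(x.read_id, x.start, x.end, x.strand, "cB", x.count) for x in b]
        combined = pk.ping_pong_profile(a + b).overlap_counts
        pa = pk.ping_pong_profile(a).overlap_counts
        pb = pk.ping_pong_profile(b).overlap_counts
        assert combined == {o: pa[o] + pb[o] for o in pa}

    def test_uniform_count_scaling_leaves_z10_unchanged(self, bsb_small):
        alns = bsb_small[1][:2000]
        scaled = [
            _aln(a.read_id, a.start, a.end, a.strand, a.chrom, a.count * 3)
            for a in alns
        ]
        p1, p3 = pk.ping_pong_profile(alns), pk.ping_pong_profile(scaled)
        for o in p1.overlap_counts:
            assert p3.overlap_counts[o] == pytest.approx(9 * p1.overlap_counts[o])
        assert p3.z10 == pytest.approx(p1.z10)

    def test_pingpong_library_shows_strong_bin_ten_signal(self, bsb_small):
        assert pk.ping_pong_profile(bsb_small[1]).z10 > 1.96
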