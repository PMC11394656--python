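"""Generator contracts: coverage, determinism, geometry and truth labels."""

import numpy as np
import pandas as pd
import pytest

import pirnascape as pk
from pirnascape.sequences import reverse_complement


def _pirna_only_config(**kw):
    return pk.GeneratorConfig(class_fractions={"BSB": {"piRNA": 1.0}}, **kw)


class TestSimulateGenome:
    def test_zero_repeat_fraction_gives_no_repeat_intervals(self):
        g = pk.simulate_genome(10_000, 0.0, 0.01, seed=1)
        assert not [iv for iv in g.annotation if iv.category == "repeat"]

    def test_repeat_coverage_matches_requested_fraction(self):
        g = pk.simulate_genome(10_000, 0.15, 0.01, seed=1)
        cov = sum(iv.end - iv.start for iv in g.annotation if iv.category == "repeat")
        assert 0.14 <= cov / 10_000 <= 0.16

    def test_same_seed_is_byte_identical(self):
        a = pk.simulate_genome(20_000, 0.2, 0.05, seed=7)
        b = pk.simulate_genome(20_000, 0.2, 0.05, seed=7)
        assert a.sequence == b.sequence
        assert a.annotation == b.annotation

    def test_repeat_and_gene_intervals_are_disjoint(self):
        g = pk.simulate_genome(50_000, 0.3, 0.1, seed=3)
        ivs = sorted((iv.start, iv.end) for iv in g.annotation)
        assert all(ivs[i][1] <= ivs[i + 1][0] for i in range(len(ivs) - 1))

    @pytest.mark.parametrize("rep,gene", [(0.8, 0.2), (-0.1, 0.1), (0.1, -0.1)])
    def test_invalid_fractions_rejected(self, rep, gene):
        with pytest.raises(ValueError):
            pk.simulate_genome(10_000, rep, gene, seed=1)


class TestSimulateLibrary:
    def test_same_seed_is_byte_identical(self, small_genome):
        cfg = pk.GeneratorConfig(n_reads=2000)
        r1, a1, t1 = pk.simulate_library(cfg, small_genome, "BSB", seed=5)
        r2, a2, t2 = pk.simulate_library(cfg, small_genome, "BSB", seed=5)
        assert [(r.id, r.sequence) for r in r1] == [(r.id, r.sequence) for r in r2]
        assert a1 == a2
        pd.testing.assert_frame_equal(t1.reads, t2.reads)

    def test_reads_match_realised_genome_at_alignment(self, small_genome, bsb_small):
        reads, alignments, truth = bsb_small
        realised = truth.genome
        assert realised.annotation == small_genome.annotation
        by_id = {r.id: r.sequence for r in reads}
        for aln in alignments:
            expect = realised.sequence[aln.start : aln.end]
            if aln.strand == "-":
                expect = reverse_complement(expect)
            assert by_id[aln.read_id] == expect

    def test_forced_1u_makes_all_reads_start_with_u(self, small_genome):
        """q1U=1 forces a 5' U everywhere it is geometrically possible.

        The one exception a genome-consistent simulation must allow: when two
        opposite-strand reads share the same 5' genomic base, that base cannot
        spell U for both (plus needs T, minus needs A), so exactly one of the
        pair keeps it.
        """
        cfg = _pirna_only_config(pingpong_fraction=0.0, q1U=1.0, n_reads=500)
        reads, alignments, _ = pk.simulate_library(cfg, small_genome, "BSB", seed=2)
        five = {}
        for a in alignments:
            five.setdefault(a.five_prime, set()).add(a.strand)
        shared = {a.read_id for a in alignments if len(five[a.five_prime]) == 2}
        violations = {r.id for r in reads if r.sequence[0] != "T"}
        assert violations <= shared
        assert len(violations) <= max(1, 0.01 * len(reads))

    def test_pingpong_partners_overlap_exactly_ten(self, small_genome):
        cfg = _pirna_only_config(pingpong_fraction=0.5, n_reads=10_000)
        reads, alignments, truth = pk.simulate_library(cfg, small_genome, "BSB", seed=7)
        five = {a.read_id: (a.five_prime, a.strand) for a in alignments}
        sec = truth.reads[truth.reads.role == "secondary"]
        overlaps = []
        for rid, row in sec.iterrows():
            (f_sec, s_sec), (f_pri, s_pri) = five[rid], five[row.partner]
            assert s_sec != s_pri
            a, b = (f_pri, f_sec) if s_pri == "+" else (f_sec, f_pri)
            overlaps.append(b - a + 1)
        assert len(overlaps) == 5000
        assert np.mean(np.array(overlaps) == 10) >= 0.99

    def test_partner_relation_is_symmetric(self, bsb_small):
        truth = bsb_small[2].reads
        paired = truth[truth.partner != ""]
        for rid, row in paired.iterrows():
            assert truth.loc[row.partner, "partner"] == rid

    def test_class_truth_fraction_recovers_configured_fraction(self, study_genome):
        cfg = pk.GeneratorConfig(n_reads=50_000)
        _, _, truth = pk.simulate_library(cfg, study_genome, "BSB", seed=11)
        frac = (truth.reads.true_class == "piRNA").mean()
        assert abs(frac - 0.678) < 0.01

    def test_missing_condition_rejected(self, small_genome):
        with pytest.raises(ValueError, match="condition"):
            pk.simulate_library(pk.GeneratorConfig(), small_genome, "XXX", seed=1)

    def test_length_dist_outside_window_rejected(self):
        cfg = pk.GeneratorConfig(pirna_length_dist={26: 0.5, 30: 0.5})
        with pytest.raises(ValueError, match="27..32"):
            cfg.validate()

    def test_config_yaml_round_trip(self, tmp_path):
        cfg = pk.GeneratorConfig(q1U=0.9, n_reads=1234)
        path = tmp_path / "cfg.yaml"
        cfg.to_yaml(str(path))
        assert pk.GeneratorConfig.from_yaml(str(path)) == cfg


class TestSimulateCountMatrix:
    def test_zero_de_fraction_gives_no_true_de(self):
        cfg = pk.GeneratorConfig(de_fraction=0.0)
        _, truth = pk.simulate_count_matrix(cfg, 200, seed=1)
        assert (truth.expression.status == "ns").all()

    def test_up_share_among_true_de(self):
        cfg = pk.GeneratorConfig(de_fraction=0.2, de_up_share=0.886)
        _, truth = pk.simulate_count_matrix(cfg, 5000, seed=3)
        de = truth.expression[truth.expression.status != "ns"]
        share = (de.status == "up").mean()
        assert 0.85 <= share <= 0.92

    def test_true_up_pirnas_show_planted_fold_change(self):
        cfg = pk.GeneratorConfig(
            de_fraction=0.2, effect_log2fc=2.0, nb_mean=500, nb_dispersion=0.05
        )
        counts, truth = pk.simulate_count_matrix(cfg, 2000, seed=4)
        up = truth.expression.status == "up"
        bsb = counts.values[counts.samples_of("BSB")].mean(axis=1)
        nbs = counts.values[counts.samples_of("NBS")].mean(axis=1)
        ratio = np.log2((bsb[up.values] + 1) / (nbs[up.values] + 1))
        assert 1.5 <= np.median(ratio) <= 2.5

    def test_nonpositive_dispersion_rejected(self):
        cfg = pk.GeneratorConfig(nb_dispersion=0.0)
        with pytest.raises(ValueError, match="nb_dispersion"):
            pk.simulate_count_matrix(cfg, 10, seed=1)

    def test_counts_are_deterministic(self):
        cfg = pk.GeneratorConfig()
        m1, _ = pk.simulate_count_matrix(cfg, 100, seed=9)
        m2, _ = pk.simulate_count_matrix(cfg, 100, seed=9)
        pd.testing.assert_frame_equal(m1.values, m2.values)
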