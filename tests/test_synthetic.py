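"""The generator: determinism, planted structure, read-set statistics."""

import math

import pytest

from haloprov.kmers import count_kmers
from haloprov.seqio import GenomeRecord, gc_percent, reverse_complement
from haloprov.synthetic import (
    build_lysogen,
    deplete_motifs,
    make_genome,
    simulate_reads,
    write_fastq,
)


class TestMakeGenome:
    def test_gc_zero_is_at_only(self):
        assert set(make_genome(1000, 0.0, 4)) <= {"A", "T"}

    def test_gc_target_concentration(self):
        # binomial sd at n=45142 is ~0.2 points; +/-1.0 is a >4 sigma band
        g = make_genome(45142, 0.678, 12)
        assert abs(gc_percent(g) - 67.8) <= 1.0

    def test_determinism(self):
        assert make_genome(500, 0.5, 77) == make_genome(500, 0.5, 77)
        assert make_genome(500, 0.5, 77) != make_genome(500, 0.5, 78)

    def test_bad_args(self):
        with pytest.raises(ValueError):
            make_genome(0, 0.5, 1)
        with pytest.raises(ValueError):
            make_genome(10, 1.5, 1)


class TestDepleteMotifs:
    def test_already_clean_unchanged(self):
        seq = ("AC" * 300).replace("CTAG", "")
        assert "CTAG" not in seq + seq[:3]
        assert deplete_motifs(seq, ["CTAG"], 1) == seq

    def test_planted_motifs_absent_both_strands_circular(self):
        motifs = ["AGCT", "CTAG", "TGCA"]
        seq = deplete_motifs(make_genome(50_000, 0.6, 2), motifs, 3)
        assert len(seq) == 50_000
        counts = count_kmers(seq, 4, "circular")
        rc_counts = count_kmers(reverse_complement(seq), 4, "circular")
        for m in motifs:
            assert counts.get(m, 0) == 0
            assert rc_counts.get(m, 0) == 0

    def test_non_palindromic_motif_removed_with_its_complement(self):
        seq = deplete_motifs(make_genome(20_000, 0.5, 5), ["CAGC"], 6)
        c = count_kmers(seq, 4, "circular")
        assert c.get("CAGC", 0) == 0
        assert c.get("GCTG", 0) == 0  # reverse complement

    def test_empty_motifs_rejected(self):
        with pytest.raises(ValueError):
            deplete_motifs("ACGT" * 10, [], 1)


class TestBuildLysogen:
    def test_att_core_is_trna_suffix(self, lysogen_bundle):
        lysogen, element, truth = lysogen_bundle
        t = truth.provirus
        core = t["att_core"]
        trna = lysogen.subseq(t["trna_start"], t["trna_stop"])
        assert trna.endswith(core)
        assert element.seq.startswith(core)  # attP at position 1

    def test_att_repeats_flank_element(self, lysogen_bundle):
        lysogen, element, truth = lysogen_bundle
        t = truth.provirus
        c = len(t["att_core"])
        assert lysogen.subseq(t["attL_start"], t["attL_start"] + c - 1) == t["att_core"]
        assert lysogen.subseq(t["attR_start"], t["attR_start"] + c - 1) == t["att_core"]
        assert t["attR_start"] - t["attL_start"] == t["element_length"]

    def test_core_unique_in_element(self, lysogen_bundle):
        _, element, truth = lysogen_bundle
        core = truth.provirus["att_core"]
        doubled = element.seq + element.seq[: len(core) - 1]
        assert doubled.count(core) == 1

    def test_planted_cds_layout(self, lysogen_bundle):
        _, element, truth = lysogen_bundle
        t = truth.provirus
        tags = {f.locus_tag: f for f in element.features}
        assert tags["syn_int"].product == "integrase"
        bridge = tags["syn_bridge"]
        assert bridge.start > bridge.stop  # wraps the origin, spanning attP
        assert (bridge.start, bridge.stop) == (
            t["bridge_circular_start"], t["bridge_circular_stop"]
        )
        # all three planted CDS share a strand
        assert {f.strand for f in element.features} == {"+"}

    def test_truth_matches_emitted_gff3(self, lysogen_bundle, tmp_path):
        from haloprov.seqio import read_gff3, write_gff3

        lysogen, _, truth = lysogen_bundle
        p = tmp_path / "lys.gff3"
        write_gff3(lysogen, p)
        feats = {f.locus_tag: f for f in read_gff3(p)}
        t = truth.provirus
        assert feats["syn_trna_pro"].stop == t["host_insertion_pos"]
        assert feats["syn_trna_pro"].start == t["trna_start"]

    def test_att_len_respected(self):
        _, element, truth = build_lysogen(
            host_length=8000, element_length=2500, att_len=15, seed=2
        )
        assert len(truth.provirus["att_core"]) == 15
        assert element.seq.startswith(truth.provirus["att_core"])


class TestSimulateReads:
    def _template(self, seed=1, L=3000):
        return GenomeRecord(id="t", seq=make_genome(L, 0.5, seed), topology="circular")

    def test_zero_reads(self):
        assert simulate_reads([(self._template(), "circular", 1.0)], 0, 100, 1) == []

    def test_deterministic_fastq(self, tmp_path):
        tpl = [(self._template(), "circular", 1.0)]
        a, b = tmp_path / "a.fastq", tmp_path / "b.fastq"
        write_fastq(simulate_reads(tpl, 200, 100, 5), a)
        write_fastq(simulate_reads(tpl, 200, 100, 5), b)
        assert a.read_bytes() == b.read_bytes()

    def test_reads_match_template(self):
        rec = self._template()
        doubled = rec.seq + rec.seq
        for r in simulate_reads([(rec, "circular", 1.0)], 100, 120, 3):
            seq = r.seq if r.strand == "+" else reverse_complement(r.seq)
            assert doubled[r.start - 1 : r.start + 119] == seq

    def test_mean_coverage_within_three_sigma(self):
        L, n, rl = 5000, 1000, 100
        rec = self._template(L=L)
        reads = simulate_reads([(rec, "circular", 1.0)], n, rl, 9)
        total = sum(len(r.seq) for r in reads)
        mean_cov = total / L
        expected = n * rl / L
        assert mean_cov == pytest.approx(expected)  # exact: all reads full length
        # per-base depth at a fixed position is Binomial(n, rl/L)
        pos = 2500
        depth = sum(
            1 for r in reads if (pos - r.start) % L < rl
        )
        sd = math.sqrt(n * (rl / L) * (1 - rl / L))
        assert abs(depth - expected) <= 3 * sd

    def test_origin_spanning_read_fraction(self):
        L, n, rl = 4000, 4000, 150
        rec = self._template(L=L)
        reads = simulate_reads([(rec, "circular", 1.0)], n, rl, 21)
        spanning = sum(1 for r in reads if r.start > L - rl + 1)
        expected = n * (rl - 1) / L
        sd = math.sqrt(n * ((rl - 1) / L) * (1 - (rl - 1) / L))
        assert abs(spanning - expected) <= 3 * sd

    def test_headful_virion_reads_exist_across_origin(self):
        rec = self._template(L=2000)
        reads = simulate_reads([(rec, "headful-linear", 1.0)], 500, 100, 2)
        doubled = rec.seq + rec.seq
        wrapped = 0
        for r in reads:
            seq = r.seq if r.strand == "+" else reverse_complement(r.seq)
            assert seq in doubled
            if r.start + 99 > 2000:
                wrapped += 1
        assert wrapped > 0  # circular permutation produces origin-crossing reads

    def test_read_longer_than_template_rejected(self):
        with pytest.raises(ValueError):
            simulate_reads([(self._template(L=50), "circular", 1.0)], 1, 100, 1)

    def test_weights_must_be_positive_somewhere(self):
        with pytest.raises(ValueError):
            simulate_reads([(self._template(), "circular", 0.0)], 1, 50, 1)
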