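"""Gene spacing, motif scans, repeats, slippery sites, tail-length arithmetic."""

import pytest

from haloprov.features import (
    cxxc_scan,
    find_direct_repeats,
    find_slippery,
    is_slippery,
    longest_common_prefix,
    protein_len_from_cds,
    spacing_stats,
    tmp_tail_length,
)
from haloprov.seqio import Feature, GenomeRecord
from haloprov.synthetic import make_genome


class TestSpacingStats:
    def test_published_annotation_counts(self, hardycor1_coords):
        """The Hardycor1 CDS table yields 27 overlapping and 13 close genes."""
        sp = spacing_stats(hardycor1_coords)
        assert sp.n_genes == 53
        assert sp.n_overlapping_genes == 27
        assert sp.n_close_genes == 13
        assert sp.n_overlapping_genes + sp.n_close_genes <= sp.n_genes

    def test_single_cds(self):
        rec = GenomeRecord(id="x", seq="A" * 99, features=[Feature("CDS", 1, 9)])
        sp = spacing_stats(rec)
        assert (sp.n_overlapping_genes, sp.n_close_genes) == (0, 0)

    def test_three_gene_toy_by_hand_enumeration(self):
        # genes 1-9 and 9-21 share base 9 (overlap); 21->32 leaves a 10 bp
        # gap, but only gene 3 counts as close: gene 2 is already in the
        # overlapping tally (per-gene counting, as in the published census)
        rec = GenomeRecord(
            id="x", seq="A" * 120, topology="circular",
            features=[Feature("CDS", 1, 9), Feature("CDS", 9, 21), Feature("CDS", 32, 40)],
        )
        sp = spacing_stats(rec)
        assert sp.n_overlapping_genes == 2
        assert sp.n_close_genes == 1
        assert sp.gaps == [-1, 10, 80]

    def test_circular_adjacency_counts_wrap_pair(self):
        rec = GenomeRecord(
            id="x", seq="A" * 60, topology="circular",
            features=[Feature("CDS", 3, 11), Feature("CDS", 54, 59)],
        )
        sp = spacing_stats(rec)
        # wrap gap = (60-59) + (3-1) = 3 -> both genes are close
        assert sp.n_close_genes == 2


class TestCxxcScan:
    @pytest.mark.parametrize(
        "prot,expected",
        [("MAAAA", []), ("CAACAAC", [1, 4]), ("MCAACX", [2]), ("CCCC", [1])],
    )
    def test_examples(self, prot, expected):
        assert cxxc_scan(prot) == expected


class TestLcp:
    def test_identical(self):
        assert longest_common_prefix("MNANT", "MNANT") == 5

    def test_first_differs(self):
        assert longest_common_prefix("MA", "VA") == 0

    def test_symmetric_and_bounded(self):
        a, b = "MNANTQR", "MNANTAA"
        assert longest_common_prefix(a, b) == longest_common_prefix(b, a) == 5
        assert longest_common_prefix(a, b) <= min(len(a), len(b))


def oracle_repeats(seq: str, min_len: int) -> set[tuple[int, int, int]]:
    """Quadratic all-pairs oracle: left-maximal pairs with their maximal
    common extension, as (unit_length, copy1_start, copy2_start), 1-based."""
    n = len(seq)
    out = set()
    for i in range(n):
        for j in range(i + 1, n):
            if seq[i] != seq[j]:
                continue
            if i > 0 and seq[i - 1] == seq[j - 1]:
                continue  # not left-maximal
            l = 0
            while j + l < n and seq[i + l] == seq[j + l]:
                l += 1
            if l >= min_len:
                out.add((l, i + 1, j + 1))
    return out


class TestDirectRepeats:
    def test_planted_tandem(self):
        unit = make_genome(50, 0.5, 1)
        # flanking bases chosen so the tandem pair cannot extend outward
        prefix = "A" if unit[-1] != "A" else "C"
        suffix = "A" if unit[0] != "A" else "C"
        seq = "ACG" + prefix + unit + unit + suffix + "CGT"
        hits = find_direct_repeats(seq, 8)
        top = hits[0]
        assert top.unit_length == 50
        assert top.tandem
        assert (top.copy1_start, top.copy2_start) == (5, 55)

    @pytest.mark.parametrize("seed", range(4))
    def test_matches_quadratic_oracle(self, seed):
        seq = make_genome(500, 0.3, seed)  # AT-rich to provoke chance repeats
        got = {(h.unit_length, h.copy1_start, h.copy2_start)
               for h in find_direct_repeats(seq, 8)}
        assert got == oracle_repeats(seq, 8)

    def test_tandem_flag_definition(self):
        unit = make_genome(30, 0.5, 2)
        spaced = unit + "ACGTACGT" + unit
        (hit,) = find_direct_repeats(spaced, 20)[:1]
        assert not hit.tandem
        assert hit.copy2_start > hit.copy1_start + hit.unit_length

    def test_min_len_guard(self):
        with pytest.raises(ValueError):
            find_direct_repeats("ACGT" * 10, 4)


class TestSlippery:
    def test_predicate(self):
        assert is_slippery("GGGAAAT")
        assert is_slippery("GGGAAAG")
        assert is_slippery("CCCTTTA")
        assert not is_slippery("GGGGGGT")  # X == Y
        assert not is_slippery("GGAAAAT")

    def test_planted_heptamer_recovered(self):
        # CDS with CCCTTTA planted 19 nt before the stop, mirroring the
        # canonical placement near the 3' end of a chaperone gene
        body = "ATG" + "GCA" * 40 + "CCCTTTA" + "GCGAC" + "GCA" * 2 + "TAA"
        pad = make_genome(100, 0.5, 3).replace("CCCTTT", "CCATTT")
        seq = pad + body + pad
        rec = GenomeRecord(
            id="x", seq=seq,
            features=[Feature("CDS", 101, 100 + len(body), "+", "orf1")],
        )
        hits = find_slippery(rec, "orf1", tail_codons=30)
        assert len(hits) == 1
        h = hits[0]
        assert h.heptamer == "CCCTTTA"
        assert seq[h.start - 1 : h.start + 6] == "CCCTTTA"

    def test_minus_strand_coordinates_reextract(self):
        from haloprov.seqio import reverse_complement

        body = "ATG" + "GCA" * 30 + "GGGAAAT" + "GC" + "TAA"
        genome = make_genome(60, 0.5, 5) + reverse_complement(body) + make_genome(60, 0.5, 6)
        rec = GenomeRecord(
            id="x", seq=genome,
            features=[Feature("CDS", 61, 60 + len(body), "-", "orfR")],
        )
        for h in find_slippery(rec, "orfR", tail_codons=40):
            window = rec.seq[h.start - 1 : h.start + 6]
            assert h.heptamer in (window, reverse_complement(window))
            assert is_slippery(h.heptamer)

    def test_short_cds_no_hit(self):
        rec = GenomeRecord(id="x", seq="ATGAAATAA" + "C" * 20,
                           features=[Feature("CDS", 1, 9, "+", "tiny")])
        assert find_slippery(rec, "tiny") == []

    def test_unknown_locus_errors(self, lysogen_bundle):
        lysogen, _, _ = lysogen_bundle
        with pytest.raises(KeyError):
            find_slippery(lysogen, "no_such_gene")


class TestTailLength:
    @pytest.mark.parametrize("aa,nm", [(703, 84), (138, 0), (1000, 129)])
    def test_regression_values(self, aa, nm):
        assert tmp_tail_length(aa) == nm


class TestProteinLen:
    @pytest.mark.parametrize(
        "start,stop,aa", [(17894, 20005, 703), (1, 6, 1), (2337, 3560, 407)]
    )
    def test_examples(self, start, stop, aa):
        assert protein_len_from_cds(start, stop) == aa

    def test_non_codon_span_rejected(self):
        with pytest.raises(ValueError):
            protein_len_from_cds(1, 7)

    def test_consistent_with_published_lengths(self, hardycor1_features):
        # every CDS row's span must reproduce its printed nt length
        for f in hardycor1_features:
            span = f.stop - f.start + 1
            assert span % 3 == 0
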