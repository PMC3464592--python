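"""Nei-Gojobori engine: site counting, pathway averaging, JC correction,
protein-guided back-translation."""

import math

import pytest
from Bio.Align import substitution_matrices
from Bio.Seq import Seq

from _oracles import (SENSE, global_enumeration_oracle, ng86_diffs_oracle,
                      ng86_sites_oracle)
from dupprofiler import ks


def _aln(cds_a: str, cds_b: str) -> ks.CodonAlignment:
    pa = str(Seq(cds_a).translate())
    pb = str(Seq(cds_b).translate())
    ga, gb, _ = ks.global_align_protein(pa, pb)
    return ks.back_translate(ga, gb, cds_a, cds_b)


class TestCodonSites:
    def test_phe_has_one_third_synonymous_site_at_position_three(self):
        s, n = ks.ng86_codon_sites("TTT")
        assert s == pytest.approx(1 / 3)
        assert n == pytest.approx(8 / 3)

    def test_met_has_no_synonymous_sites(self):
        assert ks.ng86_codon_sites("ATG") == (0.0, 3.0)

    def test_sites_conserve_three_per_codon(self):
        for codon in SENSE:
            s, n = ks.ng86_codon_sites(codon)
            assert s + n == pytest.approx(3.0, abs=1e-12)

    def test_matches_neighbor_enumeration_for_all_sense_codons(self):
        for codon in SENSE:
            s, n = ks.ng86_codon_sites(codon)
            so, no = ng86_sites_oracle(codon)
            assert s == pytest.approx(so, abs=1e-12)
            assert n == pytest.approx(no, abs=1e-12)

    def test_stop_codon_rejected(self):
        with pytest.raises(ValueError):
            ks.ng86_codon_sites("TAA")


class TestPathwayAveraging:
    def test_single_difference_columns_reduce_to_direct_classification(self):
        # exhaustive over all sense-codon pairs differing at exactly one position
        for a in SENSE:
            for pos in range(3):
                for nt in "ACGT":
                    b = a[:pos] + nt + a[pos + 1:]
                    if b == a or b not in SENSE:
                        continue
                    sd, nd = ks.ng86_codon_differences(a, b)
                    synonymous = str(Seq(a).translate()) == str(Seq(b).translate())
                    assert (sd, nd) == ((1.0, 0.0) if synonymous else (0.0, 1.0))

    @pytest.mark.parametrize("a,b", [("TTT", "GTA"), ("ATG", "TGG"),
                                     ("AAA", "CCC"), ("TGT", "AGA")])
    def test_multi_difference_pairs_match_enumeration_oracle(self, a, b):
        assert ks.ng86_codon_differences(a, b) == pytest.approx(
            ng86_diffs_oracle(a, b), abs=1e-12)

    def test_symmetric_difference_totals(self):
        for a, b in [("TTT", "GTA"), ("ATG", "CGC"), ("GGG", "TTT")]:
            fwd = ks.ng86_codon_differences(a, b)
            rev = ks.ng86_codon_differences(b, a)
            assert fwd == pytest.approx(rev, abs=1e-12)


class TestJukesCantor:
    def test_closed_form_at_p_03(self):
        assert ks.jukes_cantor(0.3) == pytest.approx(-0.75 * math.log(0.6), rel=1e-12)

    def test_saturation_boundary(self):
        assert ks.jukes_cantor(0.75) is None
        assert ks.jukes_cantor(0.9) is None

    def test_monotone_increasing_below_saturation(self):
        grid = [i / 1000 for i in range(0, 750, 5)]
        values = [ks.jukes_cantor(p) for p in grid]
        assert all(b > a for a, b in zip(values, values[1:]))


class TestNg86Pair:
    def test_identical_sequences_have_zero_divergence(self):
        cds = "ATGGCTAAATTTGGGCCC"
        r = ks.ng86_pair(_aln(cds, cds), min_codons=1)
        assert r.status == ks.STATUS_OK
        assert (r.Sd, r.Nd, r.ks, r.ka) == (0.0, 0.0, 0.0, 0.0)

    def test_sites_sum_to_three_per_compared_codon(self):
        a = "ATGGCTAAATTTGGGCCC"
        b = "ATGGCAAAGTTCGGACCA"
        r = ks.ng86_pair(_aln(a, b), min_codons=1)
        assert r.S + r.N == pytest.approx(3 * r.n_compared, abs=1e-6)

    def test_symmetry_in_sequence_order(self):
        a = "ATGGCTAAATTTGGGCCCACTATC"
        b = "ATGGGTAAGTTCGGACCAACAATT"
        r1 = ks.ng86_pair(_aln(a, b), min_codons=1)
        r2 = ks.ng86_pair(_aln(b, a), min_codons=1)
        for attr in ("S", "N", "Sd", "Nd", "ps", "pn", "ks", "ka", "status"):
            assert getattr(r1, attr) == pytest.approx(getattr(r2, attr))

    def test_too_short_status_below_min_codons(self):
        cds = "ATGGCTAAA"
        r = ks.ng86_pair(_aln(cds, cds), min_codons=30)
        assert r.status == ks.STATUS_TOO_SHORT
        assert r.ks is None


class TestGlobalAlignment:
    def test_identical_sequences_align_gapless(self):
        ga, gb, _ = ks.global_align_protein("MKLVINS", "MKLVINS")
        assert ga == gb == "MKLVINS"

    def test_score_matches_exhaustive_enumeration_on_tiny_inputs(self):
        blosum = substitution_matrices.load("BLOSUM62")
        score = lambda x, y: blosum[x, y]
        for a, b in [("ACDE", "ACE"), ("MKV", "MV"), ("WWP", "WP"), ("A", "W")]:
            _, _, got = ks.global_align_protein(a, b, gap_open=10, gap_extend=0.5)
            expected = global_enumeration_oracle(a, b, score, 10, 0.5)
            assert got == pytest.approx(expected)

    def test_single_residue_pair_scores_substitution(self):
        blosum = substitution_matrices.load("BLOSUM62")
        _, _, score = ks.global_align_protein("A", "W")
        assert score == blosum["A", "W"]

    def test_empty_sequence_rejected(self):
        with pytest.raises(ValueError):
            ks.global_align_protein("", "MKV")


class TestBackTranslate:
    def test_gapless_alignment_maps_codon_per_residue(self):
        cds = "ATGGCTAAA"
        aln = ks.back_translate("MAK", "MAK", cds, cds)
        assert aln.n_compared == 3
        assert aln.codon_columns[0] == ("ATG", "ATG")

    def test_gap_column_excluded_from_compared_count(self):
        aln = ks.back_translate("MAK", "M-K", "ATGGCTAAA", "ATGAAA")
        assert aln.n_compared == 2
        assert aln.codon_columns[1] == ("GCT", None)

    def test_ambiguous_codon_excluded(self):
        aln = ks.back_translate("MAK", "MAK", "ATGGCTAAA", "ATGANAAAA")
        assert aln.n_compared == 2

    def test_trailing_stop_stripped(self):
        aln = ks.back_translate("MAK", "MAK", "ATGGCTAAATAA", "ATGGCTAAA")
        assert aln.n_compared == 3

    def test_length_mismatch_is_hard_error(self):
        with pytest.raises(ValueError, match="gene_x"):
            ks.back_translate("MAK", "MAK", "ATGGCT", "ATGGCTAAA",
                              pair=("gene_x", "gene_y"))


class TestSetKs:
    def test_identical_pair_has_mean_zero(self):
        from conftest import make_catalog, make_gene
        cds = "ATGGCTAAATTTGGGCCCACTATCGGTACCGATGAAGCTCATATTCTGAAGGTTCGA" \
              "GGCTCTTGGCAATTCACTGCAGATCCTGCGGACGTTCAGTTAAGCATGTACCGTGAA"
        catalog = make_catalog([make_gene("a", start=1000, cds=cds),
                                make_gene("b", start=200_000, cds=cds)])
        results, mean = ks.set_pairwise_ks(["a", "b"], catalog)
        assert mean == 0.0
        assert results[0].status == ks.STATUS_OK

    def test_mean_over_defined_values_only(self):
        # mean of ks over ok pairs, saturated pairs excluded
        values = [ks.KsResult(pair=("a", "b"), ks=0.2, status=ks.STATUS_OK),
                  ks.KsResult(pair=("a", "c"), ks=0.4, status=ks.STATUS_OK),
                  ks.KsResult(pair=("b", "c"), ks=None, status=ks.STATUS_SATURATED)]
        ok = [r.ks for r in values if r.status == ks.STATUS_OK]
        assert sum(ok) / len(ok) == pytest.approx(0.3)
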