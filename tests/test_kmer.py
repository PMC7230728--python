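"""k-mer counting, Markov expectations, palindromes and IUPAC scans."""

import numpy as np
import pytest

from halomotif.genome_io import CdsFeature, GenomeRecord, reverse_complement
from halomotif.kmer import (
    UndefinedExpectationError,
    count_ambiguous_motif,
    count_kmers,
    enumerate_palindromes,
    frameshift_motif_scan,
    markov_expected,
)


def rec(seq, topology="linear", features=None):
    return GenomeRecord(id="t", sequence=seq, topology=topology, features=features or [])


class TestCountKmers:
    def test_single_window(self):
        t = count_kmers(rec("AAAA"), 4)
        assert dict(t.counts) == {"AAAA": 1}
        assert t.n_windows == 1

    def test_exhaustive_window_enumeration(self):
        t = count_kmers(rec("GATCGATC"), 4)
        assert dict(t.counts) == {"GATC": 2, "ATCG": 1, "TCGA": 1, "CGAT": 1}
        assert t.n_windows == 5

    def test_windows_with_n_skipped(self):
        t = count_kmers(rec("GANTC"), 2)
        assert dict(t.counts) == {"GA": 1, "TC": 1}
        assert t.n_windows == 2

    def test_circular_includes_wraparound(self):
        linear = count_kmers(rec("GATC"), 2)
        circular = count_kmers(rec("GATC", topology="circular"), 2)
        assert linear.n_windows == 3
        assert circular.n_windows == 4
        assert circular["CG"] == 1  # the wrap window

    def test_counts_sum_to_n_windows(self, plain_genome_10kb):
        for k in (1, 2, 3, 4, 6):
            t = count_kmers(plain_genome_10kb, k)
            assert sum(t.counts.values()) == t.n_windows == plain_genome_10kb.length_bp - k + 1

    def test_consistency_across_k(self, plain_genome_10kb):
        """Summing k-mer counts over the final base recovers the (k-1)-mer
        prefix counts, up to the single unextendable terminal window."""
        k = 4
        tk = count_kmers(plain_genome_10kb, k)
        tk1 = count_kmers(plain_genome_10kb, k - 1)
        deficit = 0
        for prefix, c in tk1.counts.items():
            extended = sum(tk[prefix + b] for b in "ACGT")
            assert extended <= c
            deficit += c - extended
        assert deficit == 1

    def test_k_larger_than_sequence(self):
        with pytest.raises(ValueError):
            count_kmers(rec("ACGT"), 5)


class TestMarkovExpected:
    def test_closed_form_on_exact_repeat(self):
        r = rec("GATC" * 50)
        tables = {k: count_kmers(r, k) for k in (2, 3, 4)}
        expected = markov_expected("GATC", tables)
        odds = tables[4]["GATC"] / expected
        assert odds == pytest.approx(198**2 / (197 * 199), abs=1e-12)

    def test_zero_order_matches_iid_simulation(self):
        """On uniform i.i.d. text the zero-order expectation tracks the
        realized count: mean over 20 seeds within 5%."""
        observed, expected = [], []
        for seed in range(20):
            rng = np.random.default_rng(seed)
            seq = "".join(np.array(list("ACGT"))[rng.integers(0, 4, size=100_000)])
            r = rec(seq)
            tables = {k: count_kmers(r, k) for k in (1, 4)}
            expected.append(markov_expected("GATC", tables, null_model="zero_order"))
            observed.append(tables[4]["GATC"])
        assert np.mean(observed) == pytest.approx(np.mean(expected), rel=0.05)

    def test_absent_motif_with_present_subwords(self):
        # GAT, ATC, AT all occur, GATC never does
        r = rec("GATTT" * 20 + "ATC" * 20)
        tables = {k: count_kmers(r, k) for k in (2, 3, 4)}
        e = markov_expected("GATC", tables)
        assert e > 0
        assert tables[4]["GATC"] == 0

    def test_zero_core_count_raises_naming_core(self):
        r = rec("AAAA" * 30)
        tables = {k: count_kmers(r, k) for k in (2, 3, 4)}
        with pytest.raises(UndefinedExpectationError, match="GC"):
            markov_expected("AGCT", tables)


class TestEnumeratePalindromes:
    def test_k2_exhaustive(self):
        assert enumerate_palindromes(2) == ["AT", "CG", "GC", "TA"]

    def test_k4_count_and_named_members(self):
        pals = enumerate_palindromes(4)
        assert len(pals) == 16
        assert {"GATC", "CTAG", "AGCT", "TGCA", "CATG"} <= set(pals)

    @pytest.mark.parametrize("k", [2, 4, 6])
    def test_defining_property_and_cardinality(self, k):
        pals = enumerate_palindromes(k)
        assert len(pals) == 4 ** (k // 2)
        assert all(w == reverse_complement(w) for w in pals)
        assert pals == sorted(pals)

    @pytest.mark.parametrize("k", [1, 3, 5])
    def test_odd_k_rejected(self, k):
        with pytest.raises(ValueError):
            enumerate_palindromes(k)


class TestAmbiguousMotif:
    def test_ggwcc_two_sites(self):
        assert count_ambiguous_motif(rec("GGACCGGTCC"), "GGWCC") == 2

    def test_ttcgaa_once(self):
        assert count_ambiguous_motif(rec("AATTCGAAGG"), "TTCGAA") == 1

    def test_all_n_motif_matches_every_window(self):
        assert count_ambiguous_motif(rec("ACGTACGTAC"), "NNNNN") == 6

    def test_sequence_n_matches_nothing(self):
        assert count_ambiguous_motif(rec("GGNCC"), "GGWCC") == 0

    def test_invalid_code_rejected(self):
        with pytest.raises(ValueError):
            count_ambiguous_motif(rec("ACGT"), "GGXCC")

    def test_both_strands_for_asymmetric_motif(self):
        # CATCC on the reverse strand only (forward carries GGATG)
        r = rec("AAGGATGAA")
        assert count_ambiguous_motif(r, "CATCC") == 0
        assert count_ambiguous_motif(r, "CATCC", both_strands=True) == 1

    def test_self_complementary_motif_counted_once(self):
        r = rec("AATTCGAAGG")
        assert count_ambiguous_motif(r, "TTCGAA", both_strands=True) == 1


class TestFrameshiftScan:
    def _record_with_cds(self, coding):
        """Plus-strand CDS spanning the whole sequence."""
        feat = CdsFeature(locus_tag="cds1", start=0, end=len(coding), strand="+")
        return rec(coding, features=[feat])

    def test_planted_motif_near_stop(self):
        coding = "ATG" + "GCA" * 20 + "TTTCGC" + "TGA"
        r = self._record_with_cds(coding)
        hits = frameshift_motif_scan(r, window_bp=15)
        assert hits == [("cds1", len(coding) - 3 - 6 + 1)]

    def test_no_motif_no_hit(self):
        coding = "ATG" + "GCA" * 20 + "TGA"
        assert frameshift_motif_scan(self._record_with_cds(coding)) == []

    def test_template_strand_motif_not_reported(self):
        # GCGAAA = reverse complement of TTTCGC: present on the template
        # strand only, so a coding-strand scan must stay silent
        coding = "ATG" + "GCA" * 20 + "GCGAAA" + "TGA"
        assert frameshift_motif_scan(self._record_with_cds(coding)) == []

    def test_minus_strand_cds_scanned_in_coding_frame(self):
        coding = "ATG" + "GCA" * 10 + "TTTCGC" + "TGA"
        genome = "TT" + reverse_complement(coding) + "AA"
        feat = CdsFeature(locus_tag="m", start=2, end=2 + len(coding), strand="-")
        r = rec(genome, features=[feat])
        hits = frameshift_motif_scan(r, window_bp=15)
        assert hits == [("m", len(coding) - 3 - 6 + 1)]

    def test_no_features_warns_and_returns_empty(self):
        with pytest.warns(UserWarning):
            assert frameshift_motif_scan(rec("ACGTACGT")) == []
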