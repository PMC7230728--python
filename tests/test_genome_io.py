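"""Record construction, FASTA/GenBank parsing and sequence transforms."""

import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from halomotif.genome_io import (
    AlphabetError,
    CdsFeature,
    CoordinateError,
    GenomeParseError,
    GenomeRecord,
    gc_content,
    linearize_provirus,
    read_fasta,
    read_genbank,
    reverse_complement,
    write_genbank,
)
from halomotif.simulate import SyntheticGenomeSpec, generate_genome

dna = st.text(alphabet="ACGTN", min_size=1, max_size=200)


class TestReadFasta:
    def test_case_folding_single_entry(self, tmp_path):
        p = tmp_path / "x.fa"
        p.write_text(">x\nacgt\n")
        records = read_fasta(p)
        assert len(records) == 1
        assert records[0].sequence == "ACGT"
        assert records[0].length_bp == 4
        assert records[0].topology == "linear"

    def test_empty_file(self, tmp_path):
        p = tmp_path / "empty.fa"
        p.write_text("")
        assert read_fasta(p) == []

    def test_two_entries_with_lengths(self, tmp_path):
        p = tmp_path / "two.fa"
        p.write_text(">a\n" + "A" * 10 + "\n>b\n" + "GC" * 10 + "\n")
        records = read_fasta(p)
        assert [r.length_bp for r in records] == [10, 20]

    def test_garbage_characters_rejected(self, tmp_path):
        p = tmp_path / "bad.fa"
        p.write_text(">a\nAC9T\n")
        with pytest.raises(AlphabetError):
            read_fasta(p)


GENBANK_MINIMAL = """LOCUS       test                     200 bp    DNA     linear   PHG 01-JAN-2020
DEFINITION  hand-written fixture.
ACCESSION   test
FEATURES             Location/Qualifiers
     CDS             101..160
                     /locus_tag="plus_cds"
     CDS             complement(11..70)
                     /locus_tag="minus_cds"
ORIGIN
        1 {seq}
//
"""


def _origin_block(seq):
    lines = []
    for i in range(0, len(seq), 60):
        chunk = seq[i : i + 60]
        groups = " ".join(chunk[j : j + 10] for j in range(0, len(chunk), 10))
        lines.append(f"{i + 1:>9} {groups}")
    return "\n".join(lines)


class TestReadGenbank:
    def test_coordinate_convention(self, tmp_path):
        seq = ("ACGT" * 50).lower()
        text = (
            GENBANK_MINIMAL.split("ORIGIN")[0]
            + "ORIGIN\n"
            + _origin_block(seq)
            + "\n//\n"
        )
        p = tmp_path / "f.gb"
        p.write_text(text)
        rec = read_genbank(p)[0]
        plus = rec.feature_by_tag("plus_cds")
        assert (plus.start, plus.end, plus.strand) == (100, 160, "+")
        minus = rec.feature_by_tag("minus_cds")
        assert (minus.start, minus.end, minus.strand) == (10, 70, "-")

    def test_translation_length_excludes_stop(self):
        feat = CdsFeature(locus_tag="t", start=0, end=60, strand="+", translation="M" * 19)
        assert len(feat.translation) == 19

    def test_missing_origin_is_error(self, tmp_path):
        p = tmp_path / "noseq.gb"
        p.write_text(
            "LOCUS       test                     200 bp    DNA     linear   PHG 01-JAN-2020\n"
            "DEFINITION  no sequence.\nACCESSION   test\nORIGIN\n//\n"
        )
        with pytest.raises(GenomeParseError):
            read_genbank(p)

    def test_feature_past_end_is_error(self, tmp_path):
        seq = "acgt" * 10
        text = (
            "LOCUS       test                      40 bp    DNA     linear   PHG 01-JAN-2020\n"
            "DEFINITION  bad.\nACCESSION   test\n"
            "FEATURES             Location/Qualifiers\n"
            "     CDS             10..80\n"
            '                     /locus_tag="beyond"\n'
            "ORIGIN\n" + _origin_block(seq) + "\n//\n"
        )
        p = tmp_path / "bad.gb"
        p.write_text(text)
        with pytest.raises((GenomeParseError, CoordinateError)):
            read_genbank(p)


class TestGenbankRoundTrip:
    @pytest.mark.parametrize(
        "spec",
        [
            SyntheticGenomeSpec(length_bp=4000, n_cds=5, cxxc_plant=(2, 1),
                                tdr_length=0, avoided_motifs=(), seed=7, name="rt5"),
            SyntheticGenomeSpec(length_bp=77000, n_cds=125, cxxc_plant=(21, 12),
                                tdr_length=306, seed=8, name="rt125"),
        ],
        ids=["five_cds", "virus_scale"],
    )
    def test_write_then_read_is_identity(self, tmp_path, spec):
        record = generate_genome(spec)
        path = tmp_path / "out.gb"
        write_genbank(record, path)
        back = read_genbank(path)[0]
        assert back.sequence == record.sequence
        got = [(f.locus_tag, f.start, f.end, f.strand, f.translation) for f in back.features]
        want = [(f.locus_tag, f.start, f.end, f.strand, f.translation) for f in record.features]
        assert got == want

    def test_featureless_record(self, tmp_path):
        record = GenomeRecord(id="bare", sequence="ACGT" * 250)
        path = tmp_path / "bare.gb"
        write_genbank(record, path)
        text = path.read_text()
        assert "CDS" not in text
        assert read_genbank(path)[0].sequence == record.sequence


class TestReverseComplement:
    @pytest.mark.parametrize(
        "seq,expected",
        [("GATC", "GATC"), ("AAAC", "GTTT"), ("N", "N"), ("ACGTN", "NACGT")],
    )
    def test_examples(self, seq, expected):
        assert reverse_complement(seq) == expected

    def test_rejects_foreign_characters(self):
        with pytest.raises(AlphabetError):
            reverse_complement("ACGU")

    @given(dna)
    @settings(max_examples=200, deadline=None, derandomize=True)
    def test_involution_and_length(self, seq):
        rc = reverse_complement(seq)
        assert len(rc) == len(seq)
        assert reverse_complement(rc) == seq

    @given(st.text(alphabet="ACGT", min_size=1, max_size=200))
    @settings(max_examples=100, deadline=None, derandomize=True)
    def test_gc_invariant_under_reverse_complement(self, seq):
        assert gc_content(seq) == pytest.approx(gc_content(reverse_complement(seq)))


class TestGcContent:
    @pytest.mark.parametrize("seq,expected", [("GCGC", 1.0), ("ATAT", 0.0), ("GCAT", 0.5)])
    def test_examples(self, seq, expected):
        assert gc_content(seq) == expected

    def test_n_excluded_from_denominator(self):
        assert gc_content("GCNN") == 1.0

    def test_all_n_is_undefined(self):
        with pytest.raises(ValueError):
            gc_content("NNNN")


class TestLinearizeProvirus:
    def host(self):
        return GenomeRecord(id="host", sequence="TTTT" + "AAACCCGGG" + "TTTT")

    def test_zero_offset_is_identity_on_excision(self):
        out = linearize_provirus(self.host(), 4, 13, 0)
        assert out.sequence == "AAACCCGGG"
        assert out.topology == "linear"

    def test_rotation_by_inspection(self):
        out = linearize_provirus(self.host(), 4, 13, 3)
        assert out.sequence == "CCCGGGAAA"

    def test_rotation_group_property(self, plain_genome_10kb):
        rec = plain_genome_10kb
        n = rec.length_bp
        first = linearize_provirus(rec, 0, n, 1234)
        back = linearize_provirus(first, 0, n, n - 1234)
        assert back.sequence == rec.sequence

    def test_base_multiset_preserved(self):
        out = linearize_provirus(self.host(), 4, 13, 5)
        assert sorted(out.sequence) == sorted("AAACCCGGG")

    @pytest.mark.parametrize("args", [(13, 4, 0), (4, 13, 9), (4, 13, -1), (-1, 13, 0)])
    def test_out_of_range_offsets(self, args):
        with pytest.raises(CoordinateError):
            linearize_provirus(self.host(), *args)
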