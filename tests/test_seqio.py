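import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from mtcpg.errors import CoordinateError, InputFormatError
from mtcpg.seqio import (Feature, FeatureTable, GenomeRecord, Interval,
                         map_interval_to_reference, map_interval_to_reversed,
                         read_fasta, read_features, reverse_complement,
                         write_features_tsv)

dna = st.text(alphabet="ACGT", min_size=1, max_size=300)


class TestReadFasta:
    def test_direct_read(self, fasta_file):
        g = read_fasta(fasta_file("ACGT", name="x"))
        assert (g.id, g.length, g.sequence) == ("x", 4, "ACGT")
        assert g.strand == "L"

    def test_case_and_ambiguity_normalisation(self, fasta_file):
        g = read_fasta(fasta_file("acgtryn"))
        assert g.sequence == "ACGTNNN"

    @pytest.mark.parametrize("text", ["", ">x\n", "ACGT\n"])
    def test_malformed_input_raises(self, tmp_path, text):
        p = tmp_path / "bad.fa"
        p.write_text(text)
        with pytest.raises(InputFormatError):
            read_fasta(p)


class TestReverseComplement:
    @pytest.mark.parametrize("seq,expected", [
        ("ACGT", "ACGT"),            # palindrome
        ("AACG", "CGTT"),
        ("AN", "NT"),
    ])
    def test_known_values(self, seq, expected):
        assert reverse_complement(GenomeRecord("t", seq)).sequence == expected

    def test_strand_label_flips(self):
        g = GenomeRecord("t", "ACCA")
        assert reverse_complement(g).strand == "H"
        assert reverse_complement(reverse_complement(g)).strand == "L"

    @settings(max_examples=200, derandomize=True)
    @given(dna)
    def test_involution_and_base_conservation(self, seq):
        g = GenomeRecord("t", seq)
        rc = reverse_complement(g)
        assert rc.length == g.length
        assert reverse_complement(rc).sequence == seq
        for a, b in (("A", "T"), ("C", "G")):
            assert seq.count(a) == rc.sequence.count(b)

    @settings(max_examples=300, derandomize=True)
    @given(dna)
    def test_cpg_count_is_strand_symmetric(self, seq):
        rc = reverse_complement(GenomeRecord("t", seq)).sequence
        assert seq.count("CG") == rc.count("CG")


class TestIntervalMapping:
    def test_formula(self):
        iv = Interval(1, 4, frame="reversed")
        out = map_interval_to_reference(iv, 10)
        assert (out.start, out.end, out.frame) == (7, 10, "reference")

    def test_human_12s_locus_coordinates(self):
        # H-strand detection at 15218..15447 of a 16569 bp genome lands at
        # 1123..1352 on the reference (inside the 12S rRNA locus)
        out = map_interval_to_reference(
            Interval(15218, 15447, frame="reversed"), 16569)
        assert (out.start, out.end) == (1123, 1352)

    def test_wrong_frame_and_bounds_rejected(self):
        with pytest.raises(CoordinateError):
            map_interval_to_reference(Interval(1, 4, frame="reference"), 10)
        with pytest.raises(CoordinateError):
            map_interval_to_reference(Interval(5, 12, frame="reversed"), 10)

    @settings(max_examples=300, derandomize=True)
    @given(st.integers(1, 10**6), st.integers(0, 10**6), st.integers(0, 10**6))
    def test_involution(self, length, a, b):
        s, e = 1 + a % length, 1 + b % length
        if s > e:
            s, e = e, s
        iv = Interval(s, e, frame="reversed")
        back = map_interval_to_reversed(
            map_interval_to_reference(iv, length), length)
        assert (back.start, back.end) == (s, e)
        assert map_interval_to_reference(iv, length).length == iv.length


class TestFeatureIO:
    def test_bed_is_converted_to_one_based(self, tmp_path):
        p = tmp_path / "f.bed"
        p.write_text("chrM\t0\t4\tTRNF\n")
        ft = read_features(p, "bed", genome_length=10)
        f = ft.features[0]
        assert (f.name, f.start, f.end) == ("TRNF", 1, 4)

    def test_tsv_roundtrip(self, tmp_path):
        ft = FeatureTable([
            Feature("ND1", "protein_gene", 10, 500),
            Feature("D-LOOP", "noncoding", 900, 50, wraps_origin=True),
        ], genome_length=1000)
        p = tmp_path / "f.tsv"
        write_features_tsv(ft, p)
        back = read_features(p, "tsv", genome_length=1000)
        assert [(f.name, f.start, f.end, f.wraps_origin) for f in back] == \
               [(f.name, f.start, f.end, f.wraps_origin) for f in ft]

    def test_genbank_origin_spanning_dloop(self, tmp_path):
        gb = tmp_path / "t.gb"
        gb.write_text(_make_genbank_doc())
        ft = read_features(gb, "genbank")
        dloop = [f for f in ft if f.name == "D-LOOP"]
        assert len(dloop) == 1 and dloop[0].wraps_origin
        assert (dloop[0].start, dloop[0].end) == (900, 57)
        trnf = [f for f in ft if f.name == "TRNF"]
        assert trnf and (trnf[0].start, trnf[0].end) == (58, 128)
        assert trnf[0].kind == "tRNA"
        nd1 = [f for f in ft if f.name == "ND1"]
        assert nd1 and nd1[0].kind == "protein_gene"

    def test_out_of_bounds_feature_rejected(self):
        with pytest.raises(CoordinateError) as err:
            FeatureTable([Feature("ND9", "protein_gene", 5, 20)],
                         genome_length=10)
        assert "ND9" in str(err.value)

    def test_overlap_query_orders_and_splits_wrapping(self):
        ft = FeatureTable([
            Feature("D-LOOP", "noncoding", 90, 10, wraps_origin=True),
            Feature("TRNF", "tRNA", 11, 20),
        ], genome_length=100)
        assert [f.name for f in ft.overlapping(Interval(5, 12))] == \
               ["D-LOOP", "TRNF"]
        assert [f.name for f in ft.overlapping(Interval(95, 99))] == ["D-LOOP"]
        assert [f.name for f in ft.overlapping(Interval(30, 40))] == []


def _make_genbank_doc() -> str:
    """Write a 1 kb circular record with an origin-spanning D-loop via
    Biopython, so our reader is exercised on a conformant flat file."""
    import io

    from Bio import SeqIO
    from Bio.Seq import Seq
    from Bio.SeqFeature import (CompoundLocation, SeqFeature, SimpleLocation)
    from Bio.SeqRecord import SeqRecord

    rec = SeqRecord(Seq("ACGT" * 250), id="TESTMT", name="TESTMT",
                    description="synthetic test record",
                    annotations={"molecule_type": "DNA",
                                 "topology": "circular"})
    rec.features = [
        SeqFeature(CompoundLocation([SimpleLocation(899, 1000, 1),
                                     SimpleLocation(0, 57, 1)]),
                   type="D-loop"),
        SeqFeature(SimpleLocation(57, 128, 1), type="tRNA",
                   qualifiers={"product": ["tRNA-Phe"]}),
        SeqFeature(SimpleLocation(128, 500, 1), type="rRNA",
                   qualifiers={"product": ["12S ribosomal RNA"]}),
        SeqFeature(SimpleLocation(500, 800, 1), type="gene",
                   qualifiers={"gene": ["ND1"]}),
    ]
    buf = io.StringIO()
    SeqIO.write(rec, buf, "genbank")
    return buf.getvalue()
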