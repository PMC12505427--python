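"""I/O, coordinate conventions, CDS extraction and translation."""

import textwrap

import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from endosym.genome_io import (
    CdsFeature,
    FeatureSet,
    FormatError,
    NucleotideGenome,
    TranslationError,
    extract_cds,
    read_fasta,
    read_features,
    translate,
    write_fasta,
    write_features_tsv,
)

# Independent oracle: the bacterial genetic code spelled out by hand.
_T, _C, _A, _G = "TCAG", "TCAG", "TCAG", "TCAG"
BACTERIAL_CODE = {
    a + b + c: aa
    for (a, b, c), aa in zip(
        [(x, y, z) for x in "TCAG" for y in "TCAG" for z in "TCAG"],
        "FFLLSSSSYY**CC*W"  # TTT..TGG
        "LLLLPPPPHHQQRRRR"
        "IIIMTTTTNNKKSSRR"
        "VVVVAAAADDEEGGGG",
    )
}


class TestFasta:
    def test_minimal_circular_record(self, tmp_path):
        p = tmp_path / "a.fasta"
        p.write_text(">g1 circular=true\nACGT\n")
        (g,) = read_fasta(p)
        assert len(g) == 4 and g.circular

    def test_duplicate_ids_rejected(self, tmp_path):
        p = tmp_path / "a.fasta"
        p.write_text(">g1\nACGT\n>g1\nACGT\n")
        with pytest.raises(FormatError, match="duplicate"):
            read_fasta(p)

    def test_lowercase_and_ambiguity_roundtrip(self, tmp_path):
        p = tmp_path / "a.fasta"
        p.write_text(">g1\nacgtNryk\n")
        (g,) = read_fasta(p)
        assert g.sequence == "ACGTNRYK"
        out = tmp_path / "b.fasta"
        write_fasta([g], out)
        (g2,) = read_fasta(out)
        assert g2.sequence == g.sequence and g2.circular == g.circular

    def test_non_iupac_character_named(self):
        with pytest.raises(FormatError, match="offset 2"):
            NucleotideGenome("g1", "AC!T")

    def test_long_sequence_wraps_and_roundtrips(self, tmp_path):
        g = NucleotideGenome("g1", "ACGT" * 100, circular=True)
        out = tmp_path / "a.fasta"
        write_fasta([g], out)
        assert max(len(l) for l in out.read_text().splitlines()) <= 80
        assert read_fasta(out)[0].sequence == g.sequence


class TestFeatureTables:
    def test_gff3_convention_shift(self, tmp_path):
        p = tmp_path / "a.gff3"
        p.write_text("g1\tsrc\tCDS\t1\t9\t.\t+\t0\tlocus_tag=t1;gene=bioB\n")
        fs = read_features(p, "gff3")
        assert fs.features[0].segments == [(0, 9)]
        assert fs.features[0].gene_symbol == "bioB"

    def test_tsv_pseudo_flag_and_involution(self, tmp_path):
        p = tmp_path / "f.tsv"
        p.write_text(textwrap.dedent("""\
            genome_id\tlocus_tag\tstart\tend\tstrand\tgene\tproduct\tpseudo
            g1\tt1\t11\t40\t-\t\thyp\ttrue
        """))
        fs = read_features(p, "tsv")
        f = fs.features[0]
        assert f.pseudo and f.segments == [(10, 40)]
        out = tmp_path / "o.tsv"
        write_features_tsv(fs, out)
        fs2 = read_features(out, "tsv")
        assert fs2.features[0].segments == f.segments
        assert fs2.features[0].pseudo == f.pseudo

    def test_genbank_complement_join_matches_hand_oracle(self, tmp_path):
        # 30 nt genome; CDS = complement(join(4..12,16..21))
        seq = "AAATTTCATCGGTTTCATAAATTTGGGCCC"
        gb = tmp_path / "a.gb"
        gb.write_text(textwrap.dedent(f"""\
            LOCUS       g1                        30 bp    DNA     circular BCT 01-JAN-2024
            FEATURES             Location/Qualifiers
                 CDS             complement(join(4..12,16..21))
                                 /locus_tag="t1"
            ORIGIN
                    1 {seq.lower()}
            //
        """))
        fs = read_features(gb, "genbank")
        f = fs.features[0]
        assert f.strand == "-" and len(f.segments) == 2
        genome = NucleotideGenome(fs.genome_id, seq)
        # hand-built: revcomp("TCATCGG") after revcomp("TTTCAT")... full span
        import endosym.compare as cmp
        expected = cmp.revcomp(seq[15:21]) + cmp.revcomp(seq[3:12])
        assert extract_cds(genome, f) == expected

    def test_linear_overflow_errors_circular_wraps(self, tmp_path):
        p = tmp_path / "f.tsv"
        p.write_text(
            "genome_id\tlocus_tag\tstart\tend\tstrand\tgene\tproduct\tpseudo\n"
            "g1\tt1\t95\t106\t+\t\t\tfalse\n")
        with pytest.raises(FormatError):
            read_features(p, "tsv", genome_length=100, circular=False)
        fs = read_features(p, "tsv", genome_length=100, circular=True)
        assert fs.features[0].segments == [(94, 100), (0, 6)]


class TestExtractCds:
    def test_plus_strand(self):
        g = NucleotideGenome("g1", "ATGAAACCC")
        f = CdsFeature("g1", [(0, 6)], "+", "t1")
        assert extract_cds(g, f) == "ATGAAA"

    def test_minus_strand_reverse_complement(self):
        g = NucleotideGenome("g1", "TTTCAT")
        f = CdsFeature("g1", [(0, 6)], "-", "t1")
        assert extract_cds(g, f) == "ATGAAA"

    def test_origin_spanning_matches_doubled_string_oracle(self):
        seq = "GGGTTTATGAAA"
        g = NucleotideGenome("g1", seq, circular=True)
        # feature starting at 9, wrapping to 3: segments in coding order
        f = CdsFeature("g1", [(9, 12), (0, 3)], "+", "t1")
        doubled = seq + seq
        assert extract_cds(g, f) == doubled[9:15]

    def test_segment_outside_linear_genome(self):
        g = NucleotideGenome("g1", "ATGAAA")
        f = CdsFeature("g1", [(3, 12)], "+", "t1")
        with pytest.raises(ValueError, match="outside"):
            extract_cds(g, f)


class TestTranslate:
    @pytest.mark.parametrize("cds,protein,stops", [
        ("ATGAAATAA", "MK", []),
        ("ATGTGAAAATAA", "M*K", [(1, "TGA")]),
        ("ATGNNNTAA", "MX", []),
    ])
    def test_examples(self, cds, protein, stops):
        prot, internal = translate(cds)
        assert prot == protein
        assert [(i, c) for i, c in internal] == stops

    def test_remainder_reported(self):
        with pytest.raises(TranslationError) as e:
            translate("ATGAA")
        assert e.value.remainder == 2

    def test_against_brute_force_codon_oracle(self):
        import numpy as np
        rng = np.random.default_rng(42)
        bases = np.array(list("ACGT"))
        for _ in range(50):
            cds = "".join(bases[rng.integers(0, 4, size=300)])
            prot, internal = translate(cds)
            codons = [cds[i:i + 3] for i in range(0, 300, 3)]
            exp = [BACTERIAL_CODE[c] for c in codons]
            if exp and exp[-1] == "*":
                exp = exp[:-1]
            assert prot == "".join(exp)
            assert [i for i, _ in internal] == [
                i for i, c in enumerate(codons[:-1] if codons[-1] in
                                        ("TAA", "TAG", "TGA") else codons)
                if BACTERIAL_CODE[c] == "*"
            ]


@settings(deadline=None, derandomize=True, max_examples=50)
@given(
    st.lists(
        st.tuples(
            st.integers(min_value=0, max_value=5_000),  # start
            st.integers(min_value=3, max_value=900),    # length
            st.sampled_from("+-"),
            st.booleans(),                              # pseudo
            st.sampled_from([None, "bioB", "hisA", "trpE"]),
        ),
        min_size=1, max_size=12,
    )
)
def test_tsv_feature_roundtrip_is_identity(tmp_path_factory, rows):
    """Writing and re-reading the TSV dialect preserves every feature."""
    feats = [
        CdsFeature("g1", [(s, s + (ln // 3) * 3)], strand, f"t{i}",
                   gene_symbol=sym, pseudo=pseudo)
        for i, (s, ln, strand, pseudo, sym) in enumerate(rows)
    ]
    fs = FeatureSet("g1", feats)
    out = tmp_path_factory.mktemp("tsv") / "f.tsv"
    write_features_tsv(fs, out)
    back = read_features(out, "tsv")
    assert [
        (f.segments, f.strand, f.locus_tag, f.gene_symbol, f.pseudo)
        for f in back.features
    ] == [
        (f.segments, f.strand, f.locus_tag, f.gene_symbol, f.pseudo)
        for f in fs.features
    ]


def test_feature_set_rejects_duplicate_tags():
    f1 = CdsFeature("g1", [(0, 6)], "+", "t1")
    f2 = CdsFeature("g1", [(9, 15)], "+", "t1")
    with pytest.raises(FormatError, match="duplicate"):
        FeatureSet("g1", [f1, f2])
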