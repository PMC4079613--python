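import textwrap

import pytest
from hypothesis import given, settings, strategies as st

from mitocode.genome_io import (
    GeneFeature, Mitogenome, ParseError, concatenated_pcgs, gene_sequence,
    normalize_gene_name, parse_feature_table, parse_genbank, revcomp,
    write_feature_table, PCG_ORDER,
)

dna = st.text(alphabet="ACGT", min_size=1, max_size=200)


@pytest.mark.parametrize(
    "raw,expected",
    [
        ("COX1", "COI"),
        ("cox3", "COIII"),
        ("nad4L", "ND4L"),
        ("CYTB", "CytB"),
        ("COB", "CytB"),
        ("atp6", "ATP6"),
        ("trnL-UUR", "tRNA-Leu(L2)"),
        ("trnL(tag)", "tRNA-Leu(L1)"),
        ("trnS1", "tRNA-Ser(S1)"),
        ("tRNA-Ser(UCN)", "tRNA-Ser(S2)"),
        ("trnK", "tRNA-Lys"),
        ("tRNA-Met", "tRNA-Met"),
        ("rrnL", "lrRNA"),
        ("12S ribosomal RNA", "srRNA"),
        ("D-loop", "control_region"),
        ("orfan-like thing", None),
        ("trnL", None),  # ambiguous duplicated tRNA without a family tag
    ],
)
def test_gene_name_normalization(raw, expected):
    assert normalize_gene_name(raw) == expected


GENBANK_MINIMAL = textwrap.dedent(
    """\
    LOCUS       TEST                    1000 bp    DNA     circular INV 01-JAN-2024
    DEFINITION  Toyus bugus mitochondrion, complete genome.
    ACCESSION   TEST0001
    VERSION     TEST0001.1
    SOURCE      mitochondrion Toyus bugus
      ORGANISM  Toyus bugus
                Eukaryota; Arthropoda; Insecta; Hemiptera; Miridae.
    FEATURES             Location/Qualifiers
         CDS             100..150
                         /gene="COX1"
         tRNA            complement(200..265)
                         /product="tRNA-Leu"
                         /gene="trnL-UUR"
         tRNA            300..365
                         /gene="trnM"
                         /anticodon=(pos:330..332,aa:Met,seq:cat)
         rRNA            join(900..1000,1..50)
                         /product="12S ribosomal RNA"
    ORIGIN
    """
)


def _genbank_file(tmp_path):
    seq = ("ACGT" * 250)[:1000]
    lines = []
    for i in range(0, 1000, 60):
        chunk = seq[i : i + 60].lower()
        spaced = " ".join(chunk[j : j + 10] for j in range(0, len(chunk), 10))
        lines.append(f"{i + 1:>9} {spaced}")
    path = tmp_path / "toy.gb"
    path.write_text(GENBANK_MINIMAL + "\n".join(lines) + "\n//\n")
    return path


def test_parse_genbank_normalizes_names_and_coordinates(tmp_path):
    g = parse_genbank(_genbank_file(tmp_path))
    assert g.organism == "Toyus bugus"
    assert g.family == "Miridae"
    assert g.circular and g.complete
    coi = g.feature("COI")
    assert (coi.kind, coi.start, coi.end, coi.strand) == ("PCG", 99, 150, "+")
    leu = g.feature("tRNA-Leu(L2)")
    assert (leu.kind, leu.strand) == ("tRNA", "-")
    met = g.feature("tRNA-Met")
    # anticodon qualifier 330..332 inside tRNA 300..365 -> 0-based offset 30
    assert met.anticodon_offset == 30
    rrna = g.feature("srRNA")
    assert (rrna.start, rrna.end) == (899, 1050)  # origin-spanning, unwrapped


def test_parse_genbank_malformed_raises(tmp_path):
    bad = tmp_path / "bad.gb"
    bad.write_text("LOCUS broken\nnot a record\n")
    with pytest.raises(ParseError):
        parse_genbank(bad)


def _write_pair(tmp_path, seq, rows, name="g"):
    fasta = tmp_path / f"{name}.fasta"
    table = tmp_path / f"{name}.features.tsv"
    fasta.write_text(f">{name}\n{seq}\n")
    table.write_text(
        "name\tkind\tstart\tend\tstrand\tanticodon_offset\n"
        + "".join("\t".join(map(str, r)) + "\n" for r in rows)
    )
    return fasta, table


def test_parse_feature_table_examples(tmp_path):
    seq = "A" * 1000
    fasta, table = _write_pair(
        tmp_path, seq, [("srRNA", "rRNA", 1, 700, "-", ".")]
    )
    g = parse_feature_table(fasta, table)
    f = g.feature("srRNA")
    assert (f.start, f.end, f.strand) == (0, 700, "-")

    # end beyond length on a circular genome -> origin-spanning feature
    fasta, table = _write_pair(
        tmp_path, seq, [("COI", "PCG", 950, 1050, "+", ".")], name="wrap"
    )
    g = parse_feature_table(fasta, table)
    f = g.feature("COI")
    assert (f.start, f.end) == (949, 1050)
    assert len(gene_sequence(g, "COI")) == 101

    # same span on a linear genome is an error
    with pytest.raises(ParseError):
        parse_feature_table(fasta, table, circular=False)

    # empty table -> zero features
    fasta, table = _write_pair(tmp_path, seq, [], name="empty")
    g = parse_feature_table(fasta, table)
    assert g.features == []

    # overlapping identical names -> error
    fasta, table = _write_pair(
        tmp_path, seq,
        [("COI", "PCG", 1, 100, "+", "."), ("COI", "PCG", 50, 150, "+", ".")],
        name="dup",
    )
    with pytest.raises(ParseError):
        parse_feature_table(fasta, table)


def test_gene_sequence_strands_and_origin():
    g = Mitogenome(
        id="t", sequence="ATGC" * 250,
        features=[
            GeneFeature("COI", "PCG", 0, 4, "+"),
            GeneFeature("COII", "PCG", 0, 4, "-"),
            GeneFeature("ND3", "PCG", 990, 1010, "+"),
        ],
    )
    assert gene_sequence(g, "COI") == "ATGC"
    assert gene_sequence(g, "COII") == revcomp("ATGC") == "GCAT"
    spanning = gene_sequence(g, "ND3")
    assert spanning == g.sequence[990:] + g.sequence[:10]
    assert len(spanning) == 20
    with pytest.raises(KeyError):
        gene_sequence(g, "ND5")


def test_concatenated_pcgs_on_synthetic(sim, caplog):
    genomes, truth = sim
    g = genomes[0]
    pcgs = concatenated_pcgs(g)
    assert list(pcgs) == list(PCG_ORDER)
    coords = truth.gene_coords[g.id]
    for name, cds in pcgs.items():
        start, end, _ = coords[name]
        assert len(cds) == end - start

    import logging
    trimmed = Mitogenome(
        id="t2", sequence=g.sequence,
        features=[f for f in g.features if f.name != "ND2"],
    )
    with caplog.at_level(logging.WARNING):
        pcgs12 = concatenated_pcgs(trimmed)
    assert len(pcgs12) == 12 and "ND2" not in pcgs12
    assert any("ND2" in rec.message for rec in caplog.records)


def test_feature_table_round_trip(sim, tmp_path):
    genomes, _ = sim
    g = genomes[0]
    fasta, table = tmp_path / "rt.fasta", tmp_path / "rt.features.tsv"
    write_feature_table(g, fasta, table)
    g2 = parse_feature_table(fasta, table, id=g.id)
    assert g2.sequence == g.sequence
    assert [
        (f.name, f.kind, f.start, f.end, f.strand, f.anticodon_offset)
        for f in g2.features
    ] == [
        (f.name, f.kind, f.start, f.end, f.strand, f.anticodon_offset)
        for f in g.features
    ]


@settings(max_examples=50, deadline=None)
@given(dna)
def test_revcomp_involution(s):
    assert revcomp(revcomp(s)) == s


def test_feature_length_matches_span(sim):
    genomes, _ = sim
    for g in genomes[:2]:
        for f in g.features:
            assert len(gene_sequence(g, f.name)) == f.length
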