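import numpy as np
import pytest
from scipy import stats

from oracles import fisher_exact_enumeration
from mitocode.codes import INVERTEBRATE_MITO
from mitocode.genome_io import GeneFeature, Mitogenome
from mitocode.inference import CodonAssignment
from mitocode.simulate import trna_scaffold, TRNA_ANTICODON_OFFSET, _STANDARD_ANTICODONS_DNA
from mitocode.trna import (
    AnticodonRecord, STANDARD_ANTICODONS, WobbleRules,
    anticodon_code_association, anticodon_table_coverage, decoded_codons,
    extract_anticodon, has_dhu_arm, locate_anticodon_loop,
)


@pytest.mark.parametrize(
    "anticodon,codons",
    [
        ("CUU", {"AAG"}),
        ("UUU", {"AAA", "AAG"}),
        ("GCU", {"AGC", "AGU"}),
        ("UCU", {"AGA", "AGG"}),
        ("CAU", {"AUG"}),
        ("GAU", {"AUC", "AUU"}),
    ],
)
def test_wobble_decoding(anticodon, codons):
    assert decoded_codons(anticodon) == codons


def test_custom_wobble_rules():
    rules = WobbleRules(position34={"C": frozenset("AG"), "U": frozenset("AG"),
                                    "G": frozenset("CU"), "A": frozenset("U")})
    assert decoded_codons("CUU", rules) == {"AAA", "AAG"}


def test_standard_anticodon_table_covers_all_sense_codons():
    """Cognate expansion of the 22 standard anticodons reads all 62 sense
    codons with no within-box double coverage."""
    cov = anticodon_table_coverage()
    sense = {c.replace("T", "U") for c in INVERTEBRATE_MITO.sense_codons()}
    assert set(cov) == sense and len(sense) == 62
    assert all(len(trnas) == 1 for trnas in cov.values())


def test_variant_anticodons_claim_the_agn_and_aar_boxes():
    cov = anticodon_table_coverage(
        {**STANDARD_ANTICODONS, "tRNA-Lys": "UUU", "tRNA-Ser(S1)": "UCU"}
    )
    assert cov["AGG"] == ["tRNA-Ser(S1)"] and cov["AAA"] == ["tRNA-Lys"]


def _trna_genome(anticodon_dna, offset=None, strand="+"):
    seq = trna_scaffold(anticodon_dna)
    from mitocode.genome_io import revcomp

    genomic = revcomp(seq) if strand == "-" else seq
    return Mitogenome(
        id="toy", sequence=genomic + "A" * 20,
        features=[GeneFeature("tRNA-Lys", "tRNA", 0, len(seq), strand,
                              anticodon_offset=offset)],
    )


def test_extract_anticodon_from_annotation_and_transcription():
    g = _trna_genome("CAT", offset=TRNA_ANTICODON_OFFSET)
    rec = extract_anticodon(g, "tRNA-Lys")
    assert rec.anticodon == "CAU" and rec.source == "annotation"


@pytest.mark.parametrize("name,ac", sorted(_STANDARD_ANTICODONS_DNA.items()))
def test_heuristic_recovers_planted_anticodon(name, ac):
    g = _trna_genome(ac, offset=None)
    rec = extract_anticodon(g, "tRNA-Lys")
    assert rec.source == "heuristic"
    assert rec.anticodon == ac.replace("T", "U")


def test_heuristic_on_minus_strand_trna():
    g = _trna_genome("TTT", offset=None, strand="-")
    assert extract_anticodon(g, "tRNA-Lys").anticodon == "UUU"


def test_heuristic_fails_on_unstructured_sequence():
    with pytest.raises(ValueError, match="not localizable"):
        locate_anticodon_loop("A" * 70)
    with pytest.raises(ValueError):
        locate_anticodon_loop("ACGT")  # shorter than one arm


def test_dhu_arm_detection():
    assert has_dhu_arm(trna_scaffold("CTT"), TRNA_ANTICODON_OFFSET)
    assert not has_dhu_arm("A" * 70)


def _records(pairs):
    return [
        AnticodonRecord(taxon=t, trna="tRNA-Ser(S1)", anticodon=ac, source="annotation")
        for t, ac in pairs
    ]


def _assignments(pairs):
    return [
        CodonAssignment(taxon=t, codon="AGG", n_occurrences=5, tally={},
                        predicted=p, support=1.0)
        for t, p in pairs
    ]


def test_perfect_association_p_value():
    # 4 Ser/UCU vs 2 Lys/GCU: exhaustive hypergeometric tail = 1/15
    recs = _records([("a", "UCU"), ("b", "UCU"), ("c", "UCU"), ("d", "UCU"),
                     ("e", "GCU"), ("f", "GCU")])
    assigns = _assignments([("a", "S"), ("b", "S"), ("c", "S"), ("d", "S"),
                            ("e", "K"), ("f", "K")])
    res = anticodon_code_association(recs, assigns)
    assert res.fisher_p == pytest.approx(1 / 15)
    assert res.table == ((0, 2), (4, 0))


def test_degenerate_margin_and_informative_exclusion():
    recs = _records([("a", "GCU"), ("b", "GCU"), ("c", "GCU"), ("d", "GCU")])
    assigns = _assignments([("a", "S"), ("b", "S"), ("c", "K"), ("d", "K")])
    res = anticodon_code_association(recs, assigns)
    assert res.fisher_p == pytest.approx(1.0)
    # UNUSED/UNPREDICTED taxa are excluded entirely
    assigns2 = _assignments([("a", "S"), ("b", "UNUSED"), ("c", "UNPREDICTED"),
                             ("d", "K")])
    res2 = anticodon_code_association(recs, assigns2)
    assert res2.n == 2
    with pytest.raises(ValueError):
        anticodon_code_association(recs, _assignments([("a", "S")]))


def test_fisher_matches_exhaustive_enumeration_small_n():
    rng = np.random.default_rng(42)
    for _ in range(200):
        n = rng.integers(2, 13)
        cells = rng.multinomial(n, [0.25] * 4)
        table = [[int(cells[0]), int(cells[1])], [int(cells[2]), int(cells[3])]]
        _, p_scipy = stats.fisher_exact(table)
        p_enum = fisher_exact_enumeration(table)
        assert p_scipy == pytest.approx(p_enum, rel=1e-9), table


def test_association_type_one_error_under_permutation():
    """Shuffling meanings independently of anticodons keeps the rejection
    rate at alpha=0.05 within the exact test's conservative bound."""
    rng = np.random.default_rng(7)
    anticodons = ["UCU"] * 6 + ["GCU"] * 6
    meanings = ["S"] * 6 + ["K"] * 6
    recs = _records(list(zip([f"t{i}" for i in range(12)], anticodons)))
    rejections = 0
    n_perm = 500
    for _ in range(n_perm):
        shuffled = list(meanings)
        rng.shuffle(shuffled)
        assigns = _assignments(list(zip([f"t{i}" for i in range(12)], shuffled)))
        res = anticodon_code_association(recs, assigns)
        rejections += res.fisher_p < 0.05
    assert rejections / n_perm <= 0.07
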