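"""tRNA anticodons, wobble decoding, and anticodon/genetic-code association.

Anticodons are stored in standard 5'->3' notation (e.g. CUU for the
typical lysine tRNA, which reads AAG; the Adelphocoris variant UUU reads
AAA and AAG).  Decoding expands the codon third position from the wobble
base at anticodon position 34; codon positions 1-2 are the reverse
complement of anticodon positions 35-36.
"""

from __future__ import annotations

import itertools
from dataclasses import dataclass, field

from scipy import stats

from .codes import GeneticCode, INVERTEBRATE_MITO
from .genome_io import Mitogenome, gene_sequence
from .inference import CodonAssignment

RNA_COMPLEMENT = {"A": "U", "U": "A", "G": "C", "C": "G"}

#: Typical anticodons of the 22 insect mitochondrial tRNAs (standard notation).
STANDARD_ANTICODONS: dict[str, str] = {
    "tRNA-Ala": "UGC", "tRNA-Arg": "UCG", "tRNA-Asn": "GUU", "tRNA-Asp": "GUC",
    "tRNA-Cys": "GCA", "tRNA-Gln": "UUG", "tRNA-Glu": "UUC", "tRNA-Gly": "UCC",
    "tRNA-His": "GUG", "tRNA-Ile": "GAU", "tRNA-Leu(L1)": "UAG",
    "tRNA-Leu(L2)": "UAA", "tRNA-Lys": "CUU", "tRNA-Met": "CAU",
    "tRNA-Phe": "GAA", "tRNA-Pro": "UGG", "tRNA-Ser(S1)": "GCU",
    "tRNA-Ser(S2)": "UGA", "tRNA-Thr": "UGU", "tRNA-Trp": "UCA",
    "tRNA-Tyr": "GUA", "tRNA-Val": "UAC",
}


@dataclass(frozen=True)
class AnticodonRecord:
    taxon: str
    trna: str
    anticodon: str  # standard 5'->3' notation over {A,C,G,U}
    source: str  # "annotation" or "heuristic"

    def __post_init__(self) -> None:
        if len(self.anticodon) != 3 or set(self.anticodon) - set("ACGU"):
            raise ValueError(f"invalid anticodon {self.anticodon!r}")
        if self.source not in ("annotation", "heuristic"):
            raise ValueError(f"unknown source {self.source!r}")


@dataclass(frozen=True)
class WobbleRules:
    """Codon third-position bases read by each base at anticodon position 34.

    The defaults are the classic wobble pairings; mitochondrial
    modified-base superwobble is handled separately at the whole-table
    level (see :func:`anticodon_table_coverage`).
    """

    position34: dict[str, frozenset[str]] = field(
        default_factory=lambda: {
            "G": frozenset("CU"),
            "U": frozenset("AG"),
            "C": frozenset("G"),
            "A": frozenset("U"),
        }
    )


def decoded_codons(ac: AnticodonRecord | str, rules: WobbleRules = WobbleRules()) -> set[str]:
    """The mRNA codons (RNA notation) an anticodon reads under wobble rules."""
    anticodon = ac.anticodon if isinstance(ac, AnticodonRecord) else ac
    anticodon = anticodon.upper().replace("T", "U")
    stem = "".join(RNA_COMPLEMENT[b] for b in reversed(anticodon[1:]))
    return {stem + third for third in rules.position34[anticodon[0]]}


def cognate_codons(anticodon: str, code: GeneticCode = INVERTEBRATE_MITO) -> set[str]:
    """The synonymous codons of the anticodon's cognate amino acid within
    its codon family box (RNA notation).

    This is the decoding a full mitochondrial tRNA set achieves in
    practice: modified wobble bases let a lone tRNA serve every codon of
    its amino acid in the box (e.g. CAU of tRNA-Met reads both AUA and
    AUG), which strict position-34 rules alone cannot express.
    """
    anticodon = anticodon.upper().replace("T", "U")
    wc = "".join(RNA_COMPLEMENT[b] for b in reversed(anticodon))
    aa = code[wc]
    box = wc[:2]
    return {box + third for third in "ACGU" if code[box + third] == aa}


def anticodon_table_coverage(
    anticodons: dict[str, str] | None = None,
    code: GeneticCode = INVERTEBRATE_MITO,
) -> dict[str, list[str]]:
    """Map each sense codon to the tRNAs decoding it under cognate expansion.

    With the standard 22 anticodons and the invertebrate mitochondrial
    code, every one of the 62 sense codons is covered exactly once.
    """
    anticodons = anticodons or STANDARD_ANTICODONS
    coverage: dict[str, list[str]] = {}
    for trna, ac in anticodons.items():
        for codon in cognate_codons(ac, code):
            coverage.setdefault(codon, []).append(trna)
    return coverage


# --- anticodon localization ---------------------------------------------------

_PAIRS = {("A", "T"), ("T", "A"), ("G", "C"), ("C", "G"), ("G", "T"), ("T", "G")}


def _stem_score(window: str) -> int:
    """Number of paired positions (Watson-Crick or GU) in a 5-bp stem
    closing a 7-nt loop: window[k] vs window[16-k] for k in 0..4."""
    return sum((window[k], window[16 - k]) in _PAIRS for k in range(5))


def locate_anticodon_loop(seq: str) -> int:
    """Offset of the best anticodon-arm window in a tRNA gene sequence.

    Scans every 17-nt window (5-bp stem + 7-nt loop + 5-bp stem), scores
    stem pairing, and among maximal scores picks the loop nearest the
    sequence midpoint — the anticodon arm is the central arm of the
    cloverleaf.  Raises when no window pairs at >=3 of 5 stem positions.
    """
    s = seq.upper().replace("U", "T")
    if len(s) < 17:
        raise ValueError("anticodon not localizable: sequence shorter than one arm")
    mid = len(s) / 2
    best: tuple[int, float, int] | None = None  # (-score, |center-mid|, start)
    for i in range(len(s) - 16):
        score = _stem_score(s[i : i + 17])
        key = (-score, abs(i + 8.5 - mid), i)
        if best is None or key < best:
            best = key
    if best is None or -best[0] < 3:
        raise ValueError("anticodon not localizable: no stem with >=3 pairs")
    return best[2] + 7  # loop positions 3-5 hold the anticodon


def extract_anticodon(genome: Mitogenome, trna: str) -> AnticodonRecord:
    """Anticodon of an annotated tRNA: sliced at the annotated offset when
    present, otherwise localized by the cloverleaf heuristic."""
    feature = genome.feature(trna)
    if feature.kind != "tRNA":
        raise ValueError(f"{trna} is a {feature.kind}, not a tRNA")
    seq = gene_sequence(genome, trna)
    if feature.anticodon_offset is not None:
        offset, source = feature.anticodon_offset, "annotation"
    else:
        offset, source = locate_anticodon_loop(seq), "heuristic"
    anticodon = seq[offset : offset + 3].replace("T", "U")
    return AnticodonRecord(
        taxon=genome.id, trna=trna, anticodon=anticodon, source=source
    )


def has_dhu_arm(seq: str, anticodon_offset: int | None = None) -> bool:
    """Whether a paired stem-loop is found 5' of the anticodon arm (a crude
    DHU-arm presence call from the same stem search, not a structure model)."""
    s = seq.upper().replace("U", "T")
    try:
        ac = anticodon_offset if anticodon_offset is not None else locate_anticodon_loop(s)
    except ValueError:
        return False
    upstream = s[: max(ac - 7, 0)]
    for i in range(len(upstream) - 12):
        window = upstream[i : i + 13]  # 4-bp stem + 5-nt loop + 4-bp stem
        if sum((window[k], window[12 - k]) in _PAIRS for k in range(4)) >= 3:
            return True
    return False


# --- association --------------------------------------------------------------


@dataclass(frozen=True)
class AssociationResult:
    trna: str
    states: tuple[str, str]  # anticodon states (rows)
    meanings: tuple[str, str]  # predicted amino acids (columns)
    table: tuple[tuple[int, int], tuple[int, int]]
    fisher_p: float

    @property
    def n(self) -> int:
        return sum(itertools.chain.from_iterable(self.table))


def anticodon_code_association(
    anticodons: list[AnticodonRecord],
    assignments: list[CodonAssignment],
    trna: str = "tRNA-Ser(S1)",
    states: tuple[str, str] = ("GCU", "UCU"),
    meanings: tuple[str, str] = ("S", "K"),
) -> AssociationResult:
    """Two-sided Fisher exact test of anticodon state against predicted
    codon meaning over taxa with an informative prediction (UNUSED and
    UNPREDICTED taxa are excluded — a taxon that never uses the codon says
    nothing about its translation)."""
    ac_by_taxon = {r.taxon: r.anticodon for r in anticodons if r.trna == trna}
    table = [[0, 0], [0, 0]]
    n = 0
    for a in assignments:
        if a.predicted not in meanings or a.taxon not in ac_by_taxon:
            continue
        ac = ac_by_taxon[a.taxon]
        if ac not in states:
            continue
        table[states.index(ac)][meanings.index(a.predicted)] += 1
        n += 1
    if n < 2:
        raise ValueError(f"fewer than 2 informative taxa for {trna} ({n})")
    _, p = stats.fisher_exact(table, alternative="two-sided")
    return AssociationResult(
        trna=trna, states=states, meanings=meanings,
        table=(tuple(table[0]), tuple(table[1])), fisher_p=float(p),
    )
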