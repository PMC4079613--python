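"""Codon-aware multiple alignment of protein-coding genes.

Sequences are aligned at the amino-acid level and back-translated to
codons, so every alignment column corresponds to a homologous codon
position.  The internal aligner is a center-star progressive alignment
(guide order from k-mer distances, pairwise global alignment under
BLOSUM62 with affine gaps, merged by the once-a-gap-always-a-gap rule);
an externally computed codon-aware alignment in FASTA always overrides it.
"""

from __future__ import annotations

import logging
from collections import Counter
from dataclasses import dataclass, field

import numpy as np
from Bio import Align, SeqIO
from Bio.Align import substitution_matrices

from .codes import GeneticCode, INVERTEBRATE_MITO

log = logging.getLogger(__name__)

GAP = "---"


@dataclass
class CodonAlignment:
    """Per-gene aligned codon matrices over a shared ordered taxon list.

    ``blocks[gene]`` is an (n_taxa, n_columns) array of 3-mers, with
    ``---`` marking gaps (including whole-gene absence for a taxon).
    """

    taxa: list[str]
    blocks: dict[str, np.ndarray] = field(default_factory=dict)

    def __post_init__(self) -> None:
        for gene, arr in self.blocks.items():
            if arr.shape[0] != len(self.taxa):
                raise ValueError(
                    f"{gene}: {arr.shape[0]} rows for {len(self.taxa)} taxa"
                )

    @property
    def n_columns(self) -> int:
        return sum(arr.shape[1] for arr in self.blocks.values())

    def row_index(self, taxon: str) -> int:
        return self.taxa.index(taxon)

    def occupancy(self, gene: str) -> np.ndarray:
        """Fraction of non-gap cells per column."""
        arr = self.blocks[gene]
        return (arr != GAP).mean(axis=0)

    def conservation(
        self,
        gene: str,
        codes: dict[str, GeneticCode] | None = None,
        exclude_codon: str | None = None,
    ) -> np.ndarray:
        """Top-amino-acid fraction per column among non-gap cells, each cell
        translated under its taxon's baseline code.

        Cells equal to ``exclude_codon`` are left out of the tally entirely
        so that candidate reassigned-codon columns are not self-filtered.
        Columns with no tallied cells are vacuously conserved (1.0).
        """
        arr = self.blocks[gene]
        out = np.ones(arr.shape[1])
        for j in range(arr.shape[1]):
            tally = self.column_tally(gene, j, codes=codes, exclude_codon=exclude_codon)
            n = sum(tally.values())
            if n:
                out[j] = max(tally.values()) / n
        return out

    def column_tally(
        self,
        gene: str,
        col: int,
        codes: dict[str, GeneticCode] | None = None,
        exclude_codon: str | None = None,
        exclude_taxon: str | None = None,
    ) -> Counter:
        """Amino-acid counts in one column (see :meth:`conservation`)."""
        arr = self.blocks[gene]
        tally: Counter = Counter()
        for i, taxon in enumerate(self.taxa):
            cell = arr[i, col]
            if cell == GAP or "-" in cell:
                continue
            if exclude_codon is not None and cell == exclude_codon:
                continue
            if taxon == exclude_taxon:
                continue
            code = (codes or {}).get(taxon, INVERTEBRATE_MITO)
            aa = code[cell] if set(cell) <= set("ACGT") else "X"
            tally[aa] += 1
        return tally

    def count_codon(self, taxon: str, codon: str) -> int:
        i = self.row_index(taxon)
        return int(sum((arr[i] == codon).sum() for arr in self.blocks.values()))


# --- internal aligner ---------------------------------------------------------


def _kmer_profile(seq: str, k: int = 3) -> Counter:
    return Counter(seq[i : i + k] for i in range(max(len(seq) - k + 1, 1)))


def _kmer_distance(a: Counter, b: Counter) -> float:
    shared = sum((a & b).values())
    total = sum((a | b).values())
    return 1.0 - shared / total if total else 0.0


def _make_aligner() -> Align.PairwiseAligner:
    aligner = Align.PairwiseAligner()
    aligner.mode = "global"
    aligner.substitution_matrix = substitution_matrices.load("BLOSUM62")
    aligner.open_gap_score = -11.0
    aligner.extend_gap_score = -1.0
    return aligner


def _pairwise_to_center(center: str, seq: str, aligner) -> tuple[list[str], list[str]]:
    """Align ``seq`` to ``center``; return per-center-position insertions
    (length L+1: block i precedes center residue i) and aligned characters
    (length L, '-' where seq gaps the center residue)."""
    aln = aligner.align(center, seq)[0]
    gc, gs = str(aln[0]), str(aln[1])
    L = len(center)
    ins: list[str] = [""] * (L + 1)
    match: list[str] = ["-"] * L
    j = 0
    for cc, sc in zip(gc, gs):
        if cc == "-":
            ins[j] += sc
        else:
            if sc != "-":
                match[j] = sc
            j += 1
    return ins, match


def center_star_align(
    seqs: dict[str, str], aligner: Align.PairwiseAligner | None = None
) -> dict[str, str]:
    """Multiple alignment by the center-star method (amino acids under
    BLOSUM62 by default; pass a nucleotide aligner for DNA).

    Returns gapped sequences of equal length, keyed like the input.
    """
    names = list(seqs)
    if len(names) == 1:
        return dict(seqs)
    profiles = {n: _kmer_profile(seqs[n]) for n in names}
    center = min(
        names,
        key=lambda n: (sum(_kmer_distance(profiles[n], profiles[m]) for m in names), n),
    )
    if aligner is None:
        aligner = _make_aligner()
    c = seqs[center]
    L = len(c)
    per_seq: dict[str, tuple[list[str], list[str]]] = {}
    master_ins = [0] * (L + 1)
    for n in names:
        if n == center:
            continue
        ins, match = _pairwise_to_center(c, seqs[n], aligner)
        per_seq[n] = (ins, match)
        for j in range(L + 1):
            master_ins[j] = max(master_ins[j], len(ins[j]))

    def assemble(ins: list[str], match: list[str]) -> str:
        parts = []
        for j in range(L):
            parts.append(ins[j].ljust(master_ins[j], "-"))
            parts.append(match[j])
        parts.append(ins[L].ljust(master_ins[L], "-"))
        return "".join(parts)

    out = {center: assemble([""] * (L + 1), list(c))}
    for n in names:
        if n != center:
            out[n] = assemble(*per_seq[n])
    return {n: out[n] for n in names}


def _prepare_cds(cds: str, code: GeneticCode) -> tuple[str, str]:
    """Trim to whole codons, drop a terminal stop, and translate; internal
    stops become '*' (scored like any rare residue by the aligner)."""
    trimmed = cds.upper()[: len(cds) - len(cds) % 3]
    if len(trimmed) >= 6 and set(trimmed[-3:]) <= set("ACGT") and code[trimmed[-3:]] == "*":
        trimmed = trimmed[:-3]
    aa = []
    for i in range(0, len(trimmed), 3):
        codon = trimmed[i : i + 3]
        aa.append(code[codon] if set(codon) <= set("ACGT") else "X")
    return trimmed, "".join(aa)


def build_codon_alignment(
    per_gene_cds: dict[str, dict[str, str]],
    code: GeneticCode = INVERTEBRATE_MITO,
) -> CodonAlignment:
    """Align each gene across taxa at the amino-acid level and back-translate.

    ``per_gene_cds`` maps taxon -> gene -> coding-strand CDS.  A taxon
    missing a gene receives an all-gap row for that gene.
    """
    taxa = list(per_gene_cds)
    if len(taxa) < 2:
        raise ValueError("need at least 2 taxa to align")
    genes: list[str] = []
    for gmap in per_gene_cds.values():
        for gene in gmap:
            if gene not in genes:
                genes.append(gene)

    blocks: dict[str, np.ndarray] = {}
    for gene in genes:
        nts: dict[str, str] = {}
        aas: dict[str, str] = {}
        for taxon in taxa:
            cds = per_gene_cds[taxon].get(gene)
            if cds:
                nts[taxon], aas[taxon] = _prepare_cds(cds, code)
        if not aas:
            continue
        gapped = center_star_align(aas)
        n_cols = len(next(iter(gapped.values())))
        arr = np.full((len(taxa), n_cols), GAP, dtype="<U3")
        for i, taxon in enumerate(taxa):
            if taxon not in gapped:
                continue
            row = gapped[taxon]
            cds = nts[taxon]
            k = 0
            for j, aa in enumerate(row):
                if aa != "-":
                    arr[i, j] = cds[3 * k : 3 * k + 3]
                    k += 1
            if 3 * k != len(cds):
                raise AssertionError(f"{gene}/{taxon}: back-translation mismatch")
        blocks[gene] = arr
    return CodonAlignment(taxa=taxa, blocks=blocks)


def filter_columns(
    aln: CodonAlignment,
    min_occupancy: float = 0.8,
    min_conservation: float = 0.5,
    target: str | None = None,
    codes: dict[str, GeneticCode] | None = None,
) -> CodonAlignment:
    """Keep columns with occupancy >= ``min_occupancy`` and top-amino-acid
    fraction >= ``min_conservation`` (cells equal to ``target`` excluded
    from the conservation tally)."""
    if not (0 <= min_occupancy <= 1 and 0 <= min_conservation <= 1):
        raise ValueError("thresholds must lie in [0, 1]")
    blocks: dict[str, np.ndarray] = {}
    for gene, arr in aln.blocks.items():
        occ = aln.occupancy(gene)
        cons = aln.conservation(gene, codes=codes, exclude_codon=target)
        keep = (occ >= min_occupancy) & (cons >= min_conservation)
        blocks[gene] = arr[:, keep]
    out = CodonAlignment(taxa=list(aln.taxa), blocks=blocks)
    if out.n_columns == 0:
        log.warning("column filter removed every alignment column")
    return out


def read_codon_alignment(path: str, gene: str = "alignment") -> CodonAlignment:
    """Read an externally aligned codon-aware FASTA (row lengths equal and
    multiples of 3) as a single-block :class:`CodonAlignment`; codons
    containing any gap character count as gap cells."""
    records = list(SeqIO.parse(str(path), "fasta"))
    if len(records) < 2:
        raise ValueError(f"{path}: need at least 2 aligned sequences")
    lengths = {len(r.seq) for r in records}
    if len(lengths) != 1:
        raise ValueError(f"{path}: unequal aligned lengths {sorted(lengths)}")
    (length,) = lengths
    if length % 3:
        raise ValueError(f"{path}: aligned length {length} is not a codon multiple")
    taxa = [r.id for r in records]
    arr = np.full((len(taxa), length // 3), GAP, dtype="<U3")
    for i, rec in enumerate(records):
        s = str(rec.seq).upper()
        for j in range(length // 3):
            codon = s[3 * j : 3 * j + 3]
            arr[i, j] = GAP if "-" in codon else codon
    return CodonAlignment(taxa=taxa, blocks={gene: arr})
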