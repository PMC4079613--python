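"""Mitochondrial genetic codes and translation.

The invertebrate mitochondrial code (NCBI translation table 5) is the
baseline for all true bugs: AGA/AGG encode Ser, AUA encodes Met, UGA
encodes Trp.  Some heteropteran lineages instead translate AGG as Lys;
that variant is provided as a one-codon modification of the base table.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterator

from Bio.Data import CodonTable as _CodonTable

BASES = "TCAG"
STOP = "*"
CODONS: tuple[str, ...] = tuple(
    a + b + c for a in BASES for b in BASES for c in BASES
)


def _table_from_ncbi(table_id: int) -> dict[str, str]:
    ncbi = _CodonTable.unambiguous_dna_by_id[table_id]
    table = dict(ncbi.forward_table)
    for stop in ncbi.stop_codons:
        table[stop] = STOP
    return table


@dataclass(frozen=True)
class GeneticCode:
    """A total map from the 64 DNA codons to amino acids (``*`` = stop)."""

    id: str
    table: dict[str, str] = field(repr=False)

    def __post_init__(self) -> None:
        if set(self.table) != set(CODONS):
            missing = set(CODONS) - set(self.table)
            extra = set(self.table) - set(CODONS)
            raise ValueError(
                f"genetic code {self.id!r} is not total: "
                f"missing={sorted(missing)} extra={sorted(extra)}"
            )

    def __getitem__(self, codon: str) -> str:
        return self.table[codon.upper().replace("U", "T")]

    def with_changes(self, changes: dict[str, str], id: str) -> "GeneticCode":
        """Derive a variant code differing only at the declared codons."""
        table = dict(self.table)
        for codon, aa in changes.items():
            codon = codon.upper().replace("U", "T")
            if codon not in table:
                raise ValueError(f"not a codon: {codon!r}")
            table[codon] = aa
        variant = GeneticCode(id=id, table=table)
        diff = {c for c in CODONS if variant.table[c] != self.table[c]}
        declared = {c.upper().replace("U", "T") for c in changes}
        if not diff <= declared:
            raise ValueError(
                f"variant {id!r} differs at undeclared codons: {sorted(diff - declared)}"
            )
        return variant

    def differences(self, other: "GeneticCode") -> dict[str, tuple[str, str]]:
        return {
            c: (self.table[c], other.table[c])
            for c in CODONS
            if self.table[c] != other.table[c]
        }

    def sense_codons(self) -> Iterator[str]:
        return (c for c in CODONS if self.table[c] != STOP)


#: NCBI table 5: AGA/AGG=Ser, ATA=Met, TGA=Trp.
INVERTEBRATE_MITO = GeneticCode(
    id="invertebrate_mitochondrial", table=_table_from_ncbi(5)
)

#: The reassigned variant seen in many Heteroptera: AGG decoded as Lys.
INVERTEBRATE_MITO_AGG_LYS = INVERTEBRATE_MITO.with_changes(
    {"AGG": "K"}, id="invertebrate_mitochondrial+AGG=Lys"
)

CODES_BY_STATE = {"Ser": INVERTEBRATE_MITO, "Lys": INVERTEBRATE_MITO_AGG_LYS}


def translate(cds: str, code: GeneticCode = INVERTEBRATE_MITO) -> str:
    """Translate a CDS one codon at a time.

    Trailing 1-2 bases (an incomplete stop completed by polyadenylation in
    mitochondria) are dropped.  Codons containing non-ACGT characters give
    ``X``; stop codons give ``*``.
    """
    if len(cds) < 3:
        raise ValueError(f"CDS shorter than one codon: {len(cds)} bases")
    cds = cds.upper().replace("U", "T")
    out = []
    for i in range(0, len(cds) - len(cds) % 3, 3):
        codon = cds[i : i + 3]
        if set(codon) <= set("ACGT"):
            out.append(code.table[codon])
        else:
            out.append("X")
    return "".join(out)
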