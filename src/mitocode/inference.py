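"""Codon usage tabulation and alignment-based genetic-code inference.

The predictor asks, for every alignment column where a focal taxon uses
the target codon (AGG by default): which amino acid do the other taxa
carry at that homologous position?  Tallies are taken over conserved,
well-occupied columns only; cells that are themselves the target codon
are excluded so the inference is never circular.  A taxon's prediction is
the majority over its per-occurrence calls, with explicit UNPREDICTED
(ambiguous) and UNUSED (codon absent) states.
"""

from __future__ import annotations

import logging
from collections import Counter
from dataclasses import dataclass, field, replace

from .alignment import CodonAlignment, GAP, filter_columns
from .codes import CODONS, GeneticCode, INVERTEBRATE_MITO

log = logging.getLogger(__name__)

UNPREDICTED = "UNPREDICTED"
UNUSED = "UNUSED"

#: Display names for predicted states (one-letter amino acids otherwise).
AA_DISPLAY = {
    "A": "Ala", "R": "Arg", "N": "Asn", "D": "Asp", "C": "Cys", "Q": "Gln",
    "E": "Glu", "G": "Gly", "H": "His", "I": "Ile", "L": "Leu", "K": "Lys",
    "M": "Met", "F": "Phe", "P": "Pro", "S": "Ser", "T": "Thr", "W": "Trp",
    "Y": "Tyr", "V": "Val", UNPREDICTED: UNPREDICTED, UNUSED: UNUSED,
}


@dataclass(frozen=True)
class CodonUsage:
    taxon: str
    counts: dict[str, int]

    @property
    def total(self) -> int:
        return sum(self.counts.values())

    def __getitem__(self, codon: str) -> int:
        return self.counts[codon.upper().replace("U", "T")]


def codon_usage(pcgs: dict[str, str], taxon: str = "") -> CodonUsage:
    """64-entry codon count table over a taxon's protein-coding genes; each
    CDS is trimmed to complete codons."""
    counts = dict.fromkeys(CODONS, 0)
    for cds in pcgs.values():
        s = cds.upper().replace("U", "T")
        for i in range(0, len(s) - len(s) % 3, 3):
            codon = s[i : i + 3]
            if codon in counts:
                counts[codon] += 1
    return CodonUsage(taxon=taxon, counts=counts)


@dataclass(frozen=True)
class ColumnTally:
    gene: str
    column: int
    counts: dict[str, int]

    @property
    def n_informative(self) -> int:
        return sum(self.counts.values())


@dataclass(frozen=True)
class CodonAssignment:
    """The inferred meaning of one codon for one taxon."""

    taxon: str
    codon: str
    n_occurrences: int
    tally: dict[str, int]  # aggregated over all scored occurrences
    predicted: str  # one-letter amino acid, UNPREDICTED, or UNUSED
    support: float  # top-amino-acid fraction of the aggregated tally

    @property
    def display(self) -> str:
        return AA_DISPLAY.get(self.predicted, self.predicted)


@dataclass(frozen=True)
class PredictorParams:
    """Thresholds of the conserved-column predictor (all CLI-exposed)."""

    min_occupancy: float = 0.8
    min_conservation: float = 0.5
    majority_threshold: float = 0.5
    min_informative: int = 3
    iterate: bool = False  # re-run with updated per-taxon codes to a fixpoint


def _majority(counter: Counter) -> tuple[str | None, int]:
    """(winner, count); winner is None on a tie or empty counter."""
    if not counter:
        return None, 0
    ranked = counter.most_common()
    if len(ranked) > 1 and ranked[0][1] == ranked[1][1]:
        return None, ranked[0][1]
    return ranked[0]


def predict_codon_meaning(
    aln: CodonAlignment,
    focal: str,
    target: str = "AGG",
    majority_threshold: float = 0.5,
    min_informative: int = 3,
    codes: dict[str, GeneticCode] | None = None,
    n_occurrences: int | None = None,
) -> CodonAssignment:
    """Predict the focal taxon's meaning of ``target`` from the columns of
    ``aln`` (pass a conservation-filtered alignment; see
    :func:`predict_all`).

    Per occurrence: the amino acids of the other taxa at that column are
    tallied (each translated under its own baseline code, cells equal to
    the target codon excluded) and called as the majority amino acid when
    its fraction reaches ``majority_threshold`` over at least
    ``min_informative`` informative taxa, else ``?``.  The taxon-level
    prediction is the majority over per-occurrence calls; ties at either
    level give UNPREDICTED.  ``n_occurrences`` overrides the occurrence
    count (used when the scanned alignment is a filtered subset).
    """
    target = target.upper().replace("U", "T")
    if len(target) != 3 or set(target) - set("ACGT"):
        raise ValueError(f"not a valid codon: {target!r}")
    if focal not in aln.taxa:
        raise ValueError(f"focal taxon {focal!r} not in alignment")
    fi = aln.row_index(focal)

    occurrence_calls: list[str] = []
    aggregated: Counter = Counter()
    for gene, arr in aln.blocks.items():
        for col in range(arr.shape[1]):
            if arr[fi, col] != target:
                continue
            tally = aln.column_tally(
                gene, col, codes=codes, exclude_codon=target, exclude_taxon=focal
            )
            aggregated.update(tally)
            call = "?"
            n_inf = sum(tally.values())
            if n_inf >= min_informative:
                winner, count = _majority(tally)
                if winner is not None and count / n_inf >= majority_threshold:
                    call = winner
            occurrence_calls.append(call)

    n_seen = len(occurrence_calls)
    n_occ = n_seen if n_occurrences is None else n_occurrences
    top, top_count = _majority(aggregated)
    support = (
        max(aggregated.values()) / sum(aggregated.values()) if aggregated else 0.0
    )
    if n_occ == 0:
        predicted = UNUSED
    else:
        real_calls = Counter(c for c in occurrence_calls if c != "?")
        winner, _ = _majority(real_calls)
        predicted = winner if winner is not None else UNPREDICTED
    return CodonAssignment(
        taxon=focal, codon=target, n_occurrences=n_occ,
        tally=dict(aggregated), predicted=predicted, support=support,
    )


def predict_all(
    aln: CodonAlignment,
    target: str = "AGG",
    params: PredictorParams = PredictorParams(),
    codes: dict[str, GeneticCode] | None = None,
) -> list[CodonAssignment]:
    """One :class:`CodonAssignment` per taxon, deterministic given inputs.

    The alignment is conservation-filtered once (target-codon cells never
    count against a column), occurrence counts are taken on the unfiltered
    alignment, and each taxon is then predicted from the filtered columns.
    With ``params.iterate`` the per-taxon baseline codes are updated from
    the predictions and the pass repeats until a fixpoint (single pass by
    default, matching a one-shot review of the alignment).
    """
    target_dna = target.upper().replace("U", "T")
    codes = dict(codes or {})
    for _round in range(5 if params.iterate else 1):
        filtered = filter_columns(
            aln,
            min_occupancy=params.min_occupancy,
            min_conservation=params.min_conservation,
            target=target_dna,
            codes=codes,
        )
        assignments = [
            predict_codon_meaning(
                filtered,
                focal=taxon,
                target=target_dna,
                majority_threshold=params.majority_threshold,
                min_informative=params.min_informative,
                codes=codes,
                n_occurrences=aln.count_codon(taxon, target_dna),
            )
            for taxon in aln.taxa
        ]
        if not params.iterate:
            return assignments
        updated = dict(codes)
        for a in assignments:
            if a.predicted in AA_DISPLAY and a.predicted not in (UNPREDICTED, UNUSED):
                base = codes.get(a.taxon, INVERTEBRATE_MITO)
                if base[target_dna] != a.predicted:
                    updated[a.taxon] = base.with_changes(
                        {target_dna: a.predicted},
                        id=f"{base.id}+{target_dna}={a.predicted}",
                    )
        if updated == codes:
            return assignments
        codes = updated
    return assignments


def usage_table(usages: list[CodonUsage]):
    """Codon-usage matrix: one row per taxon, 64 codon columns."""
    import pandas as pd

    return pd.DataFrame(
        [{"taxon": u.taxon, **u.counts} for u in usages]
    ).set_index("taxon")


def assignment_table(assignments: list[CodonAssignment]):
    """Per-taxon assignment summary (taxon, codon, n, predicted, support)."""
    import pandas as pd

    return pd.DataFrame(
        [
            {
                "taxon": a.taxon,
                "codon": a.codon,
                "n_occurrences": a.n_occurrences,
                "predicted": a.display,
                "support": round(a.support, 4),
            }
            for a in assignments
        ]
    )
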