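"""Compositional statistics of mitochondrial genomes.

AT-skew = (A-T)/(A+T) and GC-skew = (G-C)/(G+C), computed on the J-strand.
G+C%% is reported per codon position and pooled over all three positions of
the concatenated protein-coding genes; the GARP fraction is the percentage
of residues encoded by GC-rich codons (Gly, Ala, Arg, Pro), which tracks
genomic G+C content across taxa.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass

import pandas as pd
from scipy import stats

from .codes import GeneticCode, INVERTEBRATE_MITO, translate
from .genome_io import Mitogenome, concatenated_pcgs

log = logging.getLogger(__name__)

GARP = frozenset("GARP")


@dataclass(frozen=True)
class BaseComposition:
    a: int
    c: int
    g: int
    t: int

    @property
    def total(self) -> int:
        return self.a + self.c + self.g + self.t

    @property
    def at_skew(self) -> float:
        """(A-T)/(A+T); NaN (flagged undefined) when A+T == 0."""
        if self.a + self.t == 0:
            return math.nan
        return (self.a - self.t) / (self.a + self.t)

    @property
    def gc_skew(self) -> float:
        """(G-C)/(G+C); NaN (flagged undefined) when G+C == 0."""
        if self.g + self.c == 0:
            return math.nan
        return (self.g - self.c) / (self.g + self.c)

    @property
    def at_percent(self) -> float:
        return 100.0 * (self.a + self.t) / self.total if self.total else math.nan

    @property
    def gc_percent(self) -> float:
        return 100.0 * (self.g + self.c) / self.total if self.total else math.nan


def skews(seq: str) -> BaseComposition:
    """Count A/C/G/T (N excluded from all denominators) and derive skews."""
    if not seq:
        raise ValueError("empty sequence")
    s = seq.upper()
    return BaseComposition(a=s.count("A"), c=s.count("C"), g=s.count("G"), t=s.count("T"))


@dataclass(frozen=True)
class CodonPositionGC:
    gc1: float
    gc2: float
    gc3: float
    gc_all: float


def gc_by_position(cds: str) -> CodonPositionGC:
    """G+C percentage at each codon position and pooled; the trailing
    incomplete codon is dropped, N bases excluded from denominators."""
    if len(cds) < 3:
        raise ValueError(f"CDS shorter than one codon: {len(cds)} bases")
    s = cds.upper()[: len(cds) - len(cds) % 3]
    gc_counts = [0, 0, 0]
    totals = [0, 0, 0]
    for i, base in enumerate(s):
        pos = i % 3
        if base in "ACGT":
            totals[pos] += 1
            if base in "GC":
                gc_counts[pos] += 1
    pct = [100.0 * g / t if t else math.nan for g, t in zip(gc_counts, totals)]
    pooled = (
        100.0 * sum(gc_counts) / sum(totals) if sum(totals) else math.nan
    )
    return CodonPositionGC(gc1=pct[0], gc2=pct[1], gc3=pct[2], gc_all=pooled)


def garp_fraction(protein: str) -> float:
    """100 x (G+A+R+P) / length; stops and ambiguity codes are excluded
    from the denominator."""
    residues = [aa for aa in protein.upper() if aa.isalpha() and aa != "X"]
    if not residues:
        raise ValueError("no unambiguous residues")
    return 100.0 * sum(aa in GARP for aa in residues) / len(residues)


@dataclass(frozen=True)
class GarpPoint:
    taxon: str
    x: float  # G+C% over all codon positions of the concatenated PCGs
    y: float  # GARP%


@dataclass(frozen=True)
class RegressionFit:
    slope: float
    intercept: float
    r2: float


def fit_gc_garp(points: list[GarpPoint]) -> RegressionFit:
    """Ordinary least squares of GARP%% on G+C%%; r2 is the squared Pearson
    correlation."""
    if len(points) < 3:
        raise ValueError("need at least 3 points")
    xs = [p.x for p in points]
    ys = [p.y for p in points]
    if len(set(xs)) == 1:
        raise ValueError("zero variance in x")
    fit = stats.linregress(xs, ys)
    return RegressionFit(slope=fit.slope, intercept=fit.intercept, r2=fit.rvalue**2)


def _strip_terminal_stop(cds: str, code: GeneticCode) -> str:
    """Drop a terminal complete stop codon so composition is computed on the
    translated portion only (incomplete trailing codons are handled by the
    per-operation trimming)."""
    trimmed = cds[: len(cds) - len(cds) % 3]
    if len(trimmed) >= 6 and code[trimmed[-3:]] == "*":
        return trimmed[:-3]
    return trimmed


def garp_point(
    taxon: str, pcgs: dict[str, str], code: GeneticCode = INVERTEBRATE_MITO
) -> GarpPoint:
    """The (G+C%%, GARP%%) pair for one taxon, both computed on the same
    concatenation of its PCGs (terminal stop codons excluded)."""
    concat = "".join(_strip_terminal_stop(cds, code) for cds in pcgs.values())
    log.debug("%s: terminal stop codons excluded from composition", taxon)
    return GarpPoint(
        taxon=taxon,
        x=gc_by_position(concat).gc_all,
        y=garp_fraction(translate(concat, code)),
    )


def composition_table(genomes: list[Mitogenome]) -> pd.DataFrame:
    """One row per genome: whole-genome base percentages and skews on the
    J-strand, codon-position G+C of the concatenated PCGs, and GARP%%."""
    rows = []
    for g in genomes:
        comp = skews(g.sequence)
        row: dict[str, object] = {
            "id": g.id,
            "organism": g.organism,
            "family": g.family,
            "length": len(g),
            "A%": 100.0 * comp.a / comp.total,
            "T%": 100.0 * comp.t / comp.total,
            "G%": 100.0 * comp.g / comp.total,
            "C%": 100.0 * comp.c / comp.total,
            "AT-skew": comp.at_skew,
            "GC-skew": comp.gc_skew,
        }
        try:
            pcgs = concatenated_pcgs(g)
            concat = "".join(
                _strip_terminal_stop(c, INVERTEBRATE_MITO) for c in pcgs.values()
            )
            gc = gc_by_position(concat)
            row.update(
                gc1=gc.gc1, gc2=gc.gc2, gc3=gc.gc3, gc_all=gc.gc_all,
                **{"GARP%": garp_fraction(translate(concat, INVERTEBRATE_MITO))},
            )
        except ValueError as e:
            log.warning("%s: PCG composition skipped: %s", g.id, e)
        rows.append(row)
    return pd.DataFrame(rows)


def family_averages(table: pd.DataFrame) -> pd.DataFrame:
    """Per-family means and SDs of the numeric composition columns."""
    numeric = table.select_dtypes("number").columns
    grouped = table.groupby("family")[list(numeric)]
    return grouped.agg(["mean", "std"])
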