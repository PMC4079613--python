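"""Synthetic annotated mitogenomes with planted ground truth.

The generator emulates the data regime of AT-rich true-bug mitogenomes in
the ancestral insect gene arrangement: 13 protein-coding genes evolved
from a shared root with a fixed set of conserved amino-acid columns,
per-taxon AGG code states (Ser or Lys) planted only at code-consistent
conserved columns, tRNA scaffolds carrying planted anticodons, and
control regions assembled from clade backgrounds plus exact tandem-repeat
arrays.  Everything is driven by one seeded generator, so a fixed seed
yields byte-identical output, and a machine-readable truth record is
emitted and self-checked at generation time.

The target codon AGG is reserved for explicit planting: background codon
sampling never produces it, so a taxon with zero planted occurrences
truly never uses AGG.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np

from .codes import CODONS, INVERTEBRATE_MITO
from .genome_io import GeneFeature, Mitogenome, write_feature_table
from .noncoding import TandemRepeat, find_tandem_repeats

log = logging.getLogger(__name__)

TARGET_CODON = "AGG"
_STOPS = frozenset(c for c in CODONS if INVERTEBRATE_MITO.table[c] == "*")
_EXCLUDED = _STOPS | {TARGET_CODON}
_SAMPLEABLE = [c for c in CODONS if c not in _EXCLUDED]

#: Synonymous codons per amino acid under the invertebrate mitochondrial
#: code, with the reserved target codon removed.
_SYNONYMS: dict[str, list[str]] = {}
for _c in _SAMPLEABLE:
    _SYNONYMS.setdefault(INVERTEBRATE_MITO.table[_c], []).append(_c)

#: Ancestral insect mitochondrial gene arrangement (J-strand orientation).
ANCESTRAL_ORDER: tuple[tuple[str, str], ...] = (
    ("tRNA-Ile", "+"), ("tRNA-Gln", "-"), ("tRNA-Met", "+"), ("ND2", "+"),
    ("tRNA-Trp", "+"), ("tRNA-Cys", "-"), ("tRNA-Tyr", "-"), ("COI", "+"),
    ("tRNA-Leu(L2)", "+"), ("COII", "+"), ("tRNA-Lys", "+"), ("tRNA-Asp", "+"),
    ("ATP8", "+"), ("ATP6", "+"), ("COIII", "+"), ("tRNA-Gly", "+"),
    ("ND3", "+"), ("tRNA-Ala", "+"), ("tRNA-Arg", "+"), ("tRNA-Asn", "+"),
    ("tRNA-Ser(S1)", "+"), ("tRNA-Glu", "+"), ("tRNA-Phe", "-"), ("ND5", "-"),
    ("tRNA-His", "-"), ("ND4", "-"), ("ND4L", "-"), ("tRNA-Thr", "+"),
    ("tRNA-Pro", "-"), ("ND6", "+"), ("CytB", "+"), ("tRNA-Ser(S2)", "+"),
    ("ND1", "-"), ("tRNA-Leu(L1)", "-"), ("lrRNA", "-"), ("tRNA-Val", "-"),
    ("srRNA", "-"),
)

#: Typical mirid PCG lengths (bp, whole codons, no terminal stop).
DEFAULT_GENE_LENGTHS: dict[str, int] = {
    "ND2": 1020, "COI": 1536, "COII": 684, "ATP8": 156, "ATP6": 672,
    "COIII": 786, "ND3": 354, "ND5": 1716, "ND4": 1338, "ND4L": 294,
    "ND6": 519, "CytB": 1137, "ND1": 933,
}

DEFAULT_RRNA_LENGTHS = {"lrRNA": 1250, "srRNA": 780}

#: Standard anticodons (DNA) for the scaffold tRNAs.
_STANDARD_ANTICODONS_DNA = {
    "tRNA-Ala": "TGC", "tRNA-Arg": "TCG", "tRNA-Asn": "GTT", "tRNA-Asp": "GTC",
    "tRNA-Cys": "GCA", "tRNA-Gln": "TTG", "tRNA-Glu": "TTC", "tRNA-Gly": "TCC",
    "tRNA-His": "GTG", "tRNA-Ile": "GAT", "tRNA-Leu(L1)": "TAG",
    "tRNA-Leu(L2)": "TAA", "tRNA-Lys": "CTT", "tRNA-Met": "CAT",
    "tRNA-Phe": "GAA", "tRNA-Pro": "TGG", "tRNA-Ser(S1)": "GCT",
    "tRNA-Ser(S2)": "TGA", "tRNA-Thr": "TGT", "tRNA-Trp": "TCA",
    "tRNA-Tyr": "GTA", "tRNA-Val": "TAC",
}

# Fixed 66-nt cloverleaf scaffold; only the anticodon (offset 30) varies.
# Arms: 7-bp acceptor stem, 4-bp D stem + 8-nt loop, 5-bp anticodon stem +
# 7-nt loop (anticodon at loop positions 3-5), variable loop, 3-bp T stem +
# 5-nt loop.  The anticodon stem is the only perfect 5-bp stem closing a
# 7-nt loop, so the localization heuristic recovers the planted anticodon.
_SCAFFOLD_5 = "GGAATTT" + "ATCA" + "TATTTAAA" + "TGAT" + "CCATA" + "CT"
_SCAFFOLD_3 = "AA" + "TATGG" + "TATTA" + "GGA" + "TTCAA" + "TCC" + "TAA" + "AAATTCC"
TRNA_ANTICODON_OFFSET = len(_SCAFFOLD_5)  # 30


def trna_scaffold(anticodon_dna: str) -> str:
    if len(anticodon_dna) != 3 or set(anticodon_dna) - set("ACGT"):
        raise ValueError(f"bad anticodon {anticodon_dna!r}")
    return _SCAFFOLD_5 + anticodon_dna + _SCAFFOLD_3


@dataclass(frozen=True)
class CrArraySpec:
    unit_length: int
    full_copies: int
    partial_length: int = 0

    def __post_init__(self) -> None:
        if self.unit_length < 10:
            raise ValueError("unit_length must be >= 10 for recoverable arrays")
        if self.full_copies < 2:
            raise ValueError("full_copies must be >= 2")
        if not 0 <= self.partial_length < self.unit_length:
            raise ValueError("partial_length must be < unit_length")


@dataclass
class SimConfig:
    """Study conditions of the synthetic cohort.

    Defaults mirror a plant-bug-scale comparison: 12 taxa in three clades
    (an AGG=Ser clade with mutated anticodons, an AGG=Lys clade, and a
    clade that never uses AGG), 13 PCGs of realistic lengths, 60% of
    amino-acid columns conserved, AT-rich composition, and control
    regions carrying planted tandem-repeat arrays.
    """

    clades: dict[str, list[str]] = field(
        default_factory=lambda: {
            "cladeA": ["A1", "A2", "A3", "A4"],
            "cladeB": ["B1", "B2", "B3", "B4"],
            "cladeC": ["C1", "C2", "C3", "C4"],
        }
    )
    gene_lengths: dict[str, int] = field(
        default_factory=lambda: dict(DEFAULT_GENE_LENGTHS)
    )
    conserved_fraction: float = 0.6
    at_content: float = 0.72
    clade_at_content: dict[str, float] | None = None
    branch_rate: float = 0.05  # expected substitutions per codon site, tip branch
    code_map: dict[str, str] = field(
        default_factory=lambda: {
            **{t: "Ser" for t in ("A1", "A2", "A3", "A4")},
            **{t: "Lys" for t in ("B1", "B2", "B3", "B4")},
            **{t: "Lys" for t in ("C1", "C2", "C3", "C4")},
        }
    )
    agg_occurrences: int | dict[str, int] = field(
        default_factory=lambda: {
            **{t: 5 for t in ("A1", "A2", "A3", "A4", "B1", "B2", "B3", "B4")},
            **{t: 0 for t in ("C1", "C2", "C3", "C4")},
        }
    )
    anticodon_plan: dict[str, dict[str, str]] | None = None  # RNA notation
    cr_spec: list[CrArraySpec] = field(
        default_factory=lambda: [CrArraySpec(60, 11, 58), CrArraySpec(24, 6, 20)]
    )
    cr_background: int = 300  # total background bp around the arrays
    cr_tip_rate: float = 0.03  # point mutations on CR background, tip branch
    rrna_lengths: dict[str, int] = field(
        default_factory=lambda: dict(DEFAULT_RRNA_LENGTHS)
    )
    dmttf_site: str = "TTATTAA"  # planted 7-bp site between tRNA-Ser(S2) and ND1
    seed: int = 0

    @property
    def taxa(self) -> list[str]:
        return [t for members in self.clades.values() for t in members]

    def clade_of(self, taxon: str) -> str:
        for clade, members in self.clades.items():
            if taxon in members:
                return clade
        raise KeyError(taxon)

    def at_of(self, clade: str) -> float:
        if self.clade_at_content and clade in self.clade_at_content:
            return self.clade_at_content[clade]
        return self.at_content

    def occurrences_of(self, taxon: str) -> int:
        if isinstance(self.agg_occurrences, dict):
            return self.agg_occurrences.get(taxon, 0)
        return self.agg_occurrences

    def resolved_anticodon_plan(self) -> dict[str, dict[str, str]]:
        """Anticodons per taxon; by default the AGG=Ser state carries the
        mutated pair (tRNA-Lys UUU, tRNA-Ser(S1) UCU) and every other taxon
        the typical pair (CUU, GCU), mirroring the correlated states."""
        if self.anticodon_plan is not None:
            return self.anticodon_plan
        plan = {}
        for taxon in self.taxa:
            if self.code_map.get(taxon) == "Ser":
                plan[taxon] = {"tRNA-Lys": "UUU", "tRNA-Ser(S1)": "UCU"}
            else:
                plan[taxon] = {"tRNA-Lys": "CUU", "tRNA-Ser(S1)": "GCU"}
        return plan


def default_config(seed: int = 0) -> SimConfig:
    """The default 12-taxon study conditions, with clade-level AT-content
    spread (0.68/0.72/0.76) so compositional analyses see realistic
    between-clade variation."""
    return SimConfig(
        seed=seed,
        clade_at_content={"cladeA": 0.68, "cladeB": 0.72, "cladeC": 0.76},
    )


@dataclass
class SimTruth:
    """Planted ground truth, consistent with the emitted genomes."""

    code_state: dict[str, str]
    agg_positions: dict[str, list[tuple[str, int]]]  # taxon -> [(gene, codon idx)]
    anticodons: dict[str, dict[str, str]]  # taxon -> trna -> RNA anticodon
    cr_span: dict[str, tuple[int, int]]  # genome coordinates
    cr_repeats: dict[str, list[TandemRepeat]]  # CR-relative coordinates
    cr_background: dict[str, str]  # masked (repeat-free) CR sequence
    gene_coords: dict[str, dict[str, tuple[int, int, str]]]
    conserved_columns: dict[str, list[int]]  # gene -> codon indices

    def expected_assignment(self, taxon: str) -> str:
        """UNUSED for taxa with no planted occurrences, else the planted
        one-letter meaning of AGG."""
        if not self.agg_positions.get(taxon):
            return "UNUSED"
        return {"Ser": "S", "Lys": "K"}[self.code_state[taxon]]


# --- sampling helpers ---------------------------------------------------------


def _base_probs(at: float) -> np.ndarray:
    return np.array([at / 2, (1 - at) / 2, (1 - at) / 2, at / 2])  # A C G T


_BASES = np.array(list("ACGT"))


def _codon_weights(at: float) -> np.ndarray:
    p = _base_probs(at)
    idx = {b: i for i, b in enumerate("ACGT")}
    w = np.array(
        [
            p[idx[c[0]]] * p[idx[c[1]]] * p[idx[c[2]]] if c not in _EXCLUDED else 0.0
            for c in CODONS
        ]
    )
    return w / w.sum()


def _syn_weights(aa: str, at: float) -> tuple[list[str], np.ndarray]:
    codons = _SYNONYMS[aa]
    p = _base_probs(at)
    idx = {b: i for i, b in enumerate("ACGT")}
    w = np.array([p[idx[c[0]]] * p[idx[c[1]]] * p[idx[c[2]]] for c in codons])
    return codons, w / w.sum()


class _Sampler:
    """Seeded sampling of codons and raw bases at a given AT content."""

    def __init__(self, rng: np.random.Generator):
        self.rng = rng
        self._codon_cache: dict[float, tuple[list[str], np.ndarray]] = {}
        self._syn_cache: dict[tuple[str, float], tuple[list[str], np.ndarray]] = {}

    def bases(self, n: int, at: float) -> str:
        return "".join(self.rng.choice(_BASES, size=n, p=_base_probs(at)))

    def codons(self, n: int, at: float) -> list[str]:
        key = round(at, 9)
        if key not in self._codon_cache:
            w = _codon_weights(at)
            self._codon_cache[key] = (list(CODONS), w)
        codons, w = self._codon_cache[key]
        picks = self.rng.choice(len(codons), size=n, p=w)
        return [codons[i] for i in picks]

    def synonymous(self, aa: str, at: float) -> str:
        key = (aa, round(at, 9))
        if key not in self._syn_cache:
            self._syn_cache[key] = _syn_weights(aa, at)
        codons, w = self._syn_cache[key]
        return codons[self.rng.choice(len(codons), p=w)]


# --- simulation ---------------------------------------------------------------


def _evolve_clade(
    root: list[str], conserved: np.ndarray, at: float, sampler: _Sampler
) -> list[str]:
    """Clade ancestor: unconstrained sites are redrawn from the clade's
    equilibrium codon distribution (clade-level compositional divergence);
    conserved sites are redrawn synonymously, preserving the amino acid."""
    out = []
    for j, codon in enumerate(root):
        if conserved[j]:
            out.append(sampler.synonymous(INVERTEBRATE_MITO.table[codon], at))
        else:
            out.append(sampler.codons(1, at)[0])
    return out


def _evolve_tip(
    ancestor: list[str], conserved: np.ndarray, at: float, rate: float,
    sampler: _Sampler,
) -> list[str]:
    """Tip branch: point substitutions at ``rate`` per codon site,
    synonymous-only at conserved sites, unconstrained elsewhere."""
    out = list(ancestor)
    hits = np.flatnonzero(sampler.rng.random(len(ancestor)) < rate)
    for j in hits:
        if conserved[j]:
            out[j] = sampler.synonymous(INVERTEBRATE_MITO.table[ancestor[j]], at)
        else:
            out[j] = sampler.codons(1, at)[0]
    return out


def _sample_repeat_unit(spec: CrArraySpec, at: float, sampler: _Sampler) -> str:
    """A repeat unit with no internal exact period (so the planted period
    is the one recovered)."""
    for _ in range(100):
        unit = sampler.bases(spec.unit_length, at)
        periodic = any(
            spec.unit_length % q == 0 and unit == unit[:q] * (spec.unit_length // q)
            for q in range(1, spec.unit_length // 2 + 1)
        )
        if not periodic:
            return unit
    raise RuntimeError("could not sample an aperiodic repeat unit")


#: Width of the boundary guard zones: background bases flanking each planted
#: array are forced to mismatch their period-distant neighbor, so the
#: finder's score-maximal boundary is exactly the planted one.
_GUARD = 8


def _apply_guards(cr: list[str], repeats: list[TandemRepeat], sampler: _Sampler) -> None:
    n = len(cr)
    for r in repeats:
        p = r.unit_length
        for x in range(max(r.start - _GUARD, 0), r.start):
            if cr[x] == cr[x + p]:
                others = [b for b in "ACGT" if b != cr[x + p]]
                cr[x] = others[sampler.rng.choice(3)]
        for x in range(r.end, min(r.end + _GUARD, n)):
            if cr[x] == cr[x - p]:
                others = [b for b in "ACGT" if b != cr[x - p]]
                cr[x] = others[sampler.rng.choice(3)]


def _build_cr(
    specs: list[CrArraySpec], background: int, at: float, sampler: _Sampler
) -> tuple[str, list[TandemRepeat], str]:
    """Control region = background segments interleaved with exact planted
    arrays, with mismatch guard zones at every array boundary; validated
    (and in the rare failure re-sampled) so the repeat finder recovers
    exactly the planted arrays."""
    n_seg = len(specs) + 1
    for _attempt in range(30):
        seg_len = [background // n_seg] * n_seg
        seg_len[-1] += background - sum(seg_len)
        if any(m < 2 * _GUARD for m in seg_len):
            raise ValueError(
                f"cr_background too small: need >= {2 * _GUARD} bp per segment"
            )
        segments = [sampler.bases(m, at) for m in seg_len]
        parts: list[str] = [segments[0]]
        repeats: list[TandemRepeat] = []
        pos = len(segments[0])
        for k, spec in enumerate(specs):
            unit = _sample_repeat_unit(spec, at, sampler)
            array = unit * spec.full_copies + unit[: spec.partial_length]
            repeats.append(
                TandemRepeat(
                    start=pos, unit_length=spec.unit_length, unit_seq=unit,
                    full_copies=spec.full_copies,
                    partial_length=spec.partial_length, mismatch_rate=0.0,
                )
            )
            parts.append(array)
            pos += len(array)
            parts.append(segments[k + 1])
            pos += len(segments[k + 1])
        cr_list = list("".join(parts))
        _apply_guards(cr_list, repeats, sampler)
        cr = "".join(cr_list)
        if _recovers_exactly(cr, repeats):
            in_repeat = np.zeros(len(cr), dtype=bool)
            for r in repeats:
                in_repeat[r.start : r.end] = True
            background_seq = "".join(
                ch for j, ch in enumerate(cr) if not in_repeat[j]
            )
            return cr, repeats, background_seq
    raise RuntimeError("could not assemble a control region with clean arrays")


def _recovers_exactly(cr: str, planted: list[TandemRepeat]) -> bool:
    found = find_tandem_repeats(cr)
    key = [(r.start, r.unit_length, r.full_copies, r.partial_length) for r in found]
    want = [(r.start, r.unit_length, r.full_copies, r.partial_length) for r in planted]
    return key == want


def _mutate_cr_background(
    cr: str, repeats: list[TandemRepeat], rate: float, at: float, sampler: _Sampler
) -> tuple[str, str]:
    """Point mutations restricted to non-repeat, non-guard positions, so
    planted arrays (and their mismatch guard zones) stay exact while
    intra-clade CR identity drops below 100%."""
    mutable = np.ones(len(cr), dtype=bool)
    in_repeat = np.zeros(len(cr), dtype=bool)
    for r in repeats:
        mutable[max(r.start - _GUARD, 0) : min(r.end + _GUARD, len(cr))] = False
        in_repeat[r.start : r.end] = True
    seq = list(cr)
    for _attempt in range(30):
        mutated = list(seq)
        hits = np.flatnonzero(mutable & (sampler.rng.random(len(cr)) < rate))
        for j in hits:
            choices = [b for b in "ACGT" if b != seq[j]]
            mutated[j] = choices[sampler.rng.choice(3)]
        out = "".join(mutated)
        if _recovers_exactly(out, repeats):
            background = "".join(
                ch for j, ch in enumerate(out) if not in_repeat[j]
            )
            return out, background
    raise RuntimeError("control-region tip mutation broke the planted arrays")


def simulate(config: SimConfig) -> tuple[list[Mitogenome], SimTruth]:
    """Generate one annotated genome per taxon plus the planted truth."""
    rng = np.random.default_rng(config.seed)
    sampler = _Sampler(rng)
    taxa = config.taxa
    if not taxa:
        raise ValueError("no taxa configured")
    genes = list(config.gene_lengths)
    for g, length in config.gene_lengths.items():
        if length % 3:
            raise ValueError(f"{g}: gene length {length} not a codon multiple")

    # Root CDSs and the conserved-column plan (shared across taxa).
    root: dict[str, list[str]] = {}
    conserved: dict[str, np.ndarray] = {}
    for g in genes:
        n_codons = config.gene_lengths[g] // 3
        root[g] = sampler.codons(n_codons, config.at_content)
        mask = np.zeros(n_codons, dtype=bool)
        n_cons = int(round(config.conserved_fraction * n_codons))
        mask[rng.choice(n_codons, size=n_cons, replace=False)] = True
        conserved[g] = mask

    # Code-consistent conserved columns available for AGG planting.
    state_aa = {"Ser": "S", "Lys": "K"}
    state_columns: dict[str, list[tuple[str, int]]] = {"Ser": [], "Lys": []}
    for g in genes:
        for j in np.flatnonzero(conserved[g]):
            aa = INVERTEBRATE_MITO.table[root[g][j]]
            for state, target_aa in state_aa.items():
                if aa == target_aa:
                    state_columns[state].append((g, int(j)))
    need: dict[str, int] = {"Ser": 0, "Lys": 0}
    for taxon in taxa:
        k = config.occurrences_of(taxon)
        if k:
            state = config.code_map.get(taxon)
            if state not in state_aa:
                raise ValueError(f"{taxon}: AGG occurrences but no code state")
            need[state] = max(need[state], k)
    for state, k in need.items():
        if k > len(state_columns[state]):
            raise ValueError(
                f"need {k} conserved {state} columns for AGG planting, "
                f"have {len(state_columns[state])}"
            )

    # Evolve CDSs: root -> clade ancestor -> tip.
    clade_cds: dict[str, dict[str, list[str]]] = {}
    for clade in config.clades:
        at = config.at_of(clade)
        clade_cds[clade] = {
            g: _evolve_clade(root[g], conserved[g], at, sampler) for g in genes
        }
    tip_cds: dict[str, dict[str, list[str]]] = {}
    agg_positions: dict[str, list[tuple[str, int]]] = {}
    for clade, members in config.clades.items():
        at = config.at_of(clade)
        for taxon in members:
            cds = {
                g: _evolve_tip(
                    clade_cds[clade][g], conserved[g], at, config.branch_rate, sampler
                )
                for g in genes
            }
            k = config.occurrences_of(taxon)
            planted: list[tuple[str, int]] = []
            if k:
                state = config.code_map[taxon]
                for g, j in state_columns[state][:k]:
                    cds[g][j] = TARGET_CODON
                    planted.append((g, j))
            tip_cds[taxon] = cds
            agg_positions[taxon] = planted

    # Clade-level control regions.
    plan = config.resolved_anticodon_plan()
    clade_cr: dict[str, tuple[str, list[TandemRepeat]]] = {}
    for clade in config.clades:
        cr, reps, _bg = _build_cr(
            config.cr_spec, config.cr_background, config.at_of(clade), sampler
        )
        clade_cr[clade] = (cr, reps)

    genomes: list[Mitogenome] = []
    truth = SimTruth(
        code_state=dict(config.code_map),
        agg_positions=agg_positions,
        anticodons={},
        cr_span={},
        cr_repeats={},
        cr_background={},
        gene_coords={},
        conserved_columns={
            g: [int(j) for j in np.flatnonzero(conserved[g])] for g in genes
        },
    )
    spacer_after = {
        "tRNA-Glu": ("random", 15),
        "ND6": ("fixed", "T"),
        "tRNA-Ser(S2)": ("fixed", config.dmttf_site),
    }
    from .genome_io import revcomp  # local import to avoid cycle at module load

    for clade, members in config.clades.items():
        at = config.at_of(clade)
        for taxon in members:
            parts: list[str] = []
            feats: list[GeneFeature] = []
            coords: dict[str, tuple[int, int, str]] = {}
            pos = 0
            taxon_anticodons: dict[str, str] = {}
            for name, strand in ANCESTRAL_ORDER:
                if name in DEFAULT_GENE_LENGTHS and name not in config.gene_lengths:
                    continue  # configs with fewer PCGs simply omit the rest
                if name in config.gene_lengths:
                    coding = "".join(tip_cds[taxon][name])
                    kind = "PCG"
                    offset = None
                elif name in config.rrna_lengths:
                    coding = sampler.bases(config.rrna_lengths[name], at)
                    kind = "rRNA"
                    offset = None
                elif name.startswith("tRNA"):
                    ac_rna = plan.get(taxon, {}).get(
                        name, _STANDARD_ANTICODONS_DNA[name].replace("T", "U")
                    )
                    coding = trna_scaffold(ac_rna.replace("U", "T"))
                    taxon_anticodons[name] = ac_rna
                    kind = "tRNA"
                    offset = TRNA_ANTICODON_OFFSET
                else:  # pragma: no cover - order only holds known names
                    raise AssertionError(name)
                genomic = revcomp(coding) if strand == "-" else coding
                feats.append(
                    GeneFeature(
                        name=name, kind=kind, start=pos, end=pos + len(genomic),
                        strand=strand, anticodon_offset=offset,
                    )
                )
                coords[name] = (pos, pos + len(genomic), strand)
                parts.append(genomic)
                pos += len(genomic)
                if name in spacer_after:
                    mode, val = spacer_after[name]
                    spacer = sampler.bases(val, at) if mode == "random" else val
                    parts.append(spacer)
                    pos += len(spacer)
            # control region last: between srRNA and the wrap to tRNA-Ile
            cr, reps = clade_cr[clade]
            cr, background = _mutate_cr_background(
                cr, reps, config.cr_tip_rate, at, sampler
            )
            feats.append(
                GeneFeature(
                    name="control_region", kind="control_region",
                    start=pos, end=pos + len(cr), strand="+",
                )
            )
            truth.cr_span[taxon] = (pos, pos + len(cr))
            truth.cr_repeats[taxon] = list(reps)
            truth.cr_background[taxon] = background
            parts.append(cr)
            genome = Mitogenome(
                id=taxon, sequence="".join(parts), features=feats,
                organism=f"{clade} {taxon}", genus=clade, family="synthetic",
                circular=True, complete=True,
            )
            truth.anticodons[taxon] = taxon_anticodons
            truth.gene_coords[taxon] = coords
            _self_check(genome, truth, taxon)
            genomes.append(genome)
    return genomes, truth


def _self_check(genome: Mitogenome, truth: SimTruth, taxon: str) -> None:
    """Generation-time consistency: planted AGG counts and anticodons are
    recoverable from the emitted genome."""
    from .genome_io import gene_sequence

    for gene, j in truth.agg_positions[taxon]:
        cds = gene_sequence(genome, gene)
        if cds[3 * j : 3 * j + 3] != TARGET_CODON:
            raise AssertionError(f"{taxon}/{gene}: planted AGG missing at codon {j}")
    for trna, ac in truth.anticodons[taxon].items():
        seq = gene_sequence(genome, trna)
        off = genome.feature(trna).anticodon_offset
        if seq[off : off + 3].replace("T", "U") != ac:
            raise AssertionError(f"{taxon}/{trna}: planted anticodon mismatch")


def write_fixture_set(
    genomes: list[Mitogenome], truth: SimTruth, outdir
) -> list[str]:
    """FASTA + feature-table TSV per genome, plus truth.tsv and
    conserved_columns.tsv; round-trippable through genome_io."""
    from pathlib import Path

    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    written: list[str] = []
    for g in genomes:
        fasta = outdir / f"{g.id}.fasta"
        table = outdir / f"{g.id}.features.tsv"
        write_feature_table(g, fasta, table)
        written += [str(fasta), str(table)]
    truth_path = outdir / "truth.tsv"
    with open(truth_path, "w") as fh:
        fh.write(
            "taxon\tcode_state\tagg_occurrences\tanticodon_tRNA-Lys\t"
            "anticodon_tRNA-Ser(S1)\tcr_start\tcr_end\tcr_repeats\n"
        )
        for g in genomes:
            t = g.id
            reps = ";".join(
                f"{r.start}:{r.unit_length}:{r.full_copies}:{r.partial_length}"
                for r in truth.cr_repeats[t]
            )
            fh.write(
                "\t".join(
                    [
                        t,
                        truth.code_state.get(t, ""),
                        str(len(truth.agg_positions.get(t, []))),
                        truth.anticodons[t].get("tRNA-Lys", ""),
                        truth.anticodons[t].get("tRNA-Ser(S1)", ""),
                        str(truth.cr_span[t][0]),
                        str(truth.cr_span[t][1]),
                        reps,
                    ]
                )
                + "\n"
            )
    written.append(str(truth_path))
    cols_path = outdir / "conserved_columns.tsv"
    with open(cols_path, "w") as fh:
        fh.write("gene\tcodon_indices\n")
        for gene, cols in truth.conserved_columns.items():
            fh.write(f"{gene}\t{','.join(map(str, cols))}\n")
    written.append(str(cols_path))
    return written
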