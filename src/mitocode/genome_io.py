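"""Reading, normalizing and slicing annotated mitochondrial genomes.

Coordinates are 0-based half-open internally and 1-based inclusive at all
file boundaries (the GenBank convention).  The stored ``+`` strand is the
J-strand — the majority coding strand of the insect mitogenome — and all
strand-sensitive statistics downstream are computed on it.  Origin-spanning
features on a circular genome are stored unwrapped: ``start < length <=
end``, interpreted modulo the genome length.
"""

from __future__ import annotations

import logging
import re
from dataclasses import dataclass, field
from pathlib import Path

from Bio import SeqIO
from Bio.Seq import Seq

log = logging.getLogger(__name__)


class ParseError(ValueError):
    """Raised for malformed input records."""


# --- canonical 37-gene vocabulary -------------------------------------------

#: The 13 protein-coding genes in their order of appearance in the ancestral
#: insect gene arrangement; this is also the fixed concatenation order.
PCG_ORDER: tuple[str, ...] = (
    "ND2", "COI", "COII", "ATP8", "ATP6", "COIII", "ND3",
    "ND5", "ND4", "ND4L", "ND6", "CytB", "ND1",
)

#: Duplicated Leu/Ser tRNAs carry L1/L2/S1/S2 suffixes:
#: L1 reads CUN, L2 reads UUR, S1 reads AGN, S2 reads UCN.
TRNA_NAMES: tuple[str, ...] = (
    "tRNA-Ile", "tRNA-Gln", "tRNA-Met", "tRNA-Trp", "tRNA-Cys", "tRNA-Tyr",
    "tRNA-Leu(L2)", "tRNA-Lys", "tRNA-Asp", "tRNA-Gly", "tRNA-Ala",
    "tRNA-Arg", "tRNA-Asn", "tRNA-Ser(S1)", "tRNA-Glu", "tRNA-Phe",
    "tRNA-His", "tRNA-Thr", "tRNA-Pro", "tRNA-Ser(S2)", "tRNA-Leu(L1)",
    "tRNA-Val",
)

RRNA_NAMES: tuple[str, ...] = ("lrRNA", "srRNA")
CONTROL_REGION = "control_region"
CANONICAL_NAMES: frozenset[str] = frozenset(
    PCG_ORDER + TRNA_NAMES + RRNA_NAMES + (CONTROL_REGION,)
)

_AA3_TO_TRNA = {
    "ala": "tRNA-Ala", "arg": "tRNA-Arg", "asn": "tRNA-Asn", "asp": "tRNA-Asp",
    "cys": "tRNA-Cys", "gln": "tRNA-Gln", "glu": "tRNA-Glu", "gly": "tRNA-Gly",
    "his": "tRNA-His", "ile": "tRNA-Ile", "lys": "tRNA-Lys", "met": "tRNA-Met",
    "phe": "tRNA-Phe", "pro": "tRNA-Pro", "thr": "tRNA-Thr", "trp": "tRNA-Trp",
    "tyr": "tRNA-Tyr", "val": "tRNA-Val",
}
_AA1_TO_TRNA = {
    "a": "tRNA-Ala", "r": "tRNA-Arg", "n": "tRNA-Asn", "d": "tRNA-Asp",
    "c": "tRNA-Cys", "q": "tRNA-Gln", "e": "tRNA-Glu", "g": "tRNA-Gly",
    "h": "tRNA-His", "i": "tRNA-Ile", "k": "tRNA-Lys", "m": "tRNA-Met",
    "f": "tRNA-Phe", "p": "tRNA-Pro", "t": "tRNA-Thr", "w": "tRNA-Trp",
    "y": "tRNA-Tyr", "v": "tRNA-Val",
}

_PCG_SYNONYMS = {
    "nd1": "ND1", "nad1": "ND1", "nadh1": "ND1",
    "nd2": "ND2", "nad2": "ND2", "nadh2": "ND2",
    "nd3": "ND3", "nad3": "ND3", "nadh3": "ND3",
    "nd4": "ND4", "nad4": "ND4", "nadh4": "ND4",
    "nd4l": "ND4L", "nad4l": "ND4L", "nadh4l": "ND4L",
    "nd5": "ND5", "nad5": "ND5", "nadh5": "ND5",
    "nd6": "ND6", "nad6": "ND6", "nadh6": "ND6",
    "cox1": "COI", "coxi": "COI", "co1": "COI", "coi": "COI",
    "cox2": "COII", "coxii": "COII", "co2": "COII", "coii": "COII",
    "cox3": "COIII", "coxiii": "COIII", "co3": "COIII", "coiii": "COIII",
    "cytb": "CytB", "cob": "CytB", "cyb": "CytB",
    "atp6": "ATP6", "atpase6": "ATP6", "atp8": "ATP8", "atpase8": "ATP8",
}
_RRNA_SYNONYMS = {
    "rrnl": "lrRNA", "lrrna": "lrRNA", "16s": "lrRNA", "16srrna": "lrRNA",
    "lsu": "lrRNA", "largesubunitribosomalrna": "lrRNA", "16sribosomalrna": "lrRNA",
    "rrns": "srRNA", "srrna": "srRNA", "12s": "srRNA", "12srrna": "srRNA",
    "ssu": "srRNA", "smallsubunitribosomalrna": "srRNA", "12sribosomalrna": "srRNA",
}
_CR_SYNONYMS = {
    "dloop", "controlregion", "crregion", "cr", "atrichregion", "putativecontrolregion",
    "control_region",
}

_PCG_PRODUCTS = {
    "cytochromecoxidasesubunit1": "COI", "cytochromecoxidasesubuniti": "COI",
    "cytochromecoxidasesubunit2": "COII", "cytochromecoxidasesubunitii": "COII",
    "cytochromecoxidasesubunit3": "COIII", "cytochromecoxidasesubunitiii": "COIII",
    "cytochromeoxidasesubunit1": "COI", "cytochromeoxidasesubunit2": "COII",
    "cytochromeoxidasesubunit3": "COIII",
    "cytochromeb": "CytB", "cytochromebapoenzyme": "CytB",
    "atpsynthasef0subunit6": "ATP6", "atpsynthasef0subunit8": "ATP8",
    "atpsynthasesubunit6": "ATP6", "atpsynthasesubunit8": "ATP8",
}
for _i, _roman in enumerate(("1", "2", "3", "4", "4l", "5", "6")):
    _name = "ND" + _roman.upper()
    _PCG_PRODUCTS[f"nadhdehydrogenasesubunit{_roman}"] = _name

# L1/L2/S1/S2 disambiguation: recognized codon-family or anticodon tags.
_LEU_SER_TAGS = {
    "l1": "tRNA-Leu(L1)", "cun": "tRNA-Leu(L1)", "tag": "tRNA-Leu(L1)", "uag": "tRNA-Leu(L1)",
    "l2": "tRNA-Leu(L2)", "uur": "tRNA-Leu(L2)", "taa": "tRNA-Leu(L2)", "uaa": "tRNA-Leu(L2)",
    "s1": "tRNA-Ser(S1)", "agn": "tRNA-Ser(S1)", "gct": "tRNA-Ser(S1)",
    "gcu": "tRNA-Ser(S1)", "agy": "tRNA-Ser(S1)", "ucu": "tRNA-Ser(S1)",
    "s2": "tRNA-Ser(S2)", "ucn": "tRNA-Ser(S2)", "tga": "tRNA-Ser(S2)", "uga": "tRNA-Ser(S2)",
}


def _squash(name: str) -> str:
    return re.sub(r"[^a-z0-9]", "", name.lower())


def normalize_gene_name(raw: str) -> str | None:
    """Map a GenBank-dialect gene name onto the canonical vocabulary.

    Returns None when the name is unrecognizable; callers keep such
    features with kind ``misc_noncoding`` and exclude them from the PCG
    and tRNA analyses.
    """
    if not raw:
        return None
    if raw in CANONICAL_NAMES:
        return raw
    squashed = _squash(raw)
    for table in (_PCG_SYNONYMS, _RRNA_SYNONYMS, _PCG_PRODUCTS):
        if squashed in table:
            return table[squashed]
    if squashed in _CR_SYNONYMS:
        return CONTROL_REGION
    # tRNA dialects: trnK, trnL-UUR, trna-lys, tRNA-Ser(AGN), trnL2(taa) ...
    m = re.match(r"(?:trna?|transferrna)(.*)$", squashed)
    if m:
        rest = m.group(1)
        tags = [t for t in _LEU_SER_TAGS if t in rest]
        aa3 = next((a for a in _AA3_TO_TRNA if rest.startswith(a)), None)
        if aa3 == "leu" or rest[:1] == "l":
            for t in tags:
                if _LEU_SER_TAGS[t].startswith("tRNA-Leu"):
                    return _LEU_SER_TAGS[t]
            return None  # ambiguous duplicated tRNA
        if aa3 == "ser" or rest[:1] == "s":
            for t in tags:
                if _LEU_SER_TAGS[t].startswith("tRNA-Ser"):
                    return _LEU_SER_TAGS[t]
            return None
        if aa3:
            return _AA3_TO_TRNA[aa3]
        if rest[:1] in _AA1_TO_TRNA:
            return _AA1_TO_TRNA[rest[:1]]
    return None


# --- domain types ------------------------------------------------------------

KINDS = ("PCG", "tRNA", "rRNA", "control_region", "misc_noncoding")


@dataclass
class GeneFeature:
    """One annotated feature; origin-spanning features are unwrapped (end may
    exceed the genome length and is read modulo it)."""

    name: str
    kind: str
    start: int  # 0-based inclusive
    end: int  # 0-based exclusive
    strand: str = "+"  # '+' is the J-strand
    anticodon_offset: int | None = None  # 0-based, within the coding-strand tRNA

    def __post_init__(self) -> None:
        if self.kind not in KINDS:
            raise ValueError(f"unknown feature kind {self.kind!r}")
        if self.strand not in "+-":
            raise ValueError(f"strand must be + or -, got {self.strand!r}")
        if self.start >= self.end:
            raise ValueError(f"{self.name}: empty span [{self.start},{self.end})")
        if self.anticodon_offset is not None and self.kind != "tRNA":
            raise ValueError(f"{self.name}: anticodon_offset on non-tRNA feature")

    @property
    def length(self) -> int:
        return self.end - self.start


@dataclass
class Mitogenome:
    """A circular annotated mitochondrial genome."""

    id: str
    sequence: str
    features: list[GeneFeature] = field(default_factory=list)
    organism: str = ""
    genus: str = ""
    family: str = ""
    circular: bool = True
    complete: bool = True

    def __post_init__(self) -> None:
        self.sequence = self.sequence.upper()
        if not self.sequence:
            raise ValueError(f"{self.id}: empty sequence")
        bad = set(self.sequence) - set("ACGTN")
        if bad:
            raise ValueError(f"{self.id}: non-ACGTN characters {sorted(bad)}")
        n = len(self.sequence)
        for f in self.features:
            if f.end > n and not (self.circular and f.start < n):
                raise ValueError(
                    f"{self.id}:{f.name}: span [{f.start},{f.end}) outside "
                    f"linear genome of length {n}"
                )

    def __len__(self) -> int:
        return len(self.sequence)

    def feature(self, name: str) -> GeneFeature:
        for f in self.features:
            if f.name == name:
                return f
        raise KeyError(f"{self.id}: no feature named {name!r}")

    def has_feature(self, name: str) -> bool:
        return any(f.name == name for f in self.features)

    def slice(self, start: int, end: int) -> str:
        """Forward-strand sequence of [start, end), circularly if end > length."""
        n = len(self.sequence)
        if end <= n:
            return self.sequence[start:end]
        if not self.circular:
            raise ValueError(f"{self.id}: span [{start},{end}) beyond linear end")
        return self.sequence[start:] + self.sequence[: end - n]


def revcomp(seq: str) -> str:
    return str(Seq(seq).reverse_complement())


# --- operations ---------------------------------------------------------------


def gene_sequence(genome: Mitogenome, name: str) -> str:
    """Coding-strand sequence of a named feature (revcomp for '-' strand,
    concatenated across the origin for origin-spanning features)."""
    f = genome.feature(name)
    s = genome.slice(f.start, f.end)
    return revcomp(s) if f.strand == "-" else s


def concatenated_pcgs(genome: Mitogenome) -> dict[str, str]:
    """The 13 protein-coding genes, each on its coding strand, in the fixed
    canonical order; absent genes are omitted with a warning."""
    out: dict[str, str] = {}
    for name in PCG_ORDER:
        if genome.has_feature(name):
            out[name] = gene_sequence(genome, name)
        else:
            log.warning("%s: PCG %s not annotated, omitted", genome.id, name)
    if not out:
        raise ValueError(f"{genome.id}: no annotated PCGs")
    return out


# --- GenBank ------------------------------------------------------------------

_KIND_BY_GB_TYPE = {"CDS": "PCG", "tRNA": "tRNA", "rRNA": "rRNA", "D-loop": "control_region"}


def _genbank_location(feat, genome_length: int) -> tuple[int, int, str]:
    parts = sorted(feat.location.parts, key=lambda p: int(p.start))
    strand = "-" if feat.location.strand == -1 else "+"
    if len(parts) == 1:
        return int(parts[0].start), int(parts[0].end), strand
    # join across the origin: [x..L] + [0..y] -> unwrapped [x, L+y)
    first, last = parts[-1], parts[0]
    if int(first.end) == genome_length and int(last.start) == 0:
        return int(first.start), genome_length + int(last.end), strand
    # other compound locations: take the envelope
    return int(parts[0].start), int(parts[-1].end), strand


def _anticodon_offset_from_qualifiers(feat, start: int, strand: str, n: int) -> int | None:
    ac = feat.qualifiers.get("anticodon", [None])[0]
    if not ac:
        return None
    m = re.search(r"pos:(?:complement\()?(\d+)\.\.(\d+)", ac)
    if not m:
        return None
    lo, hi = int(m.group(1)) - 1, int(m.group(2))  # to 0-based half-open
    if strand == "+":
        return lo - start
    end = start + (int(feat.location.end) - int(feat.location.start))
    return end - hi


def parse_genbank(path: str | Path) -> Mitogenome:
    """Read a GenBank flat file into a normalized :class:`Mitogenome`."""
    path = Path(path)
    try:
        record = SeqIO.read(str(path), "genbank")
    except ValueError as e:
        raise ParseError(f"{path}: malformed GenBank record: {e}") from e
    seq = str(record.seq).upper()
    n = len(seq)
    organism = record.annotations.get("organism", "")
    taxonomy = record.annotations.get("taxonomy", [])
    family = next((t for t in taxonomy if t.endswith("idae")), "")
    genus = organism.split()[0] if organism else ""
    circular = record.annotations.get("topology", "circular") == "circular"
    complete = "complete" in (record.description or "").lower()

    features: list[GeneFeature] = []
    seen: set[tuple[str, int]] = set()
    for feat in record.features:
        if feat.type not in _KIND_BY_GB_TYPE and feat.type != "misc_feature":
            continue
        raw = (
            feat.qualifiers.get("gene", [None])[0]
            or feat.qualifiers.get("product", [None])[0]
            or feat.qualifiers.get("note", [""])[0]
        )
        start, end, strand = _genbank_location(feat, n)
        name = normalize_gene_name(raw or "")
        if feat.type == "misc_feature":
            kind = "control_region" if name == CONTROL_REGION else "misc_noncoding"
            name = name or (raw or "misc")
        elif name is None:
            log.warning("%s: unmappable gene name %r; kept as misc_noncoding", path, raw)
            name, kind = raw or "unknown", "misc_noncoding"
        else:
            kind = _KIND_BY_GB_TYPE[feat.type]
            if name == CONTROL_REGION:
                kind = "control_region"
        if (name, start) in seen:
            continue
        seen.add((name, start))
        offset = None
        if kind == "tRNA":
            offset = _anticodon_offset_from_qualifiers(feat, start, strand, n)
        features.append(
            GeneFeature(name=name, kind=kind, start=start, end=end,
                        strand=strand, anticodon_offset=offset)
        )
    return Mitogenome(
        id=record.id or path.stem, sequence=seq, features=features,
        organism=organism, genus=genus, family=family,
        circular=circular, complete=complete,
    )


# --- FASTA + feature table ----------------------------------------------------

TABLE_HEADER = ["name", "kind", "start", "end", "strand", "anticodon_offset"]


def parse_feature_table(fasta: str | Path, table: str | Path, **meta) -> Mitogenome:
    """Read a FASTA sequence plus a TSV feature table (1-based inclusive
    coordinates) into a :class:`Mitogenome`."""
    fasta, table = Path(fasta), Path(table)
    try:
        record = SeqIO.read(str(fasta), "fasta")
    except ValueError as e:
        raise ParseError(f"{fasta}: malformed FASTA: {e}") from e
    seq = str(record.seq).upper()
    n = len(seq)
    circular = meta.pop("circular", True)

    features: list[GeneFeature] = []
    names_seen: dict[str, list[tuple[int, int]]] = {}
    with open(table) as fh:
        lines = [ln.rstrip("\n") for ln in fh if ln.strip()]
    if lines and lines[0].split("\t")[0] == "name":
        lines = lines[1:]
    for i, line in enumerate(lines, start=2):
        cols = line.split("\t")
        if len(cols) < 5:
            raise ParseError(f"{table}:{i}: expected >=5 tab-separated columns")
        name, kind, start1, end1, strand = cols[:5]
        try:
            start, end = int(start1) - 1, int(end1)
        except ValueError as e:
            raise ParseError(f"{table}:{i}: bad coordinates: {e}") from e
        if end > n and not circular:
            raise ParseError(
                f"{table}:{i}: {name} end {end} beyond linear genome length {n}"
            )
        offset = None
        if len(cols) >= 6 and cols[5] not in ("", "."):
            offset = int(cols[5]) - 1  # file is 1-based
        for (s0, e0) in names_seen.get(name, []):
            if s0 < end and start < e0:
                raise ParseError(f"{table}:{i}: overlapping duplicate feature {name!r}")
        names_seen.setdefault(name, []).append((start, end))
        features.append(
            GeneFeature(name=name, kind=kind, start=start, end=end,
                        strand=strand, anticodon_offset=offset)
        )
    return Mitogenome(
        id=meta.pop("id", record.id or fasta.stem), sequence=seq,
        features=features, circular=circular, **meta,
    )


def write_feature_table(genome: Mitogenome, fasta: str | Path, table: str | Path) -> None:
    """Write the FASTA + TSV pair read back by :func:`parse_feature_table`."""
    with open(fasta, "w") as fh:
        fh.write(f">{genome.id} {genome.organism}\n")
        for i in range(0, len(genome.sequence), 70):
            fh.write(genome.sequence[i : i + 70] + "\n")
    with open(table, "w") as fh:
        fh.write("\t".join(TABLE_HEADER) + "\n")
        for f in genome.features:
            offset = "." if f.anticodon_offset is None else str(f.anticodon_offset + 1)
            fh.write(
                f"{f.name}\t{f.kind}\t{f.start + 1}\t{f.end}\t{f.strand}\t{offset}\n"
            )


def load_genome(path: str | Path) -> Mitogenome:
    """Dispatch on extension: .gb/.gbk/.genbank, or .fasta/.fa with a sibling
    ``<stem>.features.tsv``."""
    path = Path(path)
    if path.suffix.lower() in (".gb", ".gbk", ".genbank"):
        return parse_genbank(path)
    candidates = [
        path.parent / (path.stem + ".features.tsv"),
        path.with_suffix(".features.tsv"),
    ]
    for cand in candidates:
        if cand.exists():
            return parse_feature_table(path, cand)
    raise ParseError(f"{path}: no feature table found next to FASTA")
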