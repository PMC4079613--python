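"""Non-coding region census and control-region architecture.

The control region (CR) of insect mitogenomes — the major non-coding
region between srRNA and tRNA-Ile — varies wildly in length and is often
dominated by tandem repeat arrays.  This module censuses every
inter-feature gap on the circular genome, locates the CR, searches for
DmTTF-like transcription-termination sites, annotates maximal tandem
repeat arrays by a seed-and-extend scan, and computes repeat-masked
pairwise identity between CRs.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass, field

import numpy as np
from Bio import Align

from .genome_io import Mitogenome

log = logging.getLogger(__name__)


@dataclass(frozen=True)
class NoncodingRegion:
    genome_id: str
    left: str | None  # adjacent upstream feature (None only for a featureless genome)
    right: str | None
    start: int  # genome coordinates, 0-based half-open; end may exceed the
    end: int  # genome length for the origin-wrapping gap
    seq: str

    @property
    def length(self) -> int:
        return self.end - self.start


@dataclass(frozen=True)
class FeatureOverlap:
    genome_id: str
    left: str
    right: str
    bases: int  # positive number of shared bases


def _scan_gaps(
    genome: Mitogenome,
) -> tuple[list[NoncodingRegion], list[FeatureOverlap]]:
    n = len(genome)
    feats = sorted(genome.features, key=lambda f: (f.start, f.end))
    if not feats:
        region = NoncodingRegion(
            genome_id=genome.id, left=None, right=None, start=0, end=n,
            seq=genome.sequence,
        )
        return [region], []
    ncrs: list[NoncodingRegion] = []
    overlaps: list[FeatureOverlap] = []

    def emit(frontier: int, frontier_name: str, nxt_start: int, nxt_name: str) -> None:
        gap = nxt_start - frontier
        if gap > 0:
            ncrs.append(
                NoncodingRegion(
                    genome_id=genome.id, left=frontier_name, right=nxt_name,
                    start=frontier % n, end=(frontier % n) + gap,
                    seq=genome.slice(frontier % n, (frontier % n) + gap),
                )
            )
        elif gap < 0:
            overlaps.append(
                FeatureOverlap(
                    genome_id=genome.id, left=frontier_name, right=nxt_name,
                    bases=-gap,
                )
            )
            log.info(
                "%s: %s overlaps %s by %d bp (negative gap, not an NCR)",
                genome.id, frontier_name, nxt_name, -gap,
            )

    frontier, frontier_name = feats[0].end, feats[0].name
    for f in feats[1:]:
        emit(frontier, frontier_name, f.start, f.name)
        if f.end > frontier:
            frontier, frontier_name = f.end, f.name
    if genome.circular:
        emit(frontier, frontier_name, feats[0].start + n, feats[0].name)
    elif frontier < n:
        ncrs.append(
            NoncodingRegion(
                genome_id=genome.id, left=frontier_name, right=None,
                start=frontier, end=n, seq=genome.sequence[frontier:],
            )
        )
    return ncrs, overlaps


def noncoding_census(genome: Mitogenome) -> list[NoncodingRegion]:
    """Every inter-feature gap of >=1 bp on the circular genome; feature
    overlaps are logged, never reported as NCRs."""
    ncrs, _ = _scan_gaps(genome)
    return ncrs


def feature_overlaps(genome: Mitogenome) -> list[FeatureOverlap]:
    """The negative gaps (overlapping annotations) found by the census scan."""
    _, overlaps = _scan_gaps(genome)
    return overlaps


def noncoding_proportion(genome: Mitogenome) -> float:
    """Percentage of the genome that is non-coding: inter-feature gaps plus
    any annotated control-region or miscellaneous non-coding features."""
    total = sum(r.length for r in noncoding_census(genome))
    total += sum(
        f.length for f in genome.features
        if f.kind in ("control_region", "misc_noncoding")
    )
    return 100.0 * total / len(genome)


def locate_control_region(genome: Mitogenome) -> NoncodingRegion:
    """The control region: an explicitly annotated control_region feature,
    else the circular gap running from srRNA to tRNA-Ile."""
    for f in genome.features:
        if f.kind == "control_region":
            return NoncodingRegion(
                genome_id=genome.id, left="srRNA", right="tRNA-Ile",
                start=f.start, end=f.end, seq=genome.slice(f.start, f.end),
            )
    if not (genome.has_feature("srRNA") and genome.has_feature("tRNA-Ile")):
        raise ValueError(
            f"{genome.id}: no explicit control region and srRNA/tRNA-Ile flanks missing"
        )
    n = len(genome)
    start = genome.feature("srRNA").end % n
    end = genome.feature("tRNA-Ile").start % n
    length = (end - start) % n
    if length == 0:
        raise ValueError(f"{genome.id}: srRNA and tRNA-Ile are adjacent; no control region")
    return NoncodingRegion(
        genome_id=genome.id, left="srRNA", right="tRNA-Ile",
        start=start, end=start + length, seq=genome.slice(start, start + length),
    )


# --- DmTTF binding-site search ------------------------------------------------


@dataclass(frozen=True)
class DmttfHit:
    region: NoncodingRegion
    offset: int | None  # start of the aligned window within the region
    identity: float  # percentage over the aligned window
    window_length: int  # region-side span of the aligned window
    score: float = 0.0

    @property
    def found(self) -> bool:
        return self.offset is not None


def _nt_aligner(mode: str) -> Align.PairwiseAligner:
    aligner = Align.PairwiseAligner()
    aligner.mode = mode
    aligner.match_score = 1.0
    aligner.mismatch_score = -1.0
    aligner.open_gap_score = -2.0
    aligner.extend_gap_score = -1.0
    return aligner


def _alignment_identity(aln) -> tuple[int, int]:
    """(matches, columns) of a Bio.Align alignment, gap columns included."""
    a, b = str(aln[0]), str(aln[1])
    matches = sum(x == y and x != "-" for x, y in zip(a, b))
    return matches, len(a)


def dmttf_search(region: NoncodingRegion, reference: str) -> DmttfHit:
    """Best local alignment of a reference termination-site sequence (e.g.
    the 16-bp D. melanogaster DmTTF site) against a non-coding region."""
    if len(reference) < 5:
        raise ValueError("reference shorter than 5 bp")
    if region.length < 5:
        return DmttfHit(region=region, offset=None, identity=0.0, window_length=0)
    aligner = _nt_aligner("local")
    alns = aligner.align(region.seq.upper(), reference.upper().replace("U", "T"))
    best = alns[0]
    matches, columns = _alignment_identity(best)
    target_blocks = best.aligned[0]
    offset = int(target_blocks[0][0])
    window = int(target_blocks[-1][1]) - offset
    return DmttfHit(
        region=region, offset=offset,
        identity=100.0 * matches / columns if columns else 0.0,
        window_length=window, score=float(best.score),
    )


# --- tandem repeats -----------------------------------------------------------


@dataclass(frozen=True)
class TandemRepeat:
    start: int  # within the searched sequence
    unit_length: int
    unit_seq: str
    full_copies: int
    partial_length: int
    mismatch_rate: float
    n_mismatches: int = 0

    @property
    def span(self) -> int:
        return self.unit_length * self.full_copies + self.partial_length

    @property
    def end(self) -> int:
        return self.start + self.span

    @property
    def compared(self) -> int:
        """Positions compared against the preceding copy (span minus the
        first, uncompared unit)."""
        return self.unit_length * (self.full_copies - 1) + self.partial_length

    @property
    def match_score(self) -> int:
        """compared - 2 x mismatches: the greedy selection criterion.  For
        a fixed repetitive region this is maximized by the primitive
        (smallest explaining) period, so composite-period candidates that
        absorb flanking noise inside their larger mismatch budget lose to
        the true array."""
        return self.compared - 2 * self.n_mismatches


def _arrays_at_period(
    seq: str, p: int, min_copies: int, max_mismatch: float
) -> list[TandemRepeat]:
    """Maximal arrays of period ``p``: each full copy matches the previous
    copy within floor(max_mismatch * p) mismatches, the trailing partial
    within floor(max_mismatch * t)."""
    n = len(seq)
    if 2 * p > n:
        return []
    a = np.frombuffer(seq.encode(), dtype="S1")
    eq = a[: n - p] == a[p:]
    zeros = np.concatenate(([0], np.cumsum(~eq)))

    def block_mismatches(lo: int, hi: int) -> int:
        return int(zeros[hi] - zeros[lo])

    budget = math.floor(max_mismatch * p)

    def max_excess_prefix(lo: int, hi: int) -> int:
        """Longest prefix length of compared interval [lo, hi) maximizing
        2*mismatches - length; 0 when no prefix is mismatch-dominated.
        Trimming that prefix is the score-maximal edge refinement."""
        best_len, best_ex = 0, 0
        for x in range(lo + 1, hi + 1):
            ex = 2 * block_mismatches(lo, x) - (x - lo)
            if ex >= best_ex and ex > 0:
                best_len, best_ex = x - lo, ex
        return best_len

    def max_excess_suffix(lo: int, hi: int) -> int:
        best_len, best_ex = 0, 0
        for x in range(hi - 1, lo - 1, -1):
            ex = 2 * block_mismatches(x, hi) - (hi - x)
            if ex >= best_ex and ex > 0:
                best_len, best_ex = hi - x, ex
        return best_len

    out: list[TandemRepeat] = []
    i = 0
    while i + 2 * p <= n:
        c = 1
        while i + (c + 1) * p <= n:
            if block_mismatches(i + (c - 1) * p, i + c * p) > budget:
                break
            c += 1
        if c < min_copies:
            i += 1
            continue
        t_max = min(p - 1, n - i - c * p)
        t = 0
        for cand in range(t_max, -1, -1):
            if block_mismatches(
                i + (c - 1) * p, i + (c - 1) * p + cand
            ) <= math.floor(max_mismatch * cand):
                t = cand
                break
        span = c * p + t
        # Edge refinement: the budget lets an array absorb junk flanks (any
        # start within `budget` bases of the true boundary passes), so trim
        # mismatch-dominated edges of the compared interval [i, i+span-p).
        a = max_excess_prefix(i, i + span - p)
        b = max_excess_suffix(i + a, i + span - p)
        s2, e2 = i + a, i + span - b
        c2, t2 = (e2 - s2) // p, (e2 - s2) % p
        if c2 >= min_copies:
            mism = block_mismatches(s2, e2 - p)
            compared = p * (c2 - 1) + t2
            out.append(
                TandemRepeat(
                    start=s2, unit_length=p, unit_seq=seq[s2 : s2 + p],
                    full_copies=c2, partial_length=t2,
                    mismatch_rate=mism / compared if compared else 0.0,
                    n_mismatches=mism,
                )
            )
        i += span if span > 0 else 1
    return out


def find_tandem_repeats(
    seq: str,
    min_unit: int = 10,
    max_unit: int = 300,
    min_copies: int = 2,
    max_mismatch: float = 0.1,
) -> list[TandemRepeat]:
    """Maximal non-overlapping tandem repeat arrays.

    Candidate arrays are detected at every period in [min_unit, max_unit]
    by self-match seeding and left/right extension while the per-unit
    mismatch fraction stays within ``max_mismatch``; overlaps between
    periods are resolved greedily by descending match score (compared
    positions minus twice the mismatches, which prefers the primitive
    period over its multiples), then ascending unit length, then start.
    The trailing partial copy is reported separately.
    """
    if min_unit < 2:
        raise ValueError("min_unit must be >= 2")
    if min_copies < 2:
        raise ValueError("min_copies must be >= 2")
    seq = seq.upper()
    candidates: list[TandemRepeat] = []
    for p in range(min_unit, min(max_unit, len(seq) // 2) + 1):
        candidates.extend(_arrays_at_period(seq, p, min_copies, max_mismatch))
    candidates.sort(key=lambda r: (-r.match_score, r.unit_length, r.start))
    kept: list[TandemRepeat] = []
    for cand in candidates:
        if all(cand.end <= k.start or k.end <= cand.start for k in kept):
            kept.append(cand)
    kept.sort(key=lambda r: r.start)
    return kept


@dataclass(frozen=True)
class ControlRegionArchitecture:
    genome_id: str
    region: NoncodingRegion
    repeats: list[TandemRepeat] = field(default_factory=list)

    def __post_init__(self) -> None:
        last_end = 0
        for r in self.repeats:
            if r.start < last_end:
                raise ValueError("repeats overlap or are out of order")
            last_end = r.end
            if r.end > self.region.length:
                raise ValueError("repeat extends beyond the control region")


def annotate_control_region(
    genome: Mitogenome,
    min_unit: int = 10,
    max_unit: int = 300,
    min_copies: int = 2,
    max_mismatch: float = 0.1,
) -> ControlRegionArchitecture:
    """Locate the control region and annotate its tandem-repeat arrays."""
    region = locate_control_region(genome)
    repeats = find_tandem_repeats(
        region.seq, min_unit=min_unit, max_unit=max_unit,
        min_copies=min_copies, max_mismatch=max_mismatch,
    )
    return ControlRegionArchitecture(genome_id=genome.id, region=region, repeats=repeats)


def mask_repeats(arch: ControlRegionArchitecture, retain_one: bool = False) -> str:
    """The control-region sequence with repeat arrays removed (zero copies
    retained by default; ``retain_one`` keeps one unit per array for
    sensitivity analysis)."""
    seq = arch.region.seq
    parts: list[str] = []
    pos = 0
    for r in arch.repeats:
        parts.append(seq[pos : r.start])
        if retain_one:
            parts.append(r.unit_seq)
        pos = r.end
    parts.append(seq[pos:])
    remainder = "".join(parts)
    if not remainder:
        log.warning("%s: repeat arrays span the whole control region", arch.genome_id)
    return remainder


# --- identity -----------------------------------------------------------------


@dataclass(frozen=True)
class IdentityResult:
    identity: float  # percentage
    columns: int
    matches: int
    score: float  # alignment score (invariant across co-optimal alignments)
    gap_columns_in_denominator: bool = True
    scoring: str = "global: match +1, mismatch -1, gap open -2, gap extend -1"


def pairwise_identity(
    a: str, b: str, gap_columns_in_denominator: bool = True
) -> IdentityResult:
    """Percent identity from a global alignment (match +1, mismatch -1, gap
    open -2, gap extend -1); by default gap columns count in the
    denominator, the alternative convention is flag-selectable.

    Among co-optimal alignments the first one for a canonical
    (lexicographically smallest) presentation of the pair is used — the
    arguments may be swapped and jointly reverse-complemented — so the
    result is deterministic, exactly symmetric, and invariant under joint
    reverse-complement.
    """
    if not a or not b:
        raise ValueError("both sequences must be non-empty")
    a, b = sorted((a.upper(), b.upper()))
    if set(a + b) <= set("ACGTN"):
        from .genome_io import revcomp

        a, b = min((a, b), tuple(sorted((revcomp(a), revcomp(b)))))
    aligner = _nt_aligner("global")
    best = aligner.align(a, b)[0]
    ga, gb = str(best[0]), str(best[1])
    matches = sum(x == y and x != "-" for x, y in zip(ga, gb))
    columns = len(ga)
    denom = columns if gap_columns_in_denominator else sum(
        x != "-" and y != "-" for x, y in zip(ga, gb)
    )
    return IdentityResult(
        identity=100.0 * matches / denom if denom else 0.0,
        columns=columns, matches=matches, score=float(best.score),
        gap_columns_in_denominator=gap_columns_in_denominator,
    )


def multi_identity(seqs: dict[str, str]) -> float:
    """Average pairwise identity (%) over a progressive multiple alignment
    of the given sequences (used for inter-genus comparisons of masked
    control regions)."""
    from .alignment import center_star_align

    named = {k: v for k, v in seqs.items() if v}
    if len(named) < 2:
        raise ValueError("need at least 2 non-empty sequences")
    gapped = center_star_align(named, aligner=_nt_aligner("global"))
    rows = list(gapped.values())
    total, pairs = 0.0, 0
    for i in range(len(rows)):
        for j in range(i + 1, len(rows)):
            matches = sum(
                x == y and x != "-" for x, y in zip(rows[i], rows[j])
            )
            total += 100.0 * matches / len(rows[i])
            pairs += 1
    return total / pairs
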