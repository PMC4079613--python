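# Methods

## The codon-meaning predictor

The central procedure infers, per taxon, the amino-acid meaning of a
target codon (AGG by default) from conserved alignment context. Protein-
coding genes are aligned per gene at the amino-acid level and
back-translated to codons, so every column is a homologous codon
position. Columns are then filtered to those with occupancy ≥ 0.8
(fraction of non-gap cells) and conservation ≥ 0.5 (top-amino-acid
fraction among non-gap cells, translated under each taxon's baseline
code). Cells equal to the target codon are excluded from the
conservation tally in both numerator and denominator, so a column where
many taxa carry the candidate codon cannot filter itself out.

For each retained column where the focal taxon carries the target codon,
the other taxa's amino acids are tallied, again excluding cells that are
themselves the target codon — the inference about AGG never relies on
anyone's assumed meaning of AGG. An occurrence is *called* when at least
`min_informative` (default 3) taxa vote and the winning amino acid
reaches `majority_threshold` (default 0.5) of the votes; otherwise the
occurrence is `?`. The taxon-level prediction is the majority over its
non-`?` occurrence calls; a tie at either level yields `UNPREDICTED`,
and a taxon with zero target-codon occurrences is `UNUSED`. `support` is
the top-amino-acid fraction of the tally aggregated over all
occurrences.

Assumptions: the signal is positional conservation — a codon sitting in
a column that is otherwise invariably lysine is read as lysine. This is
exactly the regime in which reassigned codons are detectable; a genome
using the target codon only at fast-evolving sites comes back
`UNPREDICTED`, which is the honest answer. Non-focal taxa are translated
under the base invertebrate mitochondrial code in a single pass; an
iterative mode (`PredictorParams(iterate=True)`) updates each taxon's
code from its own prediction and repeats to a fixpoint, but is off by
default because a single pass is what a reviewer of the alignment does,
and on data with clear signal both give identical answers (tested).

The two-level majority rule is monotone in practice: raising
`majority_threshold` can only turn calls into `?`. A strict guarantee
that predictions never flip between amino acids holds when a taxon's
occurrence calls are unanimous (the regime the generator produces, where
the property is tested); artificial inputs whose occurrences support
different amino acids at different confidence levels can in principle
flip as the threshold silences one side, which is inherent to the rule
itself.

## Alignment

The internal aligner is a center-star progressive alignment: the center
sequence minimizes the summed k-mer (k=3) distance to the others, every
other sequence is globally aligned to it (BLOSUM62, gap open −11, extend
−1), and the pairwise alignments are merged under once-a-gap-always-a-gap.
Center-star is deliberately simple — mitochondrial proteins are short and
conserved, and indels in them are rare — and an externally computed
codon-aware alignment (aligned FASTA, row lengths multiples of 3) always
overrides it. Terminal stop codons are dropped before alignment;
internal stops translate to `*` and are scored like any rare residue.

## Anticodons and wobble

Anticodons are stored in standard 5'→3' notation. When the annotation
carries an anticodon offset it is sliced directly; otherwise a cloverleaf
heuristic scans every 17-nt window for a 5-bp stem (Watson-Crick or GU
pairs) closing a 7-nt loop, takes the best-pairing window nearest the
sequence midpoint (the anticodon arm is the central arm), and reads loop
positions 3–5. Windows pairing at fewer than 3 of 5 stem positions are
rejected.

Decoding: codon positions 1–2 are the reverse complement of anticodon
positions 35–36; the third position expands from the wobble base 34 under
G→{C,U}, U→{A,G}, C→{G}, A→{U} (overridable). These strict rules
reproduce the decodings relevant here (CUU→AAG; UUU→AAA,AAG; GCU→AGC,AGU;
UCU→AGA,AGG). They deliberately do *not* cover the whole code from 22
anticodons: real mitochondria use modified-base superwobble (e.g. the
lone tRNA-Met CAU reads both AUA and AUG). Whole-table coverage is
therefore computed by cognate expansion — each tRNA claims its amino
acid's codons within its family box — under which the standard 22
anticodons read all 62 sense codons exactly once.

The anticodon × code-state association is a two-sided Fisher exact test
over taxa with an informative (Ser or Lys) prediction; non-users carry no
information about translation and are excluded. The test is an addition
of this pipeline — the underlying observation is usually reported
descriptively — and the reports label it as such.

## Composition

AT-skew = (A−T)/(A+T), GC-skew = (G−C)/(G+C), computed on the stored
J-strand; undefined denominators yield NaN, never silent zeros. N bases
count toward length but never toward composition denominators. Codon-
position G+C and GARP% are computed on the same concatenation of the 13
protein-coding genes, with terminal stop codons excluded (whether the
original analyses excluded them is not stated anywhere we could check;
exclusion is the choice here and is logged). The GC-vs-GARP fit is
ordinary least squares; r² is the squared Pearson correlation.

## Non-coding analysis

The census walks features in coordinate order with a frontier scan on
the circular genome: every positive inter-feature gap is a non-coding
region with its two flanking genes; negative gaps (overlapping
annotations) are logged separately and never reported as NCRs, so
feature lengths + gap lengths − overlaps = genome length exactly. The
control region is the annotated `control_region` feature when present,
else the circular gap from srRNA to tRNA-Ile. The non-coding proportion
counts gaps plus annotated control-region/miscellaneous features.

**Tandem repeats.** For every period p in [10, 300] (bounds CLI-exposed;
published mirid units span 14–223 bp), the finder scans the self-match
array eq[x] = (s[x] = s[x+p]). An array extends copy by copy while each
copy differs from its predecessor at no more than ⌊max_mismatch·p⌋
positions (default max_mismatch 0.1), takes the longest trailing partial
copy within ⌊max_mismatch·t⌋, and is then *edge-refined*: the mismatch
budget would otherwise let an array absorb junk flanks (any start within
budget bases of the true boundary passes), so mismatch-dominated
prefixes and suffixes of the compared region — maximizers of
2·mismatches − length — are trimmed, which is exactly the match-score-
maximal boundary. Overlaps across periods are resolved greedily by
descending match score (compared positions − 2·mismatches), then
ascending unit length, then start. Match score rather than raw span is
the selection key because a composite period k·p scores almost as long a
span as the true period p over the same region while absorbing flanking
noise in its k-times-larger budget; score prefers the primitive period.
Reported arrays are maximal in the exact-matching sense except where a
one-base extension would overlap a neighboring reported array.

**Identity.** Pairwise identity comes from a global alignment (match +1,
mismatch −1, gap open −2, gap extend −1); by default gap columns count in
the denominator (identity = 100·matches/columns), with a flag for the
gap-excluded convention since published identity values rarely state
theirs. Co-optimal global alignments can differ in identity, so the pair
is put in a canonical form first (sorted, and jointly reverse-
complemented if that sorts lower): the result is deterministic, exactly
symmetric, and invariant under joint reverse-complement. Multi-sequence
identity (for inter-genus comparisons) is the average pairwise identity
over a center-star nucleotide alignment of the repeat-masked control
regions. Repeat masking removes arrays entirely (zero copies retained;
`retain_one=True` keeps one unit for sensitivity analysis).

## The synthetic-data generator

The generator emulates the data regime of true-bug mitogenomics: one
AT-rich circular genome per taxon in the ancestral insect gene order (13
PCGs of realistic lengths, 22 tRNAs, 2 rRNAs, a control region, and a
planted 7-bp termination-site analog between tRNA-Ser(S2) and ND1). The
default cohort is 12 taxa in three 4-taxon clades: an AGG=Ser clade
carrying the mutated anticodon pair (UUU/UCU), an AGG=Lys clade, and a
clade that never uses AGG — with clade AT contents 0.68/0.72/0.76, a
realistic between-clade spread that gives the compositional analyses
something to measure.

Coding sequences evolve from a shared root (codons sampled i.i.d. from
AT-biased base frequencies, stop codons rejected): the clade branch
redraws unconstrained sites from the clade's equilibrium composition and
redraws conserved sites synonymously (clade-level compositional
divergence with amino acids fixed); tip branches apply point
substitutions at `branch_rate` 0.05 per codon site, synonymous-only at
conserved sites. The conserved fraction defaults to 0.6 of amino-acid
sites. AGG is *reserved*: background sampling never emits it, and each
AGG-using taxon receives its occurrences (default 5) planted at conserved
columns whose amino acid matches the taxon's code state — Ser columns for
AGG=Ser taxa, Lys columns for AGG=Lys taxa — so a non-user genuinely
never uses the codon and every planted occurrence sits where the
predictor's assumptions hold.

tRNAs are a fixed 66-nt cloverleaf scaffold with only the anticodon
substituted; the anticodon stem is its only perfect 5-bp stem closing a
7-nt loop, so the localization heuristic provably recovers the planted
anticodon. No structural evolution is simulated — only the anticodon
matters downstream.

Control regions are built per clade: AT-biased background segments
interleaved with exact planted arrays (defaults 60 bp × 11 + 58 bp
partial and 24 bp × 6 + 20 bp, drawn from published plant-bug
architectures), with two safeguards making the planted coordinates the
finder's unique answer: repeat units are rejected if internally
periodic, and the 8 background bases flanking each array are forced to
mismatch their period-distant neighbor (guard zones), so the score-
maximal boundary is exactly the planted one. Tips then mutate background
(non-repeat, non-guard) positions at 0.03 per site, giving intra-clade
control-region identity in the low-to-mid 90s with planted arrays
intact. Everything is checked at generation time (planted AGGs,
anticodons, and exact repeat recovery) and re-sampled on the rare
failure; one seeded NumPy generator drives all sampling, so a fixed seed
gives byte-identical output.

What the generator does **not** emulate — and hence what passing tests
do not show about real data: indel evolution in coding genes (the
aligner is exercised on constructed indel cases instead), rate variation
across sites and lineages beyond the conserved/variable dichotomy,
realistic rRNA/tRNA sequence evolution, degraded or diverged repeat
copies, duplicated or rearranged gene orders, and annotation errors.
The real-data tier over the nine published plant-bug accessions covers
part of that gap when network access allows fetching them.

## Problem sizes and defaults

| Parameter | Default | Notes |
| --- | --- | --- |
| taxa / clades | 12 / 3 | mirrors a genus-level comparison |
| PCG lengths | 156–1716 bp | typical mirid values, 11.2 kb total |
| conserved_fraction | 0.6 | fraction of amino-acid sites invariant |
| agg_occurrences | 5 per using taxon | planted at code-consistent columns |
| branch_rate | 0.05 subs/codon site | tip branches |
| at_content | 0.72 (clades 0.68/0.72/0.76) | genome-wide A+T target |
| min_occupancy / min_conservation | 0.8 / 0.5 | column filter |
| majority_threshold / min_informative | 0.5 / 3 | occurrence calls |
| repeat unit range / max_mismatch | 10–300 bp / 0.1 | finder |
| cr_spec | 60×11+58, 24×6+20 | planted arrays |
| cr_tip_rate | 0.03 | CR background mutations |

Replicate counts (20 seeds for recovery suites) keep the full test suite
and the acceptance script at about a minute each on a single core.

## Known limitations

- Center-star alignment is weaker than profile-based progressive
  aligners on gappy, divergent inputs; supply an external alignment
  when that matters.
- The genome-wide AT content of generated genomes runs ~1.5 points below
  the nominal target because stop-codon rejection removes AT-rich codons
  and the tRNA scaffold is fixed; the calibration stays within ±0.03 and
  is measured by the acceptance script rather than assumed.
- Identity percentages depend on the gap convention and on co-optimal
  alignment choice; the canonicalization fixes determinism, not the
  convention dependence, which is why both conventions are exposed.
- The repeat finder's per-unit mismatch budget is adjacent-copy, not
  consensus-based; long arrays whose copies drift steadily can fragment.
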