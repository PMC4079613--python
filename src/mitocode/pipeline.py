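"""End-to-end orchestration over a genome set.

Stages run in a fixed order — genome I/O, composition, codon usage,
alignment and code inference, anticodons, non-coding analysis — with a
partial-failure policy: a genome failing one stage is excluded from that
stage only, with the reason logged and recorded in the report's
provenance block.  Reports are deterministic given inputs + config.
"""

from __future__ import annotations

import json
import logging
from dataclasses import asdict, dataclass, field
from pathlib import Path

import dendropy
import pandas as pd

from . import __version__
from .alignment import CodonAlignment, build_codon_alignment, read_codon_alignment
from .composition import composition_table
from .genome_io import Mitogenome, concatenated_pcgs, load_genome
from .inference import (
    CodonAssignment, PredictorParams, assignment_table, codon_usage,
    predict_all, usage_table,
)
from .noncoding import (
    annotate_control_region, feature_overlaps, mask_repeats, noncoding_census,
    pairwise_identity,
)
from .trna import anticodon_code_association, decoded_codons, extract_anticodon

log = logging.getLogger(__name__)


@dataclass
class RunConfig:
    inputs: list[str] = field(default_factory=list)
    mode: str = "custom"  # plantbugs9 | cimicomorpha22 | custom (taxon-set label)
    target_codons: list[str] = field(default_factory=lambda: ["AGG"])
    predictor: PredictorParams = field(default_factory=PredictorParams)
    repeat_min_unit: int = 10
    repeat_max_unit: int = 300
    repeat_min_copies: int = 2
    repeat_max_mismatch: float = 0.1
    identity_gap_columns: bool = True  # gap columns in the identity denominator
    external_msa: str | None = None
    newick: str | None = None
    outdir: str | None = None
    seed: int = 0
    log_level: str = "INFO"


@dataclass
class RunReport:
    composition: pd.DataFrame
    codon_usage: pd.DataFrame
    assignments: pd.DataFrame
    anticodons: pd.DataFrame
    associations: list[dict]
    ncr_census: pd.DataFrame
    cr_architecture: pd.DataFrame
    identity: pd.DataFrame
    provenance: dict

    def assignment_objects(self) -> list[CodonAssignment]:
        return self.provenance["_assignment_objects"]


def _warn(provenance: dict, message: str) -> None:
    log.warning(message)
    provenance["warnings"].append(message)


def run_pipeline(config: RunConfig, genomes: list[Mitogenome] | None = None) -> RunReport:
    """Execute every stage over the configured genomes and collect the
    report tables; pass pre-loaded genomes to skip file I/O."""
    provenance: dict = {
        "version": __version__,
        "config": {
            k: (asdict(v) if isinstance(v, PredictorParams) else v)
            for k, v in asdict(config).items()
        },
        "warnings": [],
    }
    if genomes is None:
        genomes = []
        for path in config.inputs:
            try:
                genomes.append(load_genome(path))
            except Exception as e:
                _warn(provenance, f"{path}: unparseable, excluded: {e}")
    if not genomes:
        raise ValueError("zero parseable genomes")

    comp = composition_table(genomes)

    usages = []
    per_gene_cds: dict[str, dict[str, str]] = {}
    for g in genomes:
        try:
            pcgs = concatenated_pcgs(g)
            usages.append(codon_usage(pcgs, taxon=g.id))
            per_gene_cds[g.id] = pcgs
        except ValueError as e:
            _warn(provenance, f"{g.id}: excluded from codon analyses: {e}")
    usage_df = usage_table(usages) if usages else pd.DataFrame()

    assignments: list[CodonAssignment] = []
    if config.external_msa:
        aln: CodonAlignment | None = read_codon_alignment(config.external_msa)
    elif len(per_gene_cds) >= 3:
        aln = build_codon_alignment(per_gene_cds)
    else:
        aln = None
        _warn(provenance, "fewer than 3 taxa with PCGs; code inference skipped")
    if aln is not None:
        for codon in config.target_codons:
            assignments.extend(predict_all(aln, target=codon, params=config.predictor))
    assign_df = assignment_table(assignments) if assignments else pd.DataFrame()

    ac_rows = []
    ac_records = []
    for g in genomes:
        for f in g.features:
            if f.kind != "tRNA":
                continue
            try:
                rec = extract_anticodon(g, f.name)
            except (ValueError, KeyError) as e:
                _warn(provenance, f"{g.id}/{f.name}: anticodon not extracted: {e}")
                continue
            ac_records.append(rec)
            ac_rows.append(
                {
                    "taxon": rec.taxon, "trna": rec.trna,
                    "anticodon": rec.anticodon, "source": rec.source,
                    "decoded_codons": ",".join(sorted(decoded_codons(rec))),
                }
            )
    ac_df = pd.DataFrame(ac_rows)

    associations = []
    agg_assignments = [a for a in assignments if a.codon == "AGG"]
    for trna, states in (("tRNA-Ser(S1)", ("GCU", "UCU")), ("tRNA-Lys", ("CUU", "UUU"))):
        try:
            res = anticodon_code_association(
                ac_records, agg_assignments, trna=trna, states=states
            )
            associations.append(
                {
                    "trna": trna, "states": list(states),
                    "meanings": list(res.meanings),
                    "table": [list(r) for r in res.table],
                    "fisher_p": res.fisher_p,
                    "note": "exact test added by this pipeline; the underlying "
                    "study reports the correlation without a formal test",
                }
            )
        except ValueError as e:
            _warn(provenance, f"association for {trna} not computed: {e}")

    ncr_rows = []
    for g in genomes:
        for region in noncoding_census(g):
            ncr_rows.append(
                {
                    "genome": g.id, "left": region.left, "right": region.right,
                    "start": region.start, "end": region.end,
                    "length": region.length,
                }
            )
        for ov in feature_overlaps(g):
            log.info("%s: overlap %s/%s %d bp", g.id, ov.left, ov.right, ov.bases)
    ncr_df = pd.DataFrame(ncr_rows)

    cr_rows = []
    masked: dict[str, str] = {}
    for g in genomes:
        try:
            arch = annotate_control_region(
                g, min_unit=config.repeat_min_unit, max_unit=config.repeat_max_unit,
                min_copies=config.repeat_min_copies,
                max_mismatch=config.repeat_max_mismatch,
            )
        except ValueError as e:
            _warn(provenance, f"{g.id}: control region not analyzed: {e}")
            continue
        masked[g.id] = mask_repeats(arch)
        if not arch.repeats:
            cr_rows.append(
                {"genome": g.id, "cr_length": arch.region.length, "start": None,
                 "unit_length": None, "full_copies": None, "partial_length": None}
            )
        for r in arch.repeats:
            cr_rows.append(
                {
                    "genome": g.id, "cr_length": arch.region.length,
                    "start": r.start, "unit_length": r.unit_length,
                    "full_copies": r.full_copies, "partial_length": r.partial_length,
                }
            )
    cr_df = pd.DataFrame(cr_rows)

    ids = [g for g in masked if masked[g]]
    identity = pd.DataFrame(index=ids, columns=ids, dtype=float)
    for i, a in enumerate(ids):
        identity.loc[a, a] = 100.0
        for b in ids[i + 1 :]:
            val = pairwise_identity(
                masked[a], masked[b],
                gap_columns_in_denominator=config.identity_gap_columns,
            ).identity
            identity.loc[a, b] = identity.loc[b, a] = val

    provenance["associations"] = associations
    provenance["_assignment_objects"] = assignments
    report = RunReport(
        composition=comp, codon_usage=usage_df, assignments=assign_df,
        anticodons=ac_df, associations=associations, ncr_census=ncr_df,
        cr_architecture=cr_df, identity=identity, provenance=provenance,
    )
    if config.outdir:
        write_report(report, config.outdir)
    return report


_TSV_NAMES = {
    "composition": "composition.tsv",
    "codon_usage": "codon_usage.tsv",
    "assignments": "agg_assignments.tsv",
    "anticodons": "anticodons.tsv",
    "ncr_census": "ncr_census.tsv",
    "cr_architecture": "cr_architecture.tsv",
    "identity": "identity.tsv",
}


def write_report(report: RunReport, outdir: str | Path) -> None:
    """Write the report tables as TSVs (percentages to 2 decimals) plus a
    provenance JSON sufficient to reproduce the run."""
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    for attr, name in _TSV_NAMES.items():
        df: pd.DataFrame = getattr(report, attr)
        df.to_csv(outdir / name, sep="\t", float_format="%.2f",
                  index=attr in ("codon_usage", "identity"))
    clean = {k: v for k, v in report.provenance.items() if not k.startswith("_")}
    with open(outdir / "provenance.json", "w") as fh:
        json.dump(clean, fh, indent=2, sort_keys=True)


def annotate_tree(
    assignments: list[CodonAssignment], newick: str | Path
) -> str:
    """Attach each tip's predicted AGG meaning as a newick comment
    (``[&AGG=...]``); topology and branch lengths untouched, unmatched
    tips warned and left unannotated."""
    tree = dendropy.Tree.get(
        path=str(newick), schema="newick", preserve_underscores=True
    )
    by_taxon = {a.taxon: a for a in assignments if a.codon == "AGG"}
    for leaf in tree.leaf_node_iter():
        label = leaf.taxon.label if leaf.taxon else None
        if label in by_taxon:
            leaf.annotations.add_new("AGG", by_taxon[label].display)
        elif by_taxon:
            log.warning("tree tip %r has no assignment; left unannotated", label)
    return tree.as_string(schema="newick", suppress_annotations=False).strip()
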