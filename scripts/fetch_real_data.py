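#!/usr/bin/env python
"""Fetch the nine published plant-bug mitogenome accessions from NCBI and
convert them to the FASTA + feature-table pairs consumed by the real-data
tier (tests/test_acceptance.py::test_real_data_tier_published_quantities).

Requires network access.  Usage:

    python scripts/fetch_real_data.py --email you@example.org [--outdir data/real]
"""

from __future__ import annotations

import argparse
import sys
import time
from pathlib import Path

from Bio import Entrez

sys.path.insert(0, str(Path(__file__).resolve().parent.parent / "src"))

from mitocode.genome_io import parse_genbank, write_feature_table  # noqa: E402

ACCESSIONS = [
    "NC_023083",  # Apolygus lucorum
    "NC_021975",  # Lygus lineolaris
    "KJ170898",   # Lygus rugulipennis
    "NC_022677",  # Nesidiocoris tenuis
    "KJ001714",   # Adelphocoris fasciaticollis
    "KJ020286",   # Adelphocoris lineolatus
    "KJ020287",   # Adelphocoris nigritylus
    "KJ020288",   # Adelphocoris suturalis
    "KJ170899",   # Trigonotylus caelestialium
]


def main() -> None:
    parser = argparse.ArgumentParser(description=__doc__)
    parser.add_argument("--email", required=True, help="NCBI Entrez contact email")
    parser.add_argument("--outdir", default="data/real", type=Path)
    args = parser.parse_args()
    Entrez.email = args.email
    args.outdir.mkdir(parents=True, exist_ok=True)
    for acc in ACCESSIONS:
        gb_path = args.outdir / f"{acc}.gb"
        if not gb_path.exists():
            print(f"fetching {acc} ...", file=sys.stderr)
            with Entrez.efetch(
                db="nucleotide", id=acc, rettype="gb", retmode="text"
            ) as handle:
                gb_path.write_text(handle.read())
            time.sleep(0.4)  # NCBI rate limit
        genome = parse_genbank(gb_path)
        genome.id = acc  # use the bare accession as the stable identifier
        write_feature_table(
            genome, args.outdir / f"{acc}.fasta", args.outdir / f"{acc}.features.tsv"
        )
        gb_path.unlink()  # keep only the compact text conversion
        print(f"{acc}: {len(genome)} bp, {len(genome.features)} features")


if __name__ == "__main__":
    main()
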