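#!/usr/bin/env python
"""Apply the annotation rules to the study's supplementary exports.

This utility re-runs the classification on user-supplied files (they
are not bundled with the package):

  * a protein FASTA of the family members (e.g. the 221-sequence
    supplementary table exported as FASTA),
  * optionally a gene-position TSV with columns
    gene_id, scaffold, start, end, strand (family and non-family genes)
    for the tandem-duplication rule,
  * optionally a genes x samples RPKM TSV for expressed-gene counts.

Example:
    python scripts/supplementary_recompute.py \
        --fasta table_s2.faa --positions table_s1.tsv --rpkm table_s4.tsv
"""

from __future__ import annotations

import argparse
import json

import pandas as pd

from spfam import pipeline
from spfam.genome_layout import tandem_clusters
from spfam.expression import expressed_counts
from spfam.seqio import GeneModel, read_expression, read_fasta


def positions_to_models(path: str) -> list[GeneModel]:
    df = pd.read_csv(path, sep="\t")
    required = {"gene_id", "scaffold", "start", "end", "strand"}
    if not required.issubset(df.columns):
        raise SystemExit(f"positions TSV needs columns {sorted(required)}")
    models = []
    for row in df.itertuples():
        models.append(
            GeneModel(
                gene_id=str(row.gene_id),
                scaffold=str(row.scaffold),
                start=int(row.start),
                end=int(row.end),
                strand=str(row.strand),
                exons=((int(row.start), int(row.end)),),
            )
        )
    return models


def main() -> None:
    parser = argparse.ArgumentParser(description=__doc__)
    parser.add_argument("--fasta", required=True)
    parser.add_argument("--positions")
    parser.add_argument("--rpkm")
    parser.add_argument("--max-intervening", type=int, default=5)
    args = parser.parse_args()

    records = read_fasta(args.fasta)
    table, summary = pipeline.annotate(records)
    out: dict = {"annotation": summary}

    if args.positions:
        models = positions_to_models(args.positions)
        family = {r.id for r in records} & {m.gene_id for m in models}
        clusters = tandem_clusters(family, models, args.max_intervening)
        out["tandem"] = {
            "n_clusters": len(clusters),
            "n_tandem_genes": sum(len(c) for c in clusters),
        }

    if args.rpkm:
        per_sample, any_count = expressed_counts(read_expression(args.rpkm))
        out["expression"] = {
            "expressed_any": any_count,
            "per_sample": per_sample.to_dict(),
        }

    print(json.dumps(out, indent=1))


if __name__ == "__main__":
    main()
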