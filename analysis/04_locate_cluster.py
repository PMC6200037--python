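#!/usr/bin/env python
"""Locate the cysK-ctl-cysE cluster in every genome of the panel.

Searches the annotated proteomes for homologs of the three version-B
query proteins (>= 40% identity), then applies the two selection steps:
all three homologs within a 20 kb window, and the same gene order as
the query cluster (or its exact reversal). Each accepted occurrence is
classified as chromosomal or plasmid-borne.
"""

import sys
from pathlib import Path

import pandas as pd

from genetrait.io_formats import read_fasta
from genetrait.locate import find_homologs, locate_cluster
from genetrait.pipeline import load_genomes

RESULTS = Path(__file__).resolve().parents[1] / "results"


def main() -> None:
    replicons, genes = load_genomes(RESULTS / "panel" / "dataset")
    queries = read_fasta(RESULTS / "panel" / "queries.faa")
    all_genes = [g for s in sorted(genes) for g in genes[s]]
    hits = find_homologs(queries, all_genes, min_identity=0.4)
    cluster_hits = locate_cluster(hits, replicons, list(queries),
                                  window_bp=20_000, report_rejected=True)
    rows = [(h.strain_id, h.replicon_id, h.replicon_kind, h.span_bp,
             int(h.window_ok), int(h.order_ok), int(h.accepted),
             ";".join(f"{q}:{g}:{s}-{e}:{st}" for q, g, s, e, st
                      in h.ordered_genes)) for h in cluster_hits]
    pd.DataFrame(rows, columns=["strain", "replicon", "replicon_kind",
                                "span_bp", "window_ok", "order_ok",
                                "accepted", "genes"]) \
        .to_csv(RESULTS / "cluster_hits.tsv", sep="\t", index=False)

    accepted = [h for h in cluster_hits if h.accepted]
    plasmid = [h for h in accepted if h.replicon_kind == "plasmid"]
    print(f"homolog hits: {len(hits)}; candidate replicons: {len(cluster_hits)}")
    print(f"accepted occurrences: {len(accepted)} "
          f"({len(plasmid)} plasmid-borne, "
          f"{len(accepted) - len(plasmid)} chromosomal)")
    for h in cluster_hits:
        if not h.accepted:
            reason = "window > 20 kb" if not h.window_ok else "gene order"
            print(f"  rejected {h.strain_id} ({h.replicon_id}): {reason}, "
                  f"span {h.span_bp} bp")


if __name__ == "__main__":
    sys.exit(main())
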