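#!/usr/bin/env python
"""Cluster the panel's proteomes into ortholog families at two
stringencies.

Permissive clustering (50% identity, OrthoMCL-like granularity) merges
the two cluster versions into one family per gene; strict clustering
(95%, Roary-default-like) splits them. Writes family tables and
presence/absence matrices for both modes.
"""

import sys
from pathlib import Path

from genetrait.clustering import build_gene_families, presence_absence
from genetrait.io_formats import write_matrix_tsv
from genetrait.pipeline import families_to_frame, load_genomes

RESULTS = Path(__file__).resolve().parents[1] / "results"


def main() -> None:
    _reps, genes = load_genomes(RESULTS / "panel" / "dataset")
    strains = sorted(genes)
    for mode in ("permissive", "strict"):
        fams = build_gene_families(genes, mode=mode)
        matrix = presence_absence(fams, strains)
        families_to_frame(fams).to_csv(RESULTS / f"families_{mode}.tsv",
                                       sep="\t", index=False)
        write_matrix_tsv(matrix.to_frame(),
                         RESULTS / f"presence_absence_{mode}.tsv")
        n_core = int((matrix.values.sum(axis=0) == len(strains)).sum())
        print(f"{mode}: {len(fams)} families, {n_core} present in all "
              f"{len(strains)} strains")


if __name__ == "__main__":
    sys.exit(main())
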