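#!/usr/bin/env python
"""Build the core-genome strain tree and the gene-cluster tree.

The core tree concatenates single-copy strict-mode core family CDSs,
computes Jukes-Cantor distances, and runs neighbor joining with
bootstrap supports (100 column resamples here). The cluster tree does
the same on the concatenated cluster genes of the accepted occurrences.
The plasmid carriers are expected to form a clade on the core tree
while the cluster tree separates the two versions — the incongruence
pattern that, with plasmid localization, argues for horizontal transfer.
"""

import sys
from pathlib import Path

import pandas as pd

from genetrait.clustering import GeneFamily
from genetrait.io_formats import Alignment
from genetrait.phylo import bipartitions, bootstrap_support, concat_core_alignment
from genetrait.pipeline import load_genomes

RESULTS = Path(__file__).resolve().parents[1] / "results"
BOOTSTRAP_REPS = 100
SEED = 42


def _load_families(path):
    df = pd.read_csv(path, sep="\t")
    fams = []
    for fid, grp in df.groupby("family_id"):
        members = {s: sorted(g["gene_id"]) for s, g in grp.groupby("strain")}
        fams.append(GeneFamily(str(fid), members))
    return fams


def main() -> None:
    _reps, genes = load_genomes(RESULTS / "panel" / "dataset")
    strains = sorted(genes)
    nt = {g.gene_id: g.nt_seq for s in strains for g in genes[s] if g.nt_seq}

    fams = _load_families(RESULTS / "families_strict.tsv")
    aln = concat_core_alignment(fams, strains, nt)
    core = bootstrap_support(aln, n_reps=BOOTSTRAP_REPS, seed=SEED)
    core.tree.write(str(RESULTS / "core_tree.nwk"), format="newick")
    print(f"core alignment: {aln.length} bp from single-copy core families")
    print(f"core tree written ({core.skipped} bootstrap replicates skipped)")

    hits = pd.read_csv(RESULTS / "cluster_hits.tsv", sep="\t")
    acc = hits[hits["accepted"] == 1]
    seqs = {}
    for _, row in acc.iterrows():
        parts = dict(p.split(":", 2)[:2] for p in row["genes"].split(";"))
        seqs[row["strain"]] = "".join(nt[parts[q]]
                                      for q in ("cysK", "ctl", "cysE"))
    names = sorted(seqs)
    cl = bootstrap_support(Alignment(names, [seqs[s] for s in names]),
                           n_reps=BOOTSTRAP_REPS, seed=SEED + 1)
    cl.tree.write(str(RESULTS / "cluster_tree.nwk"), format="newick")

    plasmid = frozenset(acc.loc[acc["replicon_kind"] == "plasmid", "strain"])
    leaves = frozenset(names)
    key = plasmid if min(leaves) not in plasmid else leaves - plasmid
    split = key in bipartitions(cl.tree)
    supp = cl.supports.get(key, 0)
    print(f"cluster tree: plasmid-borne version separated: {split} "
          f"(bootstrap support {supp}%)")
    core_key = plasmid if min(frozenset(strains)) not in plasmid \
        else frozenset(strains) - plasmid
    on_core = core_key in bipartitions(core.tree)
    print(f"core tree: plasmid carriers form a clade: {on_core} "
          f"(support {core.supports.get(core_key, 0)}%)")


if __name__ == "__main__":
    sys.exit(main())
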