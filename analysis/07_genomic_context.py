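#!/usr/bin/env python
"""Profile the genomic neighborhood of a plasmid-borne cluster occurrence.

Takes the first plasmid occurrence accepted by the locator, extracts
all genes within +-10 kb of the cluster span, flags transposases, and
computes each gene's conservation — the fraction of other strains whose
ortholog family contains it. The expected picture: cluster genes
conserved in all carriers, plasmid backbone genes only in the plasmid
carriers, transposases widespread.
"""

import sys
from pathlib import Path

import pandas as pd

from genetrait.clustering import GeneFamily
from genetrait.context import conservation_profile, extract_context
from genetrait.pipeline import load_genomes

RESULTS = Path(__file__).resolve().parents[1] / "results"


def main() -> None:
    replicons, genes = load_genomes(RESULTS / "panel" / "dataset")
    hits = pd.read_csv(RESULTS / "cluster_hits.tsv", sep="\t")
    plas = hits[(hits["accepted"] == 1) &
                (hits["replicon_kind"] == "plasmid")].iloc[0]
    coords = [int(p.split(":")[2].split("-")[0])
              for p in plas["genes"].split(";")]
    ends = [int(p.split(":")[2].split("-")[1])
            for p in plas["genes"].split(";")]
    strain, rep_id = plas["strain"], plas["replicon"]

    df = pd.read_csv(RESULTS / "families_permissive.tsv", sep="\t")
    fams = [GeneFamily(str(fid),
                       {s: sorted(g["gene_id"]) for s, g in grp.groupby("strain")})
            for fid, grp in df.groupby("family_id")]

    ctx = extract_context(genes[strain], rep_id, min(coords), max(ends),
                          flank_bp=10_000,
                          replicon_length=replicons[rep_id].length_bp)
    profile = conservation_profile(ctx, fams, sorted(genes), strain)
    out = pd.DataFrame(
        [(e.gene_id, e.family_id or "", e.start, e.end, e.strand,
          int(e.is_transposase), round(e.conservation, 4))
         for e in profile.entries],
        columns=["gene_id", "family_id", "start", "end", "strand",
                 "is_transposase", "conservation"])
    out.to_csv(RESULTS / "context_profile.tsv", sep="\t", index=False)

    print(f"focal occurrence: {strain}:{rep_id}:{min(coords)}-{max(ends)}")
    print(f"{len(profile.entries)} genes within +-10 kb; "
          f"{int(out['is_transposase'].sum())} transposases flagged")
    for _, row in out.iterrows():
        bar = "#" * int(round(20 * row["conservation"]))
        tnp = " [transposase]" if row["is_transposase"] else ""
        print(f"  {row['gene_id']:>10} {row['conservation']:6.3f} {bar}{tnp}")


if __name__ == "__main__":
    sys.exit(main())
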