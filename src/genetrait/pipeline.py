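"""End-to-end orchestration: simulate -> cluster -> gene-trait matching ->
cluster location -> trees -> gene content -> context, with a manifest.

A run is driven by one :class:`RunConfig`. Every stage's parameters and
output files (with SHA-256 digests) are recorded in ``manifest.json``;
the manifest contains no timestamps, so identical configs (seed
included) reproduce byte-identical manifests and outputs.

Stage conventions follow the study design: gene-trait matching runs on
the permissive (OrthoMCL-like) families, while the core-genome tree and
gene-content clustering run on the strict (Roary-like) families.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
from dataclasses import dataclass
from pathlib import Path
import pandas as pd

from . import __version__
from .association import load_phenotypes, match_traits, results_to_frame
from .clustering import (GeneFamily, build_gene_families, presence_absence)
from .context import conservation_profile, extract_context
from .genecontent import (cut_groups, dendrogram_to_newick,
                          euclidean_dendrogram, pan_core_sizes, shared_counts)
from .io_formats import (GeneFeature, Replicon, read_fasta, read_gff3,
                         write_matrix_tsv)
from .locate import find_homologs, locate_cluster
from .phylo import Alignment, bootstrap_support, concat_core_alignment
from .simulate import (SimConfig, SimulatedDataset, simulate_pangenome,
                       write_dataset)


class StageError(RuntimeError):
    """A pipeline stage failed; carries the stage name."""

    def __init__(self, stage: str, cause: Exception):
        super().__init__(f"stage {stage!r} failed: {cause}")
        self.stage = stage
        self.cause = cause


@dataclass
class RunConfig:
    """Flat configuration of one pipeline run."""

    out_dir: str
    sim: SimConfig | None = None
    genomes_dir: str | None = None
    phenotype_path: str | None = None
    queries_path: str | None = None
    alpha: float = 0.05
    m_override: int | None = None
    window_bp: int = 20_000
    min_identity: float = 0.4
    bootstrap_reps: int = 1000
    k_groups: int = 2
    flank_bp: int = 10_000
    seed: int = 0
    force: bool = False

    def validate(self) -> None:
        if self.sim is None and self.genomes_dir is None:
            raise ValueError("either a simulation config or a genomes "
                             "directory is required")


def load_genomes(genomes_dir: str | Path
                 ) -> tuple[dict[str, Replicon], dict[str, list[GeneFeature]]]:
    """Load per-strain GFF3 + FASTA pairs from a directory."""
    genomes_dir = Path(genomes_dir)
    replicons: dict[str, Replicon] = {}
    genes_by_strain: dict[str, list[GeneFeature]] = {}
    gffs = sorted(genomes_dir.glob("*.gff3"))
    if not gffs:
        raise FileNotFoundError(f"no .gff3 files in {genomes_dir}")
    for gff in gffs:
        fna = gff.with_suffix(".fna")
        if not fna.exists():
            raise FileNotFoundError(f"missing sequence file {fna}")
        reps, genes = read_gff3(gff, fna)
        strain = reps[0].strain_id or gff.stem
        for rep in reps:
            if not rep.strain_id:
                rep.strain_id = strain
            replicons[rep.replicon_id] = rep
        genes_by_strain.setdefault(strain, []).extend(genes)
    return replicons, genes_by_strain


def families_to_frame(families: list[GeneFamily]) -> pd.DataFrame:
    rows = [(f.family_id, s, g)
            for f in families for s in sorted(f.members)
            for g in f.members[s]]
    return pd.DataFrame(rows, columns=["family_id", "strain", "gene_id"])


def _sha256(path: Path) -> str:
    return hashlib.sha256(path.read_bytes()).hexdigest()


def run_pipeline(config: RunConfig) -> dict:
    """Execute all stages in dependency order; returns the manifest dict.

    A failing stage raises :class:`StageError` after writing a
    ``failed/<stage>`` marker; earlier outputs are retained.
    """
    config.validate()
    out = Path(config.out_dir)
    out.mkdir(parents=True, exist_ok=True)
    manifest: dict = {
        "tool": "genetrait",
        "version": __version__,
        "seed": config.seed,
        "parameters": {
            "alpha": config.alpha, "m_override": config.m_override,
            "window_bp": config.window_bp, "min_identity": config.min_identity,
            "bootstrap_reps": config.bootstrap_reps, "k_groups": config.k_groups,
            "flank_bp": config.flank_bp,
            "sim": dataclasses.asdict(config.sim) if config.sim else None,
            "genomes_dir": config.genomes_dir,
        },
        "stages": {},
        "summary": {},
    }
    outputs: list[Path] = []
    stage = "setup"

    def record(name: str, paths: list[Path], **info) -> None:
        manifest["stages"][name] = {
            "outputs": {p.name: _sha256(p) for p in paths}, **info}
        outputs.extend(paths)

    try:
        # --- inputs -------------------------------------------------------
        stage = "simulate"
        dataset: SimulatedDataset | None = None
        if config.sim is not None:
            sim = dataclasses.replace(config.sim, seed=config.seed)
            dataset = simulate_pangenome(sim)
            ds_dir = out / "dataset"
            if ds_dir.exists() and any(ds_dir.iterdir()):
                if not config.force:
                    raise FileExistsError(f"{ds_dir} is not empty (use force)")
                for p in ds_dir.iterdir():
                    p.unlink()
            paths = write_dataset(dataset, ds_dir, force=True)
            replicons = dataset.replicons
            genes_by_strain = dataset.genes_by_strain
            phenotypes = {
                row.strain: row.mean >= 1.0
                for row in dataset.phenotype.itertuples()}
            queries = dataset.queries
            record("simulate", paths, n_strains=len(dataset.strains))
        else:
            replicons, genes_by_strain = load_genomes(config.genomes_dir)
            if config.phenotype_path is None:
                raise FileNotFoundError("a phenotype table is required")
            phenotypes = load_phenotypes(config.phenotype_path)
            if config.queries_path is None:
                raise FileNotFoundError("a query protein FASTA is required")
            queries = read_fasta(config.queries_path)
            record("load", [], n_strains=len(genes_by_strain))
        strains = sorted(genes_by_strain)

        # --- ortholog clustering, both stringencies ------------------------
        stage = "cluster"
        fams = {}
        matrices = {}
        paths = []
        for mode in ("permissive", "strict"):
            fams[mode] = build_gene_families(genes_by_strain, mode=mode)
            matrices[mode] = presence_absence(fams[mode], strains)
            fp = out / f"families_{mode}.tsv"
            families_to_frame(fams[mode]).to_csv(fp, sep="\t", index=False)
            mp = out / f"presence_absence_{mode}.tsv"
            write_matrix_tsv(matrices[mode].to_frame(), mp)
            paths += [fp, mp]
        record("cluster", paths,
               n_families={m: len(fams[m]) for m in fams})

        # --- gene-trait matching (permissive families) ----------------------
        stage = "gtm"
        missing = [s for s in strains if s not in phenotypes]
        if missing:
            raise ValueError(f"phenotype missing for strains: {missing}")
        results = match_traits(matrices["permissive"], phenotypes,
                               alpha=config.alpha, m_override=config.m_override)
        gtm_path = out / "gtm_results.tsv"
        results_to_frame(results).to_csv(gtm_path, sep="\t", index=False,
                                         float_format="%.6g")
        sig = [r for r in results if r.significant]
        record("gtm", [gtm_path], n_significant=len(sig))
        manifest["summary"]["significant_families"] = sorted(
            r.family_id for r in sig)

        # --- cluster location ----------------------------------------------
        stage = "locate"
        all_genes = [g for s in strains for g in genes_by_strain[s]]
        hits = find_homologs(queries, all_genes,
                             min_identity=config.min_identity)
        cluster_hits = locate_cluster(
            hits, replicons, query_order=list(queries),
            window_bp=config.window_bp, report_rejected=True)
        rows = [(h.strain_id, h.replicon_id, h.replicon_kind, h.span_bp,
                 int(h.window_ok), int(h.order_ok), int(h.accepted),
                 ";".join(f"{q}:{g}:{s}-{e}:{st}" for q, g, s, e, st
                          in h.ordered_genes))
                for h in cluster_hits]
        hits_path = out / "cluster_hits.tsv"
        pd.DataFrame(rows, columns=[
            "strain", "replicon", "replicon_kind", "span_bp", "window_ok",
            "order_ok", "accepted", "genes"]).to_csv(hits_path, sep="\t",
                                                     index=False)
        accepted = [h for h in cluster_hits if h.accepted]
        record("locate", [hits_path], n_accepted=len(accepted))
        manifest["summary"]["cluster_carriers"] = sorted(
            h.strain_id for h in accepted)
        manifest["summary"]["plasmid_carriers"] = sorted(
            h.strain_id for h in accepted if h.replicon_kind == "plasmid")

        # --- phylogenies -----------------------------------------------------
        stage = "tree"
        nt_by_gene = {g.gene_id: g.nt_seq for s in strains
                      for g in genes_by_strain[s] if g.nt_seq}
        core_aln = concat_core_alignment(fams["strict"], strains, nt_by_gene)
        core_bs = bootstrap_support(core_aln, n_reps=config.bootstrap_reps,
                                    seed=config.seed)
        core_path = out / "core_tree.nwk"
        core_bs.tree.write(str(core_path), format="newick")
        paths = [core_path]
        cluster_tree_path = None
        if len(accepted) >= 3:
            gene_by_strain_and_query = {
                (h.strain_id, q): nt_by_gene[g]
                for h in accepted for q, g, *_ in h.ordered_genes}
            names = sorted(h.strain_id for h in accepted)
            rows = ["".join(gene_by_strain_and_query[(s, q)] for q in queries)
                    for s in names]
            cluster_aln = Alignment(names=names, rows=rows)
            cluster_bs = bootstrap_support(
                cluster_aln, n_reps=config.bootstrap_reps, seed=config.seed + 1)
            cluster_tree_path = out / "cluster_tree.nwk"
            cluster_bs.tree.write(str(cluster_tree_path), format="newick")
            paths.append(cluster_tree_path)
        record("tree", paths, core_alignment_length=core_aln.length,
               bootstrap_skipped=core_bs.skipped)

        # --- gene content -----------------------------------------------------
        stage = "pangenome"
        pan, core = pan_core_sizes(matrices["strict"])
        shared = shared_counts(matrices["strict"])
        dendro = euclidean_dendrogram(shared)
        groups = cut_groups(dendro, k=config.k_groups)
        sp = out / "shared_counts.tsv"
        write_matrix_tsv(shared.to_frame(), sp)
        dp = out / "gene_content_dendrogram.nwk"
        dp.write_text(dendrogram_to_newick(dendro) + "\n")
        gp = out / "gene_content_groups.tsv"
        pd.DataFrame(sorted(groups.items()),
                     columns=["strain", "group"]).to_csv(gp, sep="\t",
                                                         index=False)
        record("pangenome", [sp, dp, gp], pan=pan, core=core)
        manifest["summary"]["pan_families"] = pan
        manifest["summary"]["core_families"] = core
        manifest["summary"]["gene_content_groups"] = {
            str(g): sorted(s for s, gg in groups.items() if gg == g)
            for g in sorted(set(groups.values()))}

        # --- genomic context of the first accepted occurrence -----------------
        stage = "context"
        paths = []
        if accepted:
            plasmidic = [h for h in accepted if h.replicon_kind == "plasmid"]
            focal = sorted(plasmidic or accepted,
                           key=lambda h: h.strain_id)[0]
            span_start = min(s for _q, _g, s, _e, _st in focal.ordered_genes)
            span_end = max(e for _q, _g, _s, e, _st in focal.ordered_genes)
            ctx = extract_context(
                genes_by_strain[focal.strain_id], focal.replicon_id,
                span_start, span_end, flank_bp=config.flank_bp,
                replicon_length=replicons[focal.replicon_id].length_bp)
            profile = conservation_profile(ctx, fams["permissive"], strains,
                                           focal.strain_id)
            cp = out / "context_profile.tsv"
            pd.DataFrame(
                [(e.gene_id, e.family_id or "", e.start, e.end, e.strand,
                  int(e.is_transposase), f"{e.conservation:.6g}")
                 for e in profile.entries],
                columns=["gene_id", "family_id", "start", "end", "strand",
                         "is_transposase", "conservation"]
            ).to_csv(cp, sep="\t", index=False)
            paths = [cp]
            record("context", paths, focal=f"{focal.strain_id}:"
                   f"{focal.replicon_id}:{span_start}-{span_end}")
        else:
            record("context", [], focal=None)

    except Exception as exc:
        failed = out / "failed"
        failed.mkdir(exist_ok=True)
        (failed / stage).write_text(f"{type(exc).__name__}: {exc}\n")
        if isinstance(exc, StageError):
            raise
        raise StageError(stage, exc) from exc

    manifest_path = out / "manifest.json"
    manifest_path.write_text(json.dumps(manifest, indent=2, sort_keys=True) + "\n")
    return manifest
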