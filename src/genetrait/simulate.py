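"""Synthetic bacterial strain panels with a planted causal gene cluster.

The generator emulates the statistical structure of a two-subpopulation
panel of dairy lactobacilli in which a three-gene cysteine-synthesis
cluster (cysteine synthase *cysK*, cystathionine lyase *ctl*, serine
acetyltransferase *cysE*) determines whether a strain can grow with
methionine as its sole sulfur source:

* an ultrametric Yule strain phylogeny whose root split defines two
  subpopulations (the larger "group 1" and the smaller "group 2");
* core gene families present in every strain, evolved along the tree
  under Jukes-Cantor substitution;
* accessory families drawn from two group-biased gene pools, giving the
  panel a two-block gene-content structure;
* the causal cluster planted in two divergent sequence versions:
  version A on a plasmid carried by every group-2 strain, version B on
  the chromosome of some group-1 strains, both flanked by
  transposase-annotated genes; the versions diverge to a configurable
  protein identity (default 70%);
* a growth phenotype (OD600 triplicates) determined by cluster carriage,
  optionally with a single non-growing exception strain that carries a
  homolog of the *cysE*-like gene only;
* decoy strains carrying homologs of all three genes that violate either
  the 20 kb co-localization window (scattered placements) or the
  conserved gene order (shuffled placements), plus diverged enough
  (~45% protein identity) not to join the causal ortholog families.

Every random choice flows from one :class:`numpy.random.Generator`, so a
given :class:`SimConfig` (seed included) reproduces the dataset byte for
byte. A machine-readable :class:`TruthRecord` accompanies each dataset so
downstream stages can be scored against the planted signal.
"""

from __future__ import annotations

import json
import math
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
from Bio.Data import CodonTable
from skbio import TreeNode

from .io_formats import (GeneFeature, Replicon, reverse_complement,
                         write_fasta, write_gff3)

# ---------------------------------------------------------------------------
# Configuration and truth record


@dataclass(frozen=True)
class SimConfig:
    """Study conditions for one simulated panel.

    Defaults mirror the motivating panel: 24 strains of which 16 carry the
    cluster and grow, a group-2 fraction of 17/62 as in the extended
    62-strain panel, ~70% protein identity between the two cluster
    versions, and two window/order decoy strains.
    """

    n_strains: int = 24
    n_core: int = 200
    n_accessory: int = 600
    frac_group2: float = 17 / 62
    cluster_carrier_count: int = 16
    cysE_only_exception: bool = True
    inter_version_identity: float = 0.70
    core_substitution_rate: float = 0.02  # expected subs/site root-to-tip
    window_decoys: int = 2
    seed: int = 0
    # accessory gene-pool structure: presence probability of a family in a
    # strain of its own pool vs the other pool; high in-pool prevalence
    # keeps incidental association between accessory families and the
    # cluster-driven phenotype negligible while separating the two pools
    accessory_p_in: float = 0.90
    accessory_p_out: float = 0.15
    # within-family nucleotide divergence for accessory copies
    accessory_divergence: float = 0.005
    # decoy homolog protein identity to the version-B cluster genes: above
    # the homology-search floor (0.4) but below the permissive ortholog
    # threshold (0.5)
    decoy_identity: float = 0.45
    # exception-strain cysE homolog: fraction of residues mutated from the
    # cluster ancestor (yields ~0.72 identity to either version)
    exception_divergence: float = 0.15

    def validate(self) -> None:
        if self.n_strains < 3:
            raise ValueError("n_strains must be >= 3")
        n2 = round(self.n_strains * self.frac_group2)
        n1 = self.n_strains - n2
        if n2 < 2 or n1 < 2:
            raise ValueError(
                f"frac_group2={self.frac_group2} yields group sizes {n1}/{n2}; "
                "each group needs >= 2 strains")
        if not (0 < self.cluster_carrier_count <= self.n_strains):
            raise ValueError("cluster_carrier_count must be in [1, n_strains]")
        if n2 > self.cluster_carrier_count:
            raise ValueError(
                f"group 2 ({n2} strains) exceeds cluster_carrier_count "
                f"({self.cluster_carrier_count}); version A occupies all of group 2")
        free = self.n_strains - self.cluster_carrier_count
        need = self.window_decoys + (1 if self.cysE_only_exception else 0)
        if need > free:
            raise ValueError(
                f"decoys + exception ({need}) exceed non-carrier strains ({free})")
        if not (0 < self.inter_version_identity < 1):
            raise ValueError("inter_version_identity must be in (0, 1)")
        if self.core_substitution_rate < 0:
            raise ValueError("core_substitution_rate must be >= 0")


@dataclass
class TruthRecord:
    """Ground truth of one simulated panel, for recovery scoring."""

    causal_family_ids: set[str]
    carrier_strains: set[str]
    version_by_strain: dict[str, str]  # strain -> 'A' | 'B' | 'none'
    plasmid_strains: set[str]
    group_assignment: dict[str, int]  # strain -> 1 | 2
    decoy_strains: set[str]
    exception_strain: str | None = None
    causal_gene_ids: dict[str, list[str]] = field(default_factory=dict)

    def __post_init__(self) -> None:
        carriers = {s for s, v in self.version_by_strain.items() if v != "none"}
        if carriers != set(self.carrier_strains):
            raise ValueError("carrier_strains inconsistent with version_by_strain")
        if self.decoy_strains & self.carrier_strains:
            raise ValueError("decoy strains must not be carriers")

    def to_json(self) -> str:
        d = {
            "causal_family_ids": sorted(self.causal_family_ids),
            "carrier_strains": sorted(self.carrier_strains),
            "version_by_strain": dict(sorted(self.version_by_strain.items())),
            "plasmid_strains": sorted(self.plasmid_strains),
            "group_assignment": dict(sorted(self.group_assignment.items())),
            "decoy_strains": sorted(self.decoy_strains),
            "exception_strain": self.exception_strain,
            "causal_gene_ids": {k: sorted(v) for k, v in
                                sorted(self.causal_gene_ids.items())},
        }
        return json.dumps(d, indent=2, sort_keys=True)

    @classmethod
    def from_json(cls, text: str) -> "TruthRecord":
        d = json.loads(text)
        return cls(
            causal_family_ids=set(d["causal_family_ids"]),
            carrier_strains=set(d["carrier_strains"]),
            version_by_strain=d["version_by_strain"],
            plasmid_strains=set(d["plasmid_strains"]),
            group_assignment={k: int(v) for k, v in d["group_assignment"].items()},
            decoy_strains=set(d["decoy_strains"]),
            exception_strain=d.get("exception_strain"),
            causal_gene_ids={k: list(v) for k, v in d.get("causal_gene_ids", {}).items()},
        )


@dataclass
class SimulatedDataset:
    config: SimConfig
    strains: list[str]
    replicons: dict[str, Replicon]
    genes_by_strain: dict[str, list[GeneFeature]]
    phenotype: "pd.DataFrame"  # columns: strain, od_rep1..3, mean
    truth: TruthRecord
    tree: TreeNode
    queries: dict[str, str]  # query name -> protein sequence (version B)

    @property
    def all_genes(self) -> list[GeneFeature]:
        return [g for s in self.strains for g in self.genes_by_strain[s]]


# ---------------------------------------------------------------------------
# Tree simulation

def _yule_subtree(n_leaves: int, names: list[str], rng: np.random.Generator
                  ) -> TreeNode:
    """Ultrametric pure-birth subtree on `names`, scaled to unit height."""
    assert n_leaves == len(names)
    if n_leaves == 1:
        leaf = TreeNode(name=names[0])
        leaf.length = 1.0
        return leaf
    # forward simulation: each extant lineage splits at rate 1
    root = TreeNode()
    birth = {id(root): 0.0}
    active = [root]
    t = 0.0
    t_crown = None  # time of the root split; the crown group starts there
    while len(active) < n_leaves:
        t += rng.exponential(1.0 / len(active))
        if t_crown is None:
            t_crown = t
        i = rng.integers(len(active))
        node = active.pop(int(i))
        node.length = t - birth[id(node)]
        kids = [TreeNode(), TreeNode()]
        for k in kids:
            birth[id(k)] = t
            node.append(k)
        active.extend(kids)
    t += rng.exponential(1.0 / n_leaves)  # hold time before the present
    order = rng.permutation(n_leaves)
    for node, j in zip(active, order):
        node.length = t - birth[id(node)]
        node.name = names[int(j)]
    # normalize so the crown (root split to present) has height exactly 1
    crown = t - t_crown
    for node in root.traverse(include_self=False):
        node.length /= crown
    root.length = None
    return root


def simulate_tree(n_strains: int, frac_group2: float, seed: int | None = None,
                  rng: np.random.Generator | None = None
                  ) -> tuple[TreeNode, dict[str, int]]:
    """Random ultrametric strain tree with a two-group root split.

    The root's first child subtends group 1 (the larger group), the second
    group 2 with ``round(n_strains * frac_group2)`` strains. Total
    root-to-tip height is 1; callers scale branch lengths to substitution
    units. Returns the tree and the strain -> group assignment.
    """
    if n_strains < 3:
        raise ValueError("n_strains must be >= 3")
    n2 = round(n_strains * frac_group2)
    n1 = n_strains - n2
    if n1 < 2 or n2 < 2:
        raise ValueError(f"group sizes {n1}/{n2}: each group needs >= 2 strains")
    if rng is None:
        rng = np.random.default_rng(seed)
    width = len(str(n_strains))
    names = [f"S{i + 1:0{width}d}" for i in range(n_strains)]
    g1_names, g2_names = names[:n1], names[n1:]
    # subtree crown heights: group clades are younger than the root split
    h1 = 0.4 + 0.3 * rng.random()
    h2 = 0.4 + 0.3 * rng.random()
    sub1 = _yule_subtree(n1, g1_names, rng)
    sub2 = _yule_subtree(n2, g2_names, rng)
    for sub, h in ((sub1, h1), (sub2, h2)):
        for node in sub.traverse(include_self=True):
            if node.length is not None:
                node.length *= h
        sub.length = (sub.length or 0.0) + (1.0 - h)
    root = TreeNode()
    root.append(sub1)
    root.append(sub2)
    groups = {s: 1 for s in g1_names}
    groups.update({s: 2 for s in g2_names})
    return root, groups


# ---------------------------------------------------------------------------
# Sequence evolution

_NT = np.frombuffer(b"ACGT", dtype="S1")
_NT_INDEX = {b"A": 0, b"C": 1, b"G": 2, b"T": 3}

_table = CodonTable.unambiguous_dna_by_id[11]
STOP_CODONS = tuple(sorted(_table.stop_codons))
SENSE_CODONS = tuple(sorted(_table.forward_table))
#: amino acid -> tuple of codons, bacterial code
CODONS_FOR_AA: dict[str, tuple[str, ...]] = {}
for _codon in SENSE_CODONS:
    CODONS_FOR_AA.setdefault(_table.forward_table[_codon], tuple())
CODONS_FOR_AA = {aa: tuple(c for c in SENSE_CODONS if _table.forward_table[c] == aa)
                 for aa in CODONS_FOR_AA}
AMINO_ACIDS = tuple(sorted(CODONS_FOR_AA))

_FWD: dict[str, str] = dict(_table.forward_table)


def _fast_translate(cds: str) -> str:
    """Dict-lookup translation for generator-built CDSs (ATG start, clean
    sense codons, one trailing stop); same result as the IO-layer
    translator, an order of magnitude faster."""
    prot = "".join(_FWD[cds[i:i + 3]] for i in range(0, len(cds) - 3, 3))
    return "M" + prot[1:]


def _seq_to_idx(seq: str) -> np.ndarray:
    arr = np.frombuffer(seq.encode(), dtype="S1")
    idx = np.empty(len(seq), dtype=np.int8)
    for b, i in _NT_INDEX.items():
        idx[arr == b] = i
    return idx


def _idx_to_seq(idx: np.ndarray) -> str:
    return _NT[idx].tobytes().decode()


def evolve_sequence(ancestor: str, branch_length: float,
                    rng: np.random.Generator) -> str:
    """Evolve a nucleotide sequence under Jukes-Cantor substitution.

    Site-independent; the expected fraction of changed sites is
    ``(3/4) * (1 - exp(-4 b / 3))`` for branch length ``b`` in expected
    substitutions per site. Length is preserved; no indels.
    """
    if branch_length < 0:
        raise ValueError("branch_length must be >= 0")
    if branch_length == 0:
        return ancestor
    p_change = 0.75 * (1.0 - math.exp(-4.0 * branch_length / 3.0))
    idx = _seq_to_idx(ancestor)
    hit = rng.random(len(idx)) < p_change
    shift = rng.integers(1, 4, size=int(hit.sum()), dtype=np.int8)
    idx[hit] = (idx[hit] + shift) % 4
    return _idx_to_seq(idx)


def _sanitize_internal_stops(cds: str) -> str:
    """Replace internal stop codons (TAA/TAG/TGA -> CAA/CAG/CGA)."""
    idx = _seq_to_idx(cds).reshape(-1, 3).astype(np.int16)
    codons = idx[:, 0] * 16 + idx[:, 1] * 4 + idx[:, 2]
    # T=3, A=0, G=2: TAA=48, TAG=50, TGA=56; flipping T->C subtracts 32
    stop = np.isin(codons, (48, 50, 56))
    stop[0] = stop[-1] = False
    if not stop.any():
        return cds
    idx[stop, 0] = 1  # C
    return _idx_to_seq(idx.reshape(-1).astype(np.int8))


def evolve_cds(cds: str, branch_length: float, rng: np.random.Generator) -> str:
    """Evolve a CDS under JC while keeping it translatable.

    The start and stop codons are held fixed and internal stop codons
    arising from substitution are repaired, so that homologous CDSs stay
    gap-free, equal length, and translation-safe.
    """
    if len(cds) < 9 or len(cds) % 3:
        raise ValueError("CDS must be a codon multiple of length >= 9")
    inner = evolve_sequence(cds[3:-3], branch_length, rng)
    return _sanitize_internal_stops(cds[:3] + inner + cds[-3:])


def random_cds(n_codons: int, rng: np.random.Generator) -> str:
    """Random CDS: ATG start, sense codons, one stop codon; len = 3*n_codons."""
    if n_codons < 3:
        raise ValueError("need at least start + 1 codon + stop")
    body = rng.choice(len(SENSE_CODONS), size=n_codons - 2)
    stop = STOP_CODONS[int(rng.integers(len(STOP_CODONS)))]
    return "ATG" + "".join(SENSE_CODONS[i] for i in body) + stop


def mutate_codons_nonsynonymous(cds: str, positions: np.ndarray,
                                rng: np.random.Generator) -> str:
    """Replace the amino acid at the given internal codon positions.

    Each listed codon (0-based codon index; never the first or last codon)
    is replaced by a random codon of a different amino acid, so realized
    protein identity is exactly ``1 - len(positions)/n_protein_residues``.
    """
    codons = [cds[i:i + 3] for i in range(0, len(cds), 3)]
    for pos in positions:
        pos = int(pos)
        old_aa = _FWD.get(codons[pos])
        choices = [aa for aa in AMINO_ACIDS if aa != old_aa]
        new_aa = choices[int(rng.integers(len(choices)))]
        opts = CODONS_FOR_AA[new_aa]
        codons[pos] = opts[int(rng.integers(len(opts)))]
    return "".join(codons)


def mutate_synonymous(cds: str, rate: float, rng: np.random.Generator) -> str:
    """Synonymous codon swaps at the given per-codon rate (protein unchanged)."""
    codons = [cds[i:i + 3] for i in range(0, len(cds), 3)]
    for i in range(1, len(codons) - 1):
        if rng.random() < rate:
            aa = _FWD.get(codons[i])
            if aa is None:
                continue
            opts = CODONS_FOR_AA[aa]
            codons[i] = opts[int(rng.integers(len(opts)))]
    return "".join(codons)


def _evolve_along_tree(tree: TreeNode, ancestor: str, scale: float,
                       rng: np.random.Generator) -> dict[str, str]:
    """Evolve a CDS down an ultrametric tree; returns leaf -> sequence."""
    out: dict[str, str] = {}

    def rec(node: TreeNode, seq: str) -> None:
        for child in node.children:
            child_seq = evolve_cds(seq, (child.length or 0.0) * scale, rng)
            if child.is_tip():
                out[child.name] = child_seq
            else:
                rec(child, child_seq)

    rec(tree, ancestor)
    return out


# ---------------------------------------------------------------------------
# Panel assembly

#: cluster gene lengths in nt (incl. stop), plausible for the three enzymes
CLUSTER_GENE_LENGTHS = {"cysK": 933, "ctl": 1140, "cysE": 669}
CLUSTER_GENE_ORDER = ("cysK", "ctl", "cysE")
CLUSTER_PRODUCTS = {
    "cysK": "cysteine synthase CysK",
    "ctl": "cystathionine lyase Ctl",
    "cysE": "serine acetyltransferase CysE",
}
TRANSPOSASE_PRODUCTS = ("IS30 family transposase", "IS6 family transposase")
PLASMID_BACKBONE_PRODUCTS = (
    "plasmid replication protein RepA", "plasmid replication protein RepB",
    "mobilization protein MobA", "mobilization protein MobC",
    "plasmid partitioning protein ParA", "toxin-antitoxin system antitoxin",
    "conjugal transfer protein TraG", "plasmid recombination enzyme Pre",
)


def _draw_gap(rng: np.random.Generator) -> int:
    return int(rng.integers(50, 401))


def _random_spacer(n: int, rng: np.random.Generator) -> str:
    return _idx_to_seq(rng.integers(0, 4, size=n).astype(np.int8))


class _RepliconBuilder:
    """Accumulates (nt_seq, strand, product, tag) genes into one replicon."""

    def __init__(self, replicon_id: str, strain: str, kind: str,
                 rng: np.random.Generator):
        self.replicon_id = replicon_id
        self.strain = strain
        self.kind = kind
        self.rng = rng
        self.parts: list[str] = []
        self.pos = 0  # 0-based length so far
        self.items: list[tuple[int, int, str, str, str, str]] = []

    def add_gene(self, nt: str, strand: str, product: str, tag: str) -> None:
        gap = _draw_gap(self.rng)
        self.parts.append(_random_spacer(gap, self.rng))
        start = self.pos + gap + 1  # 1-based inclusive
        end = start + len(nt) - 1
        self.parts.append(nt if strand == "+" else reverse_complement(nt))
        self.pos = end
        self.items.append((start, end, strand, product, tag, nt))

    def pad(self, n: int) -> None:
        self.parts.append(_random_spacer(n, self.rng))
        self.pos += n

    def finish(self, gene_id_start: int
               ) -> tuple[Replicon, list[GeneFeature], dict[str, str], int]:
        tail = _draw_gap(self.rng)
        self.parts.append(_random_spacer(tail, self.rng))
        seq = "".join(self.parts)
        rep = Replicon(self.replicon_id, self.strain, self.kind, len(seq), seq)
        genes, tag_to_id = [], {}
        gid = gene_id_start
        for start, end, strand, product, tag, nt in self.items:
            gene_id = f"{self.strain}_{gid:04d}"
            gid += 1
            genes.append(GeneFeature(
                gene_id=gene_id, replicon_id=self.replicon_id, start=start,
                end=end, strand=strand, product=product,
                protein_seq=_fast_translate(nt), nt_seq=nt))
            tag_to_id[tag] = gene_id
        return rep, genes, tag_to_id, gid


def simulate_pangenome(config: SimConfig) -> SimulatedDataset:
    """Generate one strain panel with a planted causal cluster and truth.

    See the module docstring for the emulated structure. Deterministic
    given ``config`` (including its seed).
    """
    import pandas as pd  # local import keeps module import light

    config.validate()
    rng = np.random.default_rng(config.seed)
    tree, groups = simulate_tree(config.n_strains, config.frac_group2, rng=rng)
    strains = sorted(groups)
    group1 = [s for s in strains if groups[s] == 1]
    group2 = [s for s in strains if groups[s] == 2]

    # --- strain roles ------------------------------------------------------
    version_a = list(group2)  # version A (plasmid) occupies all of group 2
    n_b = config.cluster_carrier_count - len(version_a)
    version_b = sorted(rng.choice(group1, size=n_b, replace=False).tolist())
    carriers = set(version_a) | set(version_b)
    non_carriers = sorted(set(strains) - carriers)
    picks = rng.choice(non_carriers,
                       size=config.window_decoys +
                       (1 if config.cysE_only_exception else 0),
                       replace=False).tolist()
    decoys = sorted(picks[:config.window_decoys])
    exception = picks[config.window_decoys] if config.cysE_only_exception else None

    # --- gene family sequences --------------------------------------------
    scale = config.core_substitution_rate  # tree height is 1
    core_ids = [f"C{i + 1:04d}" for i in range(config.n_core)]
    core_seqs: dict[str, dict[str, str]] = {}
    core_strand: dict[str, str] = {}
    for fid in core_ids:
        n_codons = int(rng.integers(100, 501))
        anc = random_cds(n_codons, rng)
        core_seqs[fid] = _evolve_along_tree(tree, anc, scale, rng)
        core_strand[fid] = "+" if rng.random() < 0.5 else "-"

    acc_ids = [f"A{i + 1:04d}" for i in range(config.n_accessory)]
    acc_pool: dict[str, int] = {}
    acc_presence: dict[str, list[str]] = {}
    acc_seqs: dict[str, dict[str, str]] = {}
    acc_strand: dict[str, str] = {}
    for fid in acc_ids:
        pool = 1 if rng.random() < 0.5 else 2
        acc_pool[fid] = pool
        present = []
        for s in strains:
            p = config.accessory_p_in if groups[s] == pool else config.accessory_p_out
            if rng.random() < p:
                present.append(s)
        if not present:  # keep every attempted family non-empty
            pool_strains = group1 if pool == 1 else group2
            present = [pool_strains[int(rng.integers(len(pool_strains)))]]
        anc = random_cds(int(rng.integers(100, 501)), rng)
        acc_presence[fid] = present
        acc_seqs[fid] = {s: evolve_cds(anc, config.accessory_divergence, rng)
                         for s in present}
        acc_strand[fid] = "+" if rng.random() < 0.5 else "-"

    # --- the causal cluster: ancestor and two diverged versions ------------
    anc_cluster = {g: random_cds(CLUSTER_GENE_LENGTHS[g] // 3, rng)
                   for g in CLUSTER_GENE_ORDER}
    version_seq: dict[str, dict[str, str]] = {"A": {}, "B": {}}
    for g, anc in anc_cluster.items():
        n_prot = CLUSTER_GENE_LENGTHS[g] // 3 - 1  # protein residues incl. M
        k_total = round((1.0 - config.inter_version_identity) * n_prot)
        k_a = k_total // 2
        # internal codon indices only (codon 0 is the start, last is the stop)
        pos = rng.choice(np.arange(1, n_prot), size=k_total, replace=False)
        version_seq["A"][g] = mutate_codons_nonsynonymous(anc, pos[:k_a], rng)
        version_seq["B"][g] = mutate_codons_nonsynonymous(anc, pos[k_a:], rng)

    def strain_cluster_copy(version: str, g: str) -> str:
        # recent horizontal acquisition: copies differ only synonymously
        return mutate_synonymous(version_seq[version][g], 0.01, rng)

    exception_seq = None
    if exception is not None:
        g = "cysE"
        n_prot = CLUSTER_GENE_LENGTHS[g] // 3 - 1
        k = round(config.exception_divergence * n_prot)
        pos = rng.choice(np.arange(1, n_prot), size=k, replace=False)
        exception_seq = mutate_codons_nonsynonymous(anc_cluster[g], pos, rng)

    def decoy_copy(g: str) -> str:
        n_prot = CLUSTER_GENE_LENGTHS[g] // 3 - 1
        k = round((1.0 - config.decoy_identity) * n_prot)
        pos = rng.choice(np.arange(1, n_prot), size=k, replace=False)
        return mutate_codons_nonsynonymous(version_seq["B"][g], pos, rng)

    tnp_anc = [random_cds(230, rng), random_cds(260, rng)]
    backbone_anc = [random_cds(int(rng.integers(120, 400)), rng)
                    for _ in PLASMID_BACKBONE_PRODUCTS]

    # --- chromosome layout --------------------------------------------------
    slots = [("core", fid) for fid in core_ids] + [("acc", fid) for fid in acc_ids]
    order = rng.permutation(len(slots))
    slots = [slots[int(i)] for i in order]
    cluster_slot = len(slots) // 3  # version-B / decoy insertion point

    replicons: dict[str, Replicon] = {}
    genes_by_strain: dict[str, list[GeneFeature]] = {}
    causal_gene_ids: dict[str, list[str]] = {g: [] for g in CLUSTER_GENE_ORDER}
    decoy_styles: dict[str, str] = {
        s: ("scattered" if i % 2 == 0 else "shuffled")
        for i, s in enumerate(decoys)}

    for strain in strains:
        chrom = _RepliconBuilder(f"{strain}_chr", strain, "chromosome", rng)
        n_tnp = int(rng.integers(2, 5))
        tnp_slots = set(rng.choice(len(slots), size=n_tnp, replace=False).tolist())
        for i, (kind, fid) in enumerate(slots):
            if i == cluster_slot:
                if strain in version_b:
                    _plant_cluster(chrom, "B", strain_cluster_copy, rng,
                                   tnp_anc, order_names=CLUSTER_GENE_ORDER)
                elif strain in decoys:
                    _plant_decoy(chrom, decoy_styles[strain], decoy_copy,
                                 rng, tnp_anc)
                elif strain == exception:
                    chrom.add_gene(exception_seq, "+",
                                   "serine acetyltransferase homolog",
                                   "exception_cysE")
            if i in tnp_slots:
                j = int(rng.integers(2))
                chrom.add_gene(mutate_synonymous(tnp_anc[j], 0.02, rng),
                               "+" if rng.random() < 0.5 else "-",
                               TRANSPOSASE_PRODUCTS[j], f"tnp_{i}")
            if kind == "core":
                chrom.add_gene(core_seqs[fid][strain], core_strand[fid],
                               f"conserved protein {fid}", f"core_{fid}")
            elif strain in acc_presence[fid]:
                chrom.add_gene(acc_seqs[fid][strain], acc_strand[fid],
                               f"accessory protein {fid}", f"acc_{fid}")

        rep, genes, tags, next_gid = chrom.finish(1)
        replicons[rep.replicon_id] = rep
        genes_by_strain[strain] = list(genes)

        if strain in version_a:
            plas = _RepliconBuilder(f"{strain}_p1", strain, "plasmid", rng)
            for j in range(4):
                plas.add_gene(mutate_synonymous(backbone_anc[j], 0.01, rng),
                              "+", PLASMID_BACKBONE_PRODUCTS[j], f"bb_{j}")
            _plant_cluster(plas, "A", strain_cluster_copy, rng, tnp_anc,
                           order_names=CLUSTER_GENE_ORDER)
            for j in range(4, len(backbone_anc)):
                plas.add_gene(mutate_synonymous(backbone_anc[j], 0.01, rng),
                              "+", PLASMID_BACKBONE_PRODUCTS[j], f"bb_{j}")
            prep, pgenes, ptags, _ = plas.finish(next_gid)
            replicons[prep.replicon_id] = prep
            genes_by_strain[strain].extend(pgenes)
            tags.update(ptags)

        for g in CLUSTER_GENE_ORDER:
            if f"cluster_{g}" in tags:
                causal_gene_ids[g].append(tags[f"cluster_{g}"])
        if strain == exception:
            causal_gene_ids["cysE"].append(tags["exception_cysE"])

    # --- phenotype ----------------------------------------------------------
    od_rows = []
    for strain in strains:
        if strain in carriers:
            reps = rng.normal(1.6, 0.15, size=3)
        else:
            reps = rng.normal(0.3, 0.10, size=3)
        reps = np.clip(reps, 0.0, None).round(3)
        od_rows.append((strain, *reps.tolist(), round(float(reps.mean()), 3)))
    phenotype = pd.DataFrame(
        od_rows, columns=["strain", "od_rep1", "od_rep2", "od_rep3", "mean"])

    # sanity: the threshold rule must reproduce carriage exactly
    grows = phenotype["mean"] >= 1.0
    assert set(phenotype.loc[grows, "strain"]) == carriers

    from .clustering import family_id_for  # deterministic id convention
    causal_family_ids = {family_id_for(ids) for ids in causal_gene_ids.values()}

    truth = TruthRecord(
        causal_family_ids=causal_family_ids,
        carrier_strains=set(carriers),
        version_by_strain={s: ("A" if s in version_a else
                               "B" if s in version_b else "none")
                           for s in strains},
        plasmid_strains=set(version_a),
        group_assignment=groups,
        decoy_strains=set(decoys),
        exception_strain=exception,
        causal_gene_ids=causal_gene_ids,
    )
    queries = {g: _fast_translate(version_seq["B"][g]) for g in CLUSTER_GENE_ORDER}
    return SimulatedDataset(config=config, strains=strains, replicons=replicons,
                            genes_by_strain=genes_by_strain, phenotype=phenotype,
                            truth=truth, tree=tree, queries=queries)


def _plant_cluster(builder: _RepliconBuilder, version: str, copy_fn, rng,
                   tnp_anc: list[str], order_names) -> None:
    """Contiguous cluster in canonical order with transposase flanks."""
    builder.add_gene(mutate_synonymous(tnp_anc[0], 0.02, rng), "+",
                     TRANSPOSASE_PRODUCTS[0], "tnp_up")
    for g in order_names:
        builder.add_gene(copy_fn(version, g), "+", CLUSTER_PRODUCTS[g],
                         f"cluster_{g}")
    builder.add_gene(mutate_synonymous(tnp_anc[1], 0.02, rng), "+",
                     TRANSPOSASE_PRODUCTS[1], "tnp_down")


def _plant_decoy(builder: _RepliconBuilder, style: str, decoy_fn, rng,
                 tnp_anc: list[str]) -> None:
    """Homologs of all three genes violating window (scattered) or order."""
    if style == "shuffled":
        builder.add_gene(mutate_synonymous(tnp_anc[0], 0.02, rng), "+",
                         TRANSPOSASE_PRODUCTS[0], "tnp_up")
        for g in ("ctl", "cysK", "cysE"):  # neither query order nor its reversal
            builder.add_gene(decoy_fn(g), "+",
                             CLUSTER_PRODUCTS[g] + " homolog", f"decoy_{g}")
        builder.add_gene(mutate_synonymous(tnp_anc[1], 0.02, rng), "+",
                         TRANSPOSASE_PRODUCTS[1], "tnp_down")
    else:  # scattered: pairwise spans forced beyond any 20 kb window
        for i, g in enumerate(CLUSTER_GENE_ORDER):
            if i:
                start_pos = builder.pos
                while builder.pos - start_pos < 21_000:
                    builder.add_gene(random_cds(int(rng.integers(150, 400)), rng),
                                     "+" if rng.random() < 0.5 else "-",
                                     "hypothetical protein",
                                     f"filler_{g}_{builder.pos}")
            builder.add_gene(decoy_fn(g), "+",
                             CLUSTER_PRODUCTS[g] + " homolog", f"decoy_{g}")


# ---------------------------------------------------------------------------
# Dataset serialization


def write_dataset(dataset: SimulatedDataset, out_dir: str | Path,
                  force: bool = False) -> list[Path]:
    """Write per-strain GFF3 + nt FASTA + aa FASTA, phenotype TSV, truth JSON.

    Refuses a non-empty output directory unless ``force`` is set. Returns
    the paths written (3 per strain + 2).
    """
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    if any(out.iterdir()) and not force:
        raise FileExistsError(f"output directory {out} is not empty (use force)")
    written: list[Path] = []
    for strain in dataset.strains:
        reps = [r for r in dataset.replicons.values() if r.strain_id == strain]
        reps.sort(key=lambda r: r.replicon_id)
        genes = dataset.genes_by_strain[strain]
        gff = out / f"{strain}.gff3"
        write_gff3(reps, genes, gff)
        fna = out / f"{strain}.fna"
        write_fasta({r.replicon_id: r.seq for r in reps}, fna)
        faa = out / f"{strain}.faa"
        write_fasta({g.gene_id: g.protein_seq for g in genes}, faa)
        written += [gff, fna, faa]
    pheno = out / "phenotype.tsv"
    dataset.phenotype.to_csv(pheno, sep="\t", index=False)
    truth = out / "truth.json"
    truth.write_text(dataset.truth.to_json() + "\n")
    written += [pheno, truth]
    return written
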