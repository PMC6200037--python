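"""Ortholog family construction from protein sequences.

Families are the single-linkage connected components of the graph whose
edges join gene pairs with global-alignment protein identity at or above
a threshold. Two stringency modes mirror the granularity contrast between
permissive (OrthoMCL-like, T = 0.50) and strict (Roary-default-like,
T = 0.95) ortholog clustering: gene variants at ~70% identity merge into
one family under the former and split under the latter.

Identity is Needleman-Wunsch global alignment identity (match +1,
mismatch 0, linear gap -1; identity = matches / alignment length).

Scaling notes. Candidate pairs are pre-filtered by shared amino-acid
5-mers; a pair of proteins at >= 50% identity and usual gene length is
expected to conserve on the order of ten 5-mers, while unrelated pairs
essentially never share the default six of them. The pre-filter is a
screening heuristic; ``use_prefilter=False`` gives the exact all-pairs
path it is validated against. For equal-length
candidates, the ungapped (Hamming) identity is computed first: it is a
lower bound on the global-alignment identity under this scoring (any
optimal alignment with G gap columns has at least G more matches than
the ungapped one and is at most G/2 columns longer), so a pair whose
Hamming identity clears the threshold is an edge without running the
aligner. Pairs already connected in the union-find are skipped, which
cannot change the connected components.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd
from Bio import Align
from scipy import sparse

from .io_formats import GeneFeature

PERMISSIVE_IDENTITY = 0.50
STRICT_IDENTITY = 0.95

KMER_K = 5
DEFAULT_MIN_SHARED_KMERS = 6


def family_id_for(member_gene_ids: Iterable[str]) -> str:
    """Deterministic family id: the lexicographically smallest member id."""
    return f"fam|{min(member_gene_ids)}"


@dataclass
class GeneFamily:
    """An ortholog group: strain -> member gene ids (paralogs allowed)."""

    family_id: str
    members: dict[str, list[str]]

    @property
    def n_strains(self) -> int:
        return len(self.members)

    @property
    def gene_ids(self) -> list[str]:
        return sorted(g for gs in self.members.values() for g in gs)

    @property
    def is_single_copy(self) -> bool:
        return all(len(gs) == 1 for gs in self.members.values())


class PresenceAbsenceMatrix:
    """Boolean strains x families matrix (presence of >= 1 member)."""

    def __init__(self, strains: Sequence[str], families: Sequence[str],
                 values: np.ndarray):
        values = np.asarray(values, dtype=bool)
        if values.shape != (len(strains), len(families)):
            raise ValueError("matrix shape does not match label lists")
        self.strains = list(strains)
        self.families = list(families)
        self.values = values

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(self.values, index=self.strains, columns=self.families)

    @classmethod
    def from_frame(cls, df: pd.DataFrame) -> "PresenceAbsenceMatrix":
        return cls(list(df.index), list(df.columns), df.to_numpy(dtype=bool))


# ---------------------------------------------------------------------------
# Pairwise identity

def _make_aligner() -> Align.PairwiseAligner:
    aligner = Align.PairwiseAligner()
    aligner.mode = "global"
    aligner.match_score = 1
    aligner.mismatch_score = 0
    aligner.open_gap_score = -1
    aligner.extend_gap_score = -1
    return aligner


_ALIGNER = _make_aligner()


def pairwise_identity(prot_a: str, prot_b: str) -> float:
    """Global-alignment identity of two proteins, in [0, 1].

    Needleman-Wunsch with match +1, mismatch 0, linear gap -1;
    identity = matches / alignment length. Computed on the
    lexicographically sorted pair so the result is exactly symmetric.
    """
    if not prot_a or not prot_b:
        raise ValueError("protein sequences must be non-empty")
    a, b = sorted((prot_a, prot_b))
    aln = _ALIGNER.align(a, b)[0]
    counts = aln.counts()
    return counts.identities / aln.length


def _hamming_identity(a: str, b: str) -> float:
    """Ungapped identity of equal-length strings; lower-bounds NW identity."""
    arr_a = np.frombuffer(a.encode(), dtype="S1")
    arr_b = np.frombuffer(b.encode(), dtype="S1")
    return float((arr_a == arr_b).mean())


# ---------------------------------------------------------------------------
# Candidate pair generation

def _kmer_candidate_pairs(proteins: Sequence[str], k: int, min_shared: int
                          ) -> list[tuple[int, int, int]]:
    """(shared_kmer_count, i, j) for pairs sharing >= min_shared k-mers."""
    vocab: dict[str, int] = {}
    rows, cols = [], []
    for i, p in enumerate(proteins):
        kmers = {p[j:j + k] for j in range(len(p) - k + 1)}
        for km in kmers:
            idx = vocab.setdefault(km, len(vocab))
            rows.append(i)
            cols.append(idx)
    if not vocab:
        return []
    mat = sparse.csr_matrix(
        (np.ones(len(rows), dtype=np.int32), (rows, cols)),
        shape=(len(proteins), len(vocab)))
    shared = sparse.triu(mat @ mat.T, k=1).tocoo()
    keep = shared.data >= min_shared
    return sorted(zip(shared.data[keep].tolist(),
                      shared.row[keep].tolist(),
                      shared.col[keep].tolist()),
                  key=lambda t: (-t[0], t[1], t[2]))


class _UnionFind:
    def __init__(self, n: int):
        self.parent = list(range(n))

    def find(self, x: int) -> int:
        while self.parent[x] != x:
            self.parent[x] = self.parent[self.parent[x]]
            x = self.parent[x]
        return x

    def union(self, a: int, b: int) -> None:
        ra, rb = self.find(a), self.find(b)
        if ra != rb:
            self.parent[max(ra, rb)] = min(ra, rb)


def build_gene_families(genes: Mapping[str, Sequence[GeneFeature]],
                        mode: str = "permissive",
                        identity_threshold: float | None = None,
                        k: int = KMER_K,
                        min_shared_kmers: int = DEFAULT_MIN_SHARED_KMERS,
                        use_prefilter: bool = True) -> list[GeneFamily]:
    """Cluster genes into ortholog families by single linkage.

    Parameters
    ----------
    genes : mapping strain_id -> gene features (with protein_seq set)
    mode : 'permissive' (T=0.50) or 'strict' (T=0.95)
    identity_threshold : overrides the mode's threshold if given
    use_prefilter : when False, align every pair (the brute-force path the
        k-mer pre-filter is checked against in the tests)

    Families are returned sorted by family id; every input gene belongs to
    exactly one family.
    """
    if mode not in ("permissive", "strict"):
        raise ValueError(f"unknown clustering mode {mode!r}")
    threshold = identity_threshold if identity_threshold is not None else (
        PERMISSIVE_IDENTITY if mode == "permissive" else STRICT_IDENTITY)

    flat: list[tuple[str, GeneFeature]] = []
    for strain in sorted(genes):
        for g in sorted(genes[strain], key=lambda g: g.gene_id):
            if not g.protein_seq:
                raise ValueError(f"gene {g.gene_id} has no protein sequence")
            flat.append((strain, g))
    n = len(flat)
    if n == 0:
        return []
    prots = [g.protein_seq for _, g in flat]

    if use_prefilter:
        pairs = _kmer_candidate_pairs(prots, k, min_shared_kmers)
    else:
        pairs = [(0, i, j) for i in range(n) for j in range(i + 1, n)]

    uf = _UnionFind(n)
    for _shared, i, j in pairs:
        if uf.find(i) == uf.find(j):
            continue
        a, b = prots[i], prots[j]
        if len(a) == len(b) and _hamming_identity(a, b) >= threshold:
            uf.union(i, j)
        elif pairwise_identity(a, b) >= threshold:
            uf.union(i, j)

    components: dict[int, list[int]] = {}
    for i in range(n):
        components.setdefault(uf.find(i), []).append(i)
    families = []
    for idxs in components.values():
        members: dict[str, list[str]] = {}
        for i in idxs:
            strain, g = flat[i]
            members.setdefault(strain, []).append(g.gene_id)
        for v in members.values():
            v.sort()
        fid = family_id_for(g_id for gs in members.values() for g_id in gs)
        families.append(GeneFamily(fid, members))
    families.sort(key=lambda f: f.family_id)
    return families


def presence_absence(families: Sequence[GeneFamily], strains: Sequence[str]
                     ) -> PresenceAbsenceMatrix:
    """Boolean strains x families matrix from one clustering result.

    A strain absent from every family yields an all-false row.
    """
    fam_ids = [f.family_id for f in families]
    values = np.zeros((len(strains), len(fam_ids)), dtype=bool)
    index = {s: i for i, s in enumerate(strains)}
    for j, fam in enumerate(families):
        for strain in fam.members:
            if strain in index:
                values[index[strain], j] = True
    return PresenceAbsenceMatrix(list(strains), fam_ids, values)
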