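"""Locating a multi-gene query cluster in annotated genomes.

The search applies the two selection steps used for the
*cysK-ctl-cysE* cluster: a candidate occurrence must (1) place homologs
of all query genes within a 20 kb window on one replicon and (2) show
the same gene order as the query cluster (exact reversal also accepted;
intervening non-query genes are permitted). Accepted occurrences are
classified by their bearing replicon (chromosome vs plasmid), the signal
used to argue plasmid-borne mobility.

Homology search runs against annotated proteomes rather than a
translated nucleotide search, so it assumes complete CDS annotation.
The window is measured as the genomic span from the leftmost hit start
to the rightmost hit end, inclusive — the strictest natural reading of
"within a window of 20 kbp". Strand uniformity is not required; gene
order alone decides step 2.
"""

from __future__ import annotations

import itertools
from dataclasses import dataclass
from typing import Mapping, Sequence

from .clustering import _hamming_identity, pairwise_identity
from .io_formats import GeneFeature, Replicon

DEFAULT_WINDOW_BP = 20_000
DEFAULT_MIN_IDENTITY = 0.4


@dataclass
class HomologHit:
    """One query protein matching one annotated gene."""

    query_id: str
    gene: GeneFeature
    identity: float


@dataclass
class ClusterHit:
    """A candidate cluster occurrence on one replicon with filter verdicts."""

    strain_id: str
    replicon_id: str
    replicon_kind: str
    ordered_genes: list[tuple[str, str, int, int, str]]  # (query, gene, start, end, strand)
    span_bp: int
    window_ok: bool
    order_ok: bool

    @property
    def accepted(self) -> bool:
        return self.window_ok and self.order_ok


def find_homologs(query_proteins: Mapping[str, str],
                  genome_genes: Sequence[GeneFeature],
                  min_identity: float = DEFAULT_MIN_IDENTITY,
                  prefilter: bool = True) -> list[HomologHit]:
    """All (query, gene) pairs with alignment identity >= ``min_identity``.

    A gene may hit several queries; every such pair is retained. Two exact
    shortcuts keep this fast: a gene shorter or longer than the query by
    more than the identity ratio can never reach the threshold (identity
    <= min(len)/max(len)), and an equal-length gene whose ungapped
    identity clears the threshold is a hit without full alignment (the
    reported identity is still the alignment identity). With
    ``prefilter`` (default), remaining candidates must share at least one
    amino-acid 5-mer with the query; homologs at the identity floor share
    several with overwhelming probability, unrelated proteins almost
    never do.
    """
    if not query_proteins:
        raise ValueError("query set must be non-empty")
    hits: list[HomologHit] = []
    query_kmers = {q: {p[i:i + 5] for i in range(len(p) - 4)}
                   for q, p in query_proteins.items()}
    for qid in sorted(query_proteins):
        qprot = query_proteins[qid]
        qlen = len(qprot)
        for gene in genome_genes:
            plen = len(gene.protein_seq)
            if min(qlen, plen) / max(qlen, plen) < min_identity:
                continue
            equal_len_pass = (qlen == plen and
                              _hamming_identity(qprot, gene.protein_seq)
                              >= min_identity)
            if prefilter and not equal_len_pass:
                kmers = {gene.protein_seq[i:i + 5]
                         for i in range(len(gene.protein_seq) - 4)}
                if not (kmers & query_kmers[qid]):
                    continue
            ident = pairwise_identity(qprot, gene.protein_seq)
            if ident >= min_identity:
                hits.append(HomologHit(qid, gene, ident))
    return hits


def _order_of(selection: Sequence[HomologHit]) -> tuple[tuple[str, ...], int, int]:
    """(query order by start, leftmost start, span) of one hit selection."""
    by_start = sorted(selection, key=lambda h: (h.gene.start, h.gene.gene_id))
    left = by_start[0].gene.start
    right = max(h.gene.end for h in by_start)
    return tuple(h.query_id for h in by_start), left, right - left + 1


def locate_cluster(hits: Sequence[HomologHit],
                   replicons: Mapping[str, Replicon],
                   query_order: Sequence[str],
                   window_bp: int = DEFAULT_WINDOW_BP,
                   report_rejected: bool = False,
                   max_combinations: int = 20_000) -> list[ClusterHit]:
    """Apply the window and gene-order filters per replicon.

    For every replicon with at least one hit per query, all selections of
    one hit per query are scored: ``window_ok`` iff the span (leftmost
    start to rightmost end) is <= ``window_bp``; ``order_ok`` iff the
    start-sorted query sequence equals ``query_order`` or its exact
    reversal. The minimal-span accepted selection is reported per
    replicon (ties broken by leftmost start, then replicon id orders the
    output). With ``report_rejected``, replicons whose best selection
    fails are reported too, with their failure verdicts.
    """
    query_order = tuple(query_order)
    by_replicon: dict[str, dict[str, list[HomologHit]]] = {}
    for h in hits:
        by_replicon.setdefault(h.gene.replicon_id, {}) \
                   .setdefault(h.query_id, []).append(h)

    out: list[ClusterHit] = []
    for rid in sorted(by_replicon):
        rep = replicons.get(rid)
        if rep is None:
            raise ValueError(f"hit on unknown replicon {rid!r}")
        per_query = by_replicon[rid]
        if any(q not in per_query for q in query_order):
            continue  # no complete candidate on this replicon
        pools = [sorted(per_query[q], key=lambda h: (h.gene.start, h.gene.gene_id))
                 for q in query_order]
        n_comb = 1
        for p in pools:
            n_comb *= len(p)
        if n_comb > max_combinations:
            # keep the best-identity hits per query; pathological inputs only
            pools = [sorted(p, key=lambda h: -h.identity)[:10] for p in pools]
        best = None  # (span, left, selection, window_ok, order_ok)
        for sel in itertools.product(*pools):
            order, left, span = _order_of(sel)
            window_ok = span <= window_bp
            order_ok = order == query_order or order == query_order[::-1]
            key = (not (window_ok and order_ok), span, left)
            if best is None or key < best[0]:
                best = (key, sel, window_ok, order_ok, span)
        _key, sel, window_ok, order_ok, span = best
        if not (window_ok and order_ok) and not report_rejected:
            continue
        by_start = sorted(sel, key=lambda h: (h.gene.start, h.gene.gene_id))
        out.append(ClusterHit(
            strain_id=rep.strain_id, replicon_id=rid, replicon_kind=rep.kind,
            ordered_genes=[(h.query_id, h.gene.gene_id, h.gene.start,
                            h.gene.end, h.gene.strand) for h in by_start],
            span_bp=span, window_ok=window_ok, order_ok=order_ok))
    return out


def classify_replicon(cluster_hit: ClusterHit,
                      replicons: Mapping[str, Replicon]) -> str:
    """The kind (chromosome/plasmid) of the replicon bearing the hit."""
    rep = replicons.get(cluster_hit.replicon_id)
    if rep is None:
        raise ValueError(f"unknown replicon {cluster_hit.replicon_id!r}")
    return rep.kind
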