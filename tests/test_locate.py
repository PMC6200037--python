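"""Cluster location: homolog search, window/order filters, replicon class."""

import numpy as np
import pytest

from genetrait.clustering import pairwise_identity
from genetrait.io_formats import GeneFeature, Replicon
from genetrait.locate import (HomologHit, classify_replicon, find_homologs,
                              locate_cluster)
from genetrait.simulate import CLUSTER_GENE_ORDER

AA = "ACDEFGHIKLMNPQRSTVWY"


def _gene(gene_id, start, end, replicon="r1", strand="+", prot="M" * 10):
    return GeneFeature(gene_id=gene_id, replicon_id=replicon, start=start,
                       end=end, strand=strand, protein_seq=prot)


def _hit(query, gene):
    return HomologHit(query, gene, 1.0)


REPL = {"r1": Replicon("r1", "st1", "chromosome", 10_000_000)}


class TestFindHomologs:
    def test_planted_version_b_hits_near_identity_one(self, dataset):
        truth = dataset.truth
        vb = sorted(s for s, v in truth.version_by_strain.items() if v == "B")
        hits = find_homologs(dataset.queries,
                             [g for s in vb for g in dataset.genes_by_strain[s]])
        by_strain_query = {(h.gene.gene_id, h.query_id): h.identity
                           for h in hits}
        for s in vb:
            for role in CLUSTER_GENE_ORDER:
                gid = next(g for g in truth.causal_gene_ids[role]
                           if g.startswith(s))
                assert by_strain_query[(gid, role)] > 0.99

    def test_random_protein_not_hit(self):
        rng = np.random.default_rng(0)
        query = {"q": "".join(AA[i] for i in rng.integers(0, 20, 150))}
        genes = [_gene(f"g{i}", 1, 450,
                       prot="".join(AA[j] for j in rng.integers(0, 20, 150)))
                 for i in range(30)]
        hits = find_homologs(query, genes)
        assert hits == []
        # confirmed against the exhaustive alignment identity
        assert all(pairwise_identity(query["q"], g.protein_seq) < 0.4
                   for g in genes)

    def test_gene_may_hit_multiple_queries(self):
        prot = "MKVLAWERTYIPASDF" * 5
        hits = find_homologs({"q1": prot, "q2": prot}, [_gene("g", 1, 240,
                                                              prot=prot)])
        assert sorted(h.query_id for h in hits) == ["q1", "q2"]

    def test_query_order_independence(self, small_dataset):
        genes = small_dataset.all_genes[:300]
        q = small_dataset.queries
        h1 = find_homologs(q, genes)
        h2 = find_homologs(dict(reversed(list(q.items()))), genes)
        key = lambda h: (h.query_id, h.gene.gene_id)
        assert sorted([(h.query_id, h.gene.gene_id, h.identity) for h in h1]) \
            == sorted([(h.query_id, h.gene.gene_id, h.identity) for h in h2])


class TestLocateCluster:
    ORDER = ["A", "B", "C"]

    def _hits(self, coords):
        return [_hit(q, _gene(f"g{q}", s, e)) for q, (s, e) in coords.items()]

    def test_in_window_in_order_accepted(self):
        hits = self._hits({"A": (1000, 1933), "B": (9000, 10139),
                           "C": (19000, 19668)})
        out = locate_cluster(hits, REPL, self.ORDER)
        assert len(out) == 1
        hit = out[0]
        assert hit.accepted and hit.span_bp == 18669
        assert [g[0] for g in hit.ordered_genes] == self.ORDER

    def test_window_violation_rejected(self):
        # correct order, but the span 1,000..22,668 exceeds the 20 kb window
        hits = self._hits({"A": (1000, 1933), "B": (9000, 10139),
                           "C": (22000, 22668)})
        out = locate_cluster(hits, REPL, self.ORDER, report_rejected=True)
        assert len(out) == 1
        assert out[0].span_bp == 21669
        assert not out[0].window_ok and out[0].order_ok and not out[0].accepted
        assert locate_cluster(hits, REPL, self.ORDER) == []

    def test_wrong_order_rejected(self):
        hits = self._hits({"B": (1000, 1933), "A": (9000, 10139),
                           "C": (19000, 19668)})
        out = locate_cluster(hits, REPL, self.ORDER, report_rejected=True)
        assert out[0].window_ok and not out[0].order_ok and not out[0].accepted

    def test_exact_reversal_accepted(self):
        hits = self._hits({"C": (1000, 1933), "B": (9000, 10139),
                           "A": (19000, 19668)})
        out = locate_cluster(hits, REPL, self.ORDER)
        assert len(out) == 1 and out[0].accepted

    def test_intervening_genes_permitted(self):
        hits = self._hits({"A": (1000, 1933), "B": (5000, 6139),
                           "C": (9000, 9668)})
        out = locate_cluster(hits, REPL, self.ORDER)
        assert out[0].accepted  # non-query genes between them are invisible

    def test_missing_query_no_candidate(self):
        hits = self._hits({"A": (1000, 1933), "B": (9000, 10139)})
        assert locate_cluster(hits, REPL, self.ORDER,
                              report_rejected=True) == []

    def test_minimal_span_selected_among_paralogs(self):
        hits = self._hits({"A": (1000, 1933), "B": (2000, 3139),
                           "C": (4000, 4668)})
        hits.append(_hit("C", _gene("gC2", 15000, 15668)))
        out = locate_cluster(hits, REPL, self.ORDER)
        assert len(out) == 1
        assert out[0].span_bp == 3669
        assert out[0].ordered_genes[-1][1] == "gC"

    def test_truth_recovery_and_replicon_class(self, dataset):
        hits = find_homologs(dataset.queries, dataset.all_genes)
        out = locate_cluster(hits, dataset.replicons,
                             list(CLUSTER_GENE_ORDER), report_rejected=True)
        accepted = {h.strain_id for h in out if h.accepted}
        assert accepted == dataset.truth.carrier_strains
        plasmid = {h.strain_id for h in out
                   if h.accepted and classify_replicon(h, dataset.replicons)
                   == "plasmid"}
        assert plasmid == dataset.truth.plasmid_strains
        rejected = {h.strain_id: h for h in out if not h.accepted}
        assert set(rejected) == dataset.truth.decoy_strains
        for h in rejected.values():  # each decoy fails its planted criterion
            assert h.window_ok != h.order_ok

    def test_reverse_complement_symmetry(self, dataset):
        """Remapping a replicon's coordinates to the reverse strand flips
        gene order to the exact reversal, which stays accepted."""
        strain = sorted(dataset.truth.plasmid_strains)[0]
        rep_id = f"{strain}_p1"
        rep = dataset.replicons[rep_id]
        genes = [g for g in dataset.genes_by_strain[strain]
                 if g.replicon_id == rep_id]
        L = rep.length_bp
        flipped = [GeneFeature(g.gene_id, rep_id, L - g.end + 1,
                               L - g.start + 1,
                               "-" if g.strand == "+" else "+",
                               g.product, g.protein_seq)
                   for g in genes]
        for gene_set in (genes, flipped):
            hits = find_homologs(dataset.queries, gene_set)
            out = locate_cluster(hits, dataset.replicons,
                                 list(CLUSTER_GENE_ORDER))
            assert len(out) == 1 and out[0].accepted
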