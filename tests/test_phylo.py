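"""Phylogenetics: concatenation, JC distances, NJ, bootstrap."""

import math

import numpy as np
import pytest
from skbio import DistanceMatrix, TreeNode

from genetrait.clustering import GeneFamily
from genetrait.io_formats import Alignment
from genetrait.phylo import (bipartitions, bootstrap_support,
                             concat_core_alignment, jc_distance, nj_tree)
from genetrait.simulate import simulate_tree


def _random_additive_dm(n_taxa, seed):
    """Distance matrix of path lengths on a random tree (exactly additive)."""
    tree, _ = simulate_tree(n_taxa, 0.4, seed=seed)
    rng = np.random.default_rng(seed + 1)
    for node in tree.traverse(include_self=False):
        node.length = float(rng.uniform(0.05, 0.3))
    names = sorted(t.name for t in tree.tips())
    d = np.zeros((n_taxa, n_taxa))
    tips = {t.name: t for t in tree.tips()}
    for i, a in enumerate(names):
        for j in range(i + 1, n_taxa):
            dist = tips[a].distance(tips[names[j]])
            d[i, j] = d[j, i] = dist
    return DistanceMatrix(d, ids=names), tree


class TestConcatCoreAlignment:
    STRAINS = ["s1", "s2", "s3"]

    def _families(self):
        return [
            GeneFamily("fam|a", {"s1": ["a1"], "s2": ["a2"], "s3": ["a3"]}),
            GeneFamily("fam|b", {"s1": ["b1"], "s2": ["b2"]}),          # not core
            GeneFamily("fam|c", {"s1": ["c1", "c1x"], "s2": ["c2"],
                                 "s3": ["c3"]}),                        # paralog
            GeneFamily("fam|d", {"s1": ["d1"], "s2": ["d2"], "s3": ["d3"]}),
        ]

    def test_single_copy_core_only_and_length(self):
        seqs = {"a1": "ATGAAA", "a2": "ATGAAC", "a3": "ATGAAG",
                "b1": "ATG", "b2": "ATG",
                "c1": "ATGCCC", "c1x": "ATGCCC", "c2": "ATGCCC", "c3": "ATGCCC",
                "d1": "ATGTTTAAA", "d2": "ATGTTTAAC", "d3": "ATGTTTAAG"}
        aln = concat_core_alignment(self._families(), self.STRAINS, seqs)
        assert aln.length == 6 + 9  # fam|a + fam|d only
        assert aln.rows[0] == "ATGAAA" + "ATGTTTAAA"

    def test_unequal_lengths_rejected(self):
        seqs = {"a1": "ATGAAA", "a2": "ATG", "a3": "ATGAAG",
                "d1": "ATGTTTAAA", "d2": "ATGTTTAAC", "d3": "ATGTTTAAG"}
        fams = [f for f in self._families() if f.family_id in ("fam|a", "fam|d")]
        with pytest.raises(ValueError, match="fam\\|a"):
            concat_core_alignment(fams, self.STRAINS, seqs)

    def test_no_core_rejected(self):
        with pytest.raises(ValueError, match="no single-copy core"):
            concat_core_alignment(
                [GeneFamily("fam|b", {"s1": ["b1"]})], self.STRAINS,
                {"b1": "ATG"})


class TestJcDistance:
    def test_identical_rows_zero(self):
        aln = Alignment(["a", "b"], ["ACGTACGT", "ACGTACGT"])
        assert jc_distance(aln)["a", "b"] == 0.0

    def test_closed_form_value(self):
        # 0.0347 observed difference -> 0.035530 JC distance
        n_diff, L = 347, 10_000
        row_a = "A" * L
        row_b = "C" * n_diff + "A" * (L - n_diff)
        d = jc_distance(Alignment(["a", "b"], [row_a, row_b]))
        expected = -0.75 * math.log(1 - 4 / 3 * (n_diff / L))
        assert d["a", "b"] == pytest.approx(expected, rel=1e-12)
        assert d["a", "b"] == pytest.approx(0.035528, abs=1e-6)

    def test_ambiguous_sites_excluded_pairwise(self):
        aln = Alignment(["a", "b"], ["ACGTN", "ACGTA"])
        assert jc_distance(aln)["a", "b"] == 0.0

    def test_saturation_rejected(self):
        aln = Alignment(["a", "b"], ["A" * 100, "C" * 100])
        with pytest.raises(ValueError, match="saturated"):
            jc_distance(aln)


class TestNjTree:
    def test_three_taxon_closed_form(self):
        dm = DistanceMatrix(np.array([[0, 0.3, 0.5],
                                      [0.3, 0, 0.6],
                                      [0.5, 0.6, 0]]), ids=list("ABC"))
        tree = nj_tree(dm)
        lengths = {t.name: t.length for t in tree.tips()}
        assert lengths["A"] == pytest.approx(0.5 * (0.3 + 0.5 - 0.6))
        assert lengths["B"] == pytest.approx(0.5 * (0.3 + 0.6 - 0.5))
        assert lengths["C"] == pytest.approx(0.5 * (0.5 + 0.6 - 0.3))

    def test_four_taxon_additive_split(self):
        d = np.array([[0.0, 0.2, 0.3, 0.3],
                      [0.2, 0.0, 0.3, 0.3],
                      [0.3, 0.3, 0.0, 0.2],
                      [0.3, 0.3, 0.2, 0.0]])
        tree = nj_tree(DistanceMatrix(d, ids=list("ABCD")))
        assert bipartitions(tree) == {frozenset({"C", "D"})}
        # additivity forces leaf branches 0.1 and an internal branch of 0.1
        internal = [n.length for n in tree.non_tips(include_self=False)]
        assert internal == [pytest.approx(0.1)]

    def test_consistency_on_random_additive_matrices(self):
        """NJ recovers the generating topology from exact path distances."""
        for seed in range(50):
            n = 5 + seed % 8  # 5..12 taxa
            dm, true_tree = _random_additive_dm(n, seed)
            assert bipartitions(nj_tree(dm)) == bipartitions(true_tree)

    def test_matches_reference_nj_topology(self):
        from skbio.tree import nj as skbio_nj
        dm, _ = _random_additive_dm(10, 123)
        ours = nj_tree(dm)
        ref = skbio_nj(dm)
        assert bipartitions(ours) == bipartitions(ref)

    def test_too_few_taxa_rejected(self):
        with pytest.raises(ValueError):
            nj_tree(DistanceMatrix(np.zeros((2, 2)), ids=["a", "b"]))


class TestBipartitions:
    def test_identifies_topology_uniquely(self):
        t1, _ = simulate_tree(9, 0.33, seed=4)
        t2, _ = simulate_tree(9, 0.33, seed=8)
        assert bipartitions(t1) == bipartitions(t1.copy())
        assert bipartitions(t1) != bipartitions(t2)


class TestBootstrap:
    def _evolved_alignment(self, n_taxa, length, seed, depth=0.1):
        """Alignment evolved on a random topology whose branches are all
        resolvable (0.005-0.015 subs/site), so bootstrap support is a
        property of the estimator rather than of edge-length luck."""
        from genetrait.simulate import evolve_sequence, random_cds
        rng = np.random.default_rng(seed)
        tree, _ = simulate_tree(n_taxa, 0.4, seed=seed)
        for node in tree.traverse(include_self=False):
            node.length = float(rng.uniform(0.05, 0.15))
        root_seq = random_cds(length // 3, rng)
        seqs = {}

        def rec(node, seq):
            for child in node.children:
                s = evolve_sequence(seq, (child.length or 0) * depth, rng)
                if child.is_tip():
                    seqs[child.name] = s
                else:
                    rec(child, s)

        rec(tree, root_seq)
        names = sorted(seqs)
        return Alignment(names, [seqs[n] for n in names]), tree

    def test_deterministic_given_seed(self):
        aln, _ = self._evolved_alignment(6, 1200, seed=2)
        r1 = bootstrap_support(aln, n_reps=50, seed=9)
        r2 = bootstrap_support(aln, n_reps=50, seed=9)
        assert r1.supports == r2.supports

    def test_degenerate_alignment_reports_no_informative_edges(self):
        aln = Alignment(["a", "b", "c", "d"], ["ACGT"] * 4)
        res = bootstrap_support(aln, n_reps=20, seed=0)
        assert res.informative == 0

    def test_true_bipartitions_strongly_supported(self):
        """Long alignment on a shallow tree: every true bipartition gets
        >= 80% support in at least 18 of 20 seeds."""
        good = 0
        for seed in range(20):
            aln, true_tree = self._evolved_alignment(8, 9999, seed=100 + seed)
            res = bootstrap_support(aln, n_reps=100, seed=seed)
            truth = bipartitions(true_tree)
            if bipartitions(res.tree) == truth and \
                    all(res.supports[bp] >= 80 for bp in truth):
                good += 1
        assert good >= 18

    def test_point_tree_matches_panel_structure(self, dataset,
                                                families_strict):
        """Version-A carriers (group 2) form a clade on the core tree."""
        nt = {g.gene_id: g.nt_seq for g in dataset.all_genes}
        aln = concat_core_alignment(families_strict, dataset.strains, nt)
        res = bootstrap_support(aln, n_reps=50, seed=1)
        va = frozenset(dataset.truth.plasmid_strains)
        parts = bipartitions(res.tree)
        leaves = frozenset(dataset.strains)
        key = va if min(leaves) not in va else frozenset(leaves - va)
        assert key in parts
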