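"""Generator contracts: tree shape, JC evolution, planted panel structure."""

import math

import numpy as np
import pytest

from genetrait.simulate import (CLUSTER_GENE_ORDER, SimConfig, TruthRecord,
                                evolve_sequence, random_cds,
                                simulate_pangenome, simulate_tree,
                                write_dataset)


class TestSimulateTree:
    def test_group_sizes_follow_rounding(self):
        tree, groups = simulate_tree(24, 0.25, seed=1)
        sizes = sorted([sum(1 for v in groups.values() if v == g)
                        for g in (1, 2)])
        assert sizes == [6, 18]
        assert len(list(tree.tips())) == 24

    def test_same_seed_same_tree(self):
        t1, _ = simulate_tree(10, 0.3, seed=7)
        t2, _ = simulate_tree(10, 0.3, seed=7)
        assert str(t1) == str(t2)

    @pytest.mark.parametrize("n", [5, 8, 24, 40])
    def test_leaf_count_and_ultrametricity(self, n):
        for seed in range(5):
            tree, groups = simulate_tree(n, 0.3, seed=seed)
            tips = list(tree.tips())
            assert len(tips) == n == len(groups)
            depths = [tip.accumulate_to_ancestor(tree) for tip in tips]
            assert max(depths) - min(depths) < 1e-9
            assert abs(max(depths) - 1.0) < 1e-9

    def test_group_too_small_rejected(self):
        with pytest.raises(ValueError, match="group"):
            simulate_tree(24, 0.01, seed=0)

    def test_root_split_partitions_groups(self):
        tree, groups = simulate_tree(20, 0.35, seed=3)
        side = {t.name for t in tree.children[1].tips()} \
            if not tree.children[1].is_tip() else {tree.children[1].name}
        assert side == {s for s, g in groups.items() if g == 2}


class TestEvolveSequence:
    def test_zero_branch_identity(self):
        rng = np.random.default_rng(0)
        seq = random_cds(100, rng)
        assert evolve_sequence(seq, 0.0, rng) == seq

    def test_jc_expected_divergence(self):
        """Observed difference matches (3/4)(1-exp(-4b/3)) within 3 SE."""
        rng = np.random.default_rng(42)
        b = 0.1
        L, reps = 1000, 100
        expected = 0.75 * (1 - math.exp(-4 * b / 3))
        anc = "".join("ACGT"[i] for i in rng.integers(0, 4, L))
        diffs = []
        for _ in range(reps):
            mut = evolve_sequence(anc, b, rng)
            diffs.append(sum(a != m for a, m in zip(anc, mut)) / L)
        se = math.sqrt(expected * (1 - expected) / (L * reps))
        assert abs(np.mean(diffs) - expected) < 3 * se

    def test_saturation_limit(self):
        rng = np.random.default_rng(1)
        anc = "".join("ACGT"[i] for i in rng.integers(0, 4, 3000))
        mut = evolve_sequence(anc, 50.0, rng)
        ident = sum(a == m for a, m in zip(anc, mut)) / len(anc)
        assert abs(ident - 0.25) < 0.05

    def test_negative_branch_rejected(self):
        with pytest.raises(ValueError):
            evolve_sequence("ACGT", -0.1, np.random.default_rng(0))


class TestSimulatedPanel:
    def test_default_growth_split(self, dataset):
        grows = dataset.phenotype["mean"] >= 1.0
        assert int(grows.sum()) == 16
        assert len(dataset.phenotype) == 24

    def test_phenotype_explained_by_carriage(self, dataset):
        growers = set(dataset.phenotype.loc[
            dataset.phenotype["mean"] >= 1.0, "strain"])
        assert growers == dataset.truth.carrier_strains

    def test_exception_strain_has_cysE_only(self, dataset):
        exc = dataset.truth.exception_strain
        assert exc is not None and exc not in dataset.truth.carrier_strains
        ids = {role: [g for g in dataset.truth.causal_gene_ids[role]
                      if g.startswith(exc)]
               for role in CLUSTER_GENE_ORDER}
        assert len(ids["cysE"]) == 1 and not ids["cysK"] and not ids["ctl"]

    def test_carriers_bear_ordered_cluster_within_window(self, dataset):
        """Independent coordinate scan: every carrier has the three causal
        genes in order within 20 kb on one replicon; no non-carrier does."""
        role_genes = {g: role for role in CLUSTER_GENE_ORDER
                      for g in dataset.truth.causal_gene_ids[role]}
        for strain in dataset.strains:
            placed = {}
            for g in dataset.genes_by_strain[strain]:
                if g.gene_id in role_genes:
                    placed[role_genes[g.gene_id]] = g
            if strain in dataset.truth.carrier_strains:
                assert set(placed) == set(CLUSTER_GENE_ORDER)
                assert len({g.replicon_id for g in placed.values()}) == 1
                ordered = sorted(placed.values(), key=lambda g: g.start)
                assert [role_genes[g.gene_id] for g in ordered] == \
                    list(CLUSTER_GENE_ORDER)
                span = ordered[-1].end - ordered[0].start + 1
                assert span <= 20_000
            elif strain == dataset.truth.exception_strain:
                assert set(placed) == {"cysE"}
            else:
                assert not placed

    def test_version_a_is_plasmid_borne(self, dataset):
        truth = dataset.truth
        assert truth.plasmid_strains == \
            {s for s, v in truth.version_by_strain.items() if v == "A"}
        for strain in truth.plasmid_strains:
            cluster_reps = {
                g.replicon_id for g in dataset.genes_by_strain[strain]
                if g.gene_id in {i for ids in truth.causal_gene_ids.values()
                                 for i in ids}}
            kinds = {dataset.replicons[r].kind for r in cluster_reps}
            assert kinds == {"plasmid"}

    def test_cluster_flanked_by_transposases(self, dataset):
        strain = sorted(dataset.truth.plasmid_strains)[0]
        genes = sorted(dataset.genes_by_strain[strain],
                       key=lambda g: (g.replicon_id, g.start))
        causal = {i for ids in dataset.truth.causal_gene_ids.values()
                  for i in ids}
        idx = [i for i, g in enumerate(genes) if g.gene_id in causal]
        lo, hi = min(idx), max(idx)
        assert "transposase" in genes[lo - 1].product
        assert "transposase" in genes[hi + 1].product

    def test_inter_version_protein_identity(self, seed_panel):
        """Realized A-vs-B protein identity within +-5 points of target."""
        from genetrait.clustering import pairwise_identity
        for panel in seed_panel:
            ds = panel.dataset
            prot = {g.gene_id: g.protein_seq for g in ds.all_genes}
            va = sorted(ds.truth.plasmid_strains)[0]
            vb = sorted(s for s, v in ds.truth.version_by_strain.items()
                        if v == "B")[0]
            for role in CLUSTER_GENE_ORDER:
                ids = ds.truth.causal_gene_ids[role]
                ga = next(g for g in ids if g.startswith(va))
                gb = next(g for g in ids if g.startswith(vb))
                ident = pairwise_identity(prot[ga], prot[gb])
                assert abs(ident - 0.70) <= 0.05

    def test_inconsistent_config_rejected(self):
        with pytest.raises(ValueError, match="decoys"):
            SimConfig(n_strains=10, cluster_carrier_count=9,
                      frac_group2=0.3, window_decoys=2).validate()

    def test_od_values_respect_threshold_rule(self, dataset):
        df = dataset.phenotype
        means = df[["od_rep1", "od_rep2", "od_rep3"]].mean(axis=1).round(3)
        assert np.allclose(means, df["mean"], atol=5e-4)


class TestWriteDataset:
    def test_file_count_and_force(self, small_dataset, tmp_path):
        paths = write_dataset(small_dataset, tmp_path / "d")
        assert len(paths) == 3 * len(small_dataset.strains) + 2
        with pytest.raises(FileExistsError):
            write_dataset(small_dataset, tmp_path / "d")
        write_dataset(small_dataset, tmp_path / "d", force=True)

    def test_truth_json_round_trip(self, small_dataset, tmp_path):
        write_dataset(small_dataset, tmp_path / "d")
        text = (tmp_path / "d" / "truth.json").read_text()
        back = TruthRecord.from_json(text)
        assert back.carrier_strains == small_dataset.truth.carrier_strains
        assert back.causal_family_ids == small_dataset.truth.causal_family_ids
        assert back.group_assignment == small_dataset.truth.group_assignment

    def test_same_seed_reproduces_bytes(self, tmp_path):
        cfg = SimConfig(n_strains=8, n_core=10, n_accessory=20,
                        cluster_carrier_count=5, frac_group2=0.25,
                        window_decoys=1, seed=3)
        d1 = simulate_pangenome(cfg)
        d2 = simulate_pangenome(cfg)
        p1 = write_dataset(d1, tmp_path / "a")
        write_dataset(d2, tmp_path / "b")
        for p in p1:
            assert p.read_bytes() == (tmp_path / "b" / p.name).read_bytes()
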