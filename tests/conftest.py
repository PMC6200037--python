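"""Shared fixtures: simulated panels at several scales.

The expensive session fixtures (a default-scale panel and a 20-seed
panel with clustering, association and location results) are shared by
the unit and acceptance tests so the whole suite simulates each panel
exactly once.
"""

from __future__ import annotations

from dataclasses import dataclass

import pytest

from genetrait import SimConfig, simulate_pangenome
from genetrait.association import match_traits
from genetrait.clustering import build_gene_families, presence_absence
from genetrait.locate import find_homologs, locate_cluster
from genetrait.simulate import CLUSTER_GENE_ORDER

N_PANEL_SEEDS = 20
PANEL_SEED_BASE = 1000


def growth_from_phenotype(dataset) -> dict[str, bool]:
    return {row.strain: row.mean >= 1.0
            for row in dataset.phenotype.itertuples()}


@pytest.fixture(scope="session")
def dataset():
    """One default-scale panel (24 strains, 16 carriers, 2 decoys)."""
    return simulate_pangenome(SimConfig(seed=11))


@pytest.fixture(scope="session")
def families_permissive(dataset):
    return build_gene_families(dataset.genes_by_strain, mode="permissive")


@pytest.fixture(scope="session")
def matrix_permissive(dataset, families_permissive):
    return presence_absence(families_permissive, dataset.strains)


@pytest.fixture(scope="session")
def families_strict(dataset):
    return build_gene_families(dataset.genes_by_strain, mode="strict")


@pytest.fixture(scope="session")
def small_dataset():
    """A small fast panel for IO/pipeline tests."""
    return simulate_pangenome(SimConfig(
        n_strains=10, n_core=30, n_accessory=80, cluster_carrier_count=6,
        frac_group2=0.3, window_decoys=2, seed=5))


@dataclass
class PanelResult:
    """Everything the recovery criteria need from one seed."""

    dataset: object
    families: list
    matrix: object
    association: list
    cluster_hits: list


def _analyse(seed: int) -> PanelResult:
    ds = simulate_pangenome(SimConfig(seed=seed))
    fams = build_gene_families(ds.genes_by_strain, mode="permissive")
    matrix = presence_absence(fams, ds.strains)
    assoc = match_traits(matrix, growth_from_phenotype(ds))
    hits = find_homologs(ds.queries, ds.all_genes)
    cluster_hits = locate_cluster(hits, ds.replicons,
                                  list(CLUSTER_GENE_ORDER),
                                  report_rejected=True)
    return PanelResult(ds, fams, matrix, assoc, cluster_hits)


@pytest.fixture(scope="session")
def seed_panel():
    """Twenty independent default-configuration panels, fully analysed."""
    return [_analyse(PANEL_SEED_BASE + i) for i in range(N_PANEL_SEEDS)]
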