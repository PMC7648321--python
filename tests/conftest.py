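"""Shared fixtures: the species tree, small simulated genes, topology sets."""

import pytest

from convscan.aa_likelihood import AAModelSpec
from convscan.synthetic_data import (
    SimulationConfig,
    fixture_species_tree,
    simulate_gene,
)
from convscan.treekit import one_move_neighbors


@pytest.fixture(scope="session")
def species_tree():
    return fixture_species_tree()


@pytest.fixture(scope="session")
def one_move_set(species_tree):
    return one_move_neighbors(species_tree)


@pytest.fixture(scope="session")
def aa_model():
    return AAModelSpec()


@pytest.fixture(scope="session")
def neutral_gene():
    cfg = SimulationConfig(n_genes=1, length_range=(150, 150), seed=11)
    aln, truth = simulate_gene(cfg, 0)
    return aln, truth, cfg


@pytest.fixture(scope="session")
def selected_gene_rap():
    cfg = SimulationConfig(
        n_genes=1,
        length_range=(300, 300),
        seed=7,
        class_mix={"SELECTED": 1.0},
        hypothesis="H_rap",
        omega2=4.0,
        p_selected=0.1,
    )
    aln, truth = simulate_gene(cfg, 0)
    return aln, truth, cfg
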