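import numpy as np
import pytest

from bqpipe.orthogroup_io import OrthogroupTable
from bqpipe.synthetic_data import (
    CategorySpec,
    ScenarioConfig,
    simulate_gene_content,
    simulate_species_tree,
)


@pytest.fixture
def mini_table() -> OrthogroupTable:
    """Two species, one OG with counts {A: 2, B: 1}."""
    return OrthogroupTable(
        species=["A", "B"],
        rows={"OG0": {"A": ["gA1", "gA2"], "B": ["gB1"]}},
    )


@pytest.fixture
def three_species_table() -> OrthogroupTable:
    return OrthogroupTable(
        species=["A", "B", "C"],
        rows={
            "OG0": {"A": ["a0"], "B": ["b0"], "C": ["c0"]},   # core
            "OG1": {"A": ["a1"], "B": ["b1"], "C": []},        # shared
            "OG2": {"A": ["a2a", "a2b"], "B": [], "C": []},    # unique
        },
        unassigned={"A": ["a_solo"], "B": [], "C": []},
    )


def small_scenario(seed: int = 0, **overrides) -> ScenarioConfig:
    params = dict(
        n_species=8,
        n_ppe=3,
        categories=[
            CategorySpec("KO00220", 30, "soluble", 1500.0),
            CategorySpec("KO00061", 30, "insoluble", 1.0),
            CategorySpec("KO03400", 30, "informational", 1500.0),
            CategorySpec("KO09100", 30, "neutral", 1.0),
        ],
        base_loss_rate=0.01,
        annotation_fraction=0.7,
        seed=seed,
        info_coupling=2.0,
        n_unassigned_per_species=10,
    )
    params.update(overrides)
    return ScenarioConfig(**params)


@pytest.fixture(scope="session")
def small_bundle():
    tree = simulate_species_tree(8, seed=11)
    return simulate_gene_content(tree, small_scenario(seed=11))


@pytest.fixture
def rng() -> np.random.Generator:
    return np.random.default_rng(1234)
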