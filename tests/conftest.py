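import numpy as np
import pytest

from phylorange import phylo, simulate


@pytest.fixture
def three_tip_tree():
    """((A:1,B:1):1,C:2); — the hand-checkable workhorse."""
    return phylo.parse_newick("((A:1,B:1):1,C:2);")


@pytest.fixture
def star_tree():
    """A 40-tip star tree of depth 3 (independent tips, known BM variance)."""
    parts = ",".join(f"s{i}:3" for i in range(40))
    return phylo.parse_newick(f"({parts});")


@pytest.fixture(scope="session")
def dataset_369():
    """One full-size synthetic dataset shared by read-only tests."""
    return simulate.simulate_range_dataset(simulate.SimulationConfig(seed=11))


def random_tree(n_tips: int, seed: int):
    return simulate.simulate_yule_tree(n_tips, 1.0, seed)
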