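import numpy as np
import pytest

from stratdec.dec_core import DECParams, StateSpace
from stratdec.geography import CodingTable, EpochModel, RangeState
from stratdec.tree_io import DatedTree


@pytest.fixture
def two_area_space():
    return StateSpace(2)


@pytest.fixture
def cherry_tree():
    return DatedTree.from_newick("(A:1,B:1);")


@pytest.fixture
def three_tip_tree():
    return DatedTree.from_newick("((A:1,B:1):1,C:2);")


@pytest.fixture
def cherry_coding():
    return CodingTable(
        "exemplar", {"A": RangeState(1, 2), "B": RangeState(1, 2)}
    )


@pytest.fixture
def flat_epochs_2():
    return EpochModel.uniform([105.0, 0.0], 2)


def random_dated_tree(rng: np.random.Generator, n_tips: int, root_age: float) -> DatedTree:
    """Random binary ultrametric tree: random coalescent-style joins with
    uniform-stick node ages.  Independent of the package's simulators."""
    from stratdec.tree_io import Node

    nodes = [Node(f"t{i}", 0.0) for i in range(n_tips)]
    ages = np.sort(rng.uniform(0, root_age, size=n_tips - 2)) if n_tips > 2 else np.array([])
    ages = list(ages) + [root_age]
    for age in ages:
        i, j = sorted(rng.choice(len(nodes), size=2, replace=False))
        parent = Node(None, float(age))
        parent.add_child(nodes[i])
        parent.add_child(nodes[j])
        nodes = [n for k, n in enumerate(nodes) if k not in (i, j)] + [parent]
    assert len(nodes) == 1
    return DatedTree(nodes[0])


def random_coding(rng: np.random.Generator, tree: DatedTree, n_areas: int) -> CodingTable:
    return CodingTable(
        "anything-goes",
        {
            t.label: RangeState(int(rng.integers(1, 1 << n_areas)), n_areas)
            for t in tree.tips()
        },
    )


def random_params(rng: np.random.Generator) -> DECParams:
    return DECParams(float(rng.uniform(0.02, 0.4)), float(rng.uniform(0.005, 0.2)))
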