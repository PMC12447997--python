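import numpy as np
import pytest

from treelfa import (
    DiagnosisMatrix,
    SimConfig,
    flat_tree,
    make_topics,
    make_tree,
    simulate_data,
)


@pytest.fixture(scope="session")
def small_sim():
    """A small two-topic dataset for fast sampler tests.

    600 individuals, 6 codes, two disjoint active sets of 3 codes at
    probability 0.3, symmetric Dirichlet(0.1); flat tree.
    """
    cfg = SimConfig(
        D=600,
        n_internal=2,
        children_per_internal=3,
        K=2,
        p_active=0.3,
        alpha_true=np.full(2, 0.1),
        active_sets=[["D1", "D2", "D3"], ["D4", "D5", "D6"]],
        seed=11,
    )
    topics = make_topics(cfg)
    data = simulate_data(topics, cfg.alpha_true, cfg.D, cfg.seed, cfg.codes)
    tree = make_tree(cfg.n_internal, cfg.children_per_internal)
    tree.align_terminals(data.codes)
    return data, tree, topics, cfg


@pytest.fixture()
def example_tree():
    """The worked example's tree: root -> C1..C5 -> D1..D15."""
    tree = make_tree(5, 3)
    return tree


@pytest.fixture()
def tiny_data():
    """A 4x2 handmade diagnosis matrix."""
    return DiagnosisMatrix(
        values=np.array([[1, 0], [0, 1], [1, 1], [0, 0]]), codes=["D1", "D2"]
    )


@pytest.fixture()
def tiny_tree(tiny_data):
    tree = flat_tree(tiny_data.codes)
    tree.align_terminals(tiny_data.codes)
    return tree
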