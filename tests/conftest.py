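"""Shared fixtures and independent oracles for the test suite."""

from __future__ import annotations

import itertools

import numpy as np
import pytest

from irtuning.phenotype_parsimony import PhenoTree, tree_from_string
from irtuning.tables_io import OdorPanel, ResponseMatrix


@pytest.fixture
def rng():
    return np.random.default_rng(20230517)


@pytest.fixture
def acid_panel():
    return OdorPanel.acids_only()


@pytest.fixture
def small_matrix(acid_panel):
    """Three sensilla, two species, one missing cell."""
    values = np.array(
        [
            [10.0, 40.0, 20.0, 5.0, 2.0, 1.0],
            [8.0, 35.0, 18.0, np.nan, 1.0, 0.0],
            [2.0, 5.0, 10.0, 30.0, 12.0, 4.0],
        ]
    )
    return ResponseMatrix.from_records(
        ["Dmel", "Dmel", "Dsec"], values, odors=acid_panel.odors
    )


def random_pheno_tree(rng: np.random.Generator, n_tips: int, n_states: int, allow_polytomy: bool = True) -> PhenoTree:
    """Random (possibly multifurcating) rooted tree with random tip states."""
    labels = [f"t{i}" for i in range(n_tips)]
    nodes = list(labels)
    while len(nodes) > 1:
        max_join = min(len(nodes), 3 if allow_polytomy else 2)
        k = int(rng.integers(2, max_join + 1)) if max_join > 2 else 2
        picks = rng.choice(len(nodes), size=k, replace=False)
        joined = "(" + ",".join(nodes[i] for i in sorted(picks)) + ")"
        nodes = [n for i, n in enumerate(nodes) if i not in set(picks)] + [joined]
    states = [f"S{i}" for i in range(n_states)]
    tip_states = {lab: states[int(rng.integers(0, n_states))] for lab in labels}
    return tree_from_string(nodes[0] + ";", tip_states)


def brute_force_parsimony(pheno: PhenoTree) -> int:
    """Exhaustive minimum over all internal-node state assignments."""
    tree = pheno.tree
    internal = [n for n in tree.preorder_node_iter() if not n.is_leaf()]
    states = sorted(pheno.states_alphabet())
    best = None
    for assignment in itertools.product(states, repeat=len(internal)):
        node_state = dict(zip(internal, assignment))
        for leaf in tree.leaf_node_iter():
            node_state[leaf] = pheno.tip_states[leaf.taxon.label]
        cost = sum(
            1
            for node in tree.preorder_node_iter()
            if node.parent_node is not None and node_state[node] != node_state[node.parent_node]
        )
        best = cost if best is None else min(best, cost)
    return best


def labeling_cost(pheno: PhenoTree, labeling: dict[str, str], ids_of=None) -> int:
    """Number of parent-child state differences in a full labeling keyed by node id."""
    from irtuning.phenotype_parsimony import _node_ids

    ids = _node_ids(pheno.tree)
    return sum(
        1
        for node in pheno.tree.preorder_node_iter()
        if node.parent_node is not None
        and labeling[ids[node]] != labeling[ids[node.parent_node]]
    )
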