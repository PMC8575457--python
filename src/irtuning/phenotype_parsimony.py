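"""Small parsimony on discrete tuning phenotypes over a species tree.

Each tip of a rooted drosophilid tree carries a tuning state (C2-sensor vs
C4-sensor, from the cluster assignment of its sensillum responses). The
minimum number of state changes and the per-node sets of optimal ancestral
states are computed with the multifurcation-safe generalization of Fitch
parsimony (Hartigan's algorithm): at each internal node the optimal set is
the states carried by the maximal number of children, and each node where a
child misses that majority contributes changes. All state-to-state changes
cost 1; branch lengths are parsed but ignored.
"""

from __future__ import annotations

import json
from dataclasses import dataclass
from pathlib import Path
from typing import Mapping

import dendropy
import pandas as pd


class TreeFormatError(ValueError):
    """Unparseable Newick or duplicate tip names."""


class MissingStateError(ValueError):
    """A tip has no phenotype state assigned."""


@dataclass
class PhenoTree:
    """Rooted tree plus tip -> phenotype state map."""

    tree: dendropy.Tree
    tip_states: dict[str, str]

    def __post_init__(self) -> None:
        tips = self.tip_labels()
        if len(set(tips)) != len(tips):
            raise TreeFormatError("tip names must be unique")
        if not tips:
            raise TreeFormatError("tree must have at least one tip")

    def tip_labels(self) -> list[str]:
        return [leaf.taxon.label for leaf in self.tree.leaf_node_iter()]

    def states_alphabet(self) -> set[str]:
        return set(self.tip_states.values())

    def with_states(self, tip_states: Mapping[str, str]) -> "PhenoTree":
        return PhenoTree(self.tree, dict(tip_states))


def read_newick(path: str | Path, tip_states: Mapping[str, str] | None = None) -> PhenoTree:
    """Read a rooted Newick tree; optional tip states joined afterwards."""
    try:
        tree = dendropy.Tree.get(
            path=str(path), schema="newick", preserve_underscores=True, suppress_internal_node_taxa=True
        )
    except Exception as err:  # dendropy raises several parse error types
        raise TreeFormatError(f"cannot parse Newick file {path}: {err}") from err
    return PhenoTree(tree, dict(tip_states or {}))


def tree_from_string(newick: str, tip_states: Mapping[str, str] | None = None) -> PhenoTree:
    try:
        tree = dendropy.Tree.get(
            data=newick, schema="newick", preserve_underscores=True, suppress_internal_node_taxa=True
        )
    except Exception as err:
        raise TreeFormatError(f"cannot parse Newick string: {err}") from err
    return PhenoTree(tree, dict(tip_states or {}))


def write_newick(pheno: PhenoTree, path: str | Path) -> Path:
    path = Path(path)
    path.write_text(pheno.tree.as_string(schema="newick", suppress_rooting=True))
    return path


def read_tip_states(path: str | Path) -> dict[str, str]:
    """Two-column CSV (tip, state) -> state map."""
    frame = pd.read_csv(path)
    if frame.shape[1] < 2:
        raise ValueError("tip-state CSV needs two columns: tip, state")
    return dict(zip(frame.iloc[:, 0].astype(str), frame.iloc[:, 1].astype(str)))


@dataclass
class ParsimonyResult:
    """Minimum change count, optimal state sets, and one optimal labeling.

    ``node_state_sets``/``labeling`` are keyed by node id: the taxon label at
    tips, a stable postorder ``node<i>`` id at internal nodes. ``changes``
    lists, for each parent-child state difference in the reported labeling,
    the set of tip labels descending from the changed child — a
    topology-level description of the branch carrying the change.
    """

    min_changes: int
    node_state_sets: dict[str, frozenset[str]]
    labeling: dict[str, str]
    changes: list[frozenset[str]]

    def to_json(self, path: str | Path) -> Path:
        path = Path(path)
        with open(path, "w") as fh:
            json.dump(
                {
                    "min_changes": self.min_changes,
                    "node_state_sets": {k: sorted(v) for k, v in self.node_state_sets.items()},
                    "labeling": self.labeling,
                    "changes": [sorted(c) for c in self.changes],
                },
                fh,
                indent=2,
            )
        return path


def _node_ids(tree: dendropy.Tree) -> dict[dendropy.Node, str]:
    ids: dict[dendropy.Node, str] = {}
    counter = 0
    for node in tree.postorder_node_iter():
        if node.is_leaf():
            ids[node] = node.taxon.label
        else:
            ids[node] = f"node{counter}"
            counter += 1
    return ids


def fitch(pheno: PhenoTree) -> ParsimonyResult:
    """Minimum-change ancestral reconstruction of tip phenotypes.

    Bottom-up pass: an internal node's optimal set holds the states present
    in the maximal number k of its children's sets, and the node adds
    (number of children - k) changes. On strictly bifurcating trees this is
    exactly Fitch's union/intersection count. Top-down pass: the root takes
    the lexicographically smallest state of its set; a child keeps its
    parent's state when that state is in the child's set, otherwise its own
    lexicographically smallest — one documented optimal labeling.
    """
    tree = pheno.tree
    ids = _node_ids(tree)
    state_sets: dict[dendropy.Node, frozenset[str]] = {}
    min_changes = 0

    for node in tree.postorder_node_iter():
        if node.is_leaf():
            label = node.taxon.label
            if label not in pheno.tip_states:
                raise MissingStateError(f"tip {label!r} has no phenotype state")
            state_sets[node] = frozenset([pheno.tip_states[label]])
            continue
        counts: dict[str, int] = {}
        for child in node.child_nodes():
            for state in state_sets[child]:
                counts[state] = counts.get(state, 0) + 1
        k = max(counts.values())
        state_sets[node] = frozenset(s for s, c in counts.items() if c == k)
        min_changes += len(node.child_nodes()) - k

    labeling: dict[str, str] = {}
    changes: list[frozenset[str]] = []
    root = tree.seed_node
    labeling[ids[root]] = min(state_sets[root])
    for node in tree.preorder_node_iter():
        if node is root:
            continue
        parent_state = labeling[ids[node.parent_node]]
        own = state_sets[node]
        state = parent_state if parent_state in own else min(own)
        labeling[ids[node]] = state
        if state != parent_state:
            changes.append(frozenset(leaf.taxon.label for leaf in node.leaf_iter()))

    return ParsimonyResult(
        min_changes=min_changes,
        node_state_sets={ids[n]: s for n, s in state_sets.items()},
        labeling=labeling,
        changes=changes,
    )
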