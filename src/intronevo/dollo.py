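"""Dollo parsimony reconstruction of intron presence.

Dollo parsimony allows at most one gain per site: presence is placed
exactly on the minimal connected subtree spanning all leaves with an
unambiguous presence (the MRCA of presence leaves and the paths
connecting them).  The single gain sits on the edge into that MRCA (or
at the root when the MRCA is the root); a loss is counted on every
edge leaving the presence subtree toward at least one unambiguous
absence.  Ambiguous ('*') leaves impose no constraint: they join the
presence subtree only when they lie on a path between presence leaves,
and subtrees consisting solely of ambiguous leaves contribute no loss.

This is the classical baseline the probabilistic reconstructions are
compared against; because it anchors every intron's origin at the MRCA
of its extant carriers, it systematically misdates introns whose
carriers span less of the tree than their true history did.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .profiles import ABSENT, PRESENT, ProfileTable
from .trees import SpeciesTree


class DolloError(ValueError):
    pass


@dataclass
class DolloHistory:
    """Dollo labeling for one site: presence set, gain edge, loss edges."""

    labels: np.ndarray        # (n_nodes,) in {0,1}
    gain_node: int            # child node of the gain edge (MRCA of presence)
    loss_nodes: list[int]     # child nodes of loss edges


def dollo_reconstruct(column: np.ndarray | list, tree: SpeciesTree,
                      species: list[str] | None = None) -> DolloHistory:
    """Dollo labeling of one column (codes 0/1/2, '*'→2).

    Requires at least one unambiguous presence (all-absent columns are
    filtered upstream).
    """
    species = species or tree.leaf_names()
    col = np.asarray(column, dtype=np.int8)
    obs = np.full(tree.n_nodes, -1, dtype=np.int8)
    for s, c in zip(species, col):
        obs[tree.leaf_index(s)] = c
    present_leaves = [u for u in tree.leaves() if obs[u] == PRESENT]
    if not present_leaves:
        raise DolloError("column has no unambiguous presence")
    mrca = tree.mrca(present_leaves)
    labels = np.zeros(tree.n_nodes, dtype=np.int8)
    for u in present_leaves:
        v = u
        while v != mrca:
            labels[v] = 1
            v = tree.parent[v]
    labels[mrca] = 1
    # losses: edges out of the presence subtree toward an unambiguous 0
    has_zero = np.zeros(tree.n_nodes, dtype=bool)
    for u in tree.postorder():
        if tree.is_leaf(u):
            has_zero[u] = obs[u] == ABSENT
        else:
            has_zero[u] = any(has_zero[c] for c in tree.children[u])
    loss_nodes = [
        v for v in tree.nonroot()
        if labels[tree.parent[v]] == 1 and labels[v] == 0 and has_zero[v]
    ]
    return DolloHistory(labels=labels, gain_node=mrca, loss_nodes=loss_nodes)


def dollo_counts(table: ProfileTable, tree: SpeciesTree
                 ) -> tuple[dict[str, int], dict[str, tuple[int, int]]]:
    """Sum Dollo reconstructions over all columns.

    Returns per-node presence counts and per-edge (gains, losses)
    tallies keyed by node name; tallies are column-order invariant.
    """
    counts = np.zeros(tree.n_nodes, dtype=np.int64)
    gains = np.zeros(tree.n_nodes, dtype=np.int64)
    losses = np.zeros(tree.n_nodes, dtype=np.int64)
    tbl = table.reorder_species(tree.leaf_names())
    for j in range(tbl.n_sites):
        h = dollo_reconstruct(tbl.entries[:, j], tree)
        counts += h.labels
        if h.gain_node != tree.root:
            gains[h.gain_node] += 1
        for v in h.loss_nodes:
            losses[v] += 1
    node_counts = {tree.names[u]: int(counts[u]) for u in range(tree.n_nodes)}
    edge_events = {tree.names[v]: (int(gains[v]), int(losses[v]))
                   for v in tree.nonroot()}
    return node_counts, edge_events
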