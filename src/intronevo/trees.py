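"""Rooted species trees with named internal nodes.

The tree is the fixed scaffold of the analysis: every edge is identified
with its child node and carries its own gain/loss intensities (model
parameters, not tree metadata), so branch lengths found in Newick input
are deliberately discarded.  Multifurcations are allowed; the canonical
empirical tree has a trifurcating root (the unresolved split between the
eukaryotic supergroups).
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import dendropy
import numpy as np

logger = logging.getLogger(__name__)


class TreeError(ValueError):
    """Raised for malformed or inconsistent tree input."""


@dataclass
class SpeciesTree:
    """Rooted, possibly multifurcating tree in postorder array form.

    Nodes are indexed ``0..n_nodes-1`` in postorder (every child precedes
    its parent; the root is last).  An edge is identified with its child
    node, so "edge u" means the branch from ``parent[u]`` down to ``u``.

    Attributes
    ----------
    names : list of str
        Node names; leaf names come from the input, internal nodes are
        auto-named ``anc<preorder index>`` when the input has no label.
    parent : numpy.ndarray of int
        Parent index per node; ``-1`` for the root.
    children : list of list of int
        Child indices per node; empty for leaves.
    """

    names: list[str]
    parent: np.ndarray
    children: list[list[int]]
    _leaf_index: dict[str, int] = field(default_factory=dict, repr=False)

    def __post_init__(self) -> None:
        self._validate()
        self._leaf_index = {self.names[i]: i for i in self.leaves()}

    # -- construction ------------------------------------------------

    @classmethod
    def from_dendropy(cls, dtree: dendropy.Tree) -> "SpeciesTree":
        nodes = list(dtree.postorder_node_iter())
        index = {id(nd): i for i, nd in enumerate(nodes)}
        # preorder numbering for deterministic internal auto-names
        pre = {id(nd): i for i, nd in enumerate(dtree.preorder_node_iter())}
        names: list[str] = []
        parent = np.full(len(nodes), -1, dtype=np.int64)
        children: list[list[int]] = [[] for _ in nodes]
        seen: set[str] = set()
        for i, nd in enumerate(nodes):
            if nd.is_leaf():
                label = nd.taxon.label if nd.taxon is not None else nd.label
                if not label:
                    raise TreeError("leaf without a name")
            else:
                label = nd.label or f"anc{pre[id(nd)]}"
            if label in seen:
                raise TreeError(f"duplicate node name {label!r}")
            seen.add(label)
            names.append(label)
            if nd.parent_node is not None:
                parent[i] = index[id(nd.parent_node)]
                children[index[id(nd.parent_node)]].append(i)
        return cls(names=names, parent=parent, children=children)

    @classmethod
    def from_newick(cls, newick: str) -> "SpeciesTree":
        dtree = dendropy.Tree.get(
            data=newick, schema="newick", suppress_internal_node_taxa=True
        )
        if any(e.length is not None for e in dtree.edges()):
            logger.warning(
                "Newick branch lengths ignored: edge lengths are model "
                "parameters here, not tree metadata"
            )
        return cls.from_dendropy(dtree)

    # -- queries -----------------------------------------------------

    @property
    def n_nodes(self) -> int:
        return len(self.names)

    @property
    def root(self) -> int:
        return self.n_nodes - 1

    def leaves(self) -> list[int]:
        return [i for i, ch in enumerate(self.children) if not ch]

    @property
    def n_leaves(self) -> int:
        return len(self.leaves())

    def leaf_names(self) -> list[str]:
        return [self.names[i] for i in self.leaves()]

    def leaf_index(self, name: str) -> int:
        return self._leaf_index[name]

    def is_leaf(self, u: int) -> bool:
        return not self.children[u]

    def postorder(self) -> range:
        return range(self.n_nodes)

    def preorder(self) -> range:
        return range(self.n_nodes - 1, -1, -1)

    def nonroot(self) -> list[int]:
        return [u for u in range(self.n_nodes) if u != self.root]

    def subtree_leaves(self, u: int) -> list[int]:
        """Leaf indices in the subtree rooted at u."""
        out, stack = [], [u]
        while stack:
            v = stack.pop()
            if self.is_leaf(v):
                out.append(v)
            else:
                stack.extend(self.children[v])
        return out

    def mrca(self, nodes: list[int]) -> int:
        """Most recent common ancestor of a nonempty node set."""
        if not nodes:
            raise TreeError("mrca of empty set")
        paths = []
        for u in nodes:
            path = []
            v = u
            while v != -1:
                path.append(v)
                v = self.parent[v]
            paths.append(path[::-1])  # root .. u
        k = 0
        while all(len(p) > k for p in paths) and len({p[k] for p in paths}) == 1:
            k += 1
        return paths[0][k - 1]

    # -- output ------------------------------------------------------

    def to_newick(self) -> str:
        def render(u: int) -> str:
            if self.is_leaf(u):
                return self.names[u]
            inner = ",".join(render(c) for c in self.children[u])
            return f"({inner}){self.names[u]}"

        return render(self.root) + ";"

    def _validate(self) -> None:
        n = len(self.names)
        roots = [i for i in range(n) if self.parent[i] == -1]
        if len(roots) != 1:
            raise TreeError(f"expected exactly one root, found {len(roots)}")
        if roots[0] != n - 1:
            raise TreeError("nodes must be in postorder with the root last")
        for u in range(n):
            for c in self.children[u]:
                if c >= u:
                    raise TreeError("children must precede parents (postorder)")
                if self.parent[c] != u:
                    raise TreeError("parent/children arrays inconsistent")


def read_tree(path: str) -> SpeciesTree:
    """Read a rooted Newick tree; branch lengths are ignored.

    Internal nodes without labels are auto-named ``anc<preorder index>``.
    """
    with open(path) as fh:
        text = fh.read()
    stripped = text.strip()
    if not stripped.endswith(";"):
        raise TreeError(f"{path}: not a terminated Newick string")
    extra = stripped.split(";", 1)[1].strip()
    if extra:
        raise TreeError(f"{path}: trailing content after Newick tree: {extra[:30]!r}")
    try:
        return SpeciesTree.from_newick(stripped)
    except (dendropy.utility.error.DataParseError, ValueError) as exc:
        if isinstance(exc, TreeError):
            raise
        raise TreeError(f"{path}: Newick parse failure: {exc}") from exc


def write_tree(tree: SpeciesTree, path: str) -> None:
    with open(path, "w") as fh:
        fh.write(tree.to_newick() + "\n")
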