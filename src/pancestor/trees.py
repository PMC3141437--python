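"""Rooted phylogenies for pan-genome analysis.

Thin wrapper around :mod:`dendropy` that enforces the contracts the rest of
the package relies on (unique tip labels, rooted trees, internal nodes with
at least two children) and exposes the tree as flat postorder arrays, which
is the form the vectorised parsimony and contrast algorithms consume.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import dendropy


class TreeError(ValueError):
    """Raised for malformed or contract-violating trees."""


@dataclass
class TreeIndex:
    """Flat postorder view of a rooted tree.

    Nodes are numbered 0..n_nodes-1 in postorder, so every child index is
    smaller than its parent's and the root is last.
    """

    n_nodes: int
    n_tips: int
    parent: list  # parent index, -1 for root
    children: list  # list of child-index lists, [] for tips
    length: list  # branch length above each node (None if absent); root None
    labels: list  # tip label for tips, internal label or auto id otherwise
    is_tip: list
    tip_index: dict = field(default_factory=dict)  # tip label -> node index

    @property
    def root(self) -> int:
        return self.n_nodes - 1


class Phylogeny:
    """A rooted phylogeny whose tips map to genome ids."""

    def __init__(self, tree: dendropy.Tree):
        self._tree = tree
        self._validate()
        self._index: TreeIndex | None = None

    # -- construction -----------------------------------------------------

    @classmethod
    def from_newick(cls, newick: str) -> "Phylogeny":
        try:
            tree = dendropy.Tree.get(
                data=newick,
                schema="newick",
                preserve_underscores=True,
                suppress_internal_node_taxa=True,
            )
        except Exception as exc:  # dendropy raises several parse error types
            raise TreeError(f"could not parse Newick tree: {exc}") from exc
        return cls(tree)

    @classmethod
    def from_path(cls, path) -> "Phylogeny":
        with open(path, "r", encoding="utf-8") as fh:
            return cls.from_newick(fh.read())

    def _validate(self) -> None:
        seen = set()
        for leaf in self._tree.leaf_node_iter():
            label = _leaf_label(leaf)
            if label is None:
                raise TreeError("tree has an unlabelled tip")
            if label in seen:
                raise TreeError(f"duplicate tip label {label!r}")
            seen.add(label)
        if len(seen) < 2:
            raise TreeError("tree must have at least two tips")
        for node in self._tree.preorder_node_iter():
            if not node.is_leaf() and len(node.child_nodes()) == 1:
                # collapse unifurcations silently only at the root seed node
                raise TreeError("internal nodes must have >= 2 children")
        for node in self._tree.preorder_node_iter():
            if node.edge.length is not None and node.edge.length < 0:
                raise TreeError("negative branch length")

    # -- basic accessors --------------------------------------------------

    @property
    def tip_labels(self) -> list:
        return [_leaf_label(l) for l in self._tree.leaf_node_iter()]

    @property
    def n_tips(self) -> int:
        return sum(1 for _ in self._tree.leaf_node_iter())

    @property
    def dendropy_tree(self) -> dendropy.Tree:
        return self._tree

    def is_binary(self) -> bool:
        return all(
            len(n.child_nodes()) == 2
            for n in self._tree.preorder_internal_node_iter()
        )

    def has_branch_lengths(self) -> bool:
        return all(
            n.edge.length is not None
            for n in self._tree.preorder_node_iter()
            if n.parent_node is not None
        )

    # -- serialisation ----------------------------------------------------

    def to_newick(self) -> str:
        s = self._tree.as_string(
            schema="newick",
            unquoted_underscores=True,
            suppress_rooting=True,
        )
        return s.strip() + "\n"

    def write(self, path) -> None:
        with open(path, "w", encoding="utf-8") as fh:
            fh.write(self.to_newick())

    # -- indexed view ------------------------------------------------------

    def index(self) -> TreeIndex:
        """Postorder array view; cached, do not mutate the tree afterwards."""
        if self._index is None:
            self._index = self._build_index()
        return self._index

    def _build_index(self) -> TreeIndex:
        nodes = list(self._tree.postorder_node_iter())
        pos = {id(n): i for i, n in enumerate(nodes)}
        parent, children, length, labels, is_tip = [], [], [], [], []
        tip_index = {}
        n_internal = 0
        for i, node in enumerate(nodes):
            p = node.parent_node
            parent.append(pos[id(p)] if p is not None else -1)
            children.append([pos[id(c)] for c in node.child_nodes()])
            length.append(node.edge.length if p is not None else None)
            if node.is_leaf():
                label = _leaf_label(node)
                is_tip.append(True)
                tip_index[label] = i
            else:
                n_internal += 1
                label = node.label if node.label else f"node{n_internal}"
                is_tip.append(False)
            labels.append(label)
        return TreeIndex(
            n_nodes=len(nodes),
            n_tips=len(tip_index),
            parent=parent,
            children=children,
            length=length,
            labels=labels,
            is_tip=is_tip,
            tip_index=tip_index,
        )


def _leaf_label(leaf) -> str | None:
    if leaf.taxon is not None and leaf.taxon.label:
        return leaf.taxon.label
    return leaf.label
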