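"""Rooted lineage trees and their serialization.

A lineage tree is a rooted tree whose leaves are profiled entities
(cells, barcodes, or expression clusters depending on the inference
stage). The root represents the founding cell, which carries no
recorder edit. During tree search the tree is strictly binary;
afterwards, unsupported internal branchings can be contracted into
multifurcations (:func:`collapse_unsupported`).

Newick is the external topology format; an annotated JSON format
round-trips the full per-node model state bit-exactly.
"""

from __future__ import annotations

import json
from typing import Callable, Iterator, Optional

import dendropy

__all__ = [
    "Node",
    "LineageTree",
    "NewickError",
    "read_tree",
    "write_tree",
    "collapse_unsupported",
]


class NewickError(ValueError):
    """Raised when a Newick string cannot be parsed."""


class Node:
    """A tree node with parent/children links and an annotation dict."""

    __slots__ = ("name", "parent", "children", "annot")

    def __init__(self, name: Optional[str] = None):
        self.name = name
        self.parent: Optional[Node] = None
        self.children: list[Node] = []
        self.annot: dict = {}

    @property
    def is_leaf(self) -> bool:
        return not self.children

    def add_child(self, child: "Node") -> "Node":
        child.parent = self
        self.children.append(child)
        return child

    def detach(self) -> "Node":
        """Remove this node (with its subtree) from its parent."""
        if self.parent is not None:
            self.parent.children.remove(self)
            self.parent = None
        return self

    def __repr__(self) -> str:  # pragma: no cover - debugging aid
        kind = "leaf" if self.is_leaf else f"internal({len(self.children)})"
        return f"<Node {self.name!r} {kind}>"


class LineageTree:
    """A rooted lineage tree.

    Parameters
    ----------
    root : Node
        Root of the tree. The root is assumed to carry no marker
        (its ancestral state is 0 for every synthetic marker).
    """

    def __init__(self, root: Node):
        self.root = root

    # ---- traversal ------------------------------------------------
    def preorder(self) -> Iterator[Node]:
        stack = [self.root]
        while stack:
            node = stack.pop()
            yield node
            stack.extend(reversed(node.children))

    def postorder(self) -> Iterator[Node]:
        out: list[Node] = []
        stack = [self.root]
        while stack:
            node = stack.pop()
            out.append(node)
            stack.extend(node.children)
        return iter(reversed(out))

    def leaves(self) -> list[Node]:
        return [n for n in self.preorder() if n.is_leaf]

    def leaf_names(self) -> list[str]:
        return [n.name for n in self.leaves()]

    def internal_nodes(self) -> list[Node]:
        return [n for n in self.preorder() if not n.is_leaf]

    def edges(self) -> Iterator[tuple[Node, Node]]:
        for node in self.preorder():
            for child in node.children:
                yield node, child

    # ---- queries --------------------------------------------------
    @property
    def n_leaves(self) -> int:
        return len(self.leaves())

    def is_binary(self) -> bool:
        return all(len(n.children) in (0, 2) for n in self.internal_nodes())

    def leaves_under(self, node: Node) -> list[Node]:
        out = []
        stack = [node]
        while stack:
            n = stack.pop()
            if n.is_leaf:
                out.append(n)
            else:
                stack.extend(n.children)
        return out

    def topology_hash(self) -> str:
        """Canonical string identifying the rooted topology + leaf names."""

        def key(node: Node) -> str:
            if node.is_leaf:
                return node.name or ""
            return "(" + ",".join(sorted(key(c) for c in node.children)) + ")"

        return key(self.root)

    # ---- construction / copying -----------------------------------
    def copy(self, with_annotations: bool = False) -> "LineageTree":
        def clone(node: Node) -> Node:
            new = Node(node.name)
            if with_annotations:
                new.annot = dict(node.annot)
            for c in node.children:
                new.add_child(clone(c))
            return new

        return LineageTree(clone(self.root))

    @classmethod
    def from_leaf_names(
        cls, names: list[str], attach_order: Optional[list[int]] = None
    ) -> "LineageTree":
        """Build a binary tree by sequential leaf attachment.

        ``attach_order[i]`` selects the edge (by index over the current
        edge list, with the root's "virtual" edge counted first) onto
        which leaf ``i`` (for i >= 2) is attached. With ``None``, a
        caterpillar is built.
        """
        if not names:
            raise ValueError("need at least one leaf name")
        if len(names) == 1:
            return cls(Node(names[0]))
        root = Node()
        root.add_child(Node(names[0]))
        root.add_child(Node(names[1]))
        tree = cls(root)
        for i, name in enumerate(names[2:], start=2):
            nodes = [n for n in tree.preorder() if n is not tree.root]
            if attach_order is None:
                target = nodes[0]
            else:
                target = nodes[attach_order[i] % len(nodes)]
            _insert_leaf_on_edge(tree, target, Node(name))
        return tree


def _insert_leaf_on_edge(tree: LineageTree, edge_child: Node, leaf: Node) -> None:
    """Subdivide the edge above ``edge_child`` and hang ``leaf`` there."""
    parent = edge_child.parent
    mid = Node()
    idx = parent.children.index(edge_child)
    parent.children[idx] = mid
    mid.parent = parent
    mid.add_child(edge_child)
    edge_child.parent = mid
    mid.add_child(leaf)


def suppress_unary(tree: LineageTree) -> None:
    """Contract every internal node with exactly one child, in place."""
    for node in list(tree.postorder()):
        if len(node.children) == 1 and node.parent is not None:
            child = node.children[0]
            parent = node.parent
            idx = parent.children.index(node)
            parent.children[idx] = child
            child.parent = parent
    while len(tree.root.children) == 1 and not tree.root.is_leaf:
        new_root = tree.root.children[0]
        new_root.parent = None
        tree.root = new_root


# ---- Newick -------------------------------------------------------

def _to_newick(node: Node) -> str:
    if node.is_leaf:
        return node.name or ""
    return "(" + ",".join(_to_newick(c) for c in node.children) + ")" + (node.name or "")


def write_newick(tree: LineageTree) -> str:
    return _to_newick(tree.root) + ";"


def read_newick(text: str) -> LineageTree:
    try:
        dtree = dendropy.Tree.get(
            data=text,
            schema="newick",
            suppress_internal_node_taxa=True,
            preserve_underscores=True,
        )
    except Exception as exc:
        raise NewickError(f"malformed Newick: {exc}") from exc

    def convert(dnode) -> Node:
        node = Node(dnode.taxon.label if dnode.taxon is not None else dnode.label)
        for dchild in dnode.child_nodes():
            node.add_child(convert(dchild))
        return node

    return LineageTree(convert(dtree.seed_node))


# ---- annotated JSON ----------------------------------------------

def _node_to_dict(node: Node) -> dict:
    d: dict = {"name": node.name}
    if node.annot:
        d["annot"] = _jsonable(node.annot)
    if node.children:
        d["children"] = [_node_to_dict(c) for c in node.children]
    return d


def _jsonable(obj):
    import numpy as np

    if isinstance(obj, dict):
        return {k: _jsonable(v) for k, v in obj.items()}
    if isinstance(obj, (list, tuple)):
        return [_jsonable(v) for v in obj]
    if isinstance(obj, (set, frozenset)):
        return sorted(_jsonable(v) for v in obj)
    if isinstance(obj, np.integer):
        return int(obj)
    if isinstance(obj, np.floating):
        return float(obj)
    if isinstance(obj, np.ndarray):
        return obj.tolist()
    return obj


def _node_from_dict(d: dict) -> Node:
    node = Node(d.get("name"))
    node.annot = dict(d.get("annot", {}))
    for cd in d.get("children", []):
        node.add_child(_node_from_dict(cd))
    return node


def write_json(tree: LineageTree) -> str:
    return json.dumps({"format": "lineageml-tree", "root": _node_to_dict(tree.root)})


def read_json(text: str) -> LineageTree:
    obj = json.loads(text)
    if "root" not in obj:
        raise ValueError("not an annotated lineage-tree JSON document")
    return LineageTree(_node_from_dict(obj["root"]))


def write_tree(tree: LineageTree, fmt: str = "newick") -> str:
    """Serialize a tree to ``newick`` (topology) or ``json`` (full state)."""
    if fmt == "newick":
        return write_newick(tree)
    if fmt == "json":
        return write_json(tree)
    raise ValueError(f"unknown tree format: {fmt!r}")


def read_tree(text: str, fmt: str = "newick") -> LineageTree:
    if fmt == "newick":
        return read_newick(text)
    if fmt == "json":
        return read_json(text)
    raise ValueError(f"unknown tree format: {fmt!r}")


# ---- collapsing unsupported branchings ---------------------------

def collapse_unsupported(
    tree: LineageTree,
    gains: Optional[Callable[[Node], int]] = None,
    is_cut: Optional[Callable[[Node], bool]] = None,
) -> LineageTree:
    """Contract internal edges not supported by any marker gain.

    An internal edge (parent, child) is contracted when no marker
    transitions 0 -> 1 on it and the child is not flagged as a cluster
    cut. ``gains`` maps a node to the number of markers gained on the
    edge above it (default: ``len(node.annot.get("gained", ()))``);
    ``is_cut`` flags cluster-cut nodes (default: the ``"cut"``
    annotation). The leaf set is never changed.
    """
    if gains is None:
        gains = lambda n: len(n.annot.get("gained", ()))
    if is_cut is None:
        is_cut = lambda n: bool(n.annot.get("cut", False))

    out = tree.copy(with_annotations=True)
    for node in list(out.postorder()):
        if node.is_leaf or node.parent is None:
            continue
        if gains(node) == 0 and not is_cut(node):
            parent = node.parent
            idx = parent.children.index(node)
            parent.children[idx : idx + 1] = node.children
            for c in node.children:
                c.parent = parent
    return out
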