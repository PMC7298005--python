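import itertools

import numpy as np
import pytest

from lineageml.tree import LineageTree, Node


def enumerate_rooted_trees(labels):
    """All rooted binary topologies on the given leaf labels.

    Built by inserting each leaf on every edge (plus above the root)
    of every smaller tree; yields 1, 1, 3, 15, 105, 945 trees for
    1..6 leaves.
    """
    labels = list(labels)

    def insert_all(tree: LineageTree, name: str):
        out = []
        edges = [n for n in tree.preorder() if n.parent is not None]
        for i in range(len(edges)):
            t = tree.copy()
            target = [n for n in t.preorder() if n.parent is not None][i]
            parent = target.parent
            mid = Node()
            parent.children[parent.children.index(target)] = mid
            mid.parent = parent
            mid.add_child(target)
            mid.add_child(Node(name))
            out.append(t)
        t = tree.copy()
        new_root = Node()
        new_root.add_child(t.root)
        new_root.add_child(Node(name))
        out.append(LineageTree(new_root))
        return out

    trees = [LineageTree(Node(labels[0]))]
    for name in labels[1:]:
        trees = [t2 for t in trees for t2 in insert_all(t, name)]
    return trees


def brute_force_min_changes(tree: LineageTree, leaf_state: dict, root_state: int = 0) -> int:
    """Exhaustive minimum state-change count with the root state fixed."""
    internals = [n for n in tree.preorder() if not n.is_leaf and n.parent is not None]
    best = None
    for combo in itertools.product([0, 1], repeat=len(internals)):
        assign = {id(n): s for n, s in zip(internals, combo)}
        assign[id(tree.root)] = root_state
        for leaf in tree.leaves():
            assign[id(leaf)] = leaf_state[leaf.name]
        changes = sum(
            1 for v, u in tree.edges() if assign[id(v)] != assign[id(u)]
        )
        best = changes if best is None else min(best, changes)
    return best


def random_binary_tree(names, rng: np.random.Generator) -> LineageTree:
    from lineageml.search import random_tree

    return random_tree(list(names), rng)


@pytest.fixture
def rng():
    return np.random.default_rng(12345)
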