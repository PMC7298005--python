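"""Cutting a lineage tree into expression-coherent cell clusters.

At each internal node the BHC machinery yields the posterior
probability r_v that all cells under v form a single expression
cluster:

    r_v = pi_v P(Y^v|H1) / [pi_v P(Y^v|H1) + (1 - pi_v) L_u L_w]

The tree is cut top-down at the topmost nodes with r_v > 0.5 on each
root-to-leaf path; leaves reached without crossing become singleton
clusters (a leaf always has r = 1). An exact tie r_v = 0.5 counts as
"not merged" so the rule is deterministic.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .expression import NodeStats
from .tree import LineageTree, Node

__all__ = ["ClusterPartition", "ClusterCutResult", "node_posterior_r", "cut_clusters"]


@dataclass
class ClusterPartition:
    """Disjoint cell-id sets covering all leaves, with cut-node provenance."""

    clusters: list[set[str]]
    cut_nodes: list[int]  # preorder index of the cut node per cluster

    def labels(self, cell_order: list[str]) -> np.ndarray:
        lab = {}
        for k, cl in enumerate(self.clusters):
            for c in cl:
                lab[c] = k
        return np.array([lab[c] for c in cell_order])


@dataclass
class ClusterCutResult:
    partition: ClusterPartition
    r: dict[int, float]  # id(node) -> r_v
    cut_node_ids: list[int]


def node_posterior_r(stats: NodeStats) -> float:
    """Posterior probability that the node's cells form one cluster."""
    return float(np.exp(stats.log_pi + stats.log_h1 - stats.log_L))


def cut_clusters(
    tree: LineageTree, stats: dict[int, NodeStats] | dict[int, float]
) -> ClusterCutResult:
    """Partition leaves by the topmost r_v > 0.5 node on each path.

    ``stats`` maps ``id(node)`` to either NodeStats or a precomputed
    r value. The result is always a partition of the leaf set.
    """
    r: dict[int, float] = {}
    for node in tree.preorder():
        st = stats[id(node)]
        r[id(node)] = node_posterior_r(st) if isinstance(st, NodeStats) else float(st)

    preorder_index = {id(n): i for i, n in enumerate(tree.preorder())}
    clusters: list[set[str]] = []
    cut_nodes: list[int] = []

    def walk(node: Node) -> None:
        if r[id(node)] > 0.5:
            clusters.append({l.name for l in LineageTree(node).leaves()} if not node.is_leaf else {node.name})
            cut_nodes.append(preorder_index[id(node)])
            node.annot["cut"] = True
            return
        if node.is_leaf:
            # every leaf has r = 1 in the BHC model, but arbitrary r maps
            # must still yield a partition: unmerged leaves are singletons
            clusters.append({node.name})
            cut_nodes.append(preorder_index[id(node)])
            return
        for child in node.children:
            walk(child)

    import sys

    old = sys.getrecursionlimit()
    sys.setrecursionlimit(max(old, 10 * tree.n_leaves + 100))
    try:
        walk(tree.root)
    finally:
        sys.setrecursionlimit(old)

    return ClusterCutResult(
        partition=ClusterPartition(clusters, cut_nodes),
        r=r,
        cut_node_ids=cut_nodes,
    )
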