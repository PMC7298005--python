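"""Merging individual lineage trees into a species-invariant tree.

Recorder mutations are random per animal, so trees from different
individuals cannot be combined through shared characters. Instead,
expression-coherent clusters that are preserved across individuals
are matched, each individual's tree is reduced to a backbone over its
matched clusters, and a single invariant tree over the K matched
cluster groups is sought by minimizing

    omega1 * D_S + omega2 * D_E

where D_S sums, over individuals, the pairwise leaf shortest-path
disagreement between the invariant tree and the individual backbone,
and D_E sums the expression distances within each matched group.
"""

from __future__ import annotations

import itertools
import math
from dataclasses import dataclass, field
from typing import Optional, Sequence

import numpy as np

from .encoding import ExpressionMatrix
from .tree import LineageTree, Node

__all__ = [
    "ClusterSummary",
    "ClusterGroup",
    "Matching",
    "InvariantConfig",
    "InvariantResult",
    "cluster_summaries",
    "candidate_groups",
    "greedy_match",
    "backbone_tree",
    "pairwise_path_distance",
    "matching_distance",
    "optimize_invariant",
]

DEFAULT_TC = 3  # minimum cluster size kept for matching
DEFAULT_X = 1.0  # percent of candidate groups retained
_ENUM_CAP = 10**7
_PREFILTER_NEIGHBORS = 50


@dataclass
class ClusterSummary:
    individual: str
    cluster_id: str
    cells: list[str]
    mean: np.ndarray  # standardized mean expression over shared genes

    @property
    def n_cells(self) -> int:
        return len(self.cells)


@dataclass
class ClusterGroup:
    """One cluster per individual, with the summed pairwise distance."""

    clusters: tuple[ClusterSummary, ...]
    distance: float


@dataclass
class Matching:
    """Invariant leaf j <-> one cluster per individual."""

    individuals: list[str]
    groups: list[list[ClusterSummary]]  # groups[j][i]: cluster of individual i

    @property
    def K(self) -> int:
        return len(self.groups)

    def leaf_labels(self) -> list[str]:
        return [f"c{j}" for j in range(self.K)]

    def copy(self) -> "Matching":
        return Matching(list(self.individuals), [list(g) for g in self.groups])


@dataclass
class InvariantConfig:
    tc: int = DEFAULT_TC
    x: float = DEFAULT_X
    omega1: float = 1.0
    omega2: float = 1.0
    thr: float = 0.05
    stall: int = 500
    max_iter: int = 20000


@dataclass
class InvariantResult:
    tree: LineageTree
    matching: Matching
    d_s: float
    d_e: float
    objective: float
    norm_s: float
    norm_e: float
    d_e_thr: float
    accepted_objectives: list[float] = field(default_factory=list)


# ---- cluster summaries -------------------------------------------

def cluster_summaries(
    individuals: Sequence[str],
    partitions: Sequence[Sequence[set[str]]],
    expressions: Sequence[ExpressionMatrix],
    tc: int = DEFAULT_TC,
) -> list[list[ClusterSummary]]:
    """Filter clusters (size >= tc) and compute standardized means.

    Gene sets are intersected across individuals; cluster means are
    standardized per gene across the pooled clusters of all
    individuals so distances are comparable between genes.
    """
    shared = set(expressions[0].gene_ids)
    for em in expressions[1:]:
        shared &= set(em.gene_ids)
    if not shared:
        raise ValueError("individuals share no genes")
    genes = sorted(shared)

    raw: list[list[tuple[str, str, list[str], np.ndarray]]] = []
    for ind, clusters, em in zip(individuals, partitions, expressions):
        cols = [em.gene_ids.index(g) for g in genes]
        rows = {c: i for i, c in enumerate(em.cell_ids)}
        kept = []
        for k, cl in enumerate(clusters):
            if len(cl) < tc:
                continue
            idx = [rows[c] for c in sorted(cl)]
            kept.append((ind, f"{ind}:cl{k}", sorted(cl), em.Y[np.ix_(idx, cols)].mean(axis=0)))
        if not kept:
            raise ValueError(f"individual {ind!r} has no cluster of size >= {tc}")
        raw.append(kept)

    pooled = np.vstack([m for kept in raw for _, _, _, m in kept])
    mu = pooled.mean(axis=0)
    sd = pooled.std(axis=0)
    sd = np.where(sd > 0, sd, 1.0)
    return [
        [ClusterSummary(ind, cid, cells, (m - mu) / sd) for ind, cid, cells, m in kept]
        for kept in raw
    ]


def _group_distance(means: Sequence[np.ndarray]) -> float:
    d = 0.0
    for a, b in itertools.combinations(means, 2):
        d += float(np.linalg.norm(a - b))
    return d


def candidate_groups(
    summaries: list[list[ClusterSummary]], x: float = DEFAULT_X
) -> list[ClusterGroup]:
    """Enumerate cross-individual cluster tuples, keep the smallest x%.

    When the full cross product exceeds the enumeration cap, each
    individual's clusters are pre-filtered to the nearest neighbors
    of the first individual's clusters before enumeration.
    """
    if any(len(s) == 0 for s in summaries):
        raise ValueError("every individual must contribute at least one cluster")
    sizes = [len(s) for s in summaries]
    total = math.prod(sizes)
    pools = summaries
    if total > _ENUM_CAP:
        ref = summaries[0]
        pools = [ref]
        for s in summaries[1:]:
            keep: set[int] = set()
            for r in ref:
                d = [float(np.linalg.norm(r.mean - c.mean)) for c in s]
                keep.update(np.argsort(d)[:_PREFILTER_NEIGHBORS].tolist())
            pools.append([s[i] for i in sorted(keep)])
        total = math.prod(len(p) for p in pools)

    groups = [
        ClusterGroup(tup, _group_distance([c.mean for c in tup]))
        for tup in itertools.product(*pools)
    ]
    groups.sort(key=lambda g: g.distance)
    k = max(1, math.ceil(x / 100.0 * len(groups)))
    return groups[:k]


def greedy_match(ranked_groups: Sequence[ClusterGroup]) -> Matching:
    """Select disjoint groups in ascending distance order.

    A group is taken iff none of its constituent clusters was used by
    an earlier selected group; the scan stops when nothing remains
    selectable.
    """
    if not ranked_groups:
        raise ValueError("no candidate groups")
    used: set[str] = set()
    selected: list[ClusterGroup] = []
    for g in ranked_groups:
        ids = [c.cluster_id for c in g.clusters]
        if any(i in used for i in ids):
            continue
        used.update(ids)
        selected.append(g)
    individuals = [c.individual for c in selected[0].clusters]
    return Matching(individuals, [list(g.clusters) for g in selected])


# ---- backbone trees and distances --------------------------------

def backbone_tree(
    tree: LineageTree, clusters: Sequence[set[str]], labels: Sequence[str]
) -> LineageTree:
    """Restrict a tree to the given clusters' cut nodes as leaves.

    Each cluster's cut node (the node whose leaf set equals the
    cluster) becomes a leaf with the corresponding label; all other
    leaves are removed and unary nodes suppressed. Nested clusters
    (one cut node ancestral to another) are an error.
    """
    target = {frozenset(cl): lab for cl, lab in zip(clusters, labels)}
    found: dict[int, str] = {}
    leafsets: dict[int, frozenset] = {}
    for node in tree.postorder():
        if node.is_leaf:
            leafsets[id(node)] = frozenset([node.name])
        else:
            fs = frozenset().union(*(leafsets[id(c)] for c in node.children))
            leafsets[id(node)] = fs
        key = leafsets[id(node)]
        if key in target:
            found[id(node)] = target[key]
    if len(found) < len(target):
        missing = set(target.values()) - set(found.values())
        raise ValueError(f"cut node not found for cluster(s): {sorted(missing)}")

    marked_sets = [leafsets[i] for i in found]
    for a, b in itertools.combinations(found, 2):
        sa, sb = leafsets[a], leafsets[b]
        if sa < sb or sb < sa:
            raise ValueError(
                f"nested matched clusters: {found[a]!r} and {found[b]!r} overlap by ancestry"
            )

    def build(node: Node) -> Optional[Node]:
        if id(node) in found:
            return Node(found[id(node)])
        kids = [k for k in (build(c) for c in node.children) if k is not None]
        if not kids:
            return None
        if len(kids) == 1:
            return kids[0]
        parent = Node()
        for k in kids:
            parent.add_child(k)
        return parent

    root = build(tree.root)
    if root is None:
        raise ValueError("no matched cluster present in the tree")
    return LineageTree(root)


def _leaf_depth_and_paths(tree: LineageTree) -> dict[str, list[int]]:
    """Map each leaf name to the id-path from the root down to it."""
    paths: dict[str, list[int]] = {}
    def walk(node: Node, path: list[int]) -> None:
        path = path + [id(node)]
        if node.is_leaf:
            paths[node.name] = path
        for c in node.children:
            walk(c, path)
    walk(tree.root, [])
    return paths


def _pairwise_delta(tree: LineageTree, order: list[str]) -> np.ndarray:
    paths = _leaf_depth_and_paths(tree)
    K = len(order)
    D = np.zeros((K, K))
    for i in range(K):
        for j in range(i + 1, K):
            pa, pb = paths[order[i]], paths[order[j]]
            common = 0
            for x, y in zip(pa, pb):
                if x == y:
                    common += 1
                else:
                    break
            # edges from each leaf up to the MRCA
            D[i, j] = D[j, i] = (len(pa) - common) + (len(pb) - common)
    return D


def pairwise_path_distance(
    t1: LineageTree,
    t2: LineageTree,
    correspondence: Optional[dict[str, str]] = None,
) -> float:
    """Sum over leaf pairs of |delta_ij(T1) - delta_ij(T2)|.

    ``delta_ij`` counts the edges from leaves i and j up to their
    MRCA. ``correspondence`` maps T1 leaf names to T2 leaf names
    (identity by default) and must be a bijection onto T2's leaves.
    """
    names1 = t1.leaf_names()
    if correspondence is None:
        correspondence = {n: n for n in names1}
    mapped = [correspondence.get(n) for n in names1]
    if sorted(mapped) != sorted(t2.leaf_names()) or len(set(mapped)) != len(mapped):
        raise ValueError("correspondence is not a bijection between the leaf sets")
    D1 = _pairwise_delta(t1, names1)
    D2 = _pairwise_delta(t2, mapped)
    iu = np.triu_indices(len(names1), k=1)
    return float(np.abs(D1[iu] - D2[iu]).sum())


def matching_distance(matching: Matching) -> tuple[float, list[float]]:
    """D_E and the per-invariant-leaf expression disagreement E(c_j)."""
    per_leaf = [_group_distance([c.mean for c in g]) for g in matching.groups]
    return float(sum(per_leaf)), per_leaf


# ---- joint optimization ------------------------------------------

def _topology_distance_sum(
    tree: LineageTree, backbones: list[LineageTree], matching: Matching
) -> float:
    labels = matching.leaf_labels()
    total = 0.0
    for i, bt in enumerate(backbones):
        corr = {labels[j]: matching.groups[j][i].cluster_id for j in range(matching.K)}
        total += pairwise_path_distance(tree, bt, corr)
    return total


def optimize_invariant(
    backbones: list[LineageTree],
    matching: Matching,
    config: InvariantConfig,
    rng: np.random.Generator,
    initial_tree: Optional[LineageTree] = None,
) -> InvariantResult:
    """Two-step heuristic minimization of omega1*D_S + omega2*D_E.

    Step 1 alternates best-improvement matching transpositions
    (accepted iff D_E decreases) with topology hill climbing at fixed
    matching (rSPR/stNNI, accepted iff D_S decreases) until the
    matching cannot improve, then freezes the slack threshold
    D_E_thr = D_E_best + thr * D_E_best. Step 2 proposes either a
    matching transposition (accepted iff the objective decreases and
    the new D_E stays within the threshold) or a topology move
    (accepted iff the objective decreases), stopping on stall or the
    iteration cap. D_S and D_E are normalized by their initial values
    inside the objective.
    """
    from .search import rspr, stnni

    if matching.K < 3:
        raise ValueError("invariant optimization needs at least K = 3 matched groups")
    matching = matching.copy()
    labels = matching.leaf_labels()

    if initial_tree is None:
        # first individual's backbone, leaves relabelled by the matching
        tree = backbones[0].copy()
        rename = {matching.groups[j][0].cluster_id: labels[j] for j in range(matching.K)}
        for leaf in tree.leaves():
            leaf.name = rename[leaf.name]
    else:
        tree = initial_tree.copy()

    d_s = _topology_distance_sum(tree, backbones, matching)
    d_e, _ = matching_distance(matching)
    norm_s = d_s if d_s > 0 else 1.0
    norm_e = d_e if d_e > 0 else 1.0

    def objective(ds: float, de: float) -> float:
        return config.omega1 * ds / norm_s + config.omega2 * de / norm_e

    n_ind = len(backbones)
    accepted: list[float] = []

    def improve_topology(tree: LineageTree, ds: float) -> tuple[LineageTree, float]:
        stall = 0
        while stall < config.stall:
            move = rspr if rng.random() < 0.5 else stnni
            prop = move(tree, rng)
            ds_new = _topology_distance_sum(prop, backbones, matching)
            if ds_new < ds:
                tree, ds = prop, ds_new
                stall = 0
            else:
                stall += 1
        return tree, ds

    # ---- step 1: alternate matching / topology improvement
    while True:
        best_delta, best_swap = 0.0, None
        for i in range(n_ind):
            for j, k in itertools.combinations(range(matching.K), 2):
                trial = matching.copy()
                trial.groups[j][i], trial.groups[k][i] = trial.groups[k][i], trial.groups[j][i]
                de_new, _ = matching_distance(trial)
                if de_new - d_e < best_delta - 1e-12:
                    best_delta, best_swap = de_new - d_e, (i, j, k)
        if best_swap is None:
            break
        i, j, k = best_swap
        matching.groups[j][i], matching.groups[k][i] = (
            matching.groups[k][i],
            matching.groups[j][i],
        )
        d_e, _ = matching_distance(matching)
        d_s = _topology_distance_sum(tree, backbones, matching)
        tree, d_s = improve_topology(tree, d_s)
    tree, d_s = improve_topology(tree, d_s)

    d_e_best = d_e
    d_e_thr = d_e_best + config.thr * d_e_best

    # ---- step 2: stochastic joint search
    best = (tree, matching.copy(), d_s, d_e)
    cur_obj = objective(d_s, d_e)
    accepted.append(cur_obj)
    stall = 0
    it = 0
    while stall < config.stall and it < config.max_iter:
        it += 1
        if rng.random() < 0.5 and matching.K >= 2:
            i = int(rng.integers(n_ind))
            j, k = rng.choice(matching.K, size=2, replace=False)
            trial = matching.copy()
            trial.groups[j][i], trial.groups[k][i] = trial.groups[k][i], trial.groups[j][i]
            de_new, _ = matching_distance(trial)
            if de_new > d_e_thr:
                stall += 1
                continue
            ds_new = _topology_distance_sum(tree, backbones, trial)
            obj = objective(ds_new, de_new)
            if obj < cur_obj:
                matching, d_s, d_e, cur_obj = trial, ds_new, de_new, obj
                accepted.append(obj)
                stall = 0
            else:
                stall += 1
        else:
            move = rspr if rng.random() < 0.5 else stnni
            prop = move(tree, rng)
            ds_new = _topology_distance_sum(prop, backbones, matching)
            obj = objective(ds_new, d_e)
            if obj < cur_obj:
                tree, d_s, cur_obj = prop, ds_new, obj
                accepted.append(obj)
                stall = 0
            else:
                stall += 1
        if cur_obj < objective(best[2], best[3]):
            best = (tree, matching.copy(), d_s, d_e)

    tree, matching, d_s, d_e = best
    return InvariantResult(
        tree=tree,
        matching=matching,
        d_s=d_s,
        d_e=d_e,
        objective=objective(d_s, d_e),
        norm_s=norm_s,
        norm_e=norm_e,
        d_e_thr=d_e_thr,
        accepted_objectives=accepted,
    )
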