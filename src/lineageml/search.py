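"""Heuristic maximum-likelihood search for the cell lineage tree.

The combined score of a tree is the weighted joint log-likelihood

    L_T = omega1 * log L_M + omega2 * log L_E

(mutation and expression components; defaults omega1 = 50, omega2 = 1
keep the two terms in the same range). The search proceeds in four
steps:

1. hill-climb barcode-level trees (B leaves, mutation likelihood
   only, rSPR moves), keeping the top ``t`` distinct topologies;
2. for each barcode shared by >= 3 cells, hill-climb a cellular
   subtree (expression likelihood only, stNNI moves);
3. graft the cellular subtrees onto each retained barcode tree, score
   the assembled cell trees by L_T and keep the best, recording the
   mutation-likelihood slack threshold
   L_M_thr = L_M_best + thr * L_M_best;
4. refine the winner with rSPR moves on the full cell tree, accepting
   a proposal only when its mutation log-likelihood stays above
   L_M_thr and L_T strictly improves.

Each hill-climbing phase stops after a configured number of
non-improving proposals.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Optional

import numpy as np
import pandas as pd

from .encoding import ExpressionMatrix, PairedEventMatrix
from .expression import ExpressionPrior, ExpressionScorer
from .mutation import MutationScorer
from .tree import LineageTree, Node

__all__ = [
    "SearchConfig",
    "SearchTrace",
    "combined_log_likelihood",
    "stnni",
    "rspr",
    "random_tree",
    "search_barcode_trees",
    "search_cellular_subtree",
    "assemble_and_select",
    "refine_combined",
]


@dataclass
class SearchConfig:
    """Tunable knobs of the four-step search."""

    omega1: float = 50.0
    omega2: float = 1.0
    t: int = 5  # retained barcode trees
    thr: float = 0.01  # mutation-likelihood slack, close to 0
    stall: int = 2000  # non-improving proposals before a phase stops
    restarts: int = 3  # independent step-1 restarts
    seed: int = 0

    def __post_init__(self):
        if self.omega1 < 0 or self.omega2 < 0:
            raise ValueError("likelihood weights must be nonnegative")
        if self.t < 1:
            raise ValueError("t must be >= 1")
        if self.thr < 0:
            raise ValueError("thr must be >= 0")


@dataclass
class TraceRecord:
    step: str
    iteration: int
    move: str
    accepted: bool
    log_lik_mutation: float
    log_lik_expression: float
    log_lik_total: float


@dataclass
class SearchTrace:
    records: list[TraceRecord] = field(default_factory=list)

    def log(self, **kw) -> None:
        self.records.append(TraceRecord(**kw))

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame([vars(r) for r in self.records])


def combined_log_likelihood(
    log_lik_mutation: float, log_lik_expression: float, config: SearchConfig
) -> float:
    return config.omega1 * log_lik_mutation + config.omega2 * log_lik_expression


# ---- topology proposals ------------------------------------------

def _swap_subtrees(a: Node, b: Node) -> None:
    pa, pb = a.parent, b.parent
    ia, ib = pa.children.index(a), pb.children.index(b)
    pa.children[ia], pb.children[ib] = b, a
    a.parent, b.parent = pb, pa


def stnni(tree: LineageTree, rng: np.random.Generator) -> LineageTree:
    """Stochastic NNI around a random internal (unrooted) branch.

    Picks a focal branch connecting two internal nodes of the
    unrooted topology and swaps one subtree from each side. Trees
    with fewer than four leaves have no focal branch; the tree is
    returned unchanged (a no-op proposal).
    """
    t = tree.copy()
    focal: list[tuple] = []
    for v, u in t.edges():
        if not u.is_leaf and v.parent is not None:
            focal.append(("edge", v, u))
    rc = t.root.children
    if len(rc) == 2 and not rc[0].is_leaf and not rc[1].is_leaf:
        focal.append(("root", rc[0], rc[1]))
    if not focal:
        return t
    kind, a, b = focal[rng.integers(len(focal))]
    if kind == "root":
        x = a.children[rng.integers(len(a.children))]
        y = b.children[rng.integers(len(b.children))]
        _swap_subtrees(x, y)
    else:
        v, u = a, b
        sibling = next(c for c in v.children if c is not u)
        x = u.children[rng.integers(len(u.children))]
        _swap_subtrees(x, sibling)
    return t


def rspr(tree: LineageTree, rng: np.random.Generator) -> LineageTree:
    """Random subtree prune-and-regraft.

    A random non-root subtree is pruned (its unary parent suppressed)
    and regrafted onto a random branch of the remaining tree, or above
    its root. Regrafting onto the original branch reproduces the input
    topology, which is a valid (rejected-in-practice) proposal.
    """
    t = tree.copy()
    if t.n_leaves < 3:
        return t
    candidates = [n for n in t.preorder() if n.parent is not None]
    p = candidates[rng.integers(len(candidates))]

    parent = p.parent
    p.detach()
    if parent.parent is None:
        new_root = parent.children[0]
        new_root.parent = None
        t.root = new_root
    else:
        gp = parent.parent
        child = parent.children[0]
        gp.children[gp.children.index(parent)] = child
        child.parent = gp

    targets = list(t.preorder())
    q = targets[rng.integers(len(targets))]
    mid = Node()
    if q.parent is None:
        mid.add_child(q)
        mid.add_child(p)
        t.root = mid
        mid.parent = None
    else:
        qp = q.parent
        qp.children[qp.children.index(q)] = mid
        mid.parent = qp
        mid.children = []
        mid.add_child(q)
        mid.add_child(p)
    return t


def random_tree(names: list[str], rng: np.random.Generator) -> LineageTree:
    """Random binary topology by sequential random leaf attachment."""
    names = list(names)
    if len(names) <= 2:
        return LineageTree.from_leaf_names(names)
    order = rng.permutation(len(names))
    shuffled = [names[i] for i in order]
    attach = [0, 0] + [int(rng.integers(2**30)) for _ in range(len(names) - 2)]
    return LineageTree.from_leaf_names(shuffled, attach_order=attach)


# ---- step 1: barcode trees ---------------------------------------

def search_barcode_trees(
    pem: PairedEventMatrix,
    config: SearchConfig,
    rng: np.random.Generator,
) -> list[tuple[LineageTree, float]]:
    """Hill-climb barcode-level trees by mutation likelihood.

    Returns up to ``config.t`` distinct topologies sorted by
    descending log L_M. Markers are scored on barcode leaves but with
    cell-level carrier fractions m_s.
    """
    leaf_states = pd.DataFrame(pem.E, index=pem.barcode_ids, columns=pem.marker_ids)
    m = pem.marker_cell_fractions()
    scorer = MutationScorer(leaf_states, m)

    if pem.n_barcodes == 1:
        tree = LineageTree(Node(pem.barcode_ids[0]))
        return [(tree, scorer.score(tree).total)]
    if pem.n_barcodes == 2:
        tree = LineageTree.from_leaf_names(list(pem.barcode_ids))
        return [(tree, scorer.score(tree).total)]

    pool: dict[str, tuple[float, LineageTree]] = {}

    def consider(tree: LineageTree, score: float) -> None:
        key = tree.topology_hash()
        if key not in pool or pool[key][0] < score:
            pool[key] = (score, tree)

    def _guide_start() -> LineageTree:
        # perfect-phylogeny-style guide tree: recursively split the
        # barcodes by the highest-frequency marker that is informative
        # within the current block (carriers vs non-carriers). Exact on
        # Camin-Sokal-compatible data, a strong basin otherwise.
        E = pem.E.astype(bool)
        freq = m  # cell-level carrier fractions

        def build(rows: list[int]) -> Node:
            if len(rows) == 1:
                return Node(pem.barcode_ids[rows[0]])
            sub = E[rows]
            counts = sub.sum(axis=0)
            informative = np.flatnonzero((counts > 0) & (counts < len(rows)))
            if informative.size == 0:
                # identical remaining rows cannot occur (barcodes are
                # distinct); guard by a caterpillar of the block
                node = Node()
                node.add_child(Node(pem.barcode_ids[rows[0]]))
                node.add_child(build(rows[1:]))
                return node
            s = informative[np.argmax(freq[informative])]
            carriers = [r for r in rows if E[r, s]]
            others = [r for r in rows if not E[r, s]]
            node = Node()
            node.add_child(build(others))
            node.add_child(build(carriers))
            return node

        return LineageTree(build(list(range(pem.n_barcodes))))

    def climb(start: LineageTree) -> tuple[LineageTree, float]:
        current = start
        cur_score = scorer.score(current).total
        consider(current, cur_score)
        stall = 0
        while stall < config.stall:
            prop = rspr(current, rng)
            score = scorer.score(prop).total
            consider(prop, score)
            if score > cur_score:
                current, cur_score = prop, score
                stall = 0
            else:
                stall += 1
        return current, cur_score

    # iterated local search: climb from a linkage guide tree, then from
    # random starts, then ratchet rounds (best tree kicked by a few
    # random rSPR moves, cycling kick strengths) to escape single-move
    # local optima
    best_tree, best_score = climb(_guide_start())
    for _ in range(max(config.restarts - 1, 0)):
        tree, score = climb(random_tree(list(pem.barcode_ids), rng))
        if score > best_score:
            best_tree, best_score = tree, score
    kick_sizes = (2, 3, 5, 8)
    for round_ in range(2 * max(config.restarts, 1)):
        kicked = best_tree
        for _ in range(kick_sizes[round_ % len(kick_sizes)]):
            kicked = rspr(kicked, rng)
        tree, score = climb(kicked)
        if score > best_score:
            best_tree, best_score = tree, score

    ranked = sorted(pool.values(), key=lambda sv: -sv[0])[: config.t]
    return [(tree, score) for score, tree in ranked]


# ---- step 2: cellular subtrees -----------------------------------

def _linkage_tree(cells: list[str], Y: ExpressionMatrix) -> LineageTree:
    from scipy.cluster.hierarchy import linkage

    sub = Y.subset(cells)
    Z = linkage(sub.Y, method="average", metric="euclidean")
    nodes: list[Node] = [Node(c) for c in cells]
    for a, b, _, _ in Z:
        parent = Node()
        parent.add_child(nodes[int(a)])
        parent.add_child(nodes[int(b)])
        nodes.append(parent)
    return LineageTree(nodes[-1])


def search_cellular_subtree(
    cells: list[str],
    expr_scorer: ExpressionScorer,
    config: SearchConfig,
    rng: np.random.Generator,
    trace: Optional[SearchTrace] = None,
) -> LineageTree:
    """Hill-climb a binary subtree over one barcode's cells (L_E only).

    Initialized from an average-linkage agglomerative tree; stNNI
    proposals, strict improvement required.
    """
    if len(cells) == 1:
        return LineageTree(Node(cells[0]))
    if len(cells) == 2:
        return LineageTree.from_leaf_names(list(cells))

    current = _linkage_tree(cells, expr_scorer.Y)
    cur_score, _ = expr_scorer.score(current)
    stall = 0
    it = 0
    while stall < config.stall:
        prop = stnni(current, rng)
        score, _ = expr_scorer.score(prop)
        accepted = score > cur_score
        if trace is not None:
            trace.log(
                step="cellular_subtree",
                iteration=it,
                move="stnni",
                accepted=accepted,
                log_lik_mutation=float("nan"),
                log_lik_expression=score,
                log_lik_total=float("nan"),
            )
        if accepted:
            current, cur_score = prop, score
            stall = 0
        else:
            stall += 1
        it += 1
    return current


# ---- step 3: assembly --------------------------------------------

def _graft(barcode_tree: LineageTree, cells_of: dict[str, list[str]],
           subtrees: dict[str, LineageTree]) -> LineageTree:
    tree = barcode_tree.copy()
    for leaf in tree.leaves():
        cells = cells_of[leaf.name]
        if len(cells) == 1:
            leaf.name = cells[0]
        elif len(cells) == 2:
            leaf.name = None
            leaf.add_child(Node(cells[0]))
            leaf.add_child(Node(cells[1]))
        else:
            if leaf.name not in subtrees:
                raise ValueError(f"no cellular subtree for multi-cell barcode {leaf.name!r}")
            sub = subtrees[leaf.name].copy()
            leaf.name = None
            if leaf.parent is None:
                tree.root = sub.root
            else:
                parent = leaf.parent
                parent.children[parent.children.index(leaf)] = sub.root
                sub.root.parent = parent
    return tree


def assemble_and_select(
    barcode_trees: list[tuple[LineageTree, float]],
    subtrees: dict[str, LineageTree],
    pem: PairedEventMatrix,
    mut_scorer: MutationScorer,
    expr_scorer: ExpressionScorer,
    config: SearchConfig,
) -> tuple[LineageTree, float, float]:
    """Graft subtrees onto each barcode tree; pick the best full tree.

    Returns (best tree, its L_T, mutation threshold L_M_thr). A
    barcode with one cell becomes a leaf, with two cells a cherry
    under the barcode's position, with more its step-2 subtree.
    """
    cells_of: dict[str, list[str]] = {b: [] for b in pem.barcode_ids}
    for cell, b in pem.z.items():
        cells_of[pem.barcode_ids[b]].append(cell)

    best = None
    for btree, _ in barcode_trees:
        full = _graft(btree, cells_of, subtrees)
        lm = mut_scorer.score(full).total
        le, _ = expr_scorer.score(full)
        lt = combined_log_likelihood(lm, le, config)
        if best is None or lt > best[1]:
            best = (full, lt, lm)
    tree, lt, lm_best = best
    lm_thr = lm_best + config.thr * lm_best
    return tree, lt, lm_thr


# ---- step 4: joint refinement ------------------------------------

def refine_combined(
    tree: LineageTree,
    mut_scorer: MutationScorer,
    expr_scorer: ExpressionScorer,
    config: SearchConfig,
    lm_thr: float,
    rng: np.random.Generator,
    trace: Optional[SearchTrace] = None,
) -> LineageTree:
    """rSPR hill climbing on the full cell tree under the L_M slack.

    A proposal is accepted iff its mutation log-likelihood is >=
    ``lm_thr`` and the combined score strictly improves.
    """
    current = tree
    cur_lm = mut_scorer.score(current).total
    cur_le, _ = expr_scorer.score(current)
    cur_lt = combined_log_likelihood(cur_lm, cur_le, config)
    stall = 0
    it = 0
    while stall < config.stall:
        prop = rspr(current, rng)
        lm = mut_scorer.score(prop).total
        accepted = False
        le = float("nan")
        lt = float("nan")
        if lm >= lm_thr:
            le, _ = expr_scorer.score(prop)
            lt = combined_log_likelihood(lm, le, config)
            accepted = lt > cur_lt
        if trace is not None:
            trace.log(
                step="refine",
                iteration=it,
                move="rspr",
                accepted=accepted,
                log_lik_mutation=lm,
                log_lik_expression=le,
                log_lik_total=lt,
            )
        if accepted:
            current, cur_lm, cur_le, cur_lt = prop, lm, le, lt
            stall = 0
        else:
            stall += 1
        it += 1
    return current
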