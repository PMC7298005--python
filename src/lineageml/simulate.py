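"""Simulation of CRISPR lineage-recorder data on a known lineage.

Each cell carries a recorder of ``m`` target sites. Starting from an
all-unedited root (the fertilized egg), every cell division gives
each still-unedited target an independent chance ``mu`` to mutate to
one of ``n_states`` equiprobable outcomes; once edited a target is
immutable, absent dropout. Site-specific rates can be drawn from a
Beta distribution. Dropout events occur on internal branches with
probability (expected events) / (number of internal branches); an
event erases the recording of one already-mutated target for the
whole descendant subtree (the state reverts to unedited and the
early lineage information is lost).

A matched synthetic expression generator (per-cell-type diagonal
Gaussians) and a deterministic perfect-data fixture make every other
module testable without any external download.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Optional, Sequence

import numpy as np
import pandas as pd

from .encoding import (
    UNEDITED,
    AlleleTable,
    ExpressionMatrix,
    PairedEventMatrix,
    encode_barcodes,
)
from .tree import LineageTree, Node

__all__ = [
    "RecorderConfig",
    "TargetStateMatrix",
    "simulate_recorder",
    "apply_dropout",
    "states_to_markers",
    "to_allele_table",
    "synth_expression",
    "complete_binary_lineage",
    "clade_fixture",
]


@dataclass
class RecorderConfig:
    """Recorder simulation parameters.

    m : number of CRISPR target sites per recorder
    n_states : possible mutational outcomes per target (equiprobable)
    mu : per-division per-target mutation probability; a (mean, sd)
        tuple instead draws one Beta-distributed rate per site
    eps_d : expected number of dropout events over the lineage
    """

    m: int = 5
    n_states: int = 8
    mu: float | tuple[float, float] = 0.15
    eps_d: float = 0.0

    def __post_init__(self):
        if self.m < 1 or self.n_states < 1:
            raise ValueError("m and n_states must be >= 1")
        if self.eps_d < 0:
            raise ValueError("eps_d must be >= 0")
        if not isinstance(self.mu, tuple) and not 0.0 <= self.mu <= 1.0:
            raise ValueError("mu must be in [0, 1]")

    def site_rates(self, rng: np.random.Generator) -> np.ndarray:
        if not isinstance(self.mu, tuple):
            return np.full(self.m, float(self.mu))
        mean, sd = self.mu
        var = sd**2
        if not 0 < mean < 1 or var <= 0 or var >= mean * (1 - mean):
            raise ValueError(
                f"invalid Beta parameterization: need 0 < mean < 1 and "
                f"0 < sd^2 < mean*(1-mean); got mean={mean}, sd={sd}"
            )
        nu = mean * (1 - mean) / var - 1.0
        return rng.beta(mean * nu, (1 - mean) * nu, size=self.m)


@dataclass
class TargetStateMatrix:
    """Per-leaf target states (0 = unedited, 1..n_states = edits).

    Internal-node states are retained so that oracle checks of
    heritability never need to re-simulate.
    """

    leaf_states: pd.DataFrame  # (leaf x target) int
    node_states: dict[int, np.ndarray]  # id(node) -> (m,) int
    tree: LineageTree
    site_rates: np.ndarray
    dropout_events: list[tuple[str, int]] = field(default_factory=list)
    dropped: Optional[pd.DataFrame] = None  # (leaf x target) bool erased flags


def _label_nodes(tree: LineageTree) -> dict[int, str]:
    labels = {}
    for i, node in enumerate(tree.preorder()):
        labels[id(node)] = node.name if node.name else f"node{i}"
    return labels


def simulate_recorder(
    true_tree: LineageTree,
    config: RecorderConfig,
    rng: np.random.Generator,
    rates: Optional[np.ndarray] = None,
) -> TargetStateMatrix:
    """Simulate recorder edits along the tree, root (all-unedited) first.

    Branches are visited parent-before-child; on each branch every
    unedited target mutates with its site rate to a uniformly chosen
    nonzero state. ``rates`` fixes the per-site rates across calls
    (otherwise they are (re)drawn from the config).
    """
    if rates is None:
        rates = config.site_rates(rng)
    states: dict[int, np.ndarray] = {id(true_tree.root): np.zeros(config.m, dtype=int)}
    for node in true_tree.preorder():
        if node.parent is None:
            continue
        parent_state = states[id(node.parent)]
        state = parent_state.copy()
        editable = state == 0
        hits = editable & (rng.random(config.m) < rates)
        state[hits] = rng.integers(1, config.n_states + 1, size=int(hits.sum()))
        states[id(node)] = state

    leaves = true_tree.leaves()
    leaf_states = pd.DataFrame(
        np.vstack([states[id(l)] for l in leaves]),
        index=[l.name for l in leaves],
        columns=[f"site_{j + 1}" for j in range(config.m)],
    )
    return TargetStateMatrix(leaf_states, states, true_tree, rates)


def apply_dropout(
    tsm: TargetStateMatrix, config: RecorderConfig, rng: np.random.Generator
) -> TargetStateMatrix:
    """Introduce dropout events on internal branches.

    Each internal branch (one whose child is an internal node) drops
    with probability eps_d / (#internal branches); an event erases
    one currently-mutated target, chosen uniformly, for the entire
    descendant subtree. Branches whose child carries no mutated
    target are unaffected even when the trial fires.
    """
    tree = tsm.tree
    states = {k: v.copy() for k, v in tsm.node_states.items()}
    internal_edges = [(v, u) for v, u in tree.edges() if not u.is_leaf]
    events: list[tuple[str, int]] = []
    labels = _label_nodes(tree)
    erased: dict[int, np.ndarray] = {
        k: np.zeros(len(tsm.site_rates), dtype=bool) for k in states
    }
    if config.eps_d > 0 and internal_edges:
        p = config.eps_d / len(internal_edges)
        if p > 1:
            raise ValueError("eps_d exceeds the number of internal branches")
        for _, child in internal_edges:
            if rng.random() >= p:
                continue
            mutated = np.flatnonzero(states[id(child)] > 0)
            if mutated.size == 0:
                continue
            target = int(mutated[rng.integers(mutated.size)])
            events.append((labels[id(child)], target))
            stack = [child]
            while stack:
                n = stack.pop()
                states[id(n)][target] = 0
                erased[id(n)][target] = True
                stack.extend(n.children)

    leaves = tree.leaves()
    leaf_states = pd.DataFrame(
        np.vstack([states[id(l)] for l in leaves]),
        index=list(tsm.leaf_states.index),
        columns=list(tsm.leaf_states.columns),
    )
    dropped = pd.DataFrame(
        np.vstack([erased[id(l)] for l in leaves]),
        index=list(tsm.leaf_states.index),
        columns=list(tsm.leaf_states.columns),
    )
    return TargetStateMatrix(leaf_states, states, tree, tsm.site_rates, events, dropped)


def to_allele_table(tsm: TargetStateMatrix) -> AlleleTable:
    """Leaf target states as an allele table (state k -> label ``e<k>``)."""
    rows = [
        [UNEDITED if s == 0 else f"e{s}" for s in row]
        for row in tsm.leaf_states.to_numpy()
    ]
    return AlleleTable([str(c) for c in tsm.leaf_states.index], rows)


def states_to_markers(tsm: TargetStateMatrix) -> PairedEventMatrix:
    """Binary paired-event encoding of the simulated leaf states."""
    return encode_barcodes(to_allele_table(tsm))


def synth_expression(
    type_labels: Sequence,
    n_genes: int = 20,
    separation: float = 5.0,
    noise_sd: float = 1.0,
    rng: Optional[np.random.Generator] = None,
    cell_ids: Optional[Sequence[str]] = None,
) -> ExpressionMatrix:
    """Per-cell-type diagonal Gaussian expression profiles.

    Each type's mean vector is drawn N(0, separation^2) per gene, so
    ``separation`` (in units of ``noise_sd`` when that is 1) controls
    the expected between-type distance; cells add independent
    Gaussian noise.
    """
    if rng is None:
        rng = np.random.default_rng(0)
    labels = list(type_labels)
    if not labels:
        raise ValueError("need at least one cell")
    types = sorted(set(labels), key=str)
    means = {t: rng.normal(0.0, separation, size=n_genes) for t in types}
    Y = np.vstack([means[t] + rng.normal(0.0, noise_sd, size=n_genes) for t in labels])
    if cell_ids is None:
        cell_ids = [f"cell{i}" for i in range(len(labels))]
    return ExpressionMatrix(Y, [str(c) for c in cell_ids], [f"g{j}" for j in range(n_genes)])


def complete_binary_lineage(depth: int, prefix: str = "cell") -> LineageTree:
    """Complete binary division tree of the given depth (2**depth leaves)."""

    counter = [0]

    def build(d: int) -> Node:
        if d == 0:
            node = Node(f"{prefix}{counter[0]}")
            counter[0] += 1
            return node
        node = Node()
        node.add_child(build(d - 1))
        node.add_child(build(d - 1))
        return node

    return LineageTree(build(depth))


# ---- deterministic perfect-data fixture --------------------------

@dataclass
class CladeFixture:
    """A noiseless benchmark: one unique marker per clade-tree edge and
    expression clusters aligned with the clades."""

    true_cell_tree: LineageTree  # binary; within-clade order arbitrary
    true_collapsed: LineageTree  # clades as multifurcations (marker-supported only)
    clade_tree: LineageTree
    pem: PairedEventMatrix
    expression: ExpressionMatrix
    type_labels: dict[str, str]  # cell -> clade


def clade_fixture(
    n_clades: int = 20,
    cells_per_clade: int = 5,
    n_genes: int = 20,
    separation: float = 10.0,
    noise_sd: float = 1.0,
    rng: Optional[np.random.Generator] = None,
) -> CladeFixture:
    """Build the perfect-recovery scenario.

    A random binary clade tree is drawn; every edge of it gains one
    unique marker, inherited by all cells below, so each clade's cells
    share one barcode and the clade tree is a perfect phylogeny of
    the barcodes. Expression profiles are clade-specific Gaussians.
    """
    from .search import random_tree

    if rng is None:
        rng = np.random.default_rng(0)
    clade_names = [f"clade{i}" for i in range(n_clades)]
    clade_tree = random_tree(clade_names, rng)

    # one marker per edge; a clade carries the markers on its root path
    edge_ids = {}
    for v, u in clade_tree.edges():
        edge_ids[id(u)] = len(edge_ids)
    n_sites = len(edge_ids)
    carried: dict[str, list[int]] = {}
    for leaf in clade_tree.leaves():
        path = []
        node = leaf
        while node.parent is not None:
            path.append(edge_ids[id(node)])
            node = node.parent
        carried[leaf.name] = path

    cell_ids: list[str] = []
    rows: list[list[str]] = []
    labels: dict[str, str] = {}
    for clade in clade_names:
        for k in range(cells_per_clade):
            cell = f"{clade}_c{k}"
            cell_ids.append(cell)
            row = [UNEDITED] * n_sites
            for site in carried[clade]:
                row[site] = "e1"
            rows.append(row)
            labels[cell] = clade
    pem = encode_barcodes(AlleleTable(cell_ids, rows))

    expr = synth_expression(
        [labels[c] for c in cell_ids],
        n_genes=n_genes,
        separation=separation,
        noise_sd=noise_sd,
        rng=rng,
        cell_ids=cell_ids,
    )

    def expand(tree: LineageTree, binary: bool) -> LineageTree:
        t = tree.copy()
        for leaf in t.leaves():
            cells = [c for c in cell_ids if labels[c] == leaf.name]
            if len(cells) == 1:
                leaf.name = cells[0]
                continue
            leaf.name = None
            if binary:
                sub = LineageTree.from_leaf_names(cells)
                for c in list(sub.root.children):
                    leaf.add_child(c)
            else:
                for c in cells:
                    leaf.add_child(Node(c))
        return t

    return CladeFixture(
        true_cell_tree=expand(clade_tree, binary=True),
        true_collapsed=expand(clade_tree, binary=False),
        clade_tree=clade_tree,
        pem=pem,
        expression=expr,
        type_labels=labels,
    )
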