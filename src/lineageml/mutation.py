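"""Mutation likelihood of a lineage tree under Camin-Sokal parsimony.

CRISPR recorder edits are irreversible: once a target site is cut and
repaired, Cas9 cannot re-bind, so a synthetic marker gained on a
lineage branch is never lost. A candidate tree is scored by (i)
assigning ancestral presence/absence states for every marker with
Fitch's algorithm (root forced to the unedited state), then (ii)
multiplying per-branch transition probabilities from the two-state
matrix

    P_t^s = [[1 - m_s, m_s],
             [0,       1  ]]

where ``m_s`` is the fraction of cells harboring marker ``s``. A
marker whose minimum-change assignment still requires a 1 -> 0
reversal violates irreversibility and contributes a flat penalty of
-100000 to the total log-likelihood instead of its product term.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .tree import LineageTree, Node

REVERSAL_PENALTY = -100000.0

__all__ = [
    "REVERSAL_PENALTY",
    "transition_matrix",
    "AncestralAssignment",
    "MutationScore",
    "MutationScorer",
    "fitch_assign",
    "mutation_log_likelihood",
    "annotate_gains",
]


def transition_matrix(m_s: float) -> np.ndarray:
    """Two-state transition matrix for a marker with cell fraction ``m_s``."""
    if not 0.0 <= m_s <= 1.0:
        raise ValueError(f"marker fraction must be in [0, 1], got {m_s}")
    return np.array([[1.0 - m_s, m_s], [0.0, 1.0]])


@dataclass
class AncestralAssignment:
    """Fitch ancestral states and the induced per-marker change counts."""

    states: dict[int, np.ndarray]  # id(node) -> (S,) uint8 state vector
    gains: np.ndarray  # (S,) number of 0->1 edges per marker
    losses: np.ndarray  # (S,) number of 1->0 edges per marker (violations)
    n00: np.ndarray  # (S,) number of 0->0 edges per marker

    @property
    def changes(self) -> np.ndarray:
        return self.gains + self.losses

    def state_of(self, node: Node) -> np.ndarray:
        return self.states[id(node)]


@dataclass
class MutationScore:
    per_marker: np.ndarray  # (S,) log-likelihood contributions
    total: float
    violations: int  # markers whose assignment contains a reversal
    assignment: AncestralAssignment

    def __float__(self) -> float:
        return self.total


def _leaf_state_lookup(leaf_states: pd.DataFrame) -> dict[str, np.ndarray]:
    M = leaf_states.to_numpy(dtype=np.uint8)
    return {str(name): M[i] for i, name in enumerate(leaf_states.index)}


def fitch_assign(tree: LineageTree, leaf_states: pd.DataFrame) -> AncestralAssignment:
    """Minimum-change ancestral states for every marker, root forced to 0.

    ``leaf_states`` is a binary (leaf x marker) frame indexed by leaf
    name. Bottom-up state sets are encoded as 2-bit masks (1 = {0},
    2 = {1}, 3 = {0,1}); the top-down pass takes the parent's state
    when it is in the node's set and the set's single state otherwise,
    with the root forced to all-zero.
    """
    lookup = _leaf_state_lookup(leaf_states)
    S = leaf_states.shape[1]

    masks: dict[int, np.ndarray] = {}
    for node in tree.postorder():
        if node.is_leaf:
            if node.name not in lookup:
                raise ValueError(f"leaf {node.name!r} missing from leaf states")
            masks[id(node)] = (np.uint8(1) << lookup[node.name]).astype(np.uint8)
        else:
            mask = None
            for child in node.children:
                cm = masks[id(child)]
                mask = cm if mask is None else mask & cm
            union = None
            for child in node.children:
                cm = masks[id(child)]
                union = cm if union is None else union | cm
            masks[id(node)] = np.where(mask > 0, mask, union).astype(np.uint8)

    states: dict[int, np.ndarray] = {}
    gains = np.zeros(S, dtype=np.int64)
    losses = np.zeros(S, dtype=np.int64)
    n00 = np.zeros(S, dtype=np.int64)
    for node in tree.preorder():
        if node.is_leaf:
            states[id(node)] = lookup[node.name]
        elif node.parent is None:
            states[id(node)] = np.zeros(S, dtype=np.uint8)
        else:
            mask = masks[id(node)]
            ps = states[id(node.parent)]
            parent_in_set = (mask >> ps) & 1
            fallback = (mask == 2).astype(np.uint8)
            states[id(node)] = np.where(parent_in_set == 1, ps, fallback).astype(np.uint8)
        if node.parent is not None:
            ps = states[id(node.parent)]
            cs = states[id(node)]
            gains += (ps == 0) & (cs == 1)
            losses += (ps == 1) & (cs == 0)
            n00 += (ps == 0) & (cs == 0)

    return AncestralAssignment(states, gains, losses, n00)


class MutationScorer:
    """Reusable scorer binding leaf states and marker cell fractions.

    The per-marker log-likelihood has closed form under the Fitch
    assignment: ``n01 * log(m_s) + n00 * log(1 - m_s)`` (1 -> 1 edges
    contribute 0), which equals the bottom-up partial-likelihood
    recursion evaluated at the root; both routes are exposed.
    """

    def __init__(
        self,
        leaf_states: pd.DataFrame,
        m: np.ndarray,
        penalty: float = REVERSAL_PENALTY,
    ):
        self.leaf_states = leaf_states.astype(np.uint8)
        self.m = np.asarray(m, dtype=float)
        if self.m.shape != (leaf_states.shape[1],):
            raise ValueError("m must have one entry per marker")
        if np.any((self.m < 0) | (self.m > 1)):
            raise ValueError("marker fractions must lie in [0, 1]")
        self.penalty = float(penalty)
        with np.errstate(divide="ignore"):
            self._log_m = np.log(self.m)
            self._log_1m = np.log1p(-self.m)

    def score(self, tree: LineageTree) -> MutationScore:
        assignment = fitch_assign(tree, self.leaf_states)
        per_marker = (
            assignment.gains * np.where(assignment.gains > 0, self._log_m, 0.0)
            + assignment.n00 * np.where(assignment.n00 > 0, self._log_1m, 0.0)
        )
        violating = assignment.losses > 0
        per_marker = np.where(violating, self.penalty, per_marker)
        return MutationScore(
            per_marker=per_marker,
            total=float(per_marker.sum()),
            violations=int(violating.sum()),
            assignment=assignment,
        )

    def recursive_log_likelihood(self, tree: LineageTree) -> np.ndarray:
        """Per-marker log-likelihood via the bottom-up recursion.

        Leaf partials are 1; an internal node multiplies, for each
        child, the branch transition probability under the Fitch
        assignment by the child's partial. The root value (ancestral
        state 0) is the marker's likelihood. Reversal-penalized
        markers are not special-cased here; reversals yield -inf
        (log 0 transition), which the product route reports as is.
        """
        assignment = fitch_assign(tree, self.leaf_states)
        S = self.leaf_states.shape[1]
        partial: dict[int, np.ndarray] = {}
        for node in tree.postorder():
            if node.is_leaf:
                partial[id(node)] = np.zeros(S)
                continue
            acc = np.zeros(S)
            vs = assignment.state_of(node)
            for child in node.children:
                cs = assignment.state_of(child)
                with np.errstate(divide="ignore"):
                    logp = np.where(
                        (vs == 0) & (cs == 1),
                        self._log_m,
                        np.where(
                            (vs == 0) & (cs == 0),
                            self._log_1m,
                            np.where((vs == 1) & (cs == 0), -np.inf, 0.0),
                        ),
                    )
                acc = acc + logp + partial[id(child)]
            partial[id(node)] = acc
        return partial[id(tree.root)]


def mutation_log_likelihood(
    tree: LineageTree,
    leaf_states: pd.DataFrame,
    m: np.ndarray | None = None,
    penalty: float = REVERSAL_PENALTY,
) -> MutationScore:
    """Score a tree against binary leaf marker states.

    When ``m`` is omitted it is taken as the carrier fraction over the
    rows of ``leaf_states``; pass cell-level fractions explicitly when
    scoring a barcode-level tree.
    """
    if m is None:
        m = leaf_states.to_numpy(dtype=float).mean(axis=0)
    return MutationScorer(leaf_states, m, penalty).score(tree)


def annotate_gains(tree: LineageTree, assignment: AncestralAssignment) -> None:
    """Store, on each non-root node, the markers gained on its parent edge."""
    for node in tree.preorder():
        if node.parent is None:
            node.annot["gained"] = []
            continue
        ps = assignment.state_of(node.parent)
        cs = assignment.state_of(node)
        node.annot["gained"] = np.flatnonzero((ps == 0) & (cs == 1)).tolist()
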