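"""Evaluation metrics: bipartition accuracy, RF/FP/FN distances, ARI.

Rooted trees are compared as unrooted (the standard Robinson-Foulds
convention): each internal edge induces a leaf bipartition, trivial
splits (one side a singleton or empty) are discarded, and splits are
canonicalized so complementary sides compare equal.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass, field
from typing import Optional, Sequence

import numpy as np

from .tree import LineageTree

__all__ = [
    "bipartition_set",
    "bipartition_accuracy",
    "rf_distance",
    "fp_fn",
    "ari",
    "MetricReport",
    "evaluate_trees",
]


@dataclass
class MetricReport:
    accuracy: Optional[float] = None
    rf: Optional[float] = None
    fp: Optional[float] = None
    fn: Optional[float] = None
    ari: Optional[float] = None
    n_true_bipartitions: int = 0
    n_inferred_bipartitions: int = 0
    warnings: list[str] = field(default_factory=list)

    def to_dict(self) -> dict:
        return {k: v for k, v in vars(self).items()}


def bipartition_set(tree: LineageTree) -> set[frozenset[str]]:
    """Non-trivial leaf bipartitions of the unrooted topology.

    Each split is represented by the side that contains the
    lexicographically smallest leaf name, making complementary sides
    identical.
    """
    all_leaves = frozenset(tree.leaf_names())
    if len(all_leaves) != tree.n_leaves:
        raise ValueError("leaf names must be unique")
    ref = min(all_leaves)
    splits: set[frozenset[str]] = set()
    for node in tree.preorder():
        if node.parent is None or node.is_leaf:
            continue
        side = frozenset(l.name for l in tree.leaves_under(node))
        if len(side) < 2 or len(all_leaves) - len(side) < 2:
            continue
        if ref not in side:
            side = all_leaves - side
        splits.add(side)
    return splits


def _check_leaves(t1: LineageTree, t2: LineageTree) -> None:
    a, b = set(t1.leaf_names()), set(t2.leaf_names())
    if a != b:
        extra, missing = sorted(b - a), sorted(a - b)
        raise ValueError(f"leaf sets differ (only-in-second: {extra[:5]}, only-in-first: {missing[:5]})")


def bipartition_accuracy(true_tree: LineageTree, inferred_tree: LineageTree) -> float:
    """Fraction of the truth's non-trivial bipartitions recovered."""
    _check_leaves(true_tree, inferred_tree)
    bt = bipartition_set(true_tree)
    bi = bipartition_set(inferred_tree)
    if not bt:
        warnings.warn("true tree has no non-trivial bipartitions; accuracy set to 0")
        return 0.0
    return len(bt & bi) / len(bt)


def rf_distance(t1: LineageTree, t2: LineageTree) -> float:
    """Normalized Robinson-Foulds distance.

    Size of the symmetric difference of the two non-trivial
    bipartition sets, divided by the total number of bipartitions in
    the two trees (their sum).
    """
    _check_leaves(t1, t2)
    b1, b2 = bipartition_set(t1), bipartition_set(t2)
    total = len(b1) + len(b2)
    if total == 0:
        warnings.warn("neither tree has non-trivial bipartitions; RF set to 0")
        return 0.0
    return len(b1 ^ b2) / total


def fp_fn(true_tree: LineageTree, inferred_tree: LineageTree) -> tuple[float, float]:
    """False-positive / false-negative bipartition fractions.

    FP = fraction of inferred bipartitions absent from the truth;
    FN = fraction of true bipartitions absent from the inference.
    Handles non-binary (multifurcating) trees; an empty denominator
    yields 0 with a warning.
    """
    _check_leaves(true_tree, inferred_tree)
    bt = bipartition_set(true_tree)
    bi = bipartition_set(inferred_tree)
    if bi:
        fp = len(bi - bt) / len(bi)
    else:
        warnings.warn("inferred tree has no non-trivial bipartitions; FP set to 0")
        fp = 0.0
    if bt:
        fn = len(bt - bi) / len(bt)
    else:
        warnings.warn("true tree has no non-trivial bipartitions; FN set to 0")
        fn = 0.0
    return fp, fn


def ari(labels_a: Sequence, labels_b: Sequence) -> float:
    """Adjusted Rand index from the contingency table, exact integers.

    Chance-corrected pair-counting agreement of two partitions; 1 for
    identical partitions, ~0 for independent ones. When the
    correction denominator vanishes (both partitions trivial) the
    value is 1.0 if the partitions agree and 0.0 otherwise.
    """
    a = list(labels_a)
    b = list(labels_b)
    if len(a) != len(b):
        raise ValueError("label vectors must have equal length")
    n = len(a)
    table: dict[tuple, int] = {}
    ca: dict = {}
    cb: dict = {}
    for x, y in zip(a, b):
        table[(x, y)] = table.get((x, y), 0) + 1
        ca[x] = ca.get(x, 0) + 1
        cb[y] = cb.get(y, 0) + 1
    sum_ij = sum(math.comb(v, 2) for v in table.values())
    sum_a = sum(math.comb(v, 2) for v in ca.values())
    sum_b = sum(math.comb(v, 2) for v in cb.values())
    pairs = math.comb(n, 2)
    expected = sum_a * sum_b / pairs if pairs else 0.0
    max_index = 0.5 * (sum_a + sum_b)
    denom = max_index - expected
    if denom == 0:
        return 1.0 if sum_ij == max_index else 0.0
    return (sum_ij - expected) / denom


def evaluate_trees(
    true_tree: LineageTree,
    inferred_tree: LineageTree,
    labels_true: Optional[Sequence] = None,
    labels_inferred: Optional[Sequence] = None,
) -> MetricReport:
    """Full report of tree-comparison metrics (and ARI when labels given)."""
    report = MetricReport()
    with warnings.catch_warnings(record=True) as caught:
        warnings.simplefilter("always")
        report.accuracy = bipartition_accuracy(true_tree, inferred_tree)
        report.rf = rf_distance(true_tree, inferred_tree)
        report.fp, report.fn = fp_fn(true_tree, inferred_tree)
    report.warnings = sorted({str(w.message) for w in caught})
    report.n_true_bipartitions = len(bipartition_set(true_tree))
    report.n_inferred_bipartitions = len(bipartition_set(inferred_tree))
    if labels_true is not None and labels_inferred is not None:
        report.ari = ari(labels_true, labels_inferred)
    return report
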