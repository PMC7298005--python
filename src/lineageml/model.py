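"""Model/Results facade tying the inference pipeline together.

``LineageModel`` binds one individual's recorder mutations and
expression matrix; ``fit()`` runs the four-step maximum-likelihood
search and returns a ``LineageResults`` with the annotated tree, its
likelihood components, the BHC cluster cut and the search trace.
``InvariantLineageModel`` consumes two or more fitted individuals and
reconstructs the invariant lineage over matched expression clusters.
"""

from __future__ import annotations

import hashlib
import json
import os
from dataclasses import asdict, dataclass
from pathlib import Path
from typing import Optional, Sequence

import numpy as np
import pandas as pd

from . import tree as treemod
from .clusters import ClusterCutResult, cut_clusters
from .encoding import (
    AlleleTable,
    ExpressionMatrix,
    PairedEventMatrix,
    encode_barcodes,
    expand_to_cells,
    read_allele_table,
    read_expression,
)
from .expression import ExpressionPrior, ExpressionScorer, annotate_stats
from .invariant import (
    InvariantConfig,
    InvariantResult,
    backbone_tree,
    candidate_groups,
    cluster_summaries,
    greedy_match,
    matching_distance,
    optimize_invariant,
)
from .mutation import MutationScorer, annotate_gains
from .search import (
    SearchConfig,
    SearchTrace,
    assemble_and_select,
    combined_log_likelihood,
    refine_combined,
    search_barcode_trees,
    search_cellular_subtree,
)
from .tree import LineageTree, collapse_unsupported

__all__ = ["LineageModel", "LineageResults", "InvariantLineageModel", "InvariantLineageResults"]


def _config_hash(obj) -> str:
    return hashlib.sha256(json.dumps(obj, sort_keys=True, default=str).encode()).hexdigest()[:16]


class LineageModel:
    """Joint mutation + expression lineage tree model for one individual.

    Parameters
    ----------
    markers : AlleleTable or PairedEventMatrix
        Recorder edits per cell; an allele table is binary-encoded on
        construction.
    expression : ExpressionMatrix
        Processed (normalized, log-scale) expression, cells matching
        the marker data.
    prior : ExpressionPrior, optional
        BHC observation-model prior; empirical-Bayes defaults when
        omitted.
    config : SearchConfig, optional
    """

    def __init__(
        self,
        markers: AlleleTable | PairedEventMatrix,
        expression: ExpressionMatrix,
        prior: Optional[ExpressionPrior] = None,
        config: Optional[SearchConfig] = None,
    ):
        self.pem = markers if isinstance(markers, PairedEventMatrix) else encode_barcodes(markers)
        self.expression = expression
        marker_cells = set(self.pem.z)
        expr_cells = set(expression.cell_ids)
        if marker_cells != expr_cells:
            offenders = sorted(marker_cells ^ expr_cells)
            raise ValueError(f"cell ids differ between markers and expression: {offenders[:10]}")
        self.prior = prior if prior is not None else ExpressionPrior.empirical(expression.Y)
        self.config = config if config is not None else SearchConfig()

    @classmethod
    def from_files(
        cls,
        allele_path: str | os.PathLike,
        expression_path: str | os.PathLike,
        **kwargs,
    ) -> "LineageModel":
        return cls(read_allele_table(allele_path), read_expression(expression_path), **kwargs)

    def fit(self, seed: Optional[int] = None, trace: bool = True) -> "LineageResults":
        """Run the four-step search and score/annotate the final tree."""
        config = self.config
        if seed is None:
            seed = config.seed
        rng = np.random.default_rng(seed)
        search_trace = SearchTrace() if trace else None

        expr_scorer = ExpressionScorer(self.expression, self.prior)
        cell_states = expand_to_cells(self.pem)
        m = self.pem.marker_cell_fractions()
        mut_scorer = MutationScorer(cell_states, m)

        barcode_trees = search_barcode_trees(self.pem, config, rng)

        cells_of: dict[str, list[str]] = {b: [] for b in self.pem.barcode_ids}
        for cell, b in self.pem.z.items():
            cells_of[self.pem.barcode_ids[b]].append(cell)
        subtrees = {
            bc: search_cellular_subtree(cells, expr_scorer, config, rng, search_trace)
            for bc, cells in cells_of.items()
            if len(cells) >= 3
        }

        assembled, lt_assembled, lm_thr = assemble_and_select(
            barcode_trees, subtrees, self.pem, mut_scorer, expr_scorer, config
        )
        final = refine_combined(
            assembled, mut_scorer, expr_scorer, config, lm_thr, rng, search_trace
        )

        mscore = mut_scorer.score(final)
        le, stats = expr_scorer.score(final)
        lt = combined_log_likelihood(mscore.total, le, config)
        annotate_gains(final, mscore.assignment)
        annotate_stats(final, stats)
        cut = cut_clusters(final, stats)
        collapsed = collapse_unsupported(final)

        return LineageResults(
            model=self,
            tree=final,
            collapsed_tree=collapsed,
            log_lik_mutation=mscore.total,
            log_lik_expression=le,
            log_lik=lt,
            log_lik_assembled=lt_assembled,
            lm_threshold=lm_thr,
            violations=mscore.violations,
            clusters=cut,
            trace=search_trace,
            seed=seed,
        )


@dataclass
class LineageResults:
    """Fitted lineage tree with likelihoods, clusters and diagnostics."""

    model: LineageModel
    tree: LineageTree
    collapsed_tree: LineageTree
    log_lik_mutation: float
    log_lik_expression: float
    log_lik: float
    log_lik_assembled: float
    lm_threshold: float
    violations: int
    clusters: ClusterCutResult
    trace: Optional[SearchTrace]
    seed: int

    @property
    def n_clusters(self) -> int:
        return len(self.clusters.partition.clusters)

    def cluster_labels(self) -> pd.Series:
        order = self.model.expression.cell_ids
        return pd.Series(self.clusters.partition.labels(order), index=order, name="cluster")

    def summary(self) -> str:
        pem = self.model.pem
        cfg = self.model.config
        lines = [
            "Lineage tree maximum-likelihood fit",
            "=" * 45,
            f"cells:                {len(pem.z):>8d}",
            f"unique barcodes:      {pem.n_barcodes:>8d}",
            f"synthetic markers:    {pem.n_markers:>8d}",
            f"genes:                {len(self.model.expression.gene_ids):>8d}",
            f"weights (mut, expr):  ({cfg.omega1:g}, {cfg.omega2:g})",
            "-" * 45,
            f"log L_M (mutation):   {self.log_lik_mutation:>14.4f}",
            f"log L_E (expression): {self.log_lik_expression:>14.4f}",
            f"L_T (weighted):       {self.log_lik:>14.4f}",
            f"Camin-Sokal reversal markers: {self.violations}",
            f"expression clusters:  {self.n_clusters:>8d}",
            f"seed:                 {self.seed:>8d}",
        ]
        return "\n".join(lines)

    def save(self, out_dir: str | os.PathLike) -> dict[str, str]:
        out = Path(out_dir)
        out.mkdir(parents=True, exist_ok=True)
        paths = {}
        paths["newick"] = str(out / "tree.nwk")
        Path(paths["newick"]).write_text(treemod.write_tree(self.tree, "newick") + "\n")
        paths["json"] = str(out / "tree.json")
        Path(paths["json"]).write_text(treemod.write_tree(self.tree, "json"))
        paths["collapsed"] = str(out / "tree_collapsed.nwk")
        Path(paths["collapsed"]).write_text(treemod.write_tree(self.collapsed_tree, "newick") + "\n")

        labels = self.cluster_labels()
        cut_of = {}
        for k, (cl, cut) in enumerate(
            zip(self.clusters.partition.clusters, self.clusters.partition.cut_nodes)
        ):
            for c in cl:
                cut_of[c] = cut
        cdf = pd.DataFrame(
            {
                "cell_id": labels.index,
                "cluster_id": labels.to_numpy(),
                "cut_node_id": [cut_of[c] for c in labels.index],
            }
        )
        paths["clusters"] = str(out / "clusters.tsv")
        cdf.to_csv(paths["clusters"], sep="\t", index=False)

        if self.trace is not None:
            paths["trace"] = str(out / "trace.tsv")
            self.trace.to_frame().to_csv(paths["trace"], sep="\t", index=False)

        cfg = asdict(self.model.config)
        manifest = {
            "command": "infer",
            "seed": self.seed,
            "config": cfg,
            "config_hash": _config_hash(cfg),
            "log_lik_mutation": self.log_lik_mutation,
            "log_lik_expression": self.log_lik_expression,
            "log_lik": self.log_lik,
            "n_clusters": self.n_clusters,
        }
        paths["manifest"] = str(out / "manifest.json")
        Path(paths["manifest"]).write_text(json.dumps(manifest, indent=2, sort_keys=True))
        return paths


class InvariantLineageModel:
    """Invariant lineage over >= 2 fitted individuals.

    Accepts ``LineageResults`` objects or (tree, cluster sets,
    expression) triples; clusters smaller than ``tc`` cells are
    dropped, candidate cross-individual cluster groups are ranked by
    expression distance, greedily matched, and the invariant topology
    and matching optimized jointly.
    """

    def __init__(
        self,
        individuals: Sequence,
        names: Optional[Sequence[str]] = None,
        config: Optional[InvariantConfig] = None,
    ):
        if len(individuals) < 2:
            raise ValueError("invariant lineage needs at least two individuals")
        self.names = list(names) if names is not None else [f"ind{i}" for i in range(len(individuals))]
        self.trees: list[LineageTree] = []
        self.partitions: list[list[set[str]]] = []
        self.expressions: list[ExpressionMatrix] = []
        for item in individuals:
            if isinstance(item, LineageResults):
                self.trees.append(item.tree)
                self.partitions.append(item.clusters.partition.clusters)
                self.expressions.append(item.model.expression)
            else:
                tree, clusters, em = item
                self.trees.append(tree)
                self.partitions.append([set(c) for c in clusters])
                self.expressions.append(em)
        self.config = config if config is not None else InvariantConfig()

    def fit(self, seed: int = 0) -> "InvariantLineageResults":
        rng = np.random.default_rng(seed)
        cfg = self.config
        summaries = cluster_summaries(self.names, self.partitions, self.expressions, cfg.tc)
        groups = candidate_groups(summaries, cfg.x)
        matching = greedy_match(groups)

        backbones = []
        for i, (tree, name) in enumerate(zip(self.trees, self.names)):
            clusters = [set(g[i].cells) for g in matching.groups]
            labels = [g[i].cluster_id for g in matching.groups]
            backbones.append(backbone_tree(tree, clusters, labels))

        result = optimize_invariant(backbones, matching, cfg, rng)
        return InvariantLineageResults(model=self, result=result, backbones=backbones, seed=seed)


@dataclass
class InvariantLineageResults:
    model: InvariantLineageModel
    result: InvariantResult
    backbones: list[LineageTree]
    seed: int

    @property
    def tree(self) -> LineageTree:
        return self.result.tree

    @property
    def matching(self):
        return self.result.matching

    @property
    def d_s(self) -> float:
        return self.result.d_s

    @property
    def d_e(self) -> float:
        return self.result.d_e

    def matching_frame(self) -> pd.DataFrame:
        rows = []
        for j, group in enumerate(self.matching.groups):
            for cl in group:
                rows.append(
                    {
                        "invariant_leaf": f"c{j}",
                        "individual": cl.individual,
                        "cluster_id": cl.cluster_id,
                        "n_cells": cl.n_cells,
                    }
                )
        return pd.DataFrame(rows)

    def summary(self) -> str:
        r = self.result
        lines = [
            "Invariant lineage reconstruction",
            "=" * 45,
            f"individuals:         {len(self.model.trees):>8d}",
            f"matched groups (K):  {r.matching.K:>8d}",
            "-" * 45,
            f"D_S (topology):      {r.d_s:>14.4f}",
            f"D_E (expression):    {r.d_e:>14.4f}",
            f"objective:           {r.objective:>14.6f}",
            f"D_E threshold:       {r.d_e_thr:>14.4f}",
            f"seed:                {self.seed:>8d}",
        ]
        return "\n".join(lines)

    def save(self, out_dir: str | os.PathLike) -> dict[str, str]:
        out = Path(out_dir)
        out.mkdir(parents=True, exist_ok=True)
        paths = {"newick": str(out / "invariant.nwk"), "json": str(out / "invariant.json")}
        Path(paths["newick"]).write_text(treemod.write_tree(self.tree, "newick") + "\n")
        Path(paths["json"]).write_text(treemod.write_tree(self.tree, "json"))
        paths["matching"] = str(out / "matching.tsv")
        self.matching_frame().to_csv(paths["matching"], sep="\t", index=False)
        cfg = asdict(self.model.config)
        manifest = {
            "command": "invariant",
            "seed": self.seed,
            "config": cfg,
            "config_hash": _config_hash(cfg),
            "d_s": self.d_s,
            "d_e": self.d_e,
            "objective": self.result.objective,
        }
        paths["manifest"] = str(out / "manifest.json")
        Path(paths["manifest"]).write_text(json.dumps(manifest, indent=2, sort_keys=True))
        return paths
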