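"""Input containers: allele tables, binary marker matrices, expression.

A lineage recorder is a genomic array of CRISPR target sites; each
cell's combination of edits (its allele/barcode) is observed once. A
synthetic marker is one distinct (target site, edit label) pair; the
paired-event matrix ``E`` (B unique barcodes x S markers) is the
binary presence/absence encoding, with ``z`` mapping each cell to its
barcode row.
"""

from __future__ import annotations

import os
from dataclasses import dataclass, field
from typing import Optional, Sequence

import numpy as np
import pandas as pd

UNEDITED = "NONE"

__all__ = [
    "AlleleTable",
    "PairedEventMatrix",
    "ExpressionMatrix",
    "encode_barcodes",
    "expand_to_cells",
    "preprocess_expression",
    "read_allele_table",
    "read_expression",
]


@dataclass
class AlleleTable:
    """Per-cell edit labels at each recorder target site.

    ``site_edits[i]`` is the ordered list of edit labels for cell
    ``cell_ids[i]``; the token ``NONE`` marks an unedited site.
    """

    cell_ids: list[str]
    site_edits: list[list[str]]

    def __post_init__(self):
        if len(self.cell_ids) != len(self.site_edits):
            raise ValueError("cell_ids and site_edits length mismatch")
        if len(set(self.cell_ids)) != len(self.cell_ids):
            raise ValueError("cell ids must be unique")
        widths = {len(r) for r in self.site_edits}
        if len(widths) > 1:
            raise ValueError(f"ragged allele table: site counts {sorted(widths)}")

    @property
    def n_sites(self) -> int:
        return len(self.site_edits[0]) if self.site_edits else 0


@dataclass
class PairedEventMatrix:
    """B x S binary barcode-by-marker matrix with the cell -> barcode map."""

    E: np.ndarray  # (B, S) uint8
    barcode_ids: list[str]
    marker_ids: list[str]
    z: dict[str, int]  # cell_id -> barcode row

    def __post_init__(self):
        self.E = np.asarray(self.E, dtype=np.uint8)
        B, S = self.E.shape
        if len(self.barcode_ids) != B or len(self.marker_ids) != S:
            raise ValueError("id lengths inconsistent with E")
        if any(not (0 <= b < B) for b in self.z.values()):
            raise ValueError("z maps a cell outside the barcode range")
        if S and (self.E.sum(axis=0) == 0).any():
            raise ValueError("every marker column must have at least one carrier")
        if B > 1 and len({r.tobytes() for r in self.E}) != B:
            raise ValueError("barcode rows must be pairwise distinct")

    @property
    def n_barcodes(self) -> int:
        return self.E.shape[0]

    @property
    def n_markers(self) -> int:
        return self.E.shape[1]

    @property
    def cell_ids(self) -> list[str]:
        return list(self.z)

    def marker_cell_fractions(self) -> np.ndarray:
        """m_s: fraction of *cells* (not barcodes) harboring each marker."""
        M = expand_to_cells(self)
        return M.to_numpy().mean(axis=0)


@dataclass
class ExpressionMatrix:
    """N cells x G genes processed (normalized, log-scale) expression."""

    Y: np.ndarray
    cell_ids: list[str]
    gene_ids: list[str]

    def __post_init__(self):
        self.Y = np.asarray(self.Y, dtype=float)
        if self.Y.shape != (len(self.cell_ids), len(self.gene_ids)):
            raise ValueError("Y shape inconsistent with ids")
        if not np.all(np.isfinite(self.Y)):
            raise ValueError("expression values must be finite")

    def subset(self, cells: Sequence[str]) -> "ExpressionMatrix":
        index = {c: i for i, c in enumerate(self.cell_ids)}
        rows = [index[c] for c in cells]
        return ExpressionMatrix(self.Y[rows], list(cells), list(self.gene_ids))

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(self.Y, index=self.cell_ids, columns=self.gene_ids)


def encode_barcodes(table: AlleleTable) -> PairedEventMatrix:
    """Binary-encode an allele table into the paired-event matrix.

    Markers are the distinct (site, edit label) pairs with label !=
    ``NONE``, ordered by site then label; barcodes are the distinct
    binary profiles, ordered by first occurrence over cells.
    """
    if not table.cell_ids:
        raise ValueError("empty allele table")
    markers: list[tuple[int, str]] = sorted(
        {
            (s, lab)
            for row in table.site_edits
            for s, lab in enumerate(row)
            if lab != UNEDITED
        }
    )
    marker_index = {m: j for j, m in enumerate(markers)}
    S = len(markers)

    profiles: dict[bytes, int] = {}
    rows: list[np.ndarray] = []
    z: dict[str, int] = {}
    for cell, row in zip(table.cell_ids, table.site_edits):
        vec = np.zeros(S, dtype=np.uint8)
        for s, lab in enumerate(row):
            if lab != UNEDITED:
                vec[marker_index[(s, lab)]] = 1
        key = vec.tobytes()
        if key not in profiles:
            profiles[key] = len(rows)
            rows.append(vec)
        z[cell] = profiles[key]

    E = np.vstack(rows) if rows else np.zeros((0, S), dtype=np.uint8)
    barcode_ids = [f"bc{b}" for b in range(len(rows))]
    marker_ids = [f"s{s}:{lab}" for s, lab in markers]
    return PairedEventMatrix(E, barcode_ids, marker_ids, z)


def expand_to_cells(pem: PairedEventMatrix) -> pd.DataFrame:
    """Expand the B x S barcode matrix to the N x S cell-level matrix."""
    cells = list(pem.z)
    if not cells:
        raise ValueError("paired-event matrix maps no cells")
    M = pem.E[[pem.z[c] for c in cells], :]
    return pd.DataFrame(M, index=cells, columns=pem.marker_ids)


# ---- expression preprocessing ------------------------------------

def preprocess_expression(
    counts: pd.DataFrame,
    impute: bool = False,
    k_range: range = range(2, 11),
    random_state: int = 0,
) -> ExpressionMatrix:
    """Normalize raw counts to an analysis-ready expression matrix.

    Pipeline: (optional) cluster-mean imputation of zeros, per-cell
    library-size scaling to the median total, then log2(x + 1). The
    imputer is a simple stand-in built on k-means (k selected by
    silhouette over ``k_range``): each zero entry is replaced by the
    mean of the nonzero values of that gene among the cells of its
    cluster.
    """
    X = counts.to_numpy(dtype=float)
    if (X < 0).any():
        raise ValueError("counts must be nonnegative")
    totals = X.sum(axis=1)
    dead = np.flatnonzero(totals == 0)
    if dead.size:
        names = [str(counts.index[i]) for i in dead]
        raise ValueError(f"all-zero cell(s): {', '.join(names)}")

    if impute:
        X = _impute_cluster_mean(X, k_range=k_range, random_state=random_state)
        totals = X.sum(axis=1)

    scale = np.median(totals) / totals
    Y = np.log2(X * scale[:, None] + 1.0)
    return ExpressionMatrix(Y, [str(c) for c in counts.index], [str(g) for g in counts.columns])


def _impute_cluster_mean(X: np.ndarray, k_range: range, random_state: int) -> np.ndarray:
    from sklearn.cluster import KMeans
    from sklearn.metrics import silhouette_score

    n = X.shape[0]
    L = np.log2(X + 1.0)
    best_labels, best_score = np.zeros(n, dtype=int), -np.inf
    for k in k_range:
        if k >= n or k < 2:
            continue
        km = KMeans(n_clusters=k, n_init=10, random_state=random_state)
        labels = km.fit_predict(L)
        if len(set(labels)) < 2:
            continue
        score = silhouette_score(L, labels)
        if score > best_score:
            best_labels, best_score = labels, score
    out = X.copy()
    for k in np.unique(best_labels):
        members = np.flatnonzero(best_labels == k)
        block = X[members]
        nz = block > 0
        with np.errstate(invalid="ignore"):
            means = np.where(nz.any(axis=0), block.sum(axis=0) / np.maximum(nz.sum(axis=0), 1), 0.0)
        zero_mask = block == 0
        out[np.ix_(members, range(X.shape[1]))] = np.where(zero_mask, means, block)
    return out


# ---- file IO ------------------------------------------------------

def read_allele_table(path: str | os.PathLike) -> AlleleTable:
    """Read a TSV allele table (``cell_id<TAB>site_1...``; ``NONE`` = unedited)."""
    df = pd.read_csv(path, sep="\t", dtype=str).fillna(UNEDITED)
    if df.shape[1] < 2:
        raise ValueError("allele table needs a cell_id column and >=1 site column")
    return AlleleTable(
        cell_ids=[str(c) for c in df.iloc[:, 0]],
        site_edits=df.iloc[:, 1:].to_numpy(dtype=str).tolist(),
    )


def write_allele_table(table: AlleleTable, path: str | os.PathLike) -> None:
    cols = [f"site_{i + 1}" for i in range(table.n_sites)]
    df = pd.DataFrame(table.site_edits, columns=cols)
    df.insert(0, "cell_id", table.cell_ids)
    df.to_csv(path, sep="\t", index=False)


def read_expression(
    path: str | os.PathLike,
    cells_path: Optional[str | os.PathLike] = None,
    genes_path: Optional[str | os.PathLike] = None,
) -> ExpressionMatrix:
    """Read expression as TSV (cells x genes, headers) or MTX + name files."""
    path = os.fspath(path)
    if path.endswith(".mtx"):
        import scipy.io as sio

        if cells_path is None or genes_path is None:
            raise ValueError("MTX input requires row (cells) and column (genes) name files")
        M = sio.mmread(path)
        Y = np.asarray(M.todense()) if hasattr(M, "todense") else np.asarray(M)
        cells = [l.strip() for l in open(cells_path) if l.strip()]
        genes = [l.strip() for l in open(genes_path) if l.strip()]
        return ExpressionMatrix(Y, cells, genes)
    df = pd.read_csv(path, sep="\t", index_col=0)
    return ExpressionMatrix(df.to_numpy(dtype=float), [str(c) for c in df.index], [str(g) for g in df.columns])


def write_expression(em: ExpressionMatrix, path: str | os.PathLike) -> None:
    em.to_frame().to_csv(path, sep="\t")
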