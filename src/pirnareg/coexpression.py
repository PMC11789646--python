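"""Ranking of DNA-binding transcription factors by average Pearson
coexpression with a seed module of germline piRNA-pathway genes.

Given a gene-by-cell count matrix, each flagged TF that is detected in
enough cells of the chosen subset is scored by the mean Pearson ``r``
between its (log-normalised) expression and each seed gene's, across
cells.  The TF-level p-value combines the per-seed-gene correlation
tests conservatively (the *least* significant one) and is then
Bonferroni-adjusted for the total number of (TF, seed gene) tests.
The output is a deterministic ranking: a planted master regulator of the
seed module should land at rank 1.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
from scipy import stats as sps

__all__ = [
    "CellMatrix",
    "RankedTF",
    "UndefinedCorrelation",
    "normalize_counts",
    "pearson_r",
    "correlation_pvalue",
    "bonferroni",
    "rank_tfs",
]


class UndefinedCorrelation(ValueError):
    """Raised when a correlation is undefined (zero variance)."""


@dataclass
class CellMatrix:
    """Gene-by-cell integer counts with cell labels and gene flags.

    ``counts`` has shape (n_genes, n_cells); ``cell_labels`` maps each
    cell to a cluster/type label; ``gene_flags`` is indexed by gene id
    with boolean columns ``is_tf`` and ``is_seed``.
    """

    counts: np.ndarray
    gene_ids: list[str]
    cell_ids: list[str]
    cell_labels: pd.Series
    gene_flags: pd.DataFrame

    def __post_init__(self) -> None:
        self.counts = np.asarray(self.counts)
        n_genes, n_cells = self.counts.shape
        if len(self.gene_ids) != n_genes or len(self.cell_ids) != n_cells:
            raise ValueError("counts shape inconsistent with gene/cell ids")
        if len(set(self.gene_ids)) != n_genes or len(set(self.cell_ids)) != n_cells:
            raise ValueError("gene and cell ids must be unique")
        if np.any(self.counts < 0) or not np.issubdtype(self.counts.dtype, np.integer):
            raise ValueError("counts must be non-negative integers")

    @property
    def n_genes(self) -> int:
        return self.counts.shape[0]

    @property
    def n_cells(self) -> int:
        return self.counts.shape[1]

    def cells_where(self, label: str) -> list[str]:
        return list(self.cell_labels.index[self.cell_labels == label])

    # -- plain-text I/O ----------------------------------------------------
    def write(self, matrix_path, labels_path) -> None:
        pd.DataFrame(self.counts, index=self.gene_ids, columns=self.cell_ids).to_csv(
            matrix_path, sep="\t", index_label="gene_id"
        )
        self.cell_labels.rename("label").to_frame().to_csv(
            labels_path, sep="\t", index_label="cell_id"
        )

    @classmethod
    def read(cls, matrix_path, labels_path, gene_flags: pd.DataFrame) -> "CellMatrix":
        mat = pd.read_csv(matrix_path, sep="\t", index_col="gene_id")
        labels = pd.read_csv(labels_path, sep="\t", index_col="cell_id")["label"]
        return cls(
            mat.to_numpy(dtype=np.int64),
            list(mat.index),
            list(mat.columns),
            labels,
            gene_flags,
        )


@dataclass(frozen=True)
class RankedTF:
    """One row of the ranked-TF output."""

    tf_id: str
    mean_r: float
    p_raw: float
    p_adj: float
    n_cells: int
    n_tests: int
    rank: int


def normalize_counts(m: CellMatrix, scale: float = 1e4) -> np.ndarray:
    """Log-normalise: ``log(1 + scale * count / cell_total)`` per cell.

    Doubling all counts of a cell leaves its column unchanged.
    """
    totals = m.counts.sum(axis=0)
    zero = np.where(totals == 0)[0]
    if len(zero):
        raise ValueError(f"cell {m.cell_ids[zero[0]]!r} has zero total counts")
    return np.log1p(scale * m.counts / totals)


def pearson_r(x: np.ndarray, y: np.ndarray) -> float:
    """Product-moment correlation; raises on zero variance or n < 3."""
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.shape != y.shape or x.ndim != 1:
        raise ValueError("x and y must be 1-D vectors of equal length")
    if len(x) < 3:
        raise ValueError("need at least 3 observations")
    xd = x - x.mean()
    yd = y - y.mean()
    sx = np.sqrt(np.dot(xd, xd))
    sy = np.sqrt(np.dot(yd, yd))
    if sx == 0 or sy == 0:
        raise UndefinedCorrelation("zero variance in input vector")
    return float(np.clip(np.dot(xd, yd) / (sx * sy), -1.0, 1.0))


def correlation_pvalue(r: float, n: int) -> float:
    """Two-sided p for a Pearson ``r`` via the t-transform.

    ``t = r * sqrt((n - 2) / (1 - r^2))`` on ``n - 2`` degrees of
    freedom.  |r| = 1 returns the smallest positive float.
    """
    if n < 3:
        raise ValueError("need n >= 3")
    if abs(r) >= 1.0:
        return float(np.nextafter(0, 1))
    t = r * np.sqrt((n - 2) / (1.0 - r * r))
    return float(2.0 * sps.t.sf(abs(t), df=n - 2))


def bonferroni(p: float, m: int) -> float:
    """Bonferroni adjustment: ``min(1, m * p)``."""
    if not 0 < p <= 1:
        raise ValueError("p must be in (0, 1]")
    if m < 1:
        raise ValueError("m must be >= 1")
    return min(1.0, m * p)


def rank_tfs(
    m: CellMatrix,
    seed_gene_ids: Sequence[str],
    cell_subset: Sequence[str] | None = None,
    min_detect_frac: float = 0.01,
    scale: float = 1e4,
) -> tuple[list[RankedTF], dict[str, str]]:
    """Rank flagged TFs by mean Pearson ``r`` with the seed module.

    Per TF: ``mean_r`` averages ``pearson_r(TF, seed)`` over seed genes
    on log-normalised values; ``p_raw`` is the *maximum* per-seed-gene
    correlation p-value (conservative combination); ``p_adj`` applies
    Bonferroni with ``m = (#tested TFs) x (#seed genes)``.  TFs detected
    in fewer than ``min_detect_frac`` of subset cells, or with zero
    variance, are excluded and reported with the reason.

    Returns ``(ranked list, {excluded tf_id: reason})``; the list is
    sorted by (mean_r desc, p_adj asc, tf_id asc) with ranks 1..K.
    """
    gene_index = {g: i for i, g in enumerate(m.gene_ids)}
    for s in seed_gene_ids:
        if s not in gene_index:
            raise ValueError(f"seed gene {s!r} absent from matrix")
    if cell_subset is None:
        cols = np.arange(m.n_cells)
    else:
        cell_index = {c: j for j, c in enumerate(m.cell_ids)}
        cols = np.array([cell_index[c] for c in cell_subset])
    if len(cols) < 3:
        raise ValueError("need at least 3 cells in the subset")

    sub = CellMatrix(
        m.counts[:, cols],
        m.gene_ids,
        [m.cell_ids[j] for j in cols],
        m.cell_labels.iloc[cols],
        m.gene_flags,
    )
    X = normalize_counts(sub, scale=scale)
    n = len(cols)

    seed_rows = [gene_index[s] for s in seed_gene_ids]
    for s, row in zip(seed_gene_ids, seed_rows):
        if np.count_nonzero(sub.counts[row]) == 0:
            raise ValueError(f"seed gene {s!r} undetected in subset")
        if np.std(X[row]) == 0:
            raise UndefinedCorrelation(f"seed gene {s!r} has zero variance in subset")

    tf_ids = [g for g in m.gene_ids if m.gene_flags.loc[g, "is_tf"]]
    if not tf_ids:
        raise ValueError("no genes flagged as TFs")

    excluded: dict[str, str] = {}
    tested: list[str] = []
    for tf in tf_ids:
        row = gene_index[tf]
        frac = np.count_nonzero(sub.counts[row]) / n
        if frac < min_detect_frac:
            excluded[tf] = "undetected"
        elif np.std(X[row]) == 0:
            excluded[tf] = "zero_variance"
        else:
            tested.append(tf)

    n_tests = len(tested) * len(seed_gene_ids)
    results = []
    for tf in tested:
        xs = X[gene_index[tf]]
        rs = [pearson_r(xs, X[row]) for row in seed_rows]
        ps = [correlation_pvalue(r, n) for r in rs]
        p_raw = max(ps)
        results.append((tf, float(np.mean(rs)), p_raw, bonferroni(p_raw, n_tests)))

    results.sort(key=lambda t: (-t[1], t[3], t[0]))
    ranked = [
        RankedTF(tf, mean_r, p_raw, p_adj, n_cells=n, n_tests=n_tests, rank=i + 1)
        for i, (tf, mean_r, p_raw, p_adj) in enumerate(results)
    ]
    return ranked, excluded


RANKED_TF_COLUMNS = ["tf_id", "mean_r", "p_raw", "p_adj", "n_cells", "rank"]


def ranked_tfs_frame(ranked: Sequence[RankedTF]) -> pd.DataFrame:
    """Ranked-TF table with fixed column order, ready for TSV output."""
    return pd.DataFrame(
        [
            {
                "tf_id": r.tf_id,
                "mean_r": r.mean_r,
                "p_raw": r.p_raw,
                "p_adj": r.p_adj,
                "n_cells": r.n_cells,
                "rank": r.rank,
            }
            for r in ranked
        ],
        columns=RANKED_TF_COLUMNS,
    )
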