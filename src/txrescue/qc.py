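"""Nucleus- and gene-level quality control for single-nucleus count matrices.

Cells are kept when their detected-gene count lies strictly between the lower
and upper bounds and their mitochondrial fraction is strictly below the cap;
genes are then kept when expressed (count > 0) in at least ``min_cells_per_gene``
of the *kept* cells.  All comparisons are strict, following the usual
"greater than / less than / fewer than" phrasing of these filters.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
import anndata as ad
from scipy import sparse

log = logging.getLogger(__name__)


@dataclass(frozen=True)
class QCThresholds:
    min_genes_per_cell: int = 200    # exclusive
    max_genes_per_cell: int = 5000   # exclusive
    max_mito_pct: float = 5.0        # exclusive
    min_cells_per_gene: int = 3      # inclusive
    mito_prefix: str = "mt-"         # case-insensitive

    def __post_init__(self) -> None:
        if self.min_genes_per_cell >= self.max_genes_per_cell:
            raise ValueError("min_genes_per_cell must be below max_genes_per_cell")
        if not 0.0 < self.max_mito_pct <= 100.0:
            raise ValueError("max_mito_pct must lie in (0, 100]")
        if self.min_cells_per_gene < 0:
            raise ValueError("min_cells_per_gene must be nonnegative")


@dataclass
class QCReport:
    cells_in: int
    cells_out: int
    genes_in: int
    genes_out: int
    removed: dict[str, int] = field(default_factory=dict)

    def __post_init__(self) -> None:
        if self.cells_out > self.cells_in or self.genes_out > self.genes_in:
            raise ValueError("QC cannot increase the number of cells or genes")

    def to_dict(self) -> dict:
        return {"cells_in": self.cells_in, "cells_out": self.cells_out,
                "genes_in": self.genes_in, "genes_out": self.genes_out,
                "removed": dict(self.removed)}


def _mito_mask(var_names, mito_prefix: str) -> np.ndarray:
    prefix = mito_prefix.lower()
    return np.array([str(g).lower().startswith(prefix) for g in var_names])


def cell_metrics(adata: ad.AnnData, mito_prefix: str = "mt-") -> pd.DataFrame:
    """Per-cell totals, detected genes and mitochondrial percentage.

    Mito percent is 100 x (counts on mito-prefixed genes / total counts) and
    defined as 0 for all-zero cells.
    """
    X = adata.X
    if sparse.issparse(X):
        X = X.tocsr()
        total = np.asarray(X.sum(axis=1)).ravel()
        n_genes = X.getnnz(axis=1)
        mito = _mito_mask(adata.var_names, mito_prefix)
        mito_total = (np.asarray(X[:, mito].sum(axis=1)).ravel()
                      if mito.any() else np.zeros_like(total))
    else:
        X = np.asarray(X)
        total = X.sum(axis=1)
        n_genes = (X > 0).sum(axis=1)
        mito = _mito_mask(adata.var_names, mito_prefix)
        mito_total = X[:, mito].sum(axis=1) if mito.any() else np.zeros_like(total)
    with np.errstate(invalid="ignore", divide="ignore"):
        pct = np.where(total > 0, 100.0 * mito_total / np.maximum(total, 1e-300), 0.0)
    return pd.DataFrame({"total_counts": total, "n_genes": n_genes,
                         "pct_mito": pct}, index=adata.obs_names)


def apply_qc(adata: ad.AnnData,
             thresholds: QCThresholds = QCThresholds()) -> tuple[ad.AnnData, QCReport]:
    """Filter cells then genes; returns the filtered assay and a report.

    Removal reasons are attributed in order min_genes, max_genes, mito (first
    matching reason counts), so the per-reason tallies sum to the number of
    removed cells.
    """
    t = thresholds
    metrics = cell_metrics(adata, t.mito_prefix)
    low = metrics["n_genes"].to_numpy() <= t.min_genes_per_cell
    high = (~low) & (metrics["n_genes"].to_numpy() >= t.max_genes_per_cell)
    mito = (~low) & (~high) & (metrics["pct_mito"].to_numpy() >= t.max_mito_pct)
    keep_cells = ~(low | high | mito)

    filtered = adata[keep_cells].copy()
    if filtered.n_obs == 0:
        log.warning("apply_qc removed every cell")
        kept_genes = np.zeros(adata.n_vars, dtype=bool)
    else:
        X = filtered.X
        expressed = (X > 0)
        n_cells_expr = (np.asarray(expressed.sum(axis=0)).ravel()
                        if sparse.issparse(X) else expressed.sum(axis=0))
        kept_genes = n_cells_expr >= t.min_cells_per_gene
    genes_removed = int((~kept_genes).sum())
    filtered = filtered[:, kept_genes].copy()

    report = QCReport(
        cells_in=adata.n_obs, cells_out=filtered.n_obs,
        genes_in=adata.n_vars, genes_out=filtered.n_vars,
        removed={"min_genes": int(low.sum()), "max_genes": int(high.sum()),
                 "mito": int(mito.sum()), "low_expression_genes": genes_removed})
    return filtered, report
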