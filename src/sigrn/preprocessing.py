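"""Filtering and normalization chain applied before model training.

Order is fixed: gene filter (expressed in fewer than ``ceil(f*|C|)`` cells),
cell filter (fewer than ``min_genes_per_cell`` expressed genes), optional
per-cell total normalization, optional highly-variable-gene selection, log2
transform, per-gene z-scoring.  The chain is deterministic.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np

from .io_formats import ExpressionMatrix


@dataclass
class PreprocessConfig:
    min_cell_fraction: float = 0.01
    min_genes_per_cell: int = 10
    per_cell_target_total: float | None = None
    n_hvg: int | None = None
    do_log2: bool = True
    do_zscore: bool = True

    def __post_init__(self) -> None:
        if not 0.0 <= self.min_cell_fraction <= 1.0:
            raise ValueError("min_cell_fraction must lie in [0, 1]")
        if self.min_genes_per_cell < 0:
            raise ValueError("min_genes_per_cell must be nonnegative")


@dataclass
class FilterReport:
    n_genes_removed: int
    n_cells_removed: int
    genes_removed: list[str]
    cells_removed: list[str]


def filter_matrix(
    X: ExpressionMatrix, cfg: PreprocessConfig
) -> tuple[ExpressionMatrix, FilterReport]:
    """Remove rarely expressed genes, then sparsely expressed cells.

    A gene survives if it is nonzero in at least ``ceil(min_cell_fraction*|C|)``
    cells (counted on the input matrix); a cell survives if it has at least
    ``min_genes_per_cell`` nonzero genes among the surviving genes.  Applied
    once, genes before cells.
    """
    vals = X.values
    n_cells = vals.shape[0]
    gene_thresh = math.ceil(cfg.min_cell_fraction * n_cells)
    gene_nonzero = np.count_nonzero(vals, axis=0)
    gene_keep = gene_nonzero >= gene_thresh
    vals2 = vals[:, gene_keep]
    cell_nonzero = np.count_nonzero(vals2, axis=1)
    cell_keep = cell_nonzero >= cfg.min_genes_per_cell
    out_vals = vals2[cell_keep, :]
    if out_vals.size == 0 or out_vals.shape[0] == 0 or out_vals.shape[1] == 0:
        raise ValueError("filtering removed every gene or every cell")
    genes_removed = [g for g, k in zip(X.gene_ids, gene_keep) if not k]
    cells_removed = [c for c, k in zip(X.cell_ids, cell_keep) if not k]
    out = ExpressionMatrix(
        out_vals,
        [c for c, k in zip(X.cell_ids, cell_keep) if k],
        [g for g, k in zip(X.gene_ids, gene_keep) if k],
    )
    report = FilterReport(
        n_genes_removed=len(genes_removed),
        n_cells_removed=len(cells_removed),
        genes_removed=genes_removed,
        cells_removed=cells_removed,
    )
    return out, report


def normalize_per_cell(X: ExpressionMatrix, target_total: float) -> ExpressionMatrix:
    """Scale each cell so its total expression equals ``target_total``."""
    if target_total <= 0:
        raise ValueError("target_total must be positive")
    totals = X.values.sum(axis=1)
    zero = np.nonzero(totals == 0)[0]
    if zero.size:
        raise ValueError(f"cell(s) with zero total expression: {[X.cell_ids[i] for i in zero]}")
    scaled = X.values * (target_total / totals)[:, None]
    return ExpressionMatrix(scaled, list(X.cell_ids), list(X.gene_ids))


def log2_transform(X: ExpressionMatrix) -> ExpressionMatrix:
    """Replace each value v by log2(v + 1); requires v >= 0."""
    if np.any(X.values < 0):
        raise ValueError("log2 transform requires nonnegative values")
    return ExpressionMatrix(np.log2(X.values + 1.0), list(X.cell_ids), list(X.gene_ids))


def zscore_genes(X: ExpressionMatrix) -> ExpressionMatrix:
    """Center and scale each gene column (population sd, ddof 0).

    Constant genes become all-zero columns rather than being dropped.
    """
    if X.n_cells < 2:
        raise ValueError("z-scoring needs at least two cells")
    mean = X.values.mean(axis=0)
    sd = X.values.std(axis=0)
    out = np.zeros_like(X.values)
    nonconst = sd > 0
    out[:, nonconst] = (X.values[:, nonconst] - mean[nonconst]) / sd[nonconst]
    return ExpressionMatrix(out, list(X.cell_ids), list(X.gene_ids))


def dispersion(X: ExpressionMatrix) -> np.ndarray:
    """Per-gene dispersion: variance / mean of log1p of the values.

    Genes with zero mean after the transform get dispersion 0.
    """
    logged = np.log1p(np.maximum(X.values, 0.0))
    mean = logged.mean(axis=0)
    var = logged.var(axis=0)
    disp = np.zeros(X.n_genes)
    nz = mean > 0
    disp[nz] = var[nz] / mean[nz]
    return disp


def select_hvg(X: ExpressionMatrix, n: int) -> ExpressionMatrix:
    """Keep the n most dispersed genes; output preserves original gene order.

    Ties in dispersion are broken by gene name ascending, so the selected set
    is reproducible.
    """
    if n <= 0:
        raise ValueError("n must be positive")
    if n > X.n_genes:
        raise ValueError(f"asked for {n} highly variable genes but only {X.n_genes} present")
    disp = dispersion(X)
    order = sorted(range(X.n_genes), key=lambda i: (-disp[i], X.gene_ids[i]))
    chosen = set(order[:n])
    keep = [i for i in range(X.n_genes) if i in chosen]
    return ExpressionMatrix(
        X.values[:, keep], list(X.cell_ids), [X.gene_ids[i] for i in keep]
    )


def preprocess(
    X: ExpressionMatrix, cfg: PreprocessConfig | None = None
) -> tuple[ExpressionMatrix, FilterReport]:
    """Run the full chain: filter, normalize, HVG, log2, z-score."""
    cfg = cfg or PreprocessConfig()
    X, report = filter_matrix(X, cfg)
    if cfg.per_cell_target_total is not None:
        X = normalize_per_cell(X, cfg.per_cell_target_total)
    if cfg.n_hvg is not None:
        X = select_hvg(X, cfg.n_hvg)
    if cfg.do_log2:
        X = log2_transform(X)
    if cfg.do_zscore:
        X = zscore_genes(X)
    return X, report
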