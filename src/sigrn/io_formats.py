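"""Readers and writers for expression matrices, edge lists and edge rankings.

Expression matrices arrive either as delimited text (one header row, one label
column; comma or tab autodetected) or as a matrix-market triplet file with
sidecar ``<stem>_genes.txt`` / ``<stem>_cells.txt`` label files.  Ground-truth
networks use the BEELINE ``Gene1,Gene2`` dialect: directed edges, regulator
first.  All gene/cell matching is exact and case-sensitive.
"""

from __future__ import annotations

import os
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Sequence

import numpy as np
import pandas as pd
import scipy.io
import scipy.sparse


@dataclass
class ExpressionMatrix:
    """A labeled cells x genes real-valued matrix.

    ``values[c, g]`` is the expression of gene ``gene_ids[g]`` in cell
    ``cell_ids[c]``.  Labels are unique; values are finite.
    """

    values: np.ndarray
    cell_ids: list[str]
    gene_ids: list[str]

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        self.cell_ids = [str(c) for c in self.cell_ids]
        self.gene_ids = [str(g) for g in self.gene_ids]
        if self.values.ndim != 2:
            raise ValueError("expression values must be a 2-D matrix")
        n_c, n_g = self.values.shape
        if n_c < 1 or n_g < 1:
            raise ValueError("expression matrix must have at least one cell and one gene")
        if len(self.cell_ids) != n_c or len(self.gene_ids) != n_g:
            raise ValueError("label lengths do not match matrix shape")
        for kind, labels in (("cell", self.cell_ids), ("gene", self.gene_ids)):
            dupes = _duplicates(labels)
            if dupes:
                raise ValueError(f"duplicate {kind} labels: {sorted(dupes)}")
        if not np.all(np.isfinite(self.values)):
            bad = np.argwhere(~np.isfinite(self.values))[0]
            raise ValueError(f"non-finite value at cell row {bad[0]}, gene column {bad[1]}")

    @property
    def n_cells(self) -> int:
        return self.values.shape[0]

    @property
    def n_genes(self) -> int:
        return self.values.shape[1]

    def copy(self) -> "ExpressionMatrix":
        return ExpressionMatrix(self.values.copy(), list(self.cell_ids), list(self.gene_ids))


@dataclass
class EdgeListReport:
    """Load report for a ground-truth edge list."""

    n_rows: int
    n_self_loops: int
    n_after_dedup: int


@dataclass
class GroundTruthNetwork:
    """Directed ground-truth regulatory network over gene names."""

    edges: set[tuple[str, str]]
    gene_universe: set[str]
    report: EdgeListReport | None = field(default=None, compare=False)

    def __post_init__(self) -> None:
        if len(self.edges) < 1:
            raise ValueError("ground-truth network must contain at least one edge")
        for reg, tgt in self.edges:
            if reg == tgt:
                raise ValueError(f"self-loop edge ({reg},{tgt}) in ground truth")
            if reg not in self.gene_universe or tgt not in self.gene_universe:
                raise ValueError(f"edge ({reg},{tgt}) has endpoint outside gene universe")


def _duplicates(labels: Sequence[str]) -> set[str]:
    seen: set[str] = set()
    dupes: set[str] = set()
    for lab in labels:
        if lab in seen:
            dupes.add(lab)
        seen.add(lab)
    return dupes


def _detect_sep(header_line: str) -> str:
    return "\t" if header_line.count("\t") >= header_line.count(",") else ","


def read_expression_matrix(path: str | os.PathLike, orientation: str = "cells-in-rows") -> ExpressionMatrix:
    """Read an expression matrix from delimited text or matrix-market triplets.

    Parameters
    ----------
    path
        ``*.mtx`` triggers the matrix-market route (sidecar label files
        required); anything else is parsed as delimited text with a header
        row and a first label column.
    orientation
        How the on-disk matrix is laid out; the returned matrix is always
        cells x genes.
    """
    if orientation not in ("cells-in-rows", "genes-in-rows"):
        raise ValueError(f"unknown orientation {orientation!r}")
    path = Path(path)
    if path.suffix == ".mtx":
        values, row_labels, col_labels = _read_mtx(path, orientation)
    else:
        with open(path) as fh:
            header = fh.readline().rstrip("\n")
        sep = _detect_sep(header)
        col_dupes = _duplicates(header.split(sep)[1:])
        if col_dupes:
            raise ValueError(f"duplicate column labels: {sorted(col_dupes)}")
        df = pd.read_csv(path, sep=sep, index_col=0, float_precision="round_trip")
        try:
            values = df.to_numpy(dtype=float)
        except ValueError as exc:
            # locate the offending cell for a precise error
            for i, row in enumerate(df.itertuples(index=False)):
                for j, v in enumerate(row):
                    try:
                        float(v)
                    except (TypeError, ValueError):
                        raise ValueError(
                            f"non-numeric value {v!r} at data row {i}, column {df.columns[j]!r}"
                        ) from exc
            raise
        row_labels = [str(x) for x in df.index]
        col_labels = [str(x) for x in df.columns]
    if orientation == "genes-in-rows":
        values = values.T
        row_labels, col_labels = col_labels, row_labels
    return ExpressionMatrix(values, row_labels, col_labels)


def _read_mtx(path: Path, orientation: str) -> tuple[np.ndarray, list[str], list[str]]:
    mat = scipy.io.mmread(path)
    if scipy.sparse.issparse(mat):
        mat = mat.toarray()
    mat = np.asarray(mat, dtype=float)
    stem = path.with_suffix("")
    gene_file = Path(str(stem) + "_genes.txt")
    cell_file = Path(str(stem) + "_cells.txt")
    for f in (gene_file, cell_file):
        if not f.exists():
            raise FileNotFoundError(f"matrix-market sidecar label file missing: {f}")
    genes = [ln.strip() for ln in gene_file.read_text().splitlines() if ln.strip()]
    cells = [ln.strip() for ln in cell_file.read_text().splitlines() if ln.strip()]
    if orientation == "cells-in-rows":
        row_labels, col_labels = cells, genes
    else:
        row_labels, col_labels = genes, cells
    if mat.shape != (len(row_labels), len(col_labels)):
        raise ValueError(
            f"matrix shape {mat.shape} does not match labels "
            f"({len(row_labels)} rows, {len(col_labels)} cols)"
        )
    return mat, row_labels, col_labels


def read_edge_list(path: str | os.PathLike) -> GroundTruthNetwork:
    """Read a BEELINE-dialect directed edge list (``Gene1`` -> ``Gene2``).

    Header columns are matched case-insensitively; extra columns are ignored.
    Self-loops are dropped, duplicates collapsed; counts land in ``report``.
    """
    path = Path(path)
    with open(path) as fh:
        sep = _detect_sep(fh.readline())
    df = pd.read_csv(path, sep=sep, dtype=str)
    lower = {c.lower(): c for c in df.columns}
    if "gene1" not in lower or "gene2" not in lower:
        raise ValueError(
            f"edge list must contain Gene1 and Gene2 columns; found {list(df.columns)}"
        )
    regs = df[lower["gene1"]].astype(str)
    tgts = df[lower["gene2"]].astype(str)
    n_rows = len(df)
    pairs = list(zip(regs, tgts))
    n_self = sum(1 for r, t in pairs if r == t)
    edges = {(r, t) for r, t in pairs if r != t}
    universe = {g for e in edges for g in e}
    report = EdgeListReport(n_rows=n_rows, n_self_loops=n_self, n_after_dedup=len(edges))
    return GroundTruthNetwork(edges=edges, gene_universe=universe, report=report)


def restrict_truth_to_genes(
    truth: GroundTruthNetwork, genes: Iterable[str]
) -> tuple[GroundTruthNetwork, set[str]]:
    """Drop ground-truth genes (and their edges) absent from ``genes``.

    Returns the restricted network and the set of dropped gene names, so the
    caller can report them.  Matching is exact and case-sensitive.
    """
    present = set(genes)
    missing = truth.gene_universe - present
    kept = {(r, t) for r, t in truth.edges if r in present and t in present}
    if not kept:
        raise ValueError("no ground-truth edge survives restriction to the expression genes")
    universe = truth.gene_universe & present
    return GroundTruthNetwork(edges=kept, gene_universe=universe, report=truth.report), missing


def write_ranked_edges(ranking, path: str | os.PathLike) -> None:
    """Write an edge ranking as TSV: regulator, target, weight, rank (from 1).

    Weights are printed with 17 significant digits so a read-back reproduces
    them bit-exactly.
    """
    records = ranking.records
    if not records:
        raise ValueError("refusing to write an empty ranking")
    path = Path(path)
    with open(path, "w") as fh:
        fh.write("regulator\ttarget\tweight\trank\n")
        for rank, (reg, tgt, w) in enumerate(records, start=1):
            fh.write(f"{reg}\t{tgt}\t{w:.17g}\t{rank}\n")


def read_ranked_edges(path: str | os.PathLike):
    """Read a ranking written by :func:`write_ranked_edges`."""
    from .grn_extraction import EdgeRanking

    df = pd.read_csv(
        path, sep="\t", dtype={"regulator": str, "target": str},
        float_precision="round_trip",
    )
    records = [
        (str(r), str(t), float(w))
        for r, t, w in zip(df["regulator"], df["target"], df["weight"])
    ]
    return EdgeRanking(records=records, candidate_universe={(r, t) for r, t, _ in records})


def write_expression_matrix(X: ExpressionMatrix, path: str | os.PathLike) -> None:
    """Write a cells x genes matrix as CSV with cell rows and gene columns."""
    df = pd.DataFrame(X.values, index=X.cell_ids, columns=X.gene_ids)
    df.to_csv(path, float_format="%.17g")
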