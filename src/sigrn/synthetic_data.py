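"""SEM-consistent synthetic datasets with known ground truth.

A sparse directed adjacency A is planted (off-diagonal entries nonzero
independently with probability ``edge_density``, magnitudes uniform in
``weight_range``, a ``sign_mix`` fraction negative, then rescaled so the
spectral radius of A^T is at most 0.8 to keep (I - A^T) well conditioned).
Expression follows the generative law X = Z (I - A^T)^{-1} with
Z ~ N(0, noise_sd^2), after which entries are zeroed independently with
probability ``dropout_rate`` to mimic scRNA-seq dropout.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .io_formats import ExpressionMatrix, GroundTruthNetwork
from .sem_vae_model import AdjacencyMatrix, sem_decode_transform

SPECTRAL_RADIUS_CAP = 0.8


@dataclass
class SimConfig:
    n_genes: int = 100
    n_cells: int = 500
    edge_density: float = 0.05
    weight_range: tuple[float, float] = (0.5, 2.0)
    sign_mix: float = 0.3
    noise_sd: float = 1.0
    dropout_rate: float = 0.1
    seed: int = 0

    def __post_init__(self) -> None:
        if not 0.0 < self.edge_density < 1.0:
            raise ValueError("edge_density must lie in (0, 1)")
        if not 0.0 <= self.dropout_rate < 1.0:
            raise ValueError("dropout_rate must lie in [0, 1)")
        if self.noise_sd <= 0:
            raise ValueError("noise_sd must be positive")
        lo, hi = self.weight_range
        if not 0 < lo <= hi:
            raise ValueError("weight_range must be positive with low <= high")
        if self.edge_density * self.n_genes**2 < 1:
            raise ValueError("expected edge count below 1; increase density or gene count")


def simulate_grn(cfg: SimConfig) -> tuple[AdjacencyMatrix, GroundTruthNetwork]:
    """Plant a sparse stable adjacency matrix and its ground-truth edge set.

    Ground-truth edges follow the ranking convention: nonzero ``A[i, j]``
    becomes the directed edge (regulator = gene_j, target = gene_i).
    """
    rng = np.random.default_rng(cfg.seed)
    g = cfg.n_genes
    gene_ids = [f"G{i:04d}" for i in range(g)]
    present = rng.random((g, g)) < cfg.edge_density
    np.fill_diagonal(present, False)
    if not present.any():
        raise ValueError("no edge drawn; increase edge_density or n_genes")
    mags = rng.uniform(cfg.weight_range[0], cfg.weight_range[1], size=(g, g))
    signs = np.where(rng.random((g, g)) < cfg.sign_mix, -1.0, 1.0)
    A = np.where(present, mags * signs, 0.0)
    radius = max(np.abs(np.linalg.eigvals(A.T)))
    if radius > SPECTRAL_RADIUS_CAP:
        A *= SPECTRAL_RADIUS_CAP / radius
    adjacency = AdjacencyMatrix(A, gene_ids)
    edges = {
        (gene_ids[j], gene_ids[i])
        for i, j in zip(*np.nonzero(A))
    }
    truth = GroundTruthNetwork(edges=edges, gene_universe=set(gene_ids))
    return adjacency, truth


def simulate_expression(A_true: AdjacencyMatrix, cfg: SimConfig) -> ExpressionMatrix:
    """Draw X = Z (I - A^T)^{-1}, Z ~ N(0, noise_sd^2), then apply dropout."""
    rng = np.random.default_rng(cfg.seed + 1)  # distinct stream from the GRN draw
    z = cfg.noise_sd * rng.standard_normal((cfg.n_cells, A_true.n_genes))
    x = sem_decode_transform(z, A_true)
    if cfg.dropout_rate > 0:
        keep = rng.random(x.shape) >= cfg.dropout_rate
        x = x * keep
    cell_ids = [f"C{i:05d}" for i in range(cfg.n_cells)]
    return ExpressionMatrix(x, cell_ids, list(A_true.gene_ids))


def simulate_dataset(cfg: SimConfig):
    """Convenience wrapper: (A_true, truth, X)."""
    A_true, truth = simulate_grn(cfg)
    X = simulate_expression(A_true, cfg)
    return A_true, truth, X
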