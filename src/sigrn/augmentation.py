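"""Mask augmentation: randomly zero expression entries to mimic dropout.

A binary mask the same shape as the batch is drawn with entries 0 with
probability ``pm`` (default 0.1) and the batch is multiplied elementwise.
A fresh mask is drawn for every minibatch by default (``mask_mode``
"per_batch"); "once" draws a single mask for the whole run.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .io_formats import ExpressionMatrix


@dataclass
class MaskConfig:
    pm: float = 0.1
    seed: int = 0
    mask_mode: str = "per_batch"  # or "once"

    def __post_init__(self) -> None:
        if not 0.0 <= self.pm <= 1.0:
            raise ValueError("pm must lie in [0, 1]")
        if self.mask_mode not in ("per_batch", "once"):
            raise ValueError("mask_mode must be 'per_batch' or 'once'")


def sample_mask(shape: tuple[int, int], cfg: MaskConfig, rng: np.random.Generator) -> np.ndarray:
    """Draw a binary mask: entry 0 with probability ``cfg.pm``, else 1."""
    rows, cols = shape
    if rows < 1 or cols < 1:
        raise ValueError("mask shape must be at least 1x1")
    return (rng.random((rows, cols)) >= cfg.pm).astype(float)


def apply_mask(X: ExpressionMatrix | np.ndarray, M: np.ndarray):
    """Elementwise product X * M; labels (if any) unchanged."""
    if isinstance(X, ExpressionMatrix):
        if X.values.shape != M.shape:
            raise ValueError(f"mask shape {M.shape} does not match matrix {X.values.shape}")
        return ExpressionMatrix(X.values * M, list(X.cell_ids), list(X.gene_ids))
    X = np.asarray(X, dtype=float)
    if X.shape != M.shape:
        raise ValueError(f"mask shape {M.shape} does not match matrix {X.shape}")
    return X * M
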