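"""The SEM-structured variational autoencoder and its loss terms.

The model couples genes through a weighted adjacency matrix A (zero diagonal)
under the linear structural equation X = X A^T + Z, equivalently
Z = X (I - A^T) and X = Z (I - A^T)^{-1}.  A three-layer perceptron encoder
(hidden width 128, tanh) is applied to each gene independently with shared
weights — a scalar 1 -> 128 -> 1 network per head — so latent coordinate g
stays aligned with gene g; this alignment is what makes the SEM mixing step
mu = N_mu (I - A^T) identify regulatory structure.  The SEM transform mixes
the per-gene heads through (I - A^T); a matching per-gene decoder perceptron
maps the SEM-decoded latent back to expression space.

Losses: MSE reconstruction, per-dimension-normalized KL to a standard-normal
prior, a soft introspective discriminator term exp(-E(X')), and mean-scaled
L1 on the off-diagonal of A.  Normalizing KL and L1 per dimension keeps the
exp(-.) soft threshold in its responsive regime and makes beta = 100
comparable across gene-set sizes; raw-sum variants sit behind flags.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np


@dataclass
class AdjacencyMatrix:
    """A |G| x |G| real weight matrix with zero diagonal: the inferred GRN.

    Entry ``weights[i, j]`` is the influence of gene j on gene i (under
    X = X A^T + Z, gene i's expression is sum_j a_ij * expression of gene j),
    so a nonzero a_ij reads as the directed edge gene_j -> gene_i.
    """

    weights: np.ndarray
    gene_ids: list[str]

    def __post_init__(self) -> None:
        self.weights = np.asarray(self.weights, dtype=float)
        n = len(self.gene_ids)
        if self.weights.shape != (n, n):
            raise ValueError(f"adjacency shape {self.weights.shape} does not match {n} genes")
        if not np.all(np.isfinite(self.weights)):
            raise ValueError("adjacency contains non-finite entries")
        if np.any(np.diag(self.weights) != 0):
            raise ValueError("adjacency diagonal must be identically zero")
        cond = np.linalg.cond(np.eye(n) - self.weights.T)
        if not np.isfinite(cond):
            raise ValueError("(I - A^T) is numerically singular")

    @property
    def n_genes(self) -> int:
        return len(self.gene_ids)


@dataclass
class ModelParams:
    """Per-gene perceptron weights (shared across genes) plus the adjacency.

    Encoder, applied to each gene's scalar value x_g:
    h = tanh(x_g * W1 + b1) (hidden width 128), N_mu head = h . W2 + b2,
    N_sigma head = h . W3 + b3 (linear pre-activation; sigma becomes
    softplus(N_sigma (I - A^T)) downstream).  Decoder mirrors it:
    h = tanh(zt_g * V1 + c1), output h . V2 + c2 (linear head).  Sharing the
    weights across genes keeps latent coordinate g tied to gene g.
    """

    W1: np.ndarray  # (hidden,)
    b1: np.ndarray  # (hidden,)
    W2: np.ndarray  # (hidden,)
    b2: np.ndarray  # (1,)
    W3: np.ndarray  # (hidden,)
    b3: np.ndarray  # (1,)
    V1: np.ndarray  # (hidden,)
    c1: np.ndarray  # (hidden,)
    V2: np.ndarray  # (hidden,)
    c2: np.ndarray  # (1,)
    adjacency: AdjacencyMatrix

    @property
    def n_genes(self) -> int:
        return self.adjacency.n_genes

    @property
    def hidden(self) -> int:
        return self.W1.shape[0]

    def mlp_fields(self) -> list[str]:
        return ["W1", "b1", "W2", "b2", "W3", "b3", "V1", "c1", "V2", "c2"]


@dataclass
class LatentSample:
    """Per-cell posterior parameters and the reparameterized draw.

    ``n_mu``/``n_sigma`` are the raw encoder heads (``n_sigma`` is the
    pre-softplus activation); ``mu``/``sigma`` are the SEM-transformed
    posterior parameters; ``z = mu + sigma * epsilon``.
    """

    n_mu: np.ndarray
    n_sigma: np.ndarray
    mu: np.ndarray
    sigma: np.ndarray
    z: np.ndarray
    epsilon: np.ndarray


@dataclass
class LossBundle:
    """The scalar loss terms of one forward pass."""

    l_ae: float
    kl_real: float
    kl_fake: float
    l1_a: float
    l_e: float
    l_d: float


def _softplus(x: np.ndarray) -> np.ndarray:
    return np.maximum(x, 0.0) + np.log1p(np.exp(-np.abs(x)))


def init_params(
    gene_ids: list[str],
    rng: np.random.Generator,
    hidden: int = 128,
    adjacency_init_scale: float = 1e-4,
) -> ModelParams:
    """Glorot-uniform scalar-layer weights, zero biases, A ~ U(-s, s) off-diagonal."""
    g = len(gene_ids)

    def glorot(fan_in: int, fan_out: int, size: int) -> np.ndarray:
        limit = np.sqrt(6.0 / (fan_in + fan_out))
        return rng.uniform(-limit, limit, size=size)

    A = rng.uniform(-adjacency_init_scale, adjacency_init_scale, size=(g, g))
    np.fill_diagonal(A, 0.0)
    return ModelParams(
        W1=glorot(1, hidden, hidden),
        b1=np.zeros(hidden),
        W2=glorot(hidden, 1, hidden),
        b2=np.zeros(1),
        W3=glorot(hidden, 1, hidden),
        b3=np.zeros(1),
        V1=glorot(1, hidden, hidden),
        c1=np.zeros(hidden),
        V2=glorot(hidden, 1, hidden),
        c2=np.zeros(1),
        adjacency=AdjacencyMatrix(A, list(gene_ids)),
    )


def encode(X_batch: np.ndarray, params: ModelParams) -> tuple[np.ndarray, np.ndarray]:
    """Encoder heads: N_mu and the N_sigma pre-activation (both linear).

    Positivity of sigma comes from the softplus applied after the SEM mixing
    step, sigma = softplus(N_sigma (I - A^T)); keeping the head itself linear
    lets sigma shrink below softplus(0) where the data warrant a confident
    posterior.  The shared scalar perceptron acts on each (cell, gene) entry
    independently, so rows are processed independently and output shape
    equals input shape for both heads.
    """
    X_batch = np.asarray(X_batch, dtype=float)
    if X_batch.shape[0] < 1:
        raise ValueError("empty batch")
    h = np.tanh(X_batch[..., None] * params.W1 + params.b1)  # (B, G, hidden)
    n_mu = h @ params.W2 + params.b2
    n_sigma = h @ params.W3 + params.b3
    if not (np.all(np.isfinite(n_mu)) and np.all(np.isfinite(n_sigma))):
        raise FloatingPointError("non-finite encoder output (training instability)")
    return n_mu, n_sigma


def sem_encode_transform(N: np.ndarray, A: AdjacencyMatrix) -> np.ndarray:
    """The SEM mixing step N (I - A^T).  Pure linear; the sigma path applies
    softplus to the result afterwards to restore positivity."""
    n = A.n_genes
    return np.asarray(N, dtype=float) @ (np.eye(n) - A.weights.T)


def reparameterize(
    mu: np.ndarray,
    sigma: np.ndarray,
    rng: np.random.Generator,
    n_mu: np.ndarray | None = None,
    n_sigma: np.ndarray | None = None,
    epsilon: np.ndarray | None = None,
) -> LatentSample:
    """z = mu + sigma * epsilon with epsilon ~ N(0, I); the draw is recorded."""
    mu = np.asarray(mu, dtype=float)
    sigma = np.asarray(sigma, dtype=float)
    if np.any(sigma <= 0):
        raise ValueError("sigma must be strictly positive")
    if epsilon is None:
        epsilon = rng.standard_normal(mu.shape)
    z = mu + sigma * epsilon
    return LatentSample(
        n_mu=n_mu if n_mu is not None else mu,
        n_sigma=n_sigma if n_sigma is not None else sigma,
        mu=mu,
        sigma=sigma,
        z=z,
        epsilon=epsilon,
    )


def sem_decode_transform(Z: np.ndarray, A: AdjacencyMatrix) -> np.ndarray:
    """Z (I - A^T)^{-1} via a linear solve (never an explicit inverse)."""
    n = A.n_genes
    B = np.eye(n) - A.weights.T
    try:
        return np.linalg.solve(B.T, np.asarray(Z, dtype=float).T).T
    except np.linalg.LinAlgError as exc:
        raise np.linalg.LinAlgError(
            "(I - A^T) is singular; check the spectral radius of A^T"
        ) from exc


def decode(Zt: np.ndarray, params: ModelParams) -> np.ndarray:
    """Per-gene decoder perceptron with linear output head."""
    h = np.tanh(np.asarray(Zt, dtype=float)[..., None] * params.V1 + params.c1)
    out = h @ params.V2 + params.c2
    if not np.all(np.isfinite(out)):
        raise FloatingPointError("non-finite decoder output (training instability)")
    return out


def kl_divergence(mu: np.ndarray, sigma: np.ndarray, normalize: bool = True) -> float:
    """KL(q || N(0, I)) per the closed form 0.5 (mu^2 + sigma^2 - 1 - ln sigma^2),
    summed over genes, averaged over batch rows, and (by default) divided by
    |G| so the value is per-dimension."""
    mu = np.atleast_2d(np.asarray(mu, dtype=float))
    sigma = np.atleast_2d(np.asarray(sigma, dtype=float))
    if np.any(sigma <= 0):
        raise ValueError("sigma must be strictly positive")
    per_entry = 0.5 * (mu**2 + sigma**2 - 1.0 - 2.0 * np.log(sigma))
    per_row = per_entry.sum(axis=1)
    val = per_row.mean()
    if normalize:
        val /= mu.shape[1]
    return float(max(val, 0.0)) if val > -1e-12 else float(val)


def reconstruction_loss(X_batch: np.ndarray, X_prime: np.ndarray) -> float:
    """Mean squared error over all entries (unit-variance Gaussian likelihood)."""
    X_batch = np.asarray(X_batch, dtype=float)
    X_prime = np.asarray(X_prime, dtype=float)
    if X_batch.shape != X_prime.shape:
        raise ValueError("shape mismatch between batch and reconstruction")
    return float(np.mean((X_batch - X_prime) ** 2))


def l1_norm(A: AdjacencyMatrix | np.ndarray, mean_scaled: bool = True) -> float:
    """Mean (default) or sum of |a_ij| over the off-diagonal entries."""
    W = A.weights if isinstance(A, AdjacencyMatrix) else np.asarray(A, dtype=float)
    n = W.shape[0]
    off = ~np.eye(n, dtype=bool)
    total = float(np.abs(W[off]).sum())
    if mean_scaled:
        denom = n * (n - 1)
        return total / denom if denom else 0.0
    return total


def encoder_loss(kl_real: float, kl_fake: float, l1_a: float, l_ae: float, beta: float) -> float:
    """L_E = E(X) + exp(-E(X')) + beta ||A|| + L_AE.

    The exp term is the soft discriminator threshold: bounded in (0, 1]
    because KL >= 0, so the gradient never vanishes the way a hard hinge
    alpha [m - E(X')]_+ does.
    """
    return float(kl_real + np.exp(-kl_fake) + beta * l1_a + l_ae)


def decoder_loss(kl_fake: float, l1_a: float, l_ae: float, beta: float) -> float:
    """L_D = E(X') + beta ||A|| + L_AE (generator loss)."""
    return float(kl_fake + beta * l1_a + l_ae)


def forward(
    X_batch: np.ndarray,
    params: ModelParams,
    rng: np.random.Generator,
    epsilon: np.ndarray | None = None,
) -> tuple[np.ndarray, LatentSample]:
    """Full generative pass X -> Z -> X' (numpy, no gradient tape)."""
    n_mu, n_sigma = encode(X_batch, params)
    mu = sem_encode_transform(n_mu, params.adjacency)
    sigma = _softplus(sem_encode_transform(n_sigma, params.adjacency))
    sample = reparameterize(mu, sigma, rng, n_mu=n_mu, n_sigma=n_sigma, epsilon=epsilon)
    zt = sem_decode_transform(sample.z, params.adjacency)
    x_prime = decode(zt, params)
    return x_prime, sample


def save_checkpoint(params: ModelParams, path, config: dict | None = None) -> None:
    """Single-archive checkpoint (numpy .npz) with weights, A and gene ids."""
    import json

    arrays = {name: getattr(params, name) for name in params.mlp_fields()}
    arrays["A"] = params.adjacency.weights
    arrays["gene_ids"] = np.array(params.adjacency.gene_ids, dtype=object)
    arrays["config_json"] = np.array(json.dumps(config or {}))
    np.savez(path, **arrays, allow_pickle=True)


def load_checkpoint(path) -> tuple[ModelParams, dict]:
    import json

    with np.load(path, allow_pickle=True) as npz:
        gene_ids = [str(g) for g in npz["gene_ids"]]
        params = ModelParams(
            **{name: npz[name] for name in
               ["W1", "b1", "W2", "b2", "W3", "b3", "V1", "c1", "V2", "c2"]},
            adjacency=AdjacencyMatrix(npz["A"], gene_ids),
        )
        config = json.loads(str(npz["config_json"]))
    return params, config
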