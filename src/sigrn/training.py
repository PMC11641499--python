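"""Two-phase soft introspective adversarial training of the SEM-VAE.

Each minibatch runs two phases.  In the encoder (discriminator) phase the
generated batch X' is treated as a constant sample from the current generator
(stop-gradient) and
L_E = E(X) + exp(-E(X')) + beta ||A|| + L_AE
is back-propagated: the encoder/decoder perceptrons are Adam-updated at eta1
and the adjacency matrix at its own (slower) eta2.  In the decoder
(generator) phase a fresh forward is built at the updated iterate with the
encoder weights frozen, E(X') is back-propagated through X' into the decoder
and A, and theta / A are updated on L_D = E(X') + beta ||A|| + L_AE.

Term scaling.  The additive E(.) and L_AE terms are per-cell sums over genes
(averaged over the batch) — the Gaussian log-likelihood scale — while the
soft-threshold argument exp(-E(X')) uses the per-dimension (divided by |G|)
KL so it operates in its responsive regime, and ||A|| is the mean
off-diagonal |a_ij|.  This balance is what lets the data terms outweigh the
constant L1 subgradient beta/(|G|(|G|-1)) on true-edge coordinates; with
every term per-dimension the L1 pull dominates all data signal and A
collapses to zero.  ``likelihood_scale`` switches the additive terms to
per-entry means for diagnostics.

beta ||A|| enters both losses only after a delay of ``l1_delay_epochs``
epochs.  Ablation flags reproduce the non-adversarial (DSIGRN), no-L1,
no-mask and no-delay arms.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from . import autodiff as ad
from .augmentation import MaskConfig, apply_mask, sample_mask
from .io_formats import ExpressionMatrix
from .sem_vae_model import (
    AdjacencyMatrix,
    ModelParams,
    init_params,
    l1_norm,
)


@dataclass
class Ablations:
    adversarial_on: bool = True  # off reproduces the DSIGRN arm
    l1_on: bool = True
    mask_on: bool = True
    delay_on: bool = True


@dataclass
class TrainConfig:
    max_epochs: int = 120
    batch_size: int = 64
    lr_mlp: float = 1e-4      # eta1
    lr_adjacency: float = 2e-5  # eta2
    beta: float = 100.0
    l1_delay_epochs: int = 30
    seed: int = 0
    hidden: int = 128
    ablations: Ablations = field(default_factory=Ablations)
    likelihood_scale: str = "per_cell_sum"  # or "per_entry_mean"
    mean_scale_l1: bool = True  # mean |a_ij| off-diagonal; raw sum if False
    freeze_adjacency: bool = False  # A pinned at init (the "A-test" contrast arm)

    def __post_init__(self) -> None:
        if self.batch_size < 1:
            raise ValueError("batch_size must be >= 1")
        if self.l1_delay_epochs > self.max_epochs:
            raise ValueError("l1_delay_epochs cannot exceed max_epochs")
        if self.likelihood_scale not in ("per_cell_sum", "per_entry_mean"):
            raise ValueError("likelihood_scale must be 'per_cell_sum' or 'per_entry_mean'")


@dataclass
class EpochRecord:
    epoch: int
    l_e: float
    l_d: float
    l_ae: float
    kl_real: float
    kl_fake: float
    l1_a: float       # raw mean |a_ij| off-diagonal
    l1_term: float    # beta ||A|| contribution actually applied (0 during delay)


@dataclass
class TrainHistory:
    records: list[EpochRecord] = field(default_factory=list)
    seed: int = 0

    def as_arrays(self) -> dict[str, np.ndarray]:
        keys = ["epoch", "l_e", "l_d", "l_ae", "kl_real", "kl_fake", "l1_a", "l1_term"]
        return {k: np.array([getattr(r, k) for r in self.records]) for k in keys}


class Adam:
    """Standard Adam (beta1 0.9, beta2 0.999, eps 1e-8) with per-key state."""

    def __init__(self, lr: float, b1: float = 0.9, b2: float = 0.999, eps: float = 1e-8):
        self.lr, self.b1, self.b2, self.eps = lr, b1, b2, eps
        self.m: dict[str, np.ndarray] = {}
        self.v: dict[str, np.ndarray] = {}
        self.t: dict[str, int] = {}

    def step(self, key: str, value: np.ndarray, grad: np.ndarray) -> np.ndarray:
        if key not in self.m:
            self.m[key] = np.zeros_like(value)
            self.v[key] = np.zeros_like(value)
            self.t[key] = 0
        self.t[key] += 1
        t = self.t[key]
        self.m[key] = self.b1 * self.m[key] + (1 - self.b1) * grad
        self.v[key] = self.b2 * self.v[key] + (1 - self.b2) * grad**2
        mhat = self.m[key] / (1 - self.b1**t)
        vhat = self.v[key] / (1 - self.b2**t)
        return value - self.lr * mhat / (np.sqrt(vhat) + self.eps)


def epoch_shuffle(indices: np.ndarray, rng: np.random.Generator) -> np.ndarray:
    """Uniform permutation of ``indices`` drawn from the run's seeded stream."""
    indices = np.asarray(indices)
    return indices[rng.permutation(len(indices))]


def _kl_graph(mu: ad.Var, sigma: ad.Var) -> ad.Var:
    """Per-dimension KL to N(0, I): mean over batch entries of the closed form."""
    per_entry = 0.5 * (ad.square(mu) + ad.square(sigma) - 1.0 - 2.0 * ad.log(sigma))
    return ad.mean(per_entry)


def _encode_graph(X: ad.Var, p: dict[str, ad.Var]) -> tuple[ad.Var, ad.Var]:
    """Shared per-gene scalar encoder (fused hidden layer + two linear heads;
    sigma positivity comes from the softplus after the SEM mixing step)."""
    t = ad.tanh_outer(X, p["W1"], p["b1"])
    n_mu = ad.head_sum(t, p["W2"], p["b2"])
    n_sigma = ad.head_sum(t, p["W3"], p["b3"])
    return n_mu, n_sigma


def _decode_graph(Zt: ad.Var, p: dict[str, ad.Var]) -> ad.Var:
    t = ad.tanh_outer(Zt, p["V1"], p["c1"])
    return ad.head_sum(t, p["V2"], p["c2"])


def _encode_numpy(X: np.ndarray, w: dict[str, np.ndarray]) -> tuple[np.ndarray, np.ndarray]:
    """Frozen-encoder forward (no graph) for the decoder phase."""
    h = np.tanh(X[..., None] * w["W1"] + w["b1"])
    return h @ w["W2"] + w["b2"], h @ w["W3"] + w["b3"]


def _check_finite(loss_val: float, epoch: int, batch: int, name: str) -> None:
    if not np.isfinite(loss_val):
        raise FloatingPointError(
            f"non-finite {name} at epoch {epoch}, batch {batch}; training aborted"
        )


def train(
    X: ExpressionMatrix,
    mcfg: MaskConfig | None = None,
    tcfg: TrainConfig | None = None,
) -> tuple[ModelParams, TrainHistory]:
    """Run the two-phase adversarial loop on a z-scored matrix.

    Returns the final parameters (including the learned adjacency matrix A,
    diagonal re-zeroed after every update) and the per-epoch loss history.
    """
    mcfg = mcfg or MaskConfig()
    tcfg = tcfg or TrainConfig()
    ab = tcfg.ablations
    rng = np.random.default_rng(tcfg.seed)
    mask_rng = np.random.default_rng(mcfg.seed)

    data = np.asarray(X.values, dtype=float)
    n_cells, n_genes = data.shape
    params = init_params(X.gene_ids, rng, hidden=tcfg.hidden)
    A = params.adjacency.weights.copy()
    offdiag = 1.0 - np.eye(n_genes)
    eye = np.eye(n_genes)
    l1_denom = float(n_genes * (n_genes - 1)) if tcfg.mean_scale_l1 else 1.0
    scale = float(n_genes) if tcfg.likelihood_scale == "per_cell_sum" else 1.0

    opt_mlp = Adam(tcfg.lr_mlp)
    opt_A = Adam(tcfg.lr_adjacency)

    mlp_keys = params.mlp_fields()
    weights: dict[str, np.ndarray] = {k: getattr(params, k) for k in mlp_keys}
    dec_keys = ["V1", "c1", "V2", "c2"]

    fixed_mask = None
    if ab.mask_on and mcfg.mask_mode == "once":
        fixed_mask = sample_mask((n_cells, n_genes), mcfg, mask_rng)

    history = TrainHistory(seed=tcfg.seed)
    indices = np.arange(n_cells)

    def step_A(A: np.ndarray, grad: np.ndarray) -> np.ndarray:
        if tcfg.freeze_adjacency:
            return A
        A = opt_A.step("A", A, grad * offdiag)
        np.fill_diagonal(A, 0.0)  # no self-regulation, ever
        return A

    def l1_node(A_var: ad.Var) -> ad.Var:
        return ad.vsum(ad.absval(ad.mul_mask(A_var, offdiag))) * (1.0 / l1_denom)

    for epoch in range(1, tcfg.max_epochs + 1):
        l1_active = ab.l1_on and (not ab.delay_on or epoch > tcfg.l1_delay_epochs)
        perm = epoch_shuffle(indices, rng)
        acc = {k: 0.0 for k in ["l_e", "l_d", "l_ae", "kl_real", "kl_fake", "l1_term"]}
        n_batches = 0

        for start in range(0, n_cells, tcfg.batch_size):
            batch_idx = perm[start : start + tcfg.batch_size]
            Xb = data[batch_idx]
            if ab.mask_on and mcfg.pm > 0:
                if fixed_mask is not None:
                    Xb = Xb * fixed_mask[batch_idx]
                else:
                    Xb = apply_mask(Xb, sample_mask(Xb.shape, mcfg, mask_rng))

            # ---------------- encoder (discriminator) phase ----------------
            A_var = ad.Var(A)
            B = ad.Var(eye) - ad.transpose(ad.mul_mask(A_var, offdiag))
            vE = {k: ad.Var(weights[k]) for k in mlp_keys}
            n_mu, n_sigma = _encode_graph(ad.Var(Xb), vE)
            mu = n_mu @ B
            sigma = ad.softplus(n_sigma @ B)
            z = mu + sigma * ad.Var(rng.standard_normal(Xb.shape))
            zt = ad.solve_right(z, B)
            x_prime = _decode_graph(zt, vE)
            l_ae = ad.mean(ad.square(ad.Var(Xb) - x_prime))
            kl_real = _kl_graph(mu, sigma)

            loss_E = scale * kl_real + scale * l_ae
            if ab.adversarial_on:
                n_mu_f, n_sigma_f = _encode_graph(x_prime.detach(), vE)
                kl_fake_E = _kl_graph(n_mu_f @ B, ad.softplus(n_sigma_f @ B))
                loss_E = loss_E + ad.exp(-kl_fake_E)  # soft threshold, per-dim arg
            if l1_active:
                loss_E = loss_E + tcfg.beta * l1_node(A_var)

            ad.backward(loss_E)
            l_e_val = float(loss_E.value)
            _check_finite(l_e_val, epoch, n_batches, "L_E")
            for k in mlp_keys:
                if vE[k].grad is not None:
                    weights[k] = opt_mlp.step(k, weights[k], vE[k].grad)
            if A_var.grad is not None:
                A = step_A(A, A_var.grad)

            # ---------------- decoder (generator) phase --------------------
            # fresh forward at the updated iterate; encoder weights frozen
            A_var = ad.Var(A)
            B = ad.Var(eye) - ad.transpose(ad.mul_mask(A_var, offdiag))
            vD = {k: ad.Var(weights[k]) for k in dec_keys}
            n_mu2, n_sigma2 = _encode_numpy(Xb, weights)
            mu2 = ad.Var(n_mu2) @ B
            sigma2 = ad.softplus(ad.Var(n_sigma2) @ B)
            z2 = mu2 + sigma2 * ad.Var(rng.standard_normal(Xb.shape))
            zt2 = ad.solve_right(z2, B)
            x_prime2 = _decode_graph(zt2, vD)
            l_ae2 = ad.mean(ad.square(ad.Var(Xb) - x_prime2))

            loss_D = scale * l_ae2
            kl_fake_val = 0.0
            if ab.adversarial_on:
                cE = {k: ad.Var(weights[k]) for k in mlp_keys}  # phi frozen
                n_mu_f2, n_sigma_f2 = _encode_graph(x_prime2, cE)
                kl_fake_D = _kl_graph(n_mu_f2 @ B, ad.softplus(n_sigma_f2 @ B))
                loss_D = loss_D + scale * kl_fake_D
                kl_fake_val = float(kl_fake_D.value)
            l1_term = 0.0
            if l1_active:
                l1_g = l1_node(A_var)
                loss_D = loss_D + tcfg.beta * l1_g
                l1_term = tcfg.beta * float(l1_g.value)

            ad.backward(loss_D)
            l_d_val = float(loss_D.value)
            _check_finite(l_d_val, epoch, n_batches, "L_D")
            for k in dec_keys:
                if vD[k].grad is not None:
                    weights[k] = opt_mlp.step(k, weights[k], vD[k].grad)
            if A_var.grad is not None:
                A = step_A(A, A_var.grad)

            acc["l_e"] += l_e_val
            acc["l_d"] += l_d_val
            acc["l_ae"] += float(l_ae.value)
            acc["kl_real"] += float(kl_real.value)
            acc["kl_fake"] += kl_fake_val
            acc["l1_term"] += l1_term
            n_batches += 1

        history.records.append(
            EpochRecord(
                epoch=epoch,
                l_e=acc["l_e"] / n_batches,
                l_d=acc["l_d"] / n_batches,
                l_ae=acc["l_ae"] / n_batches,
                kl_real=acc["kl_real"] / n_batches,
                kl_fake=acc["kl_fake"] / n_batches,
                l1_a=l1_norm(A, mean_scaled=True),
                l1_term=acc["l1_term"] / n_batches,
            )
        )

    final = ModelParams(
        **{k: weights[k] for k in mlp_keys},
        adjacency=AdjacencyMatrix(A, list(X.gene_ids)),
    )
    return final, history
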