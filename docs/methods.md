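# Methods

## The model

`sigrn` infers a gene regulatory network (GRN) from a cells × genes
single-cell expression matrix X by learning the weighted adjacency matrix A
of a linear structural equation model (SEM),

    X = X Aᵀ + Z,        Z ~ N(0, σ²),

equivalently Z = X (I − Aᵀ) and X = Z (I − Aᵀ)⁻¹.  Entry `a_ij` is the
influence of gene *j* on gene *i*; the emitted edge is regulator *j* →
target *i*, and edges are ranked by |a_ij|.  The SEM is embedded in a
variational autoencoder: a per-gene encoder produces posterior heads
N_μ, N_σ, the SEM mixing step forms μ = N_μ(I − Aᵀ) and
σ = softplus(N_σ(I − Aᵀ)), a reparameterized draw Z = μ + σ⊙ε is mapped back
through Zt = Z(I − Aᵀ)⁻¹, and a per-gene decoder reconstructs X′ from Zt.

Training is *soft introspective adversarial*: the encoder doubles as the
discriminator and the decoder as the generator, with no extra networks.
Writing E(·) for the KL divergence of the encoder's posterior from the
standard-normal prior, each minibatch takes two phases:

- **Encoder phase** — the generated batch X′ is treated as a constant sample
  (stop-gradient) and
  `L_E = E(X) + exp(−E(X′)) + β‖A‖ + L_AE`
  is minimized over the encoder and decoder perceptrons (Adam, learning
  rate η₁ = 1e−4) and the adjacency matrix (Adam, η₂ = 2e−5).  The
  `exp(−E(X′))` term is the soft threshold: it is bounded in (0, 1], so the
  discriminator's gradient never vanishes the way a hinge `α[m − E(X′)]₊`
  does, and it needs no margin hyperparameters.
- **Decoder phase** — a fresh forward pass is built at the updated iterate
  with the encoder frozen; `L_D = E(X′) + β‖A‖ + L_AE` is minimized over the
  decoder and A, with E(X′) back-propagated *through* X′ so the generator
  learns to make its samples look posterior-typical.

A's diagonal is hard-masked to zero at every step (no self-regulation), and
the `β‖A‖` sparsity term is switched on only after a delay
(`l1_delay_epochs`, default 30), letting A find structure before being
pruned.

## Architecture

Both perceptrons are applied **per gene with shared weights**: scalar
1 → 128 → 1 networks with a tanh hidden layer (two heads for the encoder).
This keeps latent coordinate *g* aligned with gene *g*, which is what makes
the mixing step μ = N_μ(I − Aᵀ) informative about regulation: with dense
|G| → 128 → |G| networks the encoder is free to rotate the latent basis, the
per-gene correlation between N_μ and X collapses, and the gradient on A
carries no edge signal (we measured per-gene corr ≈ −0.04 and ranking AUROC
≈ 0.49 on data whose covariance alone supports AUROC ≈ 0.73).

The N_σ head is linear; positivity of σ comes from a single softplus applied
after the SEM transform.  Applying softplus to the head as well floors σ
near softplus(0) ≈ 0.69, which dilutes the decoder's regression (it must
predict through a heavy noise channel) and measurably hurts edge recovery.

## Loss-term scaling

The additive E(·) and L_AE terms are **per-cell sums over genes** (averaged
over the batch) — the natural Gaussian log-likelihood scale — while
`‖A‖` is the mean off-diagonal |a_ij| and the argument of `exp(−E(X′))` is
the per-dimension (÷|G|) KL so the soft threshold operates where its
gradient is alive.  This balance matters: the L1 subgradient is the constant
β/(|G|(|G|−1)) ≈ 0.01 per coordinate at β = 100, and if the likelihood terms
are also averaged per entry their per-coordinate gradient (~1e−3) is
dominated by it, so every A entry is pruned to zero and inference fails.
At likelihood scale the data gradient on true-edge coordinates (~0.1–0.3)
outweighs the pull and the L1 prunes only weak coordinates.
`TrainConfig.likelihood_scale="per_entry_mean"` restores the per-entry
variant for diagnostics.

Per minibatch, A receives one Adam step from each phase.  The encoder-phase
update is what routes the real-data whitening signal E(X) into A; without it
the non-adversarial ablation would leave A with no KL gradient at all.

## Defaults and what they mean

| parameter | default | meaning |
|---|---|---|
| `batch_size` | 64 | minibatch rows (cells) |
| `max_epochs` | 120 | full passes over the cells |
| `lr_mlp` (η₁) | 1e−4 | Adam rate for the perceptrons |
| `lr_adjacency` (η₂) | 2e−5 | Adam rate for A (slower: A is the estimand) |
| `beta` | 100 | weight of the mean-|a_ij| sparsity term |
| `l1_delay_epochs` | 30 | epochs before the sparsity term activates |
| `pm` | 0.1 | mask-augmentation zeroing probability |
| hidden width | 128 | per-gene perceptron hidden layer |

Mask augmentation redraws a Bernoulli(1 − pm) mask for every minibatch
(`mask_mode="per_batch"`; `"once"` freezes a single mask) and multiplies the
batch elementwise, mimicking scRNA-seq dropout; the reconstruction target is
the masked batch and the loss runs over all entries.  Adam uses the
conventional β₁ = 0.9, β₂ = 0.999, eps = 1e−8.  A is initialized
U(−1e−4, 1e−4) off-diagonal; perceptron weights are Glorot-uniform, biases
zero.  Ablation flags remove the adversarial terms (the "DSIGRN" arm), the
L1 term, the mask, or the delay.

## Synthetic data

`synthetic_data` plants a sparse directed adjacency (off-diagonal entries
present independently with probability `edge_density`, magnitudes uniform in
`weight_range` = (0.5, 2.0), a `sign_mix` = 0.3 fraction negative) and
rescales it so the spectral radius of Aᵀ is at most 0.8, guaranteeing a
well-conditioned (I − Aᵀ) everywhere.  Expression follows the SEM law
X = Z(I − Aᵀ)⁻¹ with Z ~ N(0, noise_sd²), then entries are zeroed
independently with probability `dropout_rate` (dropout as measurement
noise, applied after the SEM).  With no dropout the empirical precision
matrix of X approaches (I − Aᵀ)(I − Aᵀ)ᵀ/σ² — exactly the signal the
inference exploits.

The generator emulates linearity, Gaussian noise, and zero inflation.  It
does **not** emulate counts, library-size variation, batch effects,
nonlinear regulation, or trajectory structure, so passing recovery tests
here shows the estimator works when its model assumptions hold, not that it
resolves real-data confounders.

The reference study conditions used throughout the tests and the acceptance
script are 100 genes, 500 cells, 5% edge density, noise_sd 1, 10% dropout,
training defaults above, seeds 0–4; one training run takes roughly 80 s on
one CPU.  Under these conditions the adversarial model reaches mean edge
AUROC ≈ 0.79 and mean EPR ≈ 7 against the planted network, and beats the
non-adversarial arm on every paired seed.

## Numerical choices

- (I − Aᵀ)⁻¹ is always applied through `np.linalg.solve`, never an explicit
  inverse; the encode/decode transforms invert each other to ≤1e−9 for any
  spectral radius ≤ 0.8 matrix.
- Gradients come from a small reverse-mode tape over numpy arrays
  (`sigrn.autodiff`) with fused per-gene layers; it is validated against
  central finite differences in the test suite.  Training is deterministic
  given the seed (single-threaded numpy), so identical configurations
  reproduce adjacency files byte-for-byte.
- z-scoring uses the population (ddof 0) standard deviation; constant genes
  map to all-zero columns rather than being dropped.
- HVG selection scores genes by dispersion (variance/mean of log1p values)
  with ties broken by gene name, so selected sets are reproducible; this is
  a deliberate, documented stand-in for toolkit-specific HVG pickers and may
  select slightly different genes than they do.
- Louvain clustering runs on a 15-nearest-neighbor graph over the top 50
  principal components of the embedding (μ per cell), with the resolution
  bisected in [1e−3, 10] (≤30 iterations) to hit the requested community
  count; igraph's RNG is seeded per call.
- Edge ranking breaks score ties by (regulator, target) name so replicate
  unions and stability tables are reproducible.
- ROC-AUC uses midranks (rank-sum form), which equals the exhaustive
  threshold-sweep trapezoid; EPR normalizes early precision at k = number of
  ground-truth edges inside the candidate universe by the random-predictor
  precision k/|universe|.  Self-loops are excluded from every candidate
  universe, and non-TF regulators are excluded when a TF list is supplied.

## Known limitations

- Generation by prior sampling (Z ~ N(0, I) → decoder) is under-dispersed:
  the posterior keeps σ large, so the MSE-optimal decoder shrinks toward the
  conditional mean (generated variance ≈ 0.27 of the real ≈ 1 under the
  study conditions), and a random-forest discriminator separates real from
  generated near-perfectly for trained and untrained models alike.  Training
  improves the discriminator AUC only by ~0.003 in this regime.  The same
  check on reconstruction-based generation, or with an explicit observation
  noise model, would be more informative; both are out of scope here.
- The estimator identifies covariance structure; a_ij and a_ji are not
  strongly distinguished at small sample sizes, so directionality is weaker
  than edge detection.
- Runtime scales as O(epochs · cells · genes · hidden) plus an
  O(genes³) solve per phase; a few thousand genes is the practical ceiling
  on one CPU.
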