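"""Evaluation metrics: edge-ranking EPR and AUROC, clustering ARI/NMI,
cell embedding and Louvain clustering, generation-quality AUC, and the
Spearman TF-target interpretability check.

The edge candidate universe excludes self-loops and, when a TF list is in
play, non-TF regulators (the BEELINE evaluation regime).  All metric
functions are pure.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy.stats import rankdata, spearmanr
from sklearn.metrics import adjusted_rand_score, normalized_mutual_info_score, roc_auc_score

from .grn_extraction import EdgeRanking, top_k
from .io_formats import ExpressionMatrix, GroundTruthNetwork
from .sem_vae_model import (
    AdjacencyMatrix,
    ModelParams,
    decode,
    encode,
    sem_decode_transform,
    sem_encode_transform,
)


@dataclass
class ConfusionCounts:
    tp: int
    tn: int
    fp: int
    fn: int

    @property
    def tpr(self) -> float:
        return self.tp / (self.tp + self.fn) if (self.tp + self.fn) else 0.0

    @property
    def fpr(self) -> float:
        return self.fp / (self.fp + self.tn) if (self.fp + self.tn) else 0.0


@dataclass
class Partition:
    """Cluster labels over a set of cells (labels are arbitrary symbols)."""

    labels: list

    @property
    def n_clusters(self) -> int:
        return len(set(self.labels))


def _labels(p) -> list:
    return list(p.labels) if isinstance(p, Partition) else list(p)


def binarize(A: AdjacencyMatrix | np.ndarray, t: float) -> np.ndarray:
    """Threshold min-max-scaled |a_ij| at t: entry 1 iff scaled value > t.

    The diagonal is forced to zero.  A constant off-diagonal scales to all
    zeros (degenerate matrix carries no ranking information).
    """
    if not 0.0 <= t <= 1.0:
        raise ValueError("threshold t must lie in [0, 1]")
    W = A.weights if isinstance(A, AdjacencyMatrix) else np.asarray(A, dtype=float)
    n = W.shape[0]
    off = ~np.eye(n, dtype=bool)
    mags = np.abs(W)
    lo, hi = mags[off].min(), mags[off].max()
    scaled = np.zeros_like(mags)
    if hi > lo:
        scaled[off] = (mags[off] - lo) / (hi - lo)
    out = (scaled > t).astype(int)
    np.fill_diagonal(out, 0)
    return out


def confusion(
    Ap: np.ndarray, At: np.ndarray, universe_mask: np.ndarray | None = None
) -> ConfusionCounts:
    """Hadamard-product counting: TP = |Ap (.) At|, TN = |~Ap (.) ~At|, etc.,
    restricted to the candidate-universe mask (default: off-diagonal)."""
    Ap = np.asarray(Ap, dtype=int)
    At = np.asarray(At, dtype=int)
    if Ap.shape != At.shape:
        raise ValueError("shape mismatch between prediction and truth")
    if universe_mask is None:
        universe_mask = ~np.eye(Ap.shape[0], dtype=bool)
    m = universe_mask.astype(bool)
    tp = int(np.sum((Ap * At)[m]))
    tn = int(np.sum(((1 - Ap) * (1 - At))[m]))
    fp = int(np.sum((Ap * (1 - At))[m]))
    fn = int(np.sum(((1 - Ap) * At)[m]))
    return ConfusionCounts(tp=tp, tn=tn, fp=fp, fn=fn)


def _scores_labels(
    ranking: EdgeRanking, truth: GroundTruthNetwork
) -> tuple[np.ndarray, np.ndarray]:
    positives = truth.edges & ranking.candidate_universe
    scores = np.array([s for _, _, s in ranking.records])
    labels = np.array([(r, t) in positives for r, t, _ in ranking.records], dtype=bool)
    n_pos = int(labels.sum())
    n_neg = int((~labels).sum())
    if n_pos == 0:
        raise ValueError("no ground-truth positive inside the candidate universe")
    if n_neg == 0:
        raise ValueError("no negative pair inside the candidate universe")
    return scores, labels


def roc_auc(ranking: EdgeRanking, truth: GroundTruthNetwork) -> float:
    """AUROC of the edge scores against the binary truth, midranks for ties.

    Equivalent to sweeping the binarization threshold over all values and
    trapezoid-integrating TPR against FPR.
    """
    scores, labels = _scores_labels(ranking, truth)
    ranks = rankdata(scores)  # average (mid) ranks
    n_pos = int(labels.sum())
    n_neg = len(labels) - n_pos
    return float((ranks[labels].sum() - n_pos * (n_pos + 1) / 2.0) / (n_pos * n_neg))


def early_precision_ratio(ranking: EdgeRanking, truth: GroundTruthNetwork) -> float:
    """Early precision among the top-k edges (k = true edge count in the
    universe), divided by the random-predictor precision k/|universe|."""
    positives = truth.edges & ranking.candidate_universe
    k = len(positives)
    if k < 1:
        raise ValueError("no ground-truth positive inside the candidate universe")
    hits = len(top_k(ranking, k) & positives)
    early_precision = hits / k
    random_precision = k / len(ranking.candidate_universe)
    return float(early_precision / random_precision)


def ari(P1, P2) -> float:
    """Adjusted Rand index between two cell partitions."""
    return float(adjusted_rand_score(_labels(P1), _labels(P2)))


def nmi(P1, P2) -> float:
    """Normalized mutual information, 2 MI / (H1 + H2) (arithmetic mean)."""
    return float(
        normalized_mutual_info_score(_labels(P1), _labels(P2), average_method="arithmetic")
    )


def embed_cells(X: ExpressionMatrix, params: ModelParams) -> np.ndarray:
    """Deterministic per-cell embedding: the posterior means mu = N_mu (I - A^T)."""
    n_mu, _ = encode(X.values, params)
    return sem_encode_transform(n_mu, params.adjacency)


def cluster_cells(
    embedding: np.ndarray,
    n_clusters: int,
    seed: int = 0,
    n_neighbors: int = 15,
    n_pcs: int = 50,
    max_iter: int = 30,
) -> Partition:
    """Louvain communities on a kNN graph of the embedding's top PCs.

    The Louvain resolution is bisected in [1e-3, 10] until the community
    count hits ``n_clusters`` or the closest achievable value.
    """
    import random as _random

    import igraph
    from sklearn.decomposition import PCA
    from sklearn.neighbors import NearestNeighbors

    if n_clusters < 2:
        raise ValueError("n_clusters must be >= 2")
    emb = np.asarray(embedding, dtype=float)
    n_cells = emb.shape[0]
    n_comp = min(n_pcs, emb.shape[1], n_cells - 1)
    if n_comp < emb.shape[1]:
        emb = PCA(n_components=n_comp, random_state=seed).fit_transform(emb)
    k = min(n_neighbors, n_cells - 1)
    nn = NearestNeighbors(n_neighbors=k).fit(emb)
    _, idx = nn.kneighbors(emb)
    edges = {(min(i, j), max(i, j)) for i in range(n_cells) for j in idx[i] if i != j}
    graph = igraph.Graph(n=n_cells, edges=sorted(edges))

    def louvain_at(res: float):
        igraph.set_random_number_generator(_random.Random(seed))
        return graph.community_multilevel(resolution=res).membership

    lo, hi = 1e-3, 10.0
    best = None
    best_gap = None
    for _ in range(max_iter):
        mid = 0.5 * (lo + hi)
        membership = louvain_at(mid)
        k_found = len(set(membership))
        gap = abs(k_found - n_clusters)
        if best is None or gap < best_gap:
            best, best_gap = membership, gap
        if k_found == n_clusters:
            break
        if k_found < n_clusters:
            lo = mid
        else:
            hi = mid
    if best_gap != 0:
        import warnings

        warnings.warn(
            f"bisection could not reach {n_clusters} communities; "
            f"returning closest ({len(set(best))})",
            stacklevel=2,
        )
    return Partition(labels=list(best))


def generate_cells(params: ModelParams, n: int, rng: np.random.Generator) -> np.ndarray:
    """Sample n cells: Z ~ N(0, I), SEM-decode, then the decoder perceptron."""
    z = rng.standard_normal((n, params.n_genes))
    return decode(sem_decode_transform(z, params.adjacency), params)


def generation_auc(
    real_cells: np.ndarray,
    generated_cells: np.ndarray,
    folds: int = 5,
    rng: np.random.Generator | int = 0,
) -> float:
    """Mean out-of-fold AUC of a 100-tree random forest separating real (1)
    from generated (0) cells under stratified k-fold CV; lower is better
    generation."""
    from sklearn.ensemble import RandomForestClassifier
    from sklearn.model_selection import StratifiedKFold

    real_cells = np.asarray(real_cells, dtype=float)
    generated_cells = np.asarray(generated_cells, dtype=float)
    if real_cells.size == 0 or generated_cells.size == 0:
        raise ValueError("both real and generated sets must be nonempty")
    if real_cells.shape[1] != generated_cells.shape[1]:
        raise ValueError("real and generated cells must share one gene universe")
    seed = int(rng.integers(2**31)) if isinstance(rng, np.random.Generator) else int(rng)
    Xall = np.vstack([real_cells, generated_cells])
    y = np.concatenate([np.ones(len(real_cells)), np.zeros(len(generated_cells))])
    skf = StratifiedKFold(n_splits=folds, shuffle=True, random_state=seed)
    aucs = []
    for train_idx, test_idx in skf.split(Xall, y):
        clf = RandomForestClassifier(n_estimators=100, random_state=seed)
        clf.fit(Xall[train_idx], y[train_idx])
        prob = clf.predict_proba(Xall[test_idx])[:, 1]
        aucs.append(roc_auc_score(y[test_idx], prob))
    return float(np.mean(aucs))


def spearman_tf_target(
    generated: ExpressionMatrix, pairs: list[tuple[str, str]]
):
    """Spearman rank correlation of (TF, target) gene columns in generated data.

    Returns a DataFrame with columns tf, target, rho, pvalue.  Used to
    contrast a trained model against an A-test run (A frozen at zero).
    """
    import pandas as pd

    index = {g: i for i, g in enumerate(generated.gene_ids)}
    rows = []
    for tf, tgt in pairs:
        for g in (tf, tgt):
            if g not in index:
                raise ValueError(f"gene {g!r} not present in the generated matrix")
        rho, p = spearmanr(generated.values[:, index[tf]], generated.values[:, index[tgt]])
        rows.append({"tf": tf, "target": tgt, "rho": float(rho), "pvalue": float(p)})
    return pd.DataFrame(rows)
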