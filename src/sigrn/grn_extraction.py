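"""Turn trained adjacency matrices into ranked edge lists and stability tables.

Direction convention: entry ``a_ij`` of the adjacency matrix means gene j
regulates gene i (under X = X A^T + Z the expression of gene i is the
weighted sum over its regulators j), so the emitted edge is
(regulator = gene_j, target = gene_i).  Ranking is by |a_ij| descending with
deterministic (regulator, target) name tie-breaks so replicate unions are
reproducible.
"""

from __future__ import annotations

from collections import Counter
from dataclasses import dataclass, field

from .sem_vae_model import AdjacencyMatrix


@dataclass
class EdgeRanking:
    """Ordered (regulator, target, score) records over a candidate universe."""

    records: list[tuple[str, str, float]]
    candidate_universe: set[tuple[str, str]]

    def __post_init__(self) -> None:
        scores = [s for _, _, s in self.records]
        if any(s2 > s1 for s1, s2 in zip(scores, scores[1:])):
            raise ValueError("ranking scores must be non-increasing")
        pairs = [(r, t) for r, t, _ in self.records]
        if len(set(pairs)) != len(pairs):
            raise ValueError("duplicate edges in ranking")
        if any(r == t for r, t in pairs):
            raise ValueError("self-pairs are not rankable edges")

    def __len__(self) -> int:
        return len(self.records)


@dataclass
class StabilityTable:
    """Per-edge appearance counts of top-k sets across R replicates."""

    frequencies: dict[tuple[str, str], int]
    k: int
    n_replicates: int
    union_size: int = field(init=False)

    def __post_init__(self) -> None:
        self.union_size = len(self.frequencies)
        for edge, f in self.frequencies.items():
            if not 1 <= f <= self.n_replicates:
                raise ValueError(f"frequency {f} for edge {edge} outside [1, R]")
        if self.union_size > self.n_replicates * self.k:
            raise ValueError("union size exceeds R*k")

    def histogram(self) -> dict[int, int]:
        """Count of edges per appearance frequency."""
        return dict(Counter(self.frequencies.values()))

    def n_appearing_exactly_once(self) -> int:
        return sum(1 for f in self.frequencies.values() if f == 1)

    def n_appearing_more_than(self, times: int) -> int:
        return sum(1 for f in self.frequencies.values() if f > times)

    def n_in_all_replicates(self) -> int:
        return sum(1 for f in self.frequencies.values() if f == self.n_replicates)


def rank_edges(A: AdjacencyMatrix, tf_list: set[str] | None = None) -> EdgeRanking:
    """Rank all ordered gene pairs by |a_ij| descending.

    The candidate universe is every ordered pair (regulator, target) with
    regulator != target, restricted to ``tf_list`` regulators when supplied.
    Ties break by (regulator name, target name) ascending.
    """
    genes = A.gene_ids
    entries: list[tuple[float, str, str]] = []
    for i, target in enumerate(genes):
        for j, regulator in enumerate(genes):
            if i == j:
                continue
            if tf_list is not None and regulator not in tf_list:
                continue
            entries.append((abs(float(A.weights[i, j])), regulator, target))
    if not entries:
        raise ValueError("empty candidate universe (TF list excludes every regulator?)")
    entries.sort(key=lambda e: (-e[0], e[1], e[2]))
    records = [(reg, tgt, score) for score, reg, tgt in entries]
    universe = {(reg, tgt) for _, reg, tgt in entries}
    return EdgeRanking(records=records, candidate_universe=universe)


def top_k(ranking: EdgeRanking, k: int) -> set[tuple[str, str]]:
    """The first k edges of the ranking."""
    if k <= 0:
        raise ValueError("k must be positive")
    if k > len(ranking):
        raise ValueError(f"k={k} exceeds ranking length {len(ranking)}")
    return {(r, t) for r, t, _ in ranking.records[:k]}


def stability_union(rankings: list[EdgeRanking], k: int) -> StabilityTable:
    """Union of per-replicate top-k sets with per-edge appearance counts.

    All rankings must share one candidate universe; the union size |E_k| and
    the appearance histogram are the replicate-stability summaries.
    """
    if not rankings:
        raise ValueError("need at least one ranking")
    universe = rankings[0].candidate_universe
    for r in rankings[1:]:
        if r.candidate_universe != universe:
            raise ValueError("rankings do not share a candidate universe")
    counts: Counter = Counter()
    for r in rankings:
        counts.update(top_k(r, k))
    return StabilityTable(frequencies=dict(counts), k=k, n_replicates=len(rankings))


def write_stability_table(table: StabilityTable, path) -> None:
    """TSV with columns edge, frequency, k, R (edges sorted by frequency desc)."""
    items = sorted(table.frequencies.items(), key=lambda kv: (-kv[1], kv[0]))
    with open(path, "w") as fh:
        fh.write("regulator\ttarget\tfrequency\tk\tR\n")
        for (reg, tgt), freq in items:
            fh.write(f"{reg}\t{tgt}\t{freq}\t{table.k}\t{table.n_replicates}\n")
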