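"""Feature construction, edge splitting, negative sampling, and GCN propagation.

All edge lists use 0-based node indices and directed (source, target) pairs.
The propagation operator is the symmetrically normalized adjacency with self
loops, ``D^{-1/2} (A_sym + I) D^{-1/2}``, computed on the symmetrized 0/1
projection of the directed edge list; the directed edges themselves are kept
for decoding and evaluation.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path

import numpy as np

from .regnet_io import RegulatoryGraph

__all__ = ["EdgeSplit", "one_hot_features", "split_edges", "propagation_matrix"]

Edge = tuple[int, int]


@dataclass
class EdgeSplit:
    """Train/validation/test partition of directed edges plus matched negatives.

    The three positive sets partition the edge set exactly; each negative
    set has the same size as its positive counterpart, is disjoint from the
    true edge set and from the other negative sets, and contains no
    self-loops.
    """

    train_pos: list[Edge]
    val_pos: list[Edge]
    test_pos: list[Edge]
    train_neg: list[Edge]
    val_neg: list[Edge]
    test_neg: list[Edge]
    seed: int

    def to_tsv(self, path) -> None:
        lines = ["source_idx\ttarget_idx\tpartition"]
        for name in ("train_pos", "val_pos", "test_pos", "train_neg", "val_neg", "test_neg"):
            for s, t in getattr(self, name):
                lines.append(f"{s}\t{t}\t{name}")
        Path(path).write_text("\n".join(lines) + "\n")

    @classmethod
    def from_tsv(cls, path, seed: int = 0) -> "EdgeSplit":
        parts: dict[str, list[Edge]] = {
            k: [] for k in ("train_pos", "val_pos", "test_pos", "train_neg", "val_neg", "test_neg")
        }
        for line in Path(path).read_text().splitlines()[1:]:
            if not line.strip():
                continue
            s, t, name = line.split("\t")
            parts[name].append((int(s), int(t)))
        return cls(seed=seed, **parts)


def one_hot_features(graph: RegulatoryGraph) -> np.ndarray:
    """Identity-indicator feature matrix (|V| x |V|), row i one-hot at i."""
    if graph.n_nodes == 0:
        raise ValueError("graph has no nodes")
    return np.eye(graph.n_nodes)


def sample_negative_edges(
    graph: RegulatoryGraph,
    n: int,
    rng: np.random.Generator,
    forbidden: set[Edge] | None = None,
) -> list[Edge]:
    """Sample ``n`` distinct ordered non-edges uniformly, excluding self-loops.

    ``forbidden`` extends the exclusion set (e.g. negatives already drawn
    for another partition).  Rejection sampling; errors out when the graph
    is too dense to supply the requested count.
    """
    n_nodes = graph.n_nodes
    excluded = graph.edge_set()
    if forbidden:
        excluded = excluded | forbidden
    capacity = n_nodes * (n_nodes - 1) - len({e for e in excluded if e[0] != e[1]})
    if n > capacity:
        raise ValueError(f"cannot sample {n} negatives: only {capacity} non-edges exist")
    out: list[Edge] = []
    seen: set[Edge] = set()
    # oversample in blocks; loop terminates because capacity was checked
    while len(out) < n:
        block = max(64, 2 * (n - len(out)))
        src = rng.integers(n_nodes, size=block)
        dst = rng.integers(n_nodes, size=block)
        for s, t in zip(src.tolist(), dst.tolist()):
            if s == t:
                continue
            pair = (s, t)
            if pair in excluded or pair in seen:
                continue
            seen.add(pair)
            out.append(pair)
            if len(out) == n:
                break
    return out


def split_edges(
    graph: RegulatoryGraph,
    test_frac: float = 0.20,
    val_frac_of_train: float = 0.10,
    seed: int = 0,
) -> EdgeSplit:
    """Uniform random edge split with matched negative samples.

    ``round(test_frac * |E|)`` edges go to test; of the remainder,
    ``round(val_frac_of_train * ...)`` go to validation and the rest to
    train.  Negatives are drawn uniformly from ordered non-edge pairs,
    disjoint across the three partitions.  Deterministic under ``seed``.
    """
    if not 0.0 < test_frac < 1.0:
        raise ValueError("test_frac must be in (0, 1)")
    if not 0.0 <= val_frac_of_train < 1.0:
        raise ValueError("val_frac_of_train must be in [0, 1)")
    edges = list(graph.edges)
    if len(edges) < 10:
        raise ValueError("need at least 10 edges to split")

    rng = np.random.default_rng(np.random.SeedSequence([seed, 0x5711]))
    order = rng.permutation(len(edges))
    n_test = int(round(test_frac * len(edges)))
    test_pos = [edges[i] for i in order[:n_test]]
    rest = [edges[i] for i in order[n_test:]]
    n_val = int(round(val_frac_of_train * len(rest)))
    val_pos = rest[:n_val]
    train_pos = rest[n_val:]

    train_neg = sample_negative_edges(graph, len(train_pos), rng)
    val_neg = sample_negative_edges(graph, len(val_pos), rng, forbidden=set(train_neg))
    test_neg = sample_negative_edges(
        graph, len(test_pos), rng, forbidden=set(train_neg) | set(val_neg)
    )
    return EdgeSplit(train_pos, val_pos, test_pos, train_neg, val_neg, test_neg, seed)


def propagation_matrix(graph: RegulatoryGraph) -> np.ndarray:
    """Symmetric GCN propagation operator ``D^{-1/2} (A_sym | I) D^{-1/2}``.

    ``A_sym`` is the 0/1 symmetrized adjacency (unit edge weights); the
    union with the identity adds self-loops without double-counting any
    self-loop present in the input.
    """
    n = graph.n_nodes
    if n == 0:
        raise ValueError("graph has no nodes")
    a = np.zeros((n, n))
    for s, t in graph.edges:
        a[s, t] = 1.0
        a[t, s] = 1.0
    np.fill_diagonal(a, 1.0)
    d_inv_sqrt = 1.0 / np.sqrt(a.sum(axis=1))
    return a * d_inv_sqrt[:, None] * d_inv_sqrt[None, :]
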