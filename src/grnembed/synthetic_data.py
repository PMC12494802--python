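"""Synthetic TRRUST-like network generation and controlled Gaussian samples.

The generator emulates the statistical shape of a curated TF-target table:
heavy-tailed regulator out-degree, a configurable fraction of duplicate
annotation rows, regulation labels drawn from a fixed 3-simplex, partial
overlap between the regulator and target symbol sets, and planted modules
so clustering / neighborhood metrics downstream carry recoverable signal.

Symbols are synthetic (``TF0001`` ..., ``G0001`` ...); no real gene names
or PubMed ids are reproduced.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .regnet_io import Regulation, RegulatoryInteraction, build_graph

__all__ = [
    "NetworkGenConfig",
    "GaussianSampleConfig",
    "generate_network",
    "generate_gaussian_embeddings",
    "planted_partition_labels",
    "DEFAULT_REGULATION_PROBS",
]

# label frequencies of the reference table: (Unknown, Activation, Repression)
DEFAULT_REGULATION_PROBS = (659 / 1454, 532 / 1454, 263 / 1454)

_LABELS = (Regulation.UNKNOWN, Regulation.ACTIVATION, Regulation.REPRESSION)


@dataclass
class NetworkGenConfig:
    """Parameters of the synthetic regulatory-network generator.

    ``n_overlap`` symbols act as both regulator and target.  Unique-edge
    count is ``round(n_rows * (1 - duplicate_fraction))``; the remaining
    rows repeat already-emitted (tf, target) pairs with fresh labels.
    """

    n_tf: int = 60
    n_target: int = 160
    n_overlap: int = 20
    n_rows: int = 700
    duplicate_fraction: float = 0.15
    out_degree_exponent: float = 1.8
    n_modules: int = 5
    within_module_prob: float = 0.8
    regulation_probs: tuple[float, float, float] = DEFAULT_REGULATION_PROBS
    seed: int = 0

    def validate(self) -> None:
        if self.n_overlap > min(self.n_tf, self.n_target):
            raise ValueError("n_overlap must be <= min(n_tf, n_target)")
        if not 0.0 <= self.duplicate_fraction < 1.0:
            raise ValueError("duplicate_fraction must be in [0, 1)")
        if abs(sum(self.regulation_probs) - 1.0) > 1e-9:
            raise ValueError("regulation_probs must sum to 1")
        if min(self.regulation_probs) < 0:
            raise ValueError("regulation_probs must be nonnegative")
        if self.out_degree_exponent <= 0:
            raise ValueError("out_degree_exponent must be positive")
        if self.n_modules < 1:
            raise ValueError("n_modules must be >= 1")
        if not 0.0 <= self.within_module_prob <= 1.0:
            raise ValueError("within_module_prob must be in [0, 1]")

    @property
    def n_unique_edges(self) -> int:
        return int(round(self.n_rows * (1.0 - self.duplicate_fraction)))


@dataclass
class GaussianSampleConfig:
    """Diagonal-Gaussian sample spec for divergence-estimator validation."""

    n: int
    d: int
    mean: tuple[float, ...] | float = 0.0
    scale: tuple[float, ...] | float = 1.0
    seed: int = 0

    def mean_vector(self) -> np.ndarray:
        m = np.broadcast_to(np.asarray(self.mean, dtype=float), (self.d,))
        return np.array(m)

    def scale_vector(self) -> np.ndarray:
        s = np.array(np.broadcast_to(np.asarray(self.scale, dtype=float), (self.d,)))
        if np.any(s <= 0):
            raise ValueError("scales must be positive")
        return s


def _symbols(config: NetworkGenConfig) -> tuple[list[str], list[str]]:
    """TF symbol list and target symbol list (first n_overlap TFs reused)."""
    tfs = [f"TF{i + 1:04d}" for i in range(config.n_tf)]
    targets = tfs[: config.n_overlap] + [
        f"G{i + 1:04d}" for i in range(config.n_target - config.n_overlap)
    ]
    return tfs, targets


def _module_assignment(config: NetworkGenConfig) -> dict[str, int]:
    """Seeded module assignment guaranteeing every module holds TFs and targets.

    TFs and non-overlap targets are each shuffled and dealt round-robin, so
    modules are balanced in both roles; overlap symbols keep their TF module.
    """
    rng = np.random.default_rng(np.random.SeedSequence([config.seed, 0xA0D]))
    tfs, targets = _symbols(config)
    assignment: dict[str, int] = {}
    order = rng.permutation(config.n_tf)
    for pos, idx in enumerate(order):
        assignment[tfs[idx]] = pos % config.n_modules
    pure_targets = [t for t in targets if t not in assignment]
    order = rng.permutation(len(pure_targets))
    for pos, idx in enumerate(order):
        assignment[pure_targets[idx]] = pos % config.n_modules
    return assignment


def generate_network(config: NetworkGenConfig) -> list[RegulatoryInteraction]:
    """Generate annotation rows with the configured statistical structure.

    The unique-edge skeleton is built in three passes: one edge per TF and
    one per uncovered target (so all configured symbols appear and the node
    count is exact), then propensity-weighted filling up to the unique-edge
    budget.  TF propensities follow a Pareto law with the configured
    exponent.  Duplicate rows re-sample existing pairs; every row draws its
    regulation label i.i.d. from ``regulation_probs``.

    Deterministic under ``config.seed``.
    """
    config.validate()
    rng = np.random.default_rng(np.random.SeedSequence([config.seed, 0xE4E]))
    tfs, targets = _symbols(config)
    modules = _module_assignment(config)

    n_unique = config.n_unique_edges
    # self-loops (overlap symbol regulating itself) are excluded
    max_pairs = config.n_tf * config.n_target - config.n_overlap
    if n_unique > max_pairs:
        raise ValueError(
            f"infeasible config: {n_unique} unique edges demanded, "
            f"only {max_pairs} ordered pairs available"
        )
    if n_unique < max(config.n_tf, config.n_target):
        raise ValueError(
            "infeasible config: need at least max(n_tf, n_target) unique edges "
            "to cover every configured symbol"
        )

    propensity = 1.0 + rng.pareto(config.out_degree_exponent, size=config.n_tf)
    propensity /= propensity.sum()

    targets_by_module: dict[int, list[str]] = {}
    tfs_by_module: dict[int, list[str]] = {}
    for t in targets:
        targets_by_module.setdefault(modules[t], []).append(t)
    for t in tfs:
        tfs_by_module.setdefault(modules[t], []).append(t)

    edge_set: set[tuple[str, str]] = set()
    edge_list: list[tuple[str, str]] = []

    def _pick_target(tf: str) -> str:
        pool = targets
        if rng.random() < config.within_module_prob:
            mod_pool = targets_by_module.get(modules[tf])
            if mod_pool:
                pool = mod_pool
        return pool[rng.integers(len(pool))]

    def _pick_tf(target: str) -> str:
        if rng.random() < config.within_module_prob:
            mod_pool = tfs_by_module.get(modules[target])
            if mod_pool:
                return mod_pool[rng.integers(len(mod_pool))]
        return tfs[rng.choice(config.n_tf, p=propensity)]

    def _try_add(tf: str, target: str) -> bool:
        if tf == target or (tf, target) in edge_set:
            return False
        edge_set.add((tf, target))
        edge_list.append((tf, target))
        return True

    # pass 1: every TF regulates something
    for tf in tfs:
        for _ in range(1000):
            if _try_add(tf, _pick_target(tf)):
                break
        else:  # pragma: no cover - essentially unreachable for valid configs
            raise RuntimeError(f"could not place an edge for {tf}")
    # pass 2: every target is regulated by something
    covered = {t for _, t in edge_list}
    for target in targets:
        if target in covered:
            continue
        for _ in range(1000):
            if _try_add(_pick_tf(target), target):
                break
        else:  # pragma: no cover
            raise RuntimeError(f"could not place an edge for {target}")
    # pass 3: fill to the unique-edge budget by TF propensity
    attempts = 0
    while len(edge_list) < n_unique:
        attempts += 1
        if attempts > 200 * n_unique:  # pragma: no cover
            raise RuntimeError("edge sampling failed to reach the unique-edge budget")
        tf = tfs[rng.choice(config.n_tf, p=propensity)]
        _try_add(tf, _pick_target(tf))

    # duplicate rows repeat existing pairs (fresh labels, like repeated
    # literature evidence for one interaction)
    n_dup = config.n_rows - n_unique
    pairs = list(edge_list)
    for idx in rng.integers(len(edge_list), size=n_dup):
        pairs.append(edge_list[idx])

    order = rng.permutation(len(pairs))
    labels = rng.choice(3, size=len(pairs), p=np.asarray(config.regulation_probs))
    rows: list[RegulatoryInteraction] = []
    for pos, idx in enumerate(order):
        tf, target = pairs[idx]
        n_pmids = int(rng.integers(1, 3))
        pmids = tuple(str(int(p)) for p in rng.integers(10_000_000, 40_000_000, size=n_pmids))
        rows.append(RegulatoryInteraction(tf, target, _LABELS[labels[pos]], pmids))
    return rows


def planted_partition_labels(config: NetworkGenConfig) -> np.ndarray:
    """Module id per node, aligned to the node order of the built graph.

    Re-derives the module assignment used by :func:`generate_network` for
    the same config, and maps it onto the canonical node ordering of
    ``build_graph(generate_network(config))``.
    """
    modules = _module_assignment(config)
    graph = build_graph(generate_network(config))
    return np.array([modules[s] for s in graph.nodes], dtype=int)


def generate_gaussian_embeddings(config: GaussianSampleConfig) -> np.ndarray:
    """Draw an ``n x d`` diagonal-Gaussian sample, deterministic under seed."""
    if config.n < 1 or config.d < 1:
        raise ValueError("n and d must be positive")
    rng = np.random.default_rng(config.seed)
    return config.mean_vector() + config.scale_vector() * rng.standard_normal(
        (config.n, config.d)
    )
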