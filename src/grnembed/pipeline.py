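"""End-to-end orchestration of the autoencoder / adversarial / quantum
embedding comparison.

``run_comparison`` executes: load or generate the interaction table ->
build graph -> edge split -> train the graph autoencoder -> train the GAN
on its embeddings -> draw per-node GAN embeddings -> compute quantum
features from the autoencoder embeddings -> run the full metric battery ->
assemble a serializable report.  Per-stage seeds are derived by hashing
(master seed, stage name), so each stage is reproducible in isolation and
the whole report is bit-identical under a fixed master seed.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
import logging
import sys
import time
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np

from . import __version__
from .gae import EmbeddingMatrix, GAEConfig, decode_edges, train_gae
from .graph_gan import GANConfig, generate_node_embeddings, train_gan
from .graph_prep import one_hot_features, propagation_matrix, sample_negative_edges, split_edges
from .metrics import (
    DEFAULT_SIGMAS,
    average_precision,
    centrality_correlations,
    divergence_report,
    kmeans_labels,
    neighborhood_preservation,
    pca_2d,
    regulation_type_scores,
    roc_auc,
    silhouette,
)
from .quantum_features import CircuitSpec, quantum_feature_matrix
from .regnet_io import build_graph, parse_interaction_table
from .synthetic_data import NetworkGenConfig, generate_network

__all__ = ["MetricSettings", "RunConfig", "run_comparison", "stage_seed"]

log = logging.getLogger("grnembed")


def stage_seed(master_seed: int, stage: str) -> int:
    """Deterministic per-stage seed from the master seed and stage name."""
    digest = hashlib.sha256(f"{master_seed}:{stage}".encode()).hexdigest()
    return int(digest[:8], 16)


@dataclass
class MetricSettings:
    neighborhood_k: int = 5
    histogram_bins: int = 50
    mmd_sigmas: tuple[float, ...] = DEFAULT_SIGMAS
    kmeans_k: int = 5


@dataclass
class RunConfig:
    """Everything a comparison run needs; defaults reproduce the reference
    training recipe (GCN 128->64, Adam 0.01/5e-4, 100 epochs, patience 10;
    GAN 2e-4, betas (0.5, 0.999), batch 64, smoothing 0.9/0.1)."""

    tsv_path: str | None = None
    network: NetworkGenConfig = field(default_factory=NetworkGenConfig)
    test_frac: float = 0.20
    val_frac_of_train: float = 0.10
    gae: GAEConfig = field(default_factory=GAEConfig)
    gan: GANConfig = field(default_factory=GANConfig)
    circuit: CircuitSpec = field(default_factory=CircuitSpec)
    metrics: MetricSettings = field(default_factory=MetricSettings)
    seed: int = 0
    outdir: str | None = None


def _config_dict(config: RunConfig) -> dict:
    return json.loads(json.dumps(dataclasses.asdict(config), default=str))


def _link_prediction(emb, pos_pairs, neg_pairs) -> dict:
    pos = decode_edges(emb, pos_pairs)
    neg = decode_edges(emb, neg_pairs)
    scores = np.concatenate([pos, neg])
    labels = np.concatenate([np.ones(len(pos)), np.zeros(len(neg))])
    return {
        "auc": roc_auc(pos, neg),
        "average_precision": average_precision(scores, labels),
        "n_pos": int(len(pos)),
        "n_neg": int(len(neg)),
    }


def _timed(name: str, fn):
    t0 = time.perf_counter()
    try:
        result = fn()
    except Exception as exc:
        raise RuntimeError(f"pipeline stage {name!r} failed: {exc}") from exc
    log.info("stage %-18s %.2fs", name, time.perf_counter() - t0)
    return result


def run_comparison(config: RunConfig | None = None) -> dict:
    """Run the full comparison; returns the report as a plain dict.

    When ``config.outdir`` is set, embeddings (TSV), training histories
    (CSV), PCA coordinates (TSV), and the JSON report are also written
    there.
    """
    config = config or RunConfig()
    seeds = {name: stage_seed(config.seed, name)
             for name in ("network", "split", "gae", "gan", "gan_nodes",
                          "reconstruction", "kmeans")}

    # ---- data
    if config.tsv_path:
        interactions = _timed("load", lambda: parse_interaction_table(config.tsv_path))
    else:
        net_cfg = dataclasses.replace(config.network, seed=seeds["network"])
        interactions = _timed("generate", lambda: generate_network(net_cfg))
    graph = _timed("build_graph", lambda: build_graph(interactions))
    features = one_hot_features(graph)
    prop = propagation_matrix(graph)
    split = _timed("split", lambda: split_edges(
        graph, config.test_frac, config.val_frac_of_train, seed=seeds["split"]))

    # ---- models
    gae_cfg = dataclasses.replace(config.gae, seed=seeds["gae"])
    _, gae_history, z_gae = _timed(
        "train_gae", lambda: train_gae(graph, features, split, gae_cfg, propagation=prop))
    gan_cfg = dataclasses.replace(
        config.gan, embed_dim=z_gae.d, noise_dim=z_gae.d, seed=seeds["gan"])
    gen_params, _, gan_history = _timed("train_gan", lambda: train_gan(z_gae, gan_cfg))
    z_gan = generate_node_embeddings(gen_params, graph.n_nodes,
                                     seed=seeds["gan_nodes"], config=gan_cfg)
    qfm = _timed("quantum", lambda: quantum_feature_matrix(z_gae.values, config.circuit))
    z_quantum = EmbeddingMatrix(values=qfm.values, model_tag="QUANTUM")
    embeddings = {"GAE": z_gae, "GAN": z_gan, "QUANTUM": z_quantum}

    # ---- metrics
    def _battery():
        ms = config.metrics
        rng = np.random.default_rng(seeds["reconstruction"])
        recon_neg = sample_negative_edges(graph, graph.n_edges, rng)
        link = {}
        for name, emb in embeddings.items():
            link[name] = {
                "test": _link_prediction(emb.values, split.test_pos, split.test_neg),
                "reconstruction": _link_prediction(emb.values, graph.edges, recon_neg),
            }
        quality = {}
        for name, emb in embeddings.items():
            labels = kmeans_labels(emb.values, ms.kmeans_k, seed=seeds["kmeans"])
            quality[name] = {
                "silhouette": silhouette(emb.values, labels),
                "neighborhood_preservation": neighborhood_preservation(
                    graph, emb.values, k=ms.neighborhood_k),
                "k": ms.neighborhood_k,
                "kmeans_k": ms.kmeans_k,
            }
        centrality = {name: centrality_correlations(graph, emb.values)
                      for name, emb in embeddings.items()}
        divergence = divergence_report(z_gae.values, z_gan.values,
                                       bins=ms.histogram_bins, sigmas=ms.mmd_sigmas)
        regulation = regulation_type_scores(
            interactions, graph, {"GAE": z_gae, "GAN": z_gan})
        pca = {name: pca_2d(emb.values) for name, emb in embeddings.items()}
        return link, quality, centrality, divergence, regulation, pca

    link, quality, centrality, divergence, regulation, pca = _timed("metrics", _battery)

    n_rows = len(interactions)
    label_counts: dict[str, int] = {}
    for rec in interactions:
        label_counts[rec.regulation.value] = label_counts.get(rec.regulation.value, 0) + 1

    report = {
        "dataset": {
            "n_nodes": graph.n_nodes,
            "n_unique_edges": graph.n_edges,
            "n_annotation_rows": n_rows,
            "n_duplicate_rows": n_rows - graph.n_edges,
            "n_tf": int(sum(graph.is_tf)),
            "n_target": int(sum(graph.is_target)),
            "regulation_counts": dict(sorted(label_counts.items())),
        },
        "link_prediction": link,
        "embedding_quality": quality,
        "centrality_correlations": centrality,
        "divergence_gae_vs_gan": divergence.to_dict(),
        "regulation_type_scores": regulation,
        "pca_explained_variance": {
            name: explained.tolist() for name, (_, explained) in pca.items()
        },
        "training": {
            "gae": {
                "train_loss": gae_history.train_loss,
                "val_loss": gae_history.val_loss,
                "best_epoch": gae_history.best_epoch,
                "stopped_epoch": gae_history.stopped_epoch,
            },
            "gan": {
                "gen_loss": gan_history.gen_loss,
                "disc_loss": gan_history.disc_loss,
                "real_score": gan_history.real_score,
                "fake_score": gan_history.fake_score,
            },
        },
        "provenance": {
            "package_version": __version__,
            "master_seed": config.seed,
            "stage_seeds": seeds,
            "config": _config_dict(config),
            "config_hash": hashlib.sha256(
                json.dumps(_config_dict(config), sort_keys=True).encode()
            ).hexdigest(),
            "timestamp": time.strftime("%Y-%m-%dT%H:%M:%S"),
        },
    }

    if config.outdir:
        _write_artifacts(Path(config.outdir), report, graph, embeddings, pca)
    return report


def _write_artifacts(outdir: Path, report: dict, graph, embeddings, pca) -> None:
    outdir.mkdir(parents=True, exist_ok=True)
    (outdir / "report.json").write_text(json.dumps(report, indent=2, sort_keys=True))
    for name, emb in embeddings.items():
        lines = []
        for i, symbol in enumerate(graph.nodes):
            lines.append(symbol + "\t" + "\t".join(f"{v:.8g}" for v in emb.values[i]))
        (outdir / f"embeddings_{name.lower()}.tsv").write_text("\n".join(lines) + "\n")
        coords, _ = pca[name]
        lines = ["node\tpc1\tpc2"] + [
            f"{symbol}\t{coords[i, 0]:.8g}\t{coords[i, 1]:.8g}"
            for i, symbol in enumerate(graph.nodes)
        ]
        (outdir / f"pca_{name.lower()}.tsv").write_text("\n".join(lines) + "\n")
    gae_hist = report["training"]["gae"]
    lines = ["epoch,train_loss,val_loss"] + [
        f"{i},{tl},{vl}"
        for i, (tl, vl) in enumerate(zip(gae_hist["train_loss"], gae_hist["val_loss"]))
    ]
    (outdir / "history_gae.csv").write_text("\n".join(lines) + "\n")
    gan_hist = report["training"]["gan"]
    lines = ["epoch,gen_loss,disc_loss,real_score,fake_score"] + [
        f"{i},{g},{d},{r},{f}"
        for i, (g, d, r, f) in enumerate(zip(
            gan_hist["gen_loss"], gan_hist["disc_loss"],
            gan_hist["real_score"], gan_hist["fake_score"]))
    ]
    (outdir / "history_gan.csv").write_text("\n".join(lines) + "\n")
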