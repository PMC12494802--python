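# grnembed

Comparative embedding of transcription factor–gene regulatory networks.
The package trains a graph autoencoder (two-layer GCN encoder,
inner-product decoder) on a directed TF→target interaction graph, trains an
adversarial generator/discriminator on the resulting embedding space,
derives quantum angle-encoded node features (exact statevector simulation:
per-qubit RY/RZ rotations, a CNOT entangling chain, Pauli-Z readout), and
evaluates all three embedding sets with a common battery: link-prediction
AUC / average precision, silhouette and neighborhood preservation,
centrality–norm correlations, per-dimension KL / Jensen-Shannon /
Wasserstein divergences, RBF-kernel MMD over a bandwidth grid, and
regulation-type score breakdowns.

Everything is plain NumPy/SciPy — the neural models use hand-written exact
gradients (verified against finite differences in the test suite), and the
quantum circuit is a self-contained statevector simulator checked against a
dense Kronecker-product oracle.

## Layout

| module | role |
| --- | --- |
| `grnembed.regnet_io` | TRRUST-layout TSV parsing/writing, duplicate-row collapsing, directed graph construction |
| `grnembed.synthetic_data` | TRRUST-like network generator (heavy-tailed out-degree, planted modules, duplicate rows) and Gaussian samples for estimator validation |
| `grnembed.graph_prep` | one-hot features, 80/20 edge splits with matched negatives, symmetric GCN propagation operator |
| `grnembed.gae` | graph autoencoder + trainer (Adam 0.01, weight decay 5e-4, 100 full-batch epochs, early stopping patience 10) |
| `grnembed.graph_gan` | generator (64→128→64→64, batch norm, LeakyReLU 0.2) and discriminator (64→64→32→1, dropout 0.3), Adam 2e-4 / betas (0.5, 0.999), label smoothing 0.9/0.1 |
| `grnembed.quantum_features` | angle-encoding circuit and Pauli-Z feature extraction (1–12 qubits, default 8) |
| `grnembed.metrics` | the full evaluation battery |
| `grnembed.pipeline` | end-to-end orchestration, per-stage seeding, JSON/TSV/CSV report output |

## CLI

Run the full comparison on the built-in synthetic default (≈200 nodes):

```sh
grnembed run --seed 1 --out results/run1
```

`results/run1/report.json` then holds the dataset summary, all metrics, and
training histories; embeddings and PCA coordinates are written as TSV.
Options are set through a YAML file mirroring the `RunConfig` dataclass
tree, e.g.

```yaml
network: {n_tf: 231, n_target: 536, n_overlap: 61, n_rows: 1454, duplicate_fraction: 0.17}
gae: {epochs: 100}
```

```sh
grnembed run --config config.yaml --seed 1 --out results/full
grnembed simulate --out data/ --seed 3        # emit a synthetic TSV
grnembed run --config with_tsv_path.yaml      # train on a TSV instead
grnembed evaluate --embeddings a.tsv b.tsv    # divergence battery only
```

## Notes on fidelity

Two implementation choices depart from a literal reading of the source
description, both taken because the literal variant demonstrably breaks the
results the model is evaluated on (details in the module docstrings):

* layer normalization is applied to the hidden GCN layer pre-activation,
  and the output GCN layer is linear.  Output-side normalization equalizes
  node norms and erases the centrality correlation; an output ReLU lets
  nodes die irrecoverably and caps reconstruction AUC near 0.8.  Both
  literal variants remain available via `GAEConfig` flags and are covered
  by the gradient tests.
* per-node GAN embeddings are generated unconditionally and assigned by
  node index — the generator has no node identity, which is also why its
  link-prediction AUC is expected (and tested) to sit near chance.
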