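# molssl

Multi-task self-supervised pretraining for molecular graph representations,
with fine-tuning and latent-space analysis, runnable end-to-end on a bundled
synthetic molecule generator.

## The problem

Molecular property prediction (ADMET endpoints, target inhibition, solubility)
is label-starved: experimental annotations cover a sliver of chemical space.
Self-supervised pretraining sidesteps this by learning a molecular encoder
from unlabeled SMILES corpora, then fine-tuning it on small labeled tables.
`molssl` implements one such framework for practitioners who want a
transparent, dependency-light reference implementation of the method and of
the analyses used to audit what the learned latent space encodes.

## The method

Molecules are parsed into attributed graphs *G = (V, E)* over heavy atoms
(atoms featurized by atomic number and chirality, bonds by type and
direction). A graph isomorphism network (GIN) encoder performs K rounds of
message passing,

    a_v^(k) = Σ_{u ∈ N(v)} ( h_u^(k−1) + e_{uv} )          (AGGREGATE)
    h_v^(k) = MLP_k( (1 + ε) · h_v^(k−1) + a_v^(k) ),  ε=0  (COMBINE)

mean-pools the final node states into a 512-D graph representation h_G
(READOUT), and projects it through a one-hidden-layer MLP to a 256-D latent
z = f_θ(x). Two self-supervised objectives are optimized jointly with Adam:

* **L_MLCT** — multi-granularity pseudo-label classification. K-means is run
  on 166-bit MACCS fingerprints at several granularities (default
  K = 100, 1000, 10000); each molecule's cluster indices become pseudo-labels
  predicted from z by parallel affine heads. L_MLCT = ℓ_100 + ℓ_1000 +
  ℓ_10000, each ℓ a batch-mean cross-entropy.
* **L_MCL** — masked-graph contrastive learning. A connected region covering
  ⌈ratio·|V|⌉ atoms (default ratio 0.25) is masked by breadth-first expansion
  from a random start atom; bonds internal to the region are removed. L_MCL
  is the mean Euclidean distance ‖f_θ(x) − f_θ(x′)‖₂ between a molecule's
  latent and its masked variant's.

The total loss is the unweighted sum **L_all = L_MLCT + L_MCL**. Ablation
modes train with either term alone, or skip pretraining entirely.

Everything downstream — scaffold-split fine-tuning with AUROC/AUPRC/RMSE/MAE/
correlation metrics, kNN probing of the latent space, Tanimoto-vs-latent-
distance percentile profiles, nearest-neighbour descriptor correlations — is
provided as library functions plus a thin `molssl` CLI. The learning stack
(reverse-mode autodiff, GIN forward/backward, Adam) is pure NumPy; chemistry
primitives are delegated to RDKit, clustering and metrics to scikit-learn.

## Worked example

```python
import numpy as np
import molssl as M

# a seeded synthetic corpus of 2000 molecules from 4 scaffold families
corpus, families = M.generate_corpus(M.SynthSpec(n_molecules=2000,
                                                 n_families=4, seed=42))
fps = np.array([M.compute_maccs(m) for m in corpus], dtype=float)

cfg = M.PretrainConfig(
    epochs=30, batch_size=256, granularities=(4, 8, 16), mask_ratio=0.25,
    encoder=M.EncoderConfig(n_layers=5, hidden_dim=64, graph_dim=64,
                            latent_dim=32, seed=0),
    seed=0)
result = M.pretrain(list(corpus), cfg, fingerprints=fps)
print(f"L_all epoch 1: {result.log[0].l_all:.1f}  "
      f"final: {result.log[-1].l_all:.1f}")
print(f"coarsest-head pseudo-label accuracy: {result.head_accuracy[0]:.2f}")
```

prints (to run-to-run numerical identity for a fixed seed):

```
L_all epoch 1: 98.3  final: 3.4
coarsest-head pseudo-label accuracy: 0.97
```

The total loss falls by ~29x over 30 epochs and the coarsest classifier head
predicts its K=4 fingerprint-cluster pseudo-labels for 97% of molecules
(chance 25%) — the encoder has internalized the fingerprint-cluster
structure from graphs alone. The same encoder then transfers: fine-tuned for
a single epoch on a scaffold-split aromatic-ring task it reaches test AUROC
≈ 0.99 versus ≈ 0.94 for a randomly initialized encoder under the identical
budget.

The equivalent shell workflow:

```bash
molssl --set synth.n_molecules=2000 synth --out corpus.smi
molssl --set "augment.granularities=[4,8,16]" \
       --set encoder.hidden_dim=64 --set encoder.graph_dim=64 \
       --set encoder.latent_dim=32 \
       pretrain --corpus corpus.smi --out model.npz --log train.csv
molssl embed --ckpt model.npz --in corpus.smi --out latents.tsv
```

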