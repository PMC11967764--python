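# Methods

## Model

Molecules are attributed graphs over heavy atoms; hydrogens are implicit, as
is standard for molecular message passing. Atom features are (atomic number,
chirality code) with a four-value chirality vocabulary (unspecified /
clockwise / counter-clockwise / other); bond features are (type, direction)
with type in {single, double, triple, aromatic} and direction in {none,
end-upward, end-downward}. Multi-fragment SMILES (salts) are reduced to the
largest fragment by default; the choice is a parser flag.

The encoder is a GIN with edge features. Atom embeddings are the sum of an
atomic-number and a chirality embedding; each message-passing layer adds a
layer-specific bond embedding to the neighbour state before summation
(the standard GIN-with-edge-features construction), applies the COMBINE
update with ε fixed at 0 (non-learnable), and passes the result through a
2-layer ReLU MLP. Five layers are used by default; the last layer widens
from the hidden width (default 300) to the 512-D graph representation, which
is mean-pooled over nodes. A one-hidden-layer projection MLP maps the
representation to the 256-D latent. The per-layer MLPs deliberately omit
batch normalization: with no stochastic or batch-coupled layers anywhere,
encoding is deterministic, training and evaluation modes coincide exactly,
and per-molecule embeddings are independent of batch composition. All
learning components — reverse-mode autodiff, the GIN forward/backward pass,
Adam — are implemented in NumPy inside the package (`molssl.autodiff`),
keeping the numerical path small, inspectable and exactly reproducible.

## Objectives

**Pseudo-label classification (L_MLCT).** K-means (k-means++ init, 10
restarts, 300-iteration cap, Euclidean metric on the 166-bit MACCS vectors
treated as real) is fitted once per granularity on the full corpus before
training and frozen; the runs at different K are independent. Cluster
assignment is nearest-centroid with ties broken toward the lowest index.
One affine head per granularity maps the 256-D latent to K logits; L_MLCT is
the sum over granularities of batch-mean cross-entropies. Defaults
K = (100, 1000, 10000) with matching head widths; desk-scale runs use
proportionally smaller K.

**Masked-graph contrastive loss (L_MCL).** The mask grows breadth-first from
a single seeded start atom, visiting neighbours in ascending node index,
until exactly ⌈ratio·n_atoms⌉ atoms are masked (restarting from a fresh
unmasked atom if a disconnected fragment exhausts the frontier). Masked
atoms keep their position but their features are replaced by a reserved
mask token outside the chemical vocabulary; bonds with both endpoints masked
are deleted, boundary bonds kept. This feature-replacement realization keeps
the graph order fixed so the contrastive pair is always well-defined; an
excision variant (dropping the masked subgraph) would change the readout
support and is not used. L_MCL is the batch-mean plain Euclidean distance
between original and masked latents (a squared variant sits behind a flag);
gradients flow through both branches. Default mask ratio 0.25, one fresh
masked view per molecule per epoch with mask seeds derived from
(root seed, epoch, molecule index) so any run replays exactly.

**Total.** L_all = L_MLCT + L_MCL, unweighted; Adam with lr 1e-3, betas
(0.9, 0.999), batch 256. Modes `mlct_only` / `mcl_only` / `none` implement
the single-objective and no-pretraining ablations; in `mlct_only` the masked
branch is never constructed.

## Fine-tuning and evaluation

A 2-layer task head on the 512-D representation is trained end-to-end with
the encoder (binary cross-entropy or MSE), early-stopped on validation AUROC
or RMSE with patience 10; a frozen-encoder linear-probe mode exists for
representation audits. Datasets are split by Bemis–Murcko scaffold by
default: groups are taken largest-first and each is assigned to the split
with the smallest fill ratio (current/target, ties train < valid < test), so
no scaffold straddles splits and all three splits stay populated whenever at
least three scaffold groups exist. Metrics are standard scikit-learn /
SciPy definitions (AUROC, AUPRC, accuracy; RMSE, MAE, Pearson, Spearman).

## Latent-space analyses

kNN classification uses cosine distance on the latent with majority vote
(the positive-vote fraction is the score). The similarity profile ranks
references by cosine distance to a query, cuts the ranking into 10
percentile bins (bin i covers ranks ⌈(i−1)N/10⌉ … ⌈iN/10⌉−1, ties broken by
input order), samples up to 1000 members per bin, and reports per-bin mean
Tanimoto similarity of MACCS fingerprints to the query; a structure-aware
embedding shows the mean falling with bin index (summarized as the Spearman
correlation between bin index and mean). Descriptor correlation finds each
molecule's cosine-nearest neighbour (self excluded) and reports per-
descriptor Spearman r between own and neighbour values over MolLogP, MolWt,
TPSA, rotatable-bond count, QED and synthetic accessibility; constant or
failed descriptors are flagged absent rather than propagated.

## Synthetic corpora

The generator emulates the one property of real pretraining corpora the
method actually exploits: latent structural families with clusterable
fingerprints. Each molecule is one of up to 12 scaffolds (aromatic and
aliphatic ring systems and an alkane chain, interleaved so any family subset
mixes both chemistries) decorated with seeded random substituents at
H-bearing positions; sanitization failures are resampled, so every emitted
SMILES is valid by construction. Two substituent regimes are study
conditions fixed in the package:

* the default pool (halogens, hydroxyl, methyl, amino, nitro, phenyl; 0–3
  per molecule) keeps the scaffold the dominant fingerprint signal, so
  families are recoverable by k-means at K = n_families — the regime used
  for pretraining and latent-analysis corpora;
* a diverse pool adding five ring substituents (1–4 per molecule) multiplies
  the number of distinct Bemis–Murcko scaffolds, so scaffold-grouped splits
  consist of many small, label-mixed groups — the regime used for
  property-prediction corpora, where phenyl substituents also decouple the
  aromatic-ring label from family membership.

Labels are computed from structure (aromatic-ring presence; heteroatom-count
threshold; a linear function of heavy-atom and heteroatom counts with
optional Gaussian noise), so fine-tuning always has an exact oracle. What
the generator does **not** emulate: realistic drug-likeness distributions,
activity cliffs, assay noise structure, tautomers/stereoisomer ambiguity, or
the scale of multi-million-molecule corpora. Passing tests therefore show
the machinery learns and transfers the structure it was given — not that it
matches published benchmark numbers on real assay data.

## Study sizes and protocols

Desk-scale study conditions: a 2000-molecule, 4-family corpus, granularities
(4, 8, 16), mask ratio 0.25, 30 epochs, with a narrow encoder (hidden 64,
representation 64, latent 32) sized for single-CPU runs; architecture
constants (5 layers, 512/256, head widths 100/1000/10000) are verified on
freshly built default-configuration models separately. The transfer
comparison is a deliberately limited-budget probe: the aromatic-ring task
(n = 1000, scaffold split, 3 seeds) is fine-tuned for a single epoch at a
shared learning rate of 1e-4 in both arms. At generous budgets both
initializations saturate at AUROC 1.0 and the comparison degenerates to
ceiling ties, so the probe is run in the underfitting regime where
initialization quality is what is measured; the pretrained arm typically
scores ≈0.99 versus ≈0.94 for random initialization, and near-ties in favor
of either arm can still occur when a random run saturates within its
single epoch.

## Numerical choices and degenerate inputs

Float64 throughout. Cross-entropy uses max-shifted softmax; the plain
Euclidean contrastive gradient is defined as 0 at coincident points; binary
cross-entropy uses the stable log1p(exp(−|x|)) form. Tanimoto similarity of
two all-zero fingerprints is defined as 1. Empty aggregation (isolated
atoms) contributes a zero vector. Invalid SMILES raise in the
single-molecule API but are skipped-and-counted during corpus reading.
Single-class label vectors make AUROC undefined and raise; constant
descriptors return an absent correlation. A k-means granularity exceeding
the corpus size is rejected naming the offending K.

## Known limitations

The NumPy training stack is single-threaded-BLAS bound and intended for
desk-scale corpora (10³–10⁴ molecules), not the multi-million-molecule
regime. Pseudo-labels are frozen after one clustering pass (no online
re-clustering). Bond direction codes are kept identical for both traversal
directions of a bond. GCN/GAT backbones and t-SNE visualization are out of
scope.
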