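"""Multi-task self-supervised pretraining.

Two objectives are optimized jointly over the unlabeled corpus:

* L_MLCT — multi-label classification of fingerprint-cluster pseudo-labels:
  one affine head per clustering granularity maps the latent to K_i logits
  and the per-head mean cross-entropies are summed;
* L_MCL — masked-graph contrastive loss: the mean Euclidean distance between
  the latent of each molecule and that of its masked variant.

The total loss L_all = L_MLCT + L_MCL (unweighted) is minimized with Adam.
Ablation modes restrict training to one objective (``mlct_only`` /
``mcl_only``) or skip pretraining entirely (``none``).
"""

from __future__ import annotations

import csv
import logging
from dataclasses import dataclass, field

import numpy as np

from . import autodiff as ad
from .augment import (ClusteringModel, DEFAULT_GRANULARITIES, DEFAULT_MASK_RATIO,
                      apply_mask_for_encoding, assign_pseudo_labels_batch,
                      fit_pseudo_labeler, mask_graph)
from .autodiff import Adam, Tensor
from .chem_io import Molecule, compute_maccs
from .encoder import (EncoderConfig, EncoderState, batch_graphs, forward_batch,
                      init_encoder)

logger = logging.getLogger(__name__)

MODES = ("full", "mlct_only", "mcl_only", "none")


@dataclass
class StructuralClassifier:
    """Parallel affine heads, one per granularity, latent_dim -> K_i logits."""

    granularities: tuple[int, ...]
    params: dict[str, Tensor]

    @classmethod
    def init(cls, latent_dim: int, granularities: tuple[int, ...],
             seed: int) -> "StructuralClassifier":
        rng = np.random.default_rng(seed)
        p: dict[str, Tensor] = {}
        for i, k in enumerate(granularities):
            p[f"head_{i}_w"] = ad.param(None, rng, scale=np.sqrt(1.0 / latent_dim),
                                        shape=(latent_dim, k))
            p[f"head_{i}_b"] = ad.param(np.zeros(k))
        return cls(tuple(granularities), p)

    def logits(self, latents: Tensor, i: int) -> Tensor:
        return ad.linear(latents, self.params[f"head_{i}_w"],
                         self.params[f"head_{i}_b"])


@dataclass
class LossReport:
    l_mlct: float
    l_mcl: float
    l_all: float
    per_head_ce: tuple[float, ...]


@dataclass
class PretrainConfig:
    epochs: int = 30
    batch_size: int = 256
    learning_rate: float = 1e-3
    mask_ratio: float = DEFAULT_MASK_RATIO
    granularities: tuple[int, ...] = DEFAULT_GRANULARITIES
    seed: int = 0
    mode: str = "full"
    encoder: EncoderConfig = field(default_factory=EncoderConfig)
    squared_mcl: bool = False  # squared Euclidean variant of L_MCL

    def __post_init__(self):
        if self.mode not in MODES:
            raise ValueError(f"mode must be one of {MODES}")
        if not 0.0 <= self.mask_ratio <= 1.0:
            raise ValueError("mask_ratio outside [0, 1]")


# -- loss operations ----------------------------------------------------------

def mlct_loss(heads: StructuralClassifier, latents: Tensor,
              labels: np.ndarray) -> tuple[Tensor, tuple[float, ...]]:
    """Sum over granularities of the batch-mean cross-entropy.

    ``labels`` is an (N, n_granularities) integer array of pseudo-labels.
    """
    labels = np.asarray(labels)
    if labels.ndim != 2 or labels.shape[1] != len(heads.granularities):
        raise ValueError("label arity does not match head count")
    total: Tensor | None = None
    per_head: list[float] = []
    for i in range(len(heads.granularities)):
        ce = ad.cross_entropy_mean(heads.logits(latents, i), labels[:, i])
        per_head.append(float(ce.data))
        total = ce if total is None else ad.add(total, ce)
    return total, tuple(per_head)


def mcl_loss(latents_original: Tensor, latents_masked: Tensor,
             squared: bool = False) -> Tensor:
    """Mean Euclidean distance between original and masked-graph latents."""
    return ad.pairwise_l2_mean(latents_original, latents_masked, squared=squared)


def total_loss(l_mlct: float, l_mcl: float, mode: str = "full") -> float:
    """Combine the two objectives according to the training mode."""
    if not (np.isfinite(l_mlct) and np.isfinite(l_mcl)):
        raise FloatingPointError(
            f"non-finite loss: l_mlct={l_mlct}, l_mcl={l_mcl}")
    if mode == "full":
        return l_mlct + l_mcl
    if mode == "mlct_only":
        return l_mlct
    if mode == "mcl_only":
        return l_mcl
    raise ValueError(f"mode must be one of {MODES[:3]} for a loss combination")


# -- training loop ------------------------------------------------------------

@dataclass
class PretrainResult:
    encoder: EncoderState
    heads: StructuralClassifier | None
    labeler: ClusteringModel | None
    log: list[LossReport]
    head_accuracy: tuple[float, ...] | None  # final top-1 accuracy per head


def _corpus_fingerprints(corpus: list[Molecule]) -> np.ndarray:
    return np.asarray([compute_maccs(m) for m in corpus], dtype=float)


def pretrain(corpus: list[Molecule], config: PretrainConfig,
             fingerprints: np.ndarray | None = None,
             log_path: str | None = None) -> PretrainResult:
    """Run the joint self-supervised optimization over a molecule corpus.

    The pseudo-labeler is fitted once on the full corpus and frozen; each
    epoch shuffles the corpus (seeded) and draws one fresh masked view per
    molecule, with mask seeds derived from (root seed, epoch, molecule
    index) so runs replay exactly.  Mode ``none`` returns the freshly
    initialized encoder untouched.
    """
    encoder = init_encoder(config.encoder)
    if config.mode == "none":
        return PretrainResult(encoder, None, None, [], None)

    if fingerprints is None:
        fingerprints = _corpus_fingerprints(corpus)
    use_mlct = config.mode in ("full", "mlct_only")
    use_mcl = config.mode in ("full", "mcl_only")

    labeler = None
    labels = None
    heads = None
    trainable = dict(encoder.params)
    if use_mlct:
        labeler = fit_pseudo_labeler(fingerprints, config.granularities,
                                     seed=config.seed)
        labels = assign_pseudo_labels_batch(labeler, fingerprints)
        heads = StructuralClassifier.init(config.encoder.latent_dim,
                                          config.granularities,
                                          seed=config.seed + 1)
        trainable.update(heads.params)

    opt = Adam(trainable, lr=config.learning_rate)
    rng = np.random.default_rng(config.seed)
    n = len(corpus)
    graphs = [m.graph for m in corpus]
    log: list[LossReport] = []

    for epoch in range(config.epochs):
        order = rng.permutation(n)
        ep_mlct, ep_mcl, ep_heads = [], [], []
        for start in range(0, n, config.batch_size):
            idx = order[start:start + config.batch_size]
            batch = batch_graphs([graphs[i] for i in idx])
            _, latents = forward_batch(encoder, batch)

            l_mlct_t: Tensor | None = None
            per_head: tuple[float, ...] = ()
            if use_mlct:
                l_mlct_t, per_head = mlct_loss(heads, latents, labels[idx])
            l_mcl_t: Tensor | None = None
            if use_mcl:
                masked = [apply_mask_for_encoding(
                    mask_graph(graphs[i], config.mask_ratio,
                               seed=(config.seed * 1000003 + epoch * 9176 + int(i))
                               % (2 ** 31)))
                    for i in idx]
                _, latents_masked = forward_batch(encoder, batch_graphs(masked))
                l_mcl_t = mcl_loss(latents, latents_masked,
                                   squared=config.squared_mcl)

            if l_mlct_t is not None and l_mcl_t is not None:
                loss = ad.add(l_mlct_t, l_mcl_t)
            else:
                loss = l_mlct_t if l_mlct_t is not None else l_mcl_t
            lm = float(l_mlct_t.data) if l_mlct_t is not None else 0.0
            lc = float(l_mcl_t.data) if l_mcl_t is not None else 0.0
            if not np.isfinite(loss.data):
                raise FloatingPointError(
                    f"non-finite loss at epoch {epoch}: {lm}, {lc}")
            opt.zero_grad()
            loss.backward()
            opt.step()
            ep_mlct.append(lm)
            ep_mcl.append(lc)
            ep_heads.append(per_head)

        l_mlct = float(np.mean(ep_mlct))
        l_mcl = float(np.mean(ep_mcl))
        per_head_mean = (tuple(float(x) for x in np.mean(ep_heads, axis=0))
                         if use_mlct else ())
        report = LossReport(l_mlct=l_mlct, l_mcl=l_mcl,
                            l_all=l_mlct + l_mcl, per_head_ce=per_head_mean)
        log.append(report)
        logger.info("epoch %d: l_mlct=%.4f l_mcl=%.4f l_all=%.4f",
                    epoch, l_mlct, l_mcl, report.l_all)

    head_acc = None
    if use_mlct:
        head_acc = pseudo_label_accuracy(encoder, heads, graphs, labels)
    if log_path:
        write_training_log(log_path, log)
    return PretrainResult(encoder, heads, labeler, log, head_acc)


def pseudo_label_accuracy(encoder: EncoderState, heads: StructuralClassifier,
                          graphs, labels: np.ndarray,
                          batch_size: int = 256) -> tuple[float, ...]:
    """Top-1 accuracy of each classifier head over the given corpus."""
    labels = np.asarray(labels)
    correct = np.zeros(len(heads.granularities))
    for i in range(0, len(graphs), batch_size):
        chunk = graphs[i:i + batch_size]
        _, latents = forward_batch(encoder, batch_graphs(chunk))
        for j in range(len(heads.granularities)):
            pred = np.argmax(heads.logits(latents, j).data, axis=1)
            correct[j] += np.sum(pred == labels[i:i + batch_size, j])
    return tuple(correct / len(graphs))


def write_training_log(path: str, log: list[LossReport]) -> None:
    with open(path, "w", newline="") as fh:
        writer = csv.writer(fh)
        n_heads = max((len(r.per_head_ce) for r in log), default=0)
        writer.writerow(["epoch", "l_mlct", "l_mcl", "l_all"]
                        + [f"head_{i}_ce" for i in range(n_heads)])
        for e, r in enumerate(log):
            writer.writerow([e, r.l_mlct, r.l_mcl, r.l_all, *r.per_head_ce])
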