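"""Supervised fine-tuning of a pretrained encoder on molecular property tables.

A 2-layer task head is attached to the 512-D graph representation and the
whole model (encoder included) is trained with cross-entropy (binary
classification) or mean-squared error (regression), with early stopping on
the validation metric.  Datasets are split by Bemis-Murcko scaffold by
default so test molecules come from unseen chemotypes.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass, field

import numpy as np
from rdkit.Chem.Scaffolds import MurckoScaffold
from scipy.stats import pearsonr, spearmanr
from sklearn.metrics import (accuracy_score, average_precision_score,
                             mean_absolute_error, mean_squared_error,
                             roc_auc_score)

from . import autodiff as ad
from .autodiff import Adam, Tensor
from .chem_io import Molecule
from .encoder import EncoderState, batch_graphs, clone_state, forward_batch

logger = logging.getLogger(__name__)


@dataclass
class PropertyDataset:
    molecules: list[Molecule]
    labels: np.ndarray
    task_type: str  # "classification" | "regression"
    splits: tuple[list[int], list[int], list[int]] | None = None

    def __post_init__(self):
        self.labels = np.asarray(self.labels, dtype=float)
        if len(self.labels) != len(self.molecules):
            raise ValueError("labels must align 1:1 with molecules")
        if self.task_type not in ("classification", "regression"):
            raise ValueError(f"unknown task type {self.task_type!r}")
        if self.task_type == "classification":
            vals = set(np.unique(self.labels))
            if not vals <= {0.0, 1.0}:
                raise ValueError("classification labels must be binary {0,1}")


@dataclass
class MetricsReport:
    auroc: float | None = None
    auprc: float | None = None
    accuracy: float | None = None
    rmse: float | None = None
    mae: float | None = None
    pearson_r: float | None = None
    spearman_r: float | None = None


@dataclass
class FinetuneConfig:
    epochs: int = 30
    batch_size: int = 128
    learning_rate: float = 1e-3
    head_hidden: int = 128
    patience: int = 10
    freeze_encoder: bool = False  # linear-probe mode
    seed: int = 0


@dataclass
class FinetuneResult:
    encoder: EncoderState
    head_params: dict[str, Tensor]
    metrics: dict[str, MetricsReport]  # per split
    log: list[dict] = field(default_factory=list)


# -- scaffold split -----------------------------------------------------------

def murcko_scaffold(mol: Molecule) -> str:
    try:
        return MurckoScaffold.MurckoScaffoldSmiles(mol.smiles)
    except Exception:
        return ""


def scaffold_split(molecules: list[Molecule],
                   fractions: tuple[float, float, float] = (0.8, 0.1, 0.1),
                   seed: int = 0) -> tuple[list[int], list[int], list[int]]:
    """Group molecules by Bemis-Murcko scaffold and assign groups greedily.

    Groups are taken largest-first; each goes to the split whose fill ratio
    (current size / target size) is smallest, ties resolved train < valid <
    test.  No scaffold ever straddles splits.  The seed shuffles the order
    of equal-sized groups.
    """
    if abs(sum(fractions) - 1.0) > 1e-9:
        raise ValueError("fractions must sum to 1")
    if len(molecules) < 3:
        raise ValueError("dataset too small to split (need >= 3 molecules)")
    groups: dict[str, list[int]] = {}
    for i, m in enumerate(molecules):
        groups.setdefault(murcko_scaffold(m), []).append(i)
    rng = np.random.default_rng(seed)
    keys = list(groups)
    rng.shuffle(keys)
    keys.sort(key=lambda k: -len(groups[k]))  # stable: seed only breaks ties
    n = len(molecules)
    targets = [max(f * n, 1e-12) for f in fractions]
    splits: tuple[list[int], list[int], list[int]] = ([], [], [])
    for key in keys:
        ratios = [len(s) / t for s, t in zip(splits, targets)]
        dest = int(np.argmin(ratios))
        splits[dest].extend(groups[key])
    if not splits[1] or not splits[2]:
        warnings.warn("scaffold split produced an empty valid/test split "
                      "(too few scaffold groups)", stacklevel=2)
    return splits


def random_split(molecules: list[Molecule],
                 fractions: tuple[float, float, float] = (0.8, 0.1, 0.1),
                 seed: int = 0) -> tuple[list[int], list[int], list[int]]:
    rng = np.random.default_rng(seed)
    order = rng.permutation(len(molecules))
    n = len(molecules)
    n_train = int(round(fractions[0] * n))
    n_valid = int(round(fractions[1] * n))
    return (list(order[:n_train]), list(order[n_train:n_train + n_valid]),
            list(order[n_train + n_valid:]))


# -- metrics ------------------------------------------------------------------

def compute_metrics(y_true: np.ndarray, y_score: np.ndarray,
                    task_type: str) -> MetricsReport:
    """Standard evaluation metrics for a prediction vector.

    Classification: AUROC, AUPRC, accuracy (scores thresholded at 0.5).
    Regression: RMSE, MAE, Pearson and Spearman correlations.
    """
    y_true = np.asarray(y_true, dtype=float).reshape(-1)
    y_score = np.asarray(y_score, dtype=float).reshape(-1)
    if y_true.shape != y_score.shape or y_true.size < 2:
        raise ValueError("need equal-length arrays with at least 2 entries")
    if task_type == "classification":
        if len(np.unique(y_true)) < 2:
            raise ValueError("single-class y_true: AUROC undefined")
        return MetricsReport(
            auroc=float(roc_auc_score(y_true, y_score)),
            auprc=float(average_precision_score(y_true, y_score)),
            accuracy=float(accuracy_score(y_true, (y_score >= 0.5).astype(int))),
        )
    if task_type == "regression":
        pr = sr = None
        if np.std(y_true) > 0 and np.std(y_score) > 0:
            pr = float(pearsonr(y_true, y_score)[0])
            sr = float(spearmanr(y_true, y_score)[0])
        return MetricsReport(
            rmse=float(np.sqrt(mean_squared_error(y_true, y_score))),
            mae=float(mean_absolute_error(y_true, y_score)),
            pearson_r=pr, spearman_r=sr,
        )
    raise ValueError(f"unknown task type {task_type!r}")


# -- fine-tuning --------------------------------------------------------------

def _init_head(graph_dim: int, hidden: int, seed: int) -> dict[str, Tensor]:
    rng = np.random.default_rng(seed)
    return {
        "head_w1": ad.param(None, rng, shape=(graph_dim, hidden)),
        "head_b1": ad.param(np.zeros(hidden)),
        "head_w2": ad.param(None, rng, scale=np.sqrt(1.0 / hidden),
                            shape=(hidden, 1)),
        "head_b2": ad.param(np.zeros(1)),
    }


def _head_forward(rep: Tensor, head: dict[str, Tensor]) -> Tensor:
    hidden = ad.relu(ad.linear(rep, head["head_w1"], head["head_b1"]))
    return ad.linear(hidden, head["head_w2"], head["head_b2"])


def _predict(encoder: EncoderState, head: dict[str, Tensor],
             graphs, task_type: str, batch_size: int = 256) -> np.ndarray:
    out = []
    for i in range(0, len(graphs), batch_size):
        rep, _ = forward_batch(encoder, batch_graphs(graphs[i:i + batch_size]))
        scores = _head_forward(rep, head).data.reshape(-1)
        out.append(scores)
    scores = np.concatenate(out)
    if task_type == "classification":
        scores = 1.0 / (1.0 + np.exp(-scores))
    return scores


def finetune(encoder: EncoderState, dataset: PropertyDataset,
             config: FinetuneConfig | None = None) -> FinetuneResult:
    """Train a task head (and, unless frozen, the encoder) on a property table.

    The dataset must carry (train, valid, test) splits; metrics are reported
    per split, the headline numbers being those of the held-out test split
    at the early-stopping checkpoint.
    """
    config = config or FinetuneConfig()
    if dataset.splits is None:
        raise ValueError("dataset has no splits; call scaffold_split/random_split")
    train_idx, valid_idx, test_idx = dataset.splits
    if not train_idx or not test_idx:
        raise ValueError("empty train or test split")
    if dataset.task_type == "classification":
        if len(np.unique(dataset.labels[train_idx])) < 2:
            raise ValueError("single-class training labels")

    model = clone_state(encoder)
    head = _init_head(model.config.graph_dim, config.head_hidden, config.seed)
    trainable = dict(head)
    if not config.freeze_encoder:
        trainable.update(model.params)
    opt = Adam(trainable, lr=config.learning_rate)
    rng = np.random.default_rng(config.seed)
    graphs = [m.graph for m in dataset.molecules]
    y = dataset.labels

    def valid_score() -> float | None:
        """Higher-is-better validation score, or None without a valid split."""
        if not valid_idx:
            return None
        scores = _predict(model, head, [graphs[i] for i in valid_idx],
                          dataset.task_type)
        if dataset.task_type == "classification":
            if len(np.unique(y[valid_idx])) < 2:
                return None
            return float(roc_auc_score(y[valid_idx], scores))
        return -float(np.sqrt(mean_squared_error(y[valid_idx], scores)))

    best = (-np.inf, None, None)  # (score, encoder params, head params)
    patience_left = config.patience
    log = []
    for epoch in range(config.epochs):
        order = rng.permutation(len(train_idx))
        losses = []
        for start in range(0, len(order), config.batch_size):
            idx = [train_idx[i] for i in order[start:start + config.batch_size]]
            rep, _ = forward_batch(model, batch_graphs([graphs[i] for i in idx]))
            logits = _head_forward(rep, head)
            if dataset.task_type == "classification":
                loss = ad.bce_with_logits_mean(logits, y[idx])
            else:
                loss = ad.mse_mean(logits, y[idx].reshape(-1, 1))
            if not np.isfinite(loss.data):
                raise FloatingPointError(f"non-finite loss at epoch {epoch}")
            opt.zero_grad()
            loss.backward()
            opt.step()
            losses.append(float(loss.data))
        score = valid_score()
        log.append({"epoch": epoch, "train_loss": float(np.mean(losses)),
                    "valid_score": score})
        if score is not None:
            if score > best[0]:
                best = (score,
                        {k: v.data.copy() for k, v in model.params.items()},
                        {k: v.data.copy() for k, v in head.items()})
                patience_left = config.patience
            else:
                patience_left -= 1
                if patience_left <= 0:
                    logger.info("early stop at epoch %d", epoch)
                    break

    if best[1] is not None:
        for k, v in model.params.items():
            v.data = best[1][k]
        for k, v in head.items():
            v.data = best[2][k]

    metrics: dict[str, MetricsReport] = {}
    for name, idx in (("train", train_idx), ("valid", valid_idx),
                      ("test", test_idx)):
        if not idx:
            continue
        scores = _predict(model, head, [graphs[i] for i in idx],
                          dataset.task_type)
        try:
            metrics[name] = compute_metrics(y[idx], scores, dataset.task_type)
        except ValueError as exc:
            logger.warning("metrics for %s split unavailable: %s", name, exc)
    return FinetuneResult(model, head, metrics, log)
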