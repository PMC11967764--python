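"""Latent-space investigation of a trained molecular encoder.

Three procedures probe what the latent geometry encodes:

* kNN classification of held-out molecules from their latent vectors
  (cosine distance, majority vote);
* a similarity profile: references ranked by cosine distance to a query are
  cut into 10 percentile bins and each bin's mean fingerprint Tanimoto
  similarity to the query is computed — an informative embedding shows the
  mean falling with bin index;
* nearest-neighbour descriptor correlation: the Spearman correlation, per
  physicochemical descriptor, between each molecule's value and that of its
  latent-space nearest neighbour.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass

import numpy as np
from scipy.stats import spearmanr
from sklearn.metrics import pairwise_distances

from .chem_io import DESCRIPTOR_NAMES, DescriptorVector, Molecule, tanimoto
from .finetune import MetricsReport, compute_metrics

N_BINS = 10
MAX_PER_BIN = 1000


@dataclass
class EmbeddingTable:
    ids: list[str]
    vectors: np.ndarray
    labels: np.ndarray | None = None

    def __post_init__(self):
        self.vectors = np.asarray(self.vectors, dtype=float)
        if self.vectors.ndim != 2:
            raise ValueError("vectors must be a 2-D array")
        if len(self.ids) != self.vectors.shape[0]:
            raise ValueError("one id per vector required")
        if len(set(self.ids)) != len(self.ids):
            raise ValueError("ids must be unique")
        if self.labels is not None:
            self.labels = np.asarray(self.labels)
            if len(self.labels) != len(self.ids):
                raise ValueError("one label per vector required")


@dataclass
class SimilarityProfile:
    bin_mean_tanimoto: np.ndarray   # length 10, NaN for empty bins
    bin_sd_tanimoto: np.ndarray
    bin_counts: np.ndarray


def _cosine_distances(a: np.ndarray, b: np.ndarray) -> np.ndarray:
    return pairwise_distances(a, b, metric="cosine")


def knn_classify(train: EmbeddingTable, test: EmbeddingTable,
                 k: int) -> tuple[np.ndarray, np.ndarray, MetricsReport | None]:
    """Majority vote among the k cosine-nearest training vectors.

    Returns (predictions, positive-vote fractions, metrics); metrics are
    reported when the test table carries binary labels.
    """
    if train.labels is None:
        raise ValueError("training table has no labels")
    if len(train.ids) == 0:
        raise ValueError("empty training table")
    if not 1 <= k <= len(train.ids):
        raise ValueError(f"k={k} outside [1, {len(train.ids)}]")
    dist = _cosine_distances(test.vectors, train.vectors)
    nn = np.argsort(dist, axis=1, kind="stable")[:, :k]
    votes = np.asarray(train.labels, dtype=float)[nn]
    scores = votes.mean(axis=1)
    preds = (scores >= 0.5).astype(int)
    report = None
    if test.labels is not None and len(np.unique(test.labels)) >= 2:
        report = compute_metrics(test.labels.astype(float), scores,
                                 "classification")
    return preds, scores, report


def similarity_profile(query: Molecule, references: list[Molecule],
                       embedder, fingerprinter, seed: int = 0,
                       n_bins: int = N_BINS,
                       max_per_bin: int = MAX_PER_BIN) -> SimilarityProfile:
    """Tanimoto similarity to the query, profiled over latent-distance bins.

    ``embedder`` maps a list of molecules to latent row vectors;
    ``fingerprinter`` maps one molecule to a binary fingerprint.  References
    are ranked by cosine distance to the query's latent (ties broken by
    input order), cut into ``n_bins`` percentile bins, and up to
    ``max_per_bin`` members per bin are sampled (seeded) for the Tanimoto
    computation.
    """
    n = len(references)
    if n < n_bins:
        raise ValueError(f"need at least {n_bins} references, got {n}")
    latents = np.asarray(embedder([query] + list(references)), dtype=float)
    q, ref = latents[:1], latents[1:]
    dist = _cosine_distances(q, ref)[0]
    if np.allclose(dist, dist[0]):
        warnings.warn("all reference distances are equal; bins are arbitrary",
                      stacklevel=2)
    order = np.argsort(dist, kind="stable")
    q_fp = fingerprinter(query)
    rng = np.random.default_rng(seed)
    means = np.full(n_bins, np.nan)
    sds = np.full(n_bins, np.nan)
    counts = np.zeros(n_bins, dtype=int)
    for b in range(n_bins):
        lo = math.ceil(b * n / n_bins)
        hi = math.ceil((b + 1) * n / n_bins)
        members = order[lo:hi]
        if members.size == 0:
            continue
        if members.size > max_per_bin:
            members = rng.choice(members, size=max_per_bin, replace=False)
        sims = [tanimoto(q_fp, fingerprinter(references[i])) for i in members]
        means[b] = float(np.mean(sims))
        sds[b] = float(np.std(sims))
        counts[b] = len(sims)
    return SimilarityProfile(means, sds, counts)


def profile_trend_spearman(profile: SimilarityProfile) -> float:
    """Spearman correlation between bin index and mean Tanimoto similarity.

    Negative values mean fingerprint similarity falls as latent distance
    grows — the signature of a structure-aware embedding.
    """
    ok = ~np.isnan(profile.bin_mean_tanimoto)
    idx = np.arange(len(profile.bin_mean_tanimoto))[ok]
    vals = profile.bin_mean_tanimoto[ok]
    if len(vals) < 2 or np.std(vals) == 0:
        return 0.0
    return float(spearmanr(idx, vals)[0])


def neighbor_descriptor_correlation(
        table: EmbeddingTable,
        descriptors: list[DescriptorVector]) -> dict[str, float | None]:
    """Per-descriptor Spearman r between molecules and their latent nearest
    neighbour (self excluded).  Constant or undefined descriptors come back
    as None."""
    n = len(table.ids)
    if n < 3:
        raise ValueError("need at least 3 molecules")
    if len(descriptors) != n:
        raise ValueError("one descriptor vector per molecule required")
    dist = _cosine_distances(table.vectors, table.vectors)
    np.fill_diagonal(dist, np.inf)
    nn = np.argmin(dist, axis=1)
    mat = np.asarray([d.as_array() for d in descriptors], dtype=float)
    out: dict[str, float | None] = {}
    for j, name in enumerate(DESCRIPTOR_NAMES):
        x = mat[:, j]
        y = mat[nn, j]
        ok = np.isfinite(x) & np.isfinite(y)
        if ok.sum() < 3 or np.std(x[ok]) == 0 or np.std(y[ok]) == 0:
            out[name] = None
            continue
        out[name] = float(spearmanr(x[ok], y[ok])[0])
    return out


# -- columnar embedding I/O ---------------------------------------------------

def write_embeddings(path: str, table: EmbeddingTable) -> None:
    dim = table.vectors.shape[1]
    with open(path, "w") as fh:
        fh.write("id\t" + "\t".join(f"z{i}" for i in range(dim)) + "\n")
        for mid, vec in zip(table.ids, table.vectors):
            fh.write(mid + "\t" + "\t".join(f"{v:.6g}" for v in vec) + "\n")


def read_embeddings(path: str) -> EmbeddingTable:
    ids: list[str] = []
    rows: list[list[float]] = []
    with open(path) as fh:
        next(fh)  # header
        for line in fh:
            parts = line.rstrip("\n").split("\t")
            ids.append(parts[0])
            rows.append([float(v) for v in parts[1:]])
    return EmbeddingTable(ids, np.asarray(rows))
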