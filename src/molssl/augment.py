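"""Self-supervision data augmentation: fingerprint pseudo-labels and graph masks.

Two operators drive the pretraining objectives:

* multi-granularity k-means on MACCS fingerprints, whose cluster indices at
  each granularity K become per-molecule pseudo-labels (defaults
  K = 100, 1000, 10000, coarse to fine);
* a connected-region mask that grows breadth-first from a random start atom
  until a fixed fraction of atoms is masked, removing every bond whose two
  endpoints are both masked.
"""

from __future__ import annotations

import json
import math
from dataclasses import dataclass, field

import numpy as np
from scipy.spatial.distance import cdist
from sklearn.cluster import KMeans

from .chem_io import (AtomFeature, BondFeature, FINGERPRINT_LENGTH,
                      MASK_ATOM_CODE, MolecularGraph)

DEFAULT_GRANULARITIES = (100, 1000, 10000)
DEFAULT_MASK_RATIO = 0.25


@dataclass
class PseudoLabelSet:
    labels: tuple[int, ...]
    granularities: tuple[int, ...]

    def __post_init__(self):
        if len(self.labels) != len(self.granularities):
            raise ValueError("labels and granularities must have equal arity")
        for lab, k in zip(self.labels, self.granularities):
            if not 0 <= lab < k:
                raise ValueError(f"label {lab} out of range for K={k}")


@dataclass
class ClusteringModel:
    granularities: tuple[int, ...]
    centroids: list[np.ndarray]  # one (K, 166) array per granularity
    seed: int

    def __post_init__(self):
        for k, c in zip(self.granularities, self.centroids, strict=True):
            if c.shape != (k, FINGERPRINT_LENGTH):
                raise ValueError(f"centroid block for K={k} has shape {c.shape}")

    def save(self, path: str) -> None:
        payload = {
            "format_version": 1,
            "granularities": list(self.granularities),
            "seed": self.seed,
            "centroids": [c.tolist() for c in self.centroids],
        }
        with open(path, "w") as fh:
            json.dump(payload, fh)

    @classmethod
    def load(cls, path: str) -> "ClusteringModel":
        with open(path) as fh:
            payload = json.load(fh)
        return cls(
            granularities=tuple(payload["granularities"]),
            centroids=[np.asarray(c, dtype=float) for c in payload["centroids"]],
            seed=int(payload["seed"]),
        )


def fit_pseudo_labeler(corpus_fingerprints: list[np.ndarray] | np.ndarray,
                       granularities: tuple[int, ...] = DEFAULT_GRANULARITIES,
                       seed: int = 0) -> ClusteringModel:
    """Fit one k-means model per granularity on the binary fingerprint matrix.

    Fingerprints are treated as real vectors under Euclidean distance
    (k-means++ initialization, 10 restarts, 300-iteration cap); the runs at
    different K are independent.
    """
    X = np.asarray(corpus_fingerprints, dtype=float)
    if X.ndim != 2 or X.shape[1] != FINGERPRINT_LENGTH:
        raise ValueError(f"expected (N, {FINGERPRINT_LENGTH}) fingerprints, got {X.shape}")
    n = X.shape[0]
    centroids = []
    for k in granularities:
        if k < 2:
            raise ValueError(f"granularity K={k} must be >= 2")
        if k > n:
            raise ValueError(f"granularity K={k} exceeds corpus size N={n}")
        km = KMeans(n_clusters=k, init="k-means++", n_init=10, max_iter=300,
                    random_state=seed % (2 ** 31))
        km.fit(X)
        centroids.append(km.cluster_centers_.astype(float))
    return ClusteringModel(tuple(granularities), centroids, seed)


def assign_pseudo_labels(model: ClusteringModel,
                         fp: np.ndarray) -> PseudoLabelSet:
    """Nearest-centroid label at every granularity; ties go to the lowest index."""
    fp = np.asarray(fp, dtype=float).reshape(1, -1)
    if fp.shape[1] != FINGERPRINT_LENGTH:
        raise ValueError(f"fingerprint dimension {fp.shape[1]} != {FINGERPRINT_LENGTH}")
    labels = tuple(int(np.argmin(cdist(fp, c, metric="euclidean")))
                   for c in model.centroids)
    return PseudoLabelSet(labels, model.granularities)


def assign_pseudo_labels_batch(model: ClusteringModel,
                               fps: np.ndarray) -> np.ndarray:
    """Vectorized assignment: returns an (N, n_granularities) int array."""
    X = np.asarray(fps, dtype=float)
    out = np.empty((X.shape[0], len(model.granularities)), dtype=int)
    for j, c in enumerate(model.centroids):
        out[:, j] = np.argmin(cdist(X, c, metric="euclidean"), axis=1)
    return out


# -- graph mask ---------------------------------------------------------------

@dataclass
class MaskedGraph:
    base: MolecularGraph
    masked_nodes: frozenset[int]
    removed_edges: frozenset[tuple[int, int]]
    ratio: float
    seed: int


def mask_graph(graph: MolecularGraph, ratio: float, seed: int) -> MaskedGraph:
    """Mask a connected region covering ceil(ratio * n_atoms) atoms.

    Expansion is breadth-first from one seeded start atom, visiting
    neighbours in ascending node index; if the frontier empties before the
    quota is met (disconnected molecule), a fresh unmasked start atom is
    drawn.  Bonds with both endpoints masked are recorded as removed.
    """
    if not 0.0 <= ratio <= 1.0:
        raise ValueError(f"mask ratio {ratio} outside [0, 1]")
    n = graph.n_atoms
    quota = math.ceil(ratio * n)
    masked: set[int] = set()
    if quota > 0:
        rng = np.random.default_rng(seed)
        frontier: list[int] = []
        while len(masked) < quota:
            if not frontier:
                unmasked = [v for v in range(n) if v not in masked]
                start = int(unmasked[rng.integers(len(unmasked))])
                masked.add(start)
                frontier.append(start)
                if len(masked) >= quota:
                    break
                continue
            v = frontier.pop(0)
            for u in graph.adjacency[v]:  # ascending index order
                if u not in masked:
                    masked.add(u)
                    frontier.append(u)
                    if len(masked) >= quota:
                        break
    removed = frozenset((u, v) for u, v, _ in graph.edges
                        if u in masked and v in masked)
    return MaskedGraph(graph, frozenset(masked), removed, ratio, seed)


def apply_mask_for_encoding(mg: MaskedGraph) -> MolecularGraph:
    """Realize a masked graph as encoder input.

    Masked atoms keep their place but their features are replaced by the
    reserved mask token (an atomic-number code outside the chemical
    vocabulary, chirality reset to unspecified); bonds internal to the
    masked region are deleted while boundary bonds (one masked endpoint)
    are retained.
    """
    nodes = [AtomFeature(MASK_ATOM_CODE, 0) if i in mg.masked_nodes else a
             for i, a in enumerate(mg.base.nodes)]
    edges = [(u, v, f) for u, v, f in mg.base.edges
             if (u, v) not in mg.removed_edges]
    return MolecularGraph(nodes, edges)
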