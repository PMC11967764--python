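"""Pseudo-label clustering and the connected-region graph mask."""

import itertools
import math

import numpy as np
import pytest

import molssl as M
from molssl.augment import (DEFAULT_GRANULARITIES, ClusteringModel,
                            assign_pseudo_labels_batch)
from molssl.chem_io import FINGERPRINT_LENGTH, MASK_ATOM_CODE


def _blob_fingerprints():
    """Two well-separated fingerprint blobs of 6 points each."""
    rng = np.random.default_rng(5)
    base_a = np.zeros(FINGERPRINT_LENGTH)
    base_a[:30] = 1
    base_b = np.zeros(FINGERPRINT_LENGTH)
    base_b[80:110] = 1
    pts = []
    for base in (base_a, base_b):
        for _ in range(6):
            x = base.copy()
            flip = rng.integers(0, FINGERPRINT_LENGTH, size=2)
            x[flip] = 1 - x[flip]
            pts.append(x)
    return np.array(pts), np.repeat([0, 1], 6)


def _brute_force_two_partition(X):
    """Exhaustive optimal 2-means partition by total within-cluster SSE."""
    n = len(X)
    best, best_sse = None, np.inf
    for r in range(1, n // 2 + 1):
        for subset in itertools.combinations(range(n), r):
            mask = np.zeros(n, dtype=bool)
            mask[list(subset)] = True
            sse = 0.0
            for side in (mask, ~mask):
                c = X[side].mean(axis=0)
                sse += np.sum((X[side] - c) ** 2)
            if sse < best_sse:
                best_sse, best = sse, mask.copy()
    return best


def test_two_blobs_recovered_and_match_exhaustive_optimum():
    X, truth = _blob_fingerprints()
    model = M.fit_pseudo_labeler(X, granularities=(2,), seed=0)
    labels = assign_pseudo_labels_batch(model, X)[:, 0]
    # blobs are internally consistent and separated
    assert len(set(labels[:6])) == 1 and len(set(labels[6:])) == 1
    assert labels[0] != labels[6]
    # and the fitted partition is the exhaustive-search optimum
    best = _brute_force_two_partition(X)
    assert (np.array_equal(best, labels == labels[0])
            or np.array_equal(~best, labels == labels[0]))


def test_duplicate_fingerprints_share_labels(small_fingerprints):
    X = np.vstack([small_fingerprints, small_fingerprints[:5]])
    model = M.fit_pseudo_labeler(X, granularities=(3, 6), seed=2)
    lab = assign_pseudo_labels_batch(model, X)
    np.testing.assert_array_equal(lab[:5], lab[-5:])


def test_default_granularities_and_arity():
    assert DEFAULT_GRANULARITIES == (100, 1000, 10000)
    rng = np.random.default_rng(0)
    model = ClusteringModel(
        granularities=DEFAULT_GRANULARITIES,
        centroids=[rng.random((k, FINGERPRINT_LENGTH))
                   for k in DEFAULT_GRANULARITIES],
        seed=0)
    pls = M.assign_pseudo_labels(model, rng.random(FINGERPRINT_LENGTH))
    assert len(pls.labels) == 3
    for lab, k in zip(pls.labels, pls.granularities):
        assert 0 <= lab < k


def test_fit_errors(small_fingerprints):
    with pytest.raises(ValueError, match="K=1000"):
        M.fit_pseudo_labeler(small_fingerprints, granularities=(2, 1000))
    with pytest.raises(ValueError, match="K=1"):
        M.fit_pseudo_labeler(small_fingerprints, granularities=(1,))


def test_assign_exact_centroid_and_tie_break():
    c0 = np.zeros(FINGERPRINT_LENGTH)
    c1 = np.zeros(FINGERPRINT_LENGTH)
    c1[0] = 1.0
    model = ClusteringModel((2,), [np.vstack([c0, c1])], seed=0)
    assert M.assign_pseudo_labels(model, c1).labels == (1,)
    midpoint = np.zeros(FINGERPRINT_LENGTH)
    midpoint[0] = 0.5  # equidistant to both centroids
    assert M.assign_pseudo_labels(model, midpoint).labels == (0,)


def test_pseudo_labeler_deterministic(small_fingerprints):
    m1 = M.fit_pseudo_labeler(small_fingerprints, (4, 8), seed=9)
    m2 = M.fit_pseudo_labeler(small_fingerprints, (4, 8), seed=9)
    l1 = assign_pseudo_labels_batch(m1, small_fingerprints)
    l2 = assign_pseudo_labels_batch(m2, small_fingerprints)
    np.testing.assert_array_equal(l1, l2)


def test_clustering_model_serialization(tmp_path, small_fingerprints):
    model = M.fit_pseudo_labeler(small_fingerprints, (3,), seed=1)
    path = tmp_path / "labeler.json"
    model.save(str(path))
    loaded = M.ClusteringModel.load(str(path))
    assert loaded.granularities == model.granularities
    np.testing.assert_allclose(loaded.centroids[0], model.centroids[0])


# -- graph mask ---------------------------------------------------------------

def _path_graph(n):
    return M.parse_smiles("C" * n).graph


def test_mask_ratio_zero_is_identity():
    g = _path_graph(6)
    mg = M.mask_graph(g, 0.0, seed=1)
    assert mg.masked_nodes == frozenset()
    assert mg.removed_edges == frozenset()
    out = M.apply_mask_for_encoding(mg)
    assert [a.atomic_number for a in out.nodes] == [a.atomic_number for a in g.nodes]
    assert out.edge_pairs() == g.edge_pairs()


def test_mask_ratio_one_masks_everything():
    g = M.parse_smiles("C1CC1").graph
    mg = M.mask_graph(g, 1.0, seed=3)
    assert mg.masked_nodes == frozenset({0, 1, 2})
    assert mg.removed_edges == g.edge_pairs()  # all 3 ring bonds removed
    out = M.apply_mask_for_encoding(mg)
    assert all(a.atomic_number == MASK_ATOM_CODE for a in out.nodes)
    assert out.n_edges == 0


def test_mask_path_contiguous_segment():
    g = _path_graph(10)
    mg = M.mask_graph(g, 0.3, seed=7)
    assert len(mg.masked_nodes) == 3
    nodes = sorted(mg.masked_nodes)
    assert nodes[-1] - nodes[0] == 2  # consecutive on the path
    out = M.apply_mask_for_encoding(mg)
    interior = {(u, v) for u, v in g.edge_pairs()
                if u in mg.masked_nodes and v in mg.masked_nodes}
    assert len(interior) == 2  # 3 contiguous path atoms span 2 bonds
    assert out.edge_pairs() == g.edge_pairs() - interior


def _masked_is_connected(graph, masked):
    if not masked:
        return True
    masked = set(masked)
    seen = {next(iter(masked))}
    frontier = list(seen)
    while frontier:
        v = frontier.pop()
        for u in graph.adjacency[v]:
            if u in masked and u not in seen:
                seen.add(u)
                frontier.append(u)
    return seen == masked


def test_mask_accounting_and_connectivity(small_corpus):
    """Quota is exactly ceil(ratio * n_atoms) and, for connected molecules,
    the masked region is a connected induced subgraph."""
    corpus, _ = small_corpus
    rng = np.random.default_rng(0)
    for _ in range(300):
        g = corpus[int(rng.integers(len(corpus)))].graph
        ratio = float(rng.random())
        mg = M.mask_graph(g, ratio, seed=int(rng.integers(2 ** 31)))
        assert len(mg.masked_nodes) == math.ceil(ratio * g.n_atoms)
        assert all((u, v) in g.edge_pairs() for u, v in mg.removed_edges)
        assert all(u in mg.masked_nodes and v in mg.masked_nodes
                   for u, v in mg.removed_edges)
        assert _masked_is_connected(g, mg.masked_nodes)


def test_mask_deterministic_for_seed():
    g = _path_graph(12)
    a = M.mask_graph(g, 0.4, seed=123)
    b = M.mask_graph(g, 0.4, seed=123)
    assert a.masked_nodes == b.masked_nodes
    assert a.removed_edges == b.removed_edges


def test_mask_invalid_ratio():
    with pytest.raises(ValueError):
        M.mask_graph(_path_graph(4), 1.5, seed=0)
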