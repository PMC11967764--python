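"""GIN molecular encoder: embeddings, message passing, readout, projection.

Atoms are embedded from (atomic number, chirality), bonds from
(type, direction).  Each of the K message-passing rounds performs

    a_v = sum_{u in N(v)} (h_u + e_{uv})          # AGGREGATE
    h_v = MLP_k((1 + eps) * h_v + a_v),  eps = 0  # COMBINE

with per-layer 2-layer ReLU MLPs; the bond embedding e_{uv} is layer-specific
and enters the neighbour sum additively.  The graph representation h_G is the
mean over final node states (READOUT), and a one-hidden-layer projection MLP
maps h_G to the latent space used by the pretraining losses and the latent
analyses.  There are no stochastic layers, so encoding is deterministic.

Defaults follow the reference architecture: 5 layers, 512-D graph
representation, 256-D latent.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, replace

import numpy as np

from . import autodiff as ad
from .autodiff import Tensor
from .chem_io import (N_ATOM_CODES, N_BOND_DIRS, N_BOND_TYPES, N_CHIRALITY,
                      MolecularGraph)


@dataclass(frozen=True)
class EncoderConfig:
    n_layers: int = 5
    hidden_dim: int = 300
    graph_dim: int = 512
    latent_dim: int = 256
    seed: int = 0

    def __post_init__(self):
        if self.n_layers < 1:
            raise ValueError("n_layers must be >= 1")
        for name in ("hidden_dim", "graph_dim", "latent_dim"):
            if getattr(self, name) < 1:
                raise ValueError(f"{name} must be >= 1")

    def layer_dims(self) -> list[tuple[int, int]]:
        """(in, out) dimension of each message-passing layer; the final layer
        widens to graph_dim so the readout has the configured width."""
        dims = []
        for k in range(self.n_layers):
            d_in = self.hidden_dim
            d_out = self.graph_dim if k == self.n_layers - 1 else self.hidden_dim
            dims.append((d_in, d_out))
        return dims


@dataclass
class EncoderState:
    config: EncoderConfig
    params: dict[str, Tensor]


@dataclass
class LayerState:
    node_states: np.ndarray   # h_v^(k), one row per node
    aggregates: np.ndarray    # a_v^(k)
    layer_index: int


@dataclass
class GraphEmbedding:
    representation: np.ndarray  # h_G, length graph_dim
    latent: np.ndarray          # projection output, length latent_dim


def init_encoder(config: EncoderConfig) -> EncoderState:
    """Seeded initialization; embedding tables cover the atom/bond
    vocabularies plus the reserved mask token."""
    rng = np.random.default_rng(config.seed)
    p: dict[str, Tensor] = {}
    d = config.hidden_dim
    p["atom_z_emb"] = ad.param(None, rng, scale=0.1, shape=(N_ATOM_CODES, d))
    p["atom_chir_emb"] = ad.param(None, rng, scale=0.1, shape=(N_CHIRALITY, d))
    for k, (d_in, d_out) in enumerate(config.layer_dims()):
        p[f"bond_type_emb_{k}"] = ad.param(None, rng, scale=0.1,
                                           shape=(N_BOND_TYPES, d_in))
        p[f"bond_dir_emb_{k}"] = ad.param(None, rng, scale=0.1,
                                          shape=(N_BOND_DIRS, d_in))
        p[f"mlp_{k}_w1"] = ad.param(None, rng, shape=(d_in, 2 * d_in))
        p[f"mlp_{k}_b1"] = ad.param(np.zeros(2 * d_in))
        p[f"mlp_{k}_w2"] = ad.param(None, rng, shape=(2 * d_in, d_out))
        p[f"mlp_{k}_b2"] = ad.param(np.zeros(d_out))
    g, z = config.graph_dim, config.latent_dim
    p["proj_w1"] = ad.param(None, rng, shape=(g, g))
    p["proj_b1"] = ad.param(np.zeros(g))
    p["proj_w2"] = ad.param(None, rng, shape=(g, z))
    p["proj_b2"] = ad.param(np.zeros(z))
    return EncoderState(config, p)


# -- graph batching -----------------------------------------------------------

@dataclass
class GraphBatch:
    """Concatenated node/edge arrays for a list of graphs.

    Edges are expanded to both directions so the neighbour sum sees every
    incident bond once per endpoint.
    """

    atom_z: np.ndarray
    atom_chir: np.ndarray
    edge_src: np.ndarray
    edge_dst: np.ndarray
    bond_type: np.ndarray
    bond_dir: np.ndarray
    node_graph: np.ndarray
    n_graphs: int
    n_nodes: int


def batch_graphs(graphs: list[MolecularGraph]) -> GraphBatch:
    if not graphs:
        raise ValueError("empty graph batch")
    atom_z, atom_chir, node_graph = [], [], []
    src, dst, btype, bdir = [], [], [], []
    offset = 0
    for gi, g in enumerate(graphs):
        for a in g.nodes:
            atom_z.append(a.atomic_number)
            atom_chir.append(a.chirality)
            node_graph.append(gi)
        for u, v, f in g.edges:
            src.extend((offset + u, offset + v))
            dst.extend((offset + v, offset + u))
            btype.extend((f.bond_type, f.bond_type))
            bdir.extend((f.direction, f.direction))
        offset += g.n_atoms
    return GraphBatch(
        atom_z=np.asarray(atom_z, dtype=np.intp),
        atom_chir=np.asarray(atom_chir, dtype=np.intp),
        edge_src=np.asarray(src, dtype=np.intp),
        edge_dst=np.asarray(dst, dtype=np.intp),
        bond_type=np.asarray(btype, dtype=np.intp),
        bond_dir=np.asarray(bdir, dtype=np.intp),
        node_graph=np.asarray(node_graph, dtype=np.intp),
        n_graphs=len(graphs),
        n_nodes=offset,
    )


def _layer_forward(state: EncoderState, batch: GraphBatch, h: Tensor,
                   k: int, last: bool) -> tuple[Tensor, Tensor]:
    """One AGGREGATE/COMBINE round; returns (aggregates, new node states)."""
    p = state.params
    if batch.edge_src.size > 0:
        msg = ad.add(ad.gather(h, batch.edge_src),
                     ad.add(ad.gather(p[f"bond_type_emb_{k}"], batch.bond_type),
                            ad.gather(p[f"bond_dir_emb_{k}"], batch.bond_dir)))
        agg = ad.segment_sum(msg, batch.edge_dst, batch.n_nodes)
    else:
        agg = ad.constant(np.zeros_like(h.data))
    pre = ad.add(h, agg)  # (1 + eps) h + a with eps = 0
    hidden = ad.relu(ad.linear(pre, p[f"mlp_{k}_w1"], p[f"mlp_{k}_b1"]))
    out = ad.linear(hidden, p[f"mlp_{k}_w2"], p[f"mlp_{k}_b2"])
    if not last:
        out = ad.relu(out)
    return agg, out


def forward_batch(state: EncoderState, batch: GraphBatch) -> tuple[Tensor, Tensor]:
    """Differentiable forward pass; returns (h_G tensor, latent tensor)."""
    p = state.params
    h = ad.add(ad.gather(p["atom_z_emb"], batch.atom_z),
               ad.gather(p["atom_chir_emb"], batch.atom_chir))
    n_layers = state.config.n_layers
    for k in range(n_layers):
        _, h = _layer_forward(state, batch, h, k, last=(k == n_layers - 1))
    h_g = ad.segment_mean(h, batch.node_graph, batch.n_graphs)
    hidden = ad.relu(ad.linear(h_g, p["proj_w1"], p["proj_b1"]))
    latent = ad.linear(hidden, p["proj_w2"], p["proj_b2"])
    return h_g, latent


def message_passing_step(state: EncoderState, graph: MolecularGraph,
                         node_states: np.ndarray, k: int) -> LayerState:
    """Run round ``k`` on explicit node states (inspection/testing surface)."""
    batch = batch_graphs([graph])
    h = ad.constant(np.asarray(node_states, dtype=float))
    agg, out = _layer_forward(state, batch, h, k,
                              last=(k == state.config.n_layers - 1))
    return LayerState(node_states=out.data.copy(),
                      aggregates=agg.data.copy(), layer_index=k)


def encode(state: EncoderState, graph: MolecularGraph) -> GraphEmbedding:
    h_g, latent = forward_batch(state, batch_graphs([graph]))
    return GraphEmbedding(representation=h_g.data[0].copy(),
                          latent=latent.data[0].copy())


def encode_many(state: EncoderState, graphs: list[MolecularGraph],
                batch_size: int = 256) -> tuple[np.ndarray, np.ndarray]:
    """Encode a corpus in batches; returns (representations, latents)."""
    reps, lats = [], []
    for i in range(0, len(graphs), batch_size):
        h_g, latent = forward_batch(state, batch_graphs(graphs[i:i + batch_size]))
        reps.append(h_g.data)
        lats.append(latent.data)
    return np.vstack(reps), np.vstack(lats)


# -- checkpointing ------------------------------------------------------------

def save_checkpoint(path: str, state: EncoderState,
                    extra: dict | None = None) -> None:
    """Round-trippable checkpoint: config JSON + raw parameter arrays."""
    meta = {
        "format_version": 1,
        "config": {
            "n_layers": state.config.n_layers,
            "hidden_dim": state.config.hidden_dim,
            "graph_dim": state.config.graph_dim,
            "latent_dim": state.config.latent_dim,
            "seed": state.config.seed,
        },
        "extra": extra or {},
    }
    arrays = {f"param/{k}": v.data for k, v in state.params.items()}
    np.savez(path, __meta__=np.frombuffer(
        json.dumps(meta).encode(), dtype=np.uint8), **arrays)


def load_checkpoint(path: str) -> tuple[EncoderState, dict]:
    with np.load(path) as zf:
        meta = json.loads(bytes(zf["__meta__"]).decode())
        params = {k[len("param/"):]: Tensor(zf[k].copy(), requires_grad=True)
                  for k in zf.files if k.startswith("param/")}
    config = EncoderConfig(**meta["config"])
    return EncoderState(config, params), meta.get("extra", {})


def clone_state(state: EncoderState) -> EncoderState:
    return EncoderState(replace(state.config),
                        {k: Tensor(v.data.copy(), requires_grad=True)
                         for k, v in state.params.items()})
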