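"""Run configuration, seed derivation and artifact manifests.

A run is driven by one YAML file with nested per-component sections and a
single root seed; every component seed is derived deterministically from
(root seed, component name) so one number reproduces a whole run.
"""

from __future__ import annotations

import copy
import hashlib
import json
import os
from datetime import datetime, timezone

import yaml

DEFAULTS: dict = {
    "seed": 0,
    "output_dir": "runs",
    "synth": {"n_molecules": 1000, "n_families": 4,
              "substituents_per_molecule": [0, 3], "noise_sd": 0.0,
              "label_rule": None},
    "chem_io": {"smiles_column": "smiles", "keep_largest_fragment": True},
    "augment": {"granularities": [100, 1000, 10000], "mask_ratio": 0.25},
    "encoder": {"n_layers": 5, "hidden_dim": 300, "graph_dim": 512,
                "latent_dim": 256},
    "pretrain": {"epochs": 30, "batch_size": 256, "learning_rate": 1e-3,
                 "mode": "full"},
    "finetune": {"epochs": 30, "batch_size": 128, "learning_rate": 1e-3,
                 "head_hidden": 128, "patience": 10, "split": "scaffold",
                 "fractions": [0.8, 0.1, 0.1]},
    "analysis": {"knn_k": 5, "n_bins": 10, "max_per_bin": 1000},
}


def derive_seed(root_seed: int, component: str) -> int:
    """Deterministic per-component seed below 2**31."""
    digest = hashlib.sha256(f"{component}:{root_seed}".encode()).digest()
    return int.from_bytes(digest[:4], "big") % (2 ** 31)


def _merge(base: dict, override: dict) -> dict:
    out = dict(base)
    for k, v in override.items():
        if isinstance(v, dict) and isinstance(out.get(k), dict):
            out[k] = _merge(out[k], v)
        else:
            out[k] = v
    return out


def load_config(path: str | None = None, overrides: dict | None = None) -> dict:
    cfg = copy.deepcopy(DEFAULTS)
    if path:
        with open(path) as fh:
            user = yaml.safe_load(fh) or {}
        if not isinstance(user, dict):
            raise ValueError(f"config root in {path} must be a mapping")
        cfg = _merge(cfg, user)
    if overrides:
        for dotted, value in overrides.items():
            node = cfg
            *parents, leaf = dotted.split(".")
            for key in parents:
                node = node.setdefault(key, {})
            node[leaf] = value
    validate_config(cfg)
    return cfg


def validate_config(cfg: dict) -> None:
    problems = []
    gran = cfg["augment"]["granularities"]
    if not gran or any(int(k) < 2 for k in gran):
        problems.append("augment.granularities: every K must be >= 2")
    if not 0.0 <= float(cfg["augment"]["mask_ratio"]) <= 1.0:
        problems.append("augment.mask_ratio: must lie in [0, 1]")
    enc = cfg["encoder"]
    for key in ("n_layers", "hidden_dim", "graph_dim", "latent_dim"):
        if int(enc[key]) < 1:
            problems.append(f"encoder.{key}: must be >= 1")
    fr = cfg["finetune"]["fractions"]
    if abs(sum(fr) - 1.0) > 1e-9:
        problems.append("finetune.fractions: must sum to 1")
    if cfg["pretrain"]["mode"] not in ("full", "mlct_only", "mcl_only", "none"):
        problems.append("pretrain.mode: unknown mode")
    if problems:
        raise ValueError("invalid configuration:\n  " + "\n  ".join(problems))


def config_hash(cfg: dict) -> str:
    return hashlib.sha256(
        json.dumps(cfg, sort_keys=True, default=str).encode()).hexdigest()


def file_digest(path: str) -> str:
    h = hashlib.sha256()
    with open(path, "rb") as fh:
        for chunk in iter(lambda: fh.read(1 << 16), b""):
            h.update(chunk)
    return h.hexdigest()


def write_manifest(artifact_path: str, cfg: dict, command: str,
                   inputs: list[str] | None = None) -> str:
    """Write a reproducibility manifest next to an artifact."""
    manifest = {
        "artifact": os.path.basename(artifact_path),
        "command": command,
        "config_hash": config_hash(cfg),
        "root_seed": cfg.get("seed"),
        "component_seeds": {c: derive_seed(int(cfg.get("seed", 0)), c)
                            for c in ("synth", "augment", "encoder",
                                      "pretrain", "finetune", "analysis")},
        "inputs": {p: file_digest(p) for p in (inputs or []) if os.path.exists(p)},
        "created": datetime.now(timezone.utc).isoformat(),
    }
    path = artifact_path + ".manifest.json"
    with open(path, "w") as fh:
        json.dump(manifest, fh, indent=2)
    return path
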