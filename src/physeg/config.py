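"""Run configuration, seeding, and output manifests for the CLI.

Every stochastic command takes a seed (explicit or defaulted and
logged); each command writes a ``manifest.json`` next to its outputs
recording the command, configuration hash, seed and package version, so
re-running with the same configuration reproduces outputs bit-for-bit on
the same platform.
"""

from __future__ import annotations

import hashlib
import json
import os

import yaml

from . import __version__

# Paper-anchored defaults, in the units conventionally printed
# (milliseconds / degrees); converted to SI at ingestion.
DEFAULT_CONFIG = {
    "seed": 0,
    "phantom": {
        "shape": [48, 48, 48],
        "boundary_smoothing_sigma": 1.0,
        "n_subjects": 1,
    },
    "simulate": {
        "sequence": "mprage",
        "ti_ms": [600.0, 1200.0],
        "ptd_ms": [500.0, 1600.0],
        "tr_ms": [15.0, 100.0],
        "te_ms": [4.0, 10.0],
        "fa_deg": [15.0, 75.0],
        "n": 10,
    },
    "train": {
        "batch_size": 4,
        "patch_size": 128,
        "patience": 7,
        "dropout_rate": 0.5,
        "first_layer_dropout_rate": 0.05,
        "base_channels": 30,
        "n_levels": 4,
        "physics": True,
        "strat": True,
        "pregenerated": False,
        "n_pregenerated": 121,
        "lr": 1.0e-3,
        "iterations_per_epoch": 150,
        "smoke": False,
    },
    "sample": {"T": 50, "mode": "mc-dropout"},
    "ugrid": {
        "sequence": "mprage",
        "ti_ms": [400.0, 2000.0],
        "ptd_ms": [200.0, 2000.0],
        "n_points": 5,
        "T": 20,
        "spgr_te_ms": 4.0,
    },
}


def load_config(path=None, overrides: dict | None = None) -> dict:
    cfg = json.loads(json.dumps(DEFAULT_CONFIG))  # deep copy
    if path is not None:
        with open(path) as fh:
            user = yaml.safe_load(fh) or {}
        _merge(cfg, user)
    if overrides:
        _merge(cfg, overrides)
    _validate(cfg)
    return cfg


def _merge(base: dict, extra: dict) -> None:
    for k, v in extra.items():
        if isinstance(v, dict) and isinstance(base.get(k), dict):
            _merge(base[k], v)
        else:
            base[k] = v


def _validate(cfg: dict) -> None:
    sim = cfg["simulate"]
    for key in ("ti_ms", "ptd_ms", "tr_ms", "te_ms", "fa_deg"):
        lo, hi = sim[key]
        if lo > hi:
            raise ValueError(f"simulate.{key}: lower bound exceeds upper bound")
    if cfg["train"]["patience"] < 1:
        raise ValueError("train.patience must be >= 1")


def config_hash(cfg: dict) -> str:
    return hashlib.sha256(
        json.dumps(cfg, sort_keys=True).encode()
    ).hexdigest()[:16]


def write_manifest(out_dir, command: str, cfg: dict, seed: int,
                   outputs: dict | None = None) -> str:
    os.makedirs(out_dir, exist_ok=True)
    manifest = {
        "command": command,
        "config_hash": config_hash(cfg),
        "seed": int(seed),
        "version": __version__,
        "outputs": outputs or {},
    }
    path = os.path.join(out_dir, "manifest.json")
    with open(path, "w") as fh:
        json.dump(manifest, fh, indent=2, sort_keys=True)
    return path
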