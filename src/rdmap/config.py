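"""Run configuration: defaults, YAML loading and dotted-path overrides.

Defaults mirror the reference protocol (focal alpha 0.65 / gamma 1.15,
learning rates 0.01 / 0.001, probability threshold 0.5, 50-pixel partition
rule at a 512 reference grid) with a desk-scale profile (128 px canvas,
tiny backbone) so the whole pipeline runs on one CPU.
"""

from __future__ import annotations

import copy
from pathlib import Path
from typing import Any, Dict, List, Optional

import yaml

__all__ = ["DEFAULTS", "load_config", "apply_overrides", "dump_config"]

DEFAULTS: Dict[str, Any] = {
    "seed": 0,
    "output_dir": "runs/default",
    "synth": {
        "n": 200,
        "canvas_px": 128,
        "rd_probability": 0.10,
        "shallow_probability": 0.25,
        "artifact_level": 0.0,
        "train_fraction": 0.8,
    },
    "roi": {"fundus_radius_fraction": 0.48},
    "clahe": {"clip_limit": 2.0, "tile_grid": [8, 8]},
    "train": {
        "input_resolution": 128,
        "lr_pretrain": 0.01,
        "lr_finetune": 0.001,
        "focal_alpha": 0.65,
        "focal_gamma": 1.15,
        "epochs_pretrain": 8,
        "epochs_finetune": 4,
        "batch_size": 16,
        "backbone_depth": "tiny",
        "decision_threshold": 0.5,
    },
    "amm": {"reduction_ratio": 4, "lam": 1.0},
    "camloc": {"threshold": 0.5},
    "anatomy": {"min_pixels": 50, "reference_resolution": 512},
    "disc": {"source": "sidecar", "epochs": 30},  # sidecar | segmented
    "eval": {"n_thresholds": 101},
}


def _deep_merge(base: Dict[str, Any], update: Dict[str, Any]) -> Dict[str, Any]:
    out = copy.deepcopy(base)
    for key, val in update.items():
        if isinstance(val, dict) and isinstance(out.get(key), dict):
            out[key] = _deep_merge(out[key], val)
        else:
            out[key] = copy.deepcopy(val)
    return out


def load_config(path: Optional[str] = None,
                overrides: Optional[List[str]] = None) -> Dict[str, Any]:
    """Merge defaults <- YAML file <- ``key.path=value`` overrides."""
    cfg = copy.deepcopy(DEFAULTS)
    if path is not None:
        with open(path) as fh:
            user = yaml.safe_load(fh) or {}
        if not isinstance(user, dict):
            raise ValueError("config file must contain a mapping")
        cfg = _deep_merge(cfg, user)
    if overrides:
        cfg = apply_overrides(cfg, overrides)
    return cfg


def apply_overrides(cfg: Dict[str, Any], overrides: List[str]) -> Dict[str, Any]:
    cfg = copy.deepcopy(cfg)
    for item in overrides:
        if "=" not in item:
            raise ValueError(f"override {item!r} is not of the form key=value")
        key, raw = item.split("=", 1)
        value = yaml.safe_load(raw)
        node = cfg
        parts = key.split(".")
        for p in parts[:-1]:
            node = node.setdefault(p, {})
            if not isinstance(node, dict):
                raise ValueError(f"cannot descend into non-mapping at {p!r}")
        node[parts[-1]] = value
    return cfg


def dump_config(cfg: Dict[str, Any], path: str | Path) -> None:
    """Write the fully-resolved config next to the run's outputs."""
    Path(path).parent.mkdir(parents=True, exist_ok=True)
    with open(path, "w") as fh:
        yaml.safe_dump(cfg, fh, sort_keys=True)
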