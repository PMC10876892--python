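"""Artifact serialization: images, masks, sidecars, manifests, maps.

Samples are written as 8-bit RGB PNGs with a JSON landmark sidecar per
image and a single-channel truth-mask PNG; probability maps are stored as
16-bit PNGs (value = round(p * 65535)).  Coordinates in sidecars are
0-based pixel indices, x rightward, y downward.
"""

from __future__ import annotations

import json
from pathlib import Path
from typing import List, Optional, Sequence

import imageio.v3 as iio
import numpy as np
import pandas as pd

from . import anatomy
from .anatomy import PartitionRule
from .synthdata import SyntheticSample

__all__ = [
    "save_sample",
    "load_sample",
    "save_dataset",
    "load_dataset",
    "save_probability_map",
    "load_probability_map",
    "save_mask",
    "load_mask",
]


def _to_uint8(image: np.ndarray) -> np.ndarray:
    return np.clip(np.asarray(image) * 255.0 + 0.5, 0, 255).astype(np.uint8)


def save_sample(sample: SyntheticSample, outdir: str | Path, stem: str) -> dict:
    """Write image, truth mask and sidecar; return the manifest row."""
    outdir = Path(outdir)
    (outdir / "images").mkdir(parents=True, exist_ok=True)
    (outdir / "masks").mkdir(parents=True, exist_ok=True)
    (outdir / "sidecars").mkdir(parents=True, exist_ok=True)
    iio.imwrite(outdir / "images" / f"{stem}.png", _to_uint8(sample.image))
    iio.imwrite(
        outdir / "masks" / f"{stem}.png",
        (sample.truth_mask.astype(np.uint8) * 255),
    )
    sidecar = {
        "fovea": list(sample.fovea),
        "disc_center": list(sample.disc_center),
        "disc_radius": float(sample.disc_radius),
        "laterality": sample.laterality,
        "is_rd": bool(sample.is_rd),
        "seed": int(sample.seed),
    }
    with open(outdir / "sidecars" / f"{stem}.json", "w") as fh:
        json.dump(sidecar, fh, indent=1, sort_keys=True)
    return {
        "image_id": stem,
        "path": f"images/{stem}.png",
        "label": "RD" if sample.is_rd else "Non-RD",
    }


def load_sample(outdir: str | Path, stem: str) -> SyntheticSample:
    """Reload a sample; truth labels are recomputed from the stored mask."""
    outdir = Path(outdir)
    image = iio.imread(outdir / "images" / f"{stem}.png").astype(np.float32) / 255.0
    mask = (iio.imread(outdir / "masks" / f"{stem}.png") > 127).astype(np.uint8)
    with open(outdir / "sidecars" / f"{stem}.json") as fh:
        sc = json.load(fh)
    n = mask.shape[0]
    sample = SyntheticSample(
        image=image,
        truth_mask=mask,
        fovea=tuple(sc["fovea"]),
        disc_center=tuple(sc["disc_center"]),
        disc_radius=sc["disc_radius"],
        laterality=sc["laterality"],
        is_rd=bool(sc["is_rd"]),
        truth_partitions=np.zeros(48, dtype=np.uint8),
        truth_primary_zone=None,
        seed=int(sc.get("seed", 0)),
    )
    frame = sample.frame()
    rule = PartitionRule().scaled(n)
    sample.truth_partitions = anatomy.partition_vector(mask, frame, rule)
    sample.truth_primary_zone = (
        anatomy.primary_zone(mask, frame) if sample.is_rd else None
    )
    return sample


def save_dataset(
    samples: Sequence[SyntheticSample],
    outdir: str | Path,
    splits: Optional[Sequence[str]] = None,
) -> pd.DataFrame:
    """Write all samples plus a manifest CSV (image_id, path, split, label)."""
    outdir = Path(outdir)
    rows = []
    for i, s in enumerate(samples):
        row = save_sample(s, outdir, f"img{i:05d}")
        row["split"] = splits[i] if splits is not None else "unsplit"
        rows.append(row)
    manifest = pd.DataFrame(rows, columns=["image_id", "path", "split", "label"])
    manifest.to_csv(outdir / "manifest.csv", index=False)
    return manifest


def load_dataset(
    outdir: str | Path, split: Optional[str] = None
) -> List[SyntheticSample]:
    outdir = Path(outdir)
    manifest = pd.read_csv(outdir / "manifest.csv")
    if split is not None:
        manifest = manifest[manifest["split"] == split]
    return [load_sample(outdir, sid) for sid in manifest["image_id"]]


def save_probability_map(values: np.ndarray, path: str | Path) -> None:
    arr = np.clip(np.asarray(values, dtype=np.float64), 0.0, 1.0)
    iio.imwrite(Path(path), np.round(arr * 65535.0).astype(np.uint16))


def load_probability_map(path: str | Path) -> np.ndarray:
    return iio.imread(Path(path)).astype(np.float64) / 65535.0


def save_mask(mask: np.ndarray, path: str | Path) -> None:
    iio.imwrite(Path(path), ((np.asarray(mask) != 0) * 255).astype(np.uint8))


def load_mask(path: str | Path) -> np.ndarray:
    return (iio.imread(Path(path)) > 127).astype(np.uint8)
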