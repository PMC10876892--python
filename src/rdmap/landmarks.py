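"""Anchor landmarks of the anatomical frame: fovea and optic disc.

The fovea is a manual annotation read from a JSON sidecar (absent for
macula-off images, which are excluded from anatomical evaluation).  The
optic disc comes either from the sidecar (oracle) or from a small
encoder-decoder segmentation network trained on synthetic samples; the
mask is reduced to a center and an equivalent-circle radius.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Optional, Sequence, Tuple

import numpy as np
from scipy import ndimage

from ._nn import (
    SGD,
    BatchNorm2d,
    Conv2d,
    ReLU,
    Sequential,
    Upsample2x,
    sigmoid,
)

__all__ = [
    "FoveaAnnotation",
    "DiscGeometry",
    "DiscSegmenter",
    "train_disc_segmenter",
    "segment_disc",
    "extract_disc_geometry",
    "read_landmarks",
    "disc_truth_mask",
]


@dataclass(frozen=True)
class FoveaAnnotation:
    """Manual fovea position; ``present=False`` flags a macula-off image."""

    position: Optional[Tuple[float, float]]
    present: bool


@dataclass
class DiscGeometry:
    """Optic-disc center and equivalent-circle radius (pixels)."""

    center: Tuple[float, float]
    radius: float
    mask: Optional[np.ndarray] = None


class DiscSegmenter:
    """Tiny two-down/two-up encoder-decoder with one skip connection."""

    def __init__(self, seed: int = 0):
        rng = np.random.default_rng(seed)
        self.enc1 = Sequential(Conv2d(3, 8, 3, 2, rng=rng), BatchNorm2d(8), ReLU())
        self.enc2 = Sequential(Conv2d(8, 16, 3, 2, rng=rng), BatchNorm2d(16), ReLU())
        self.mid = Sequential(Conv2d(16, 16, 3, 1, rng=rng), BatchNorm2d(16), ReLU())
        self.up1 = Sequential(Upsample2x(), Conv2d(16, 8, 3, 1, rng=rng),
                              BatchNorm2d(8), ReLU())
        self.up2 = Sequential(Upsample2x(), Conv2d(8, 8, 3, 1, rng=rng),
                              BatchNorm2d(8), ReLU())
        self.out = Conv2d(8, 1, 1, 1, pad=0, rng=rng)
        self.trained = False

    def params(self):
        return (self.enc1.params() + self.enc2.params() + self.mid.params()
                + self.up1.params() + self.up2.params() + self.out.params())

    def grads(self):
        return (self.enc1.grads() + self.enc2.grads() + self.mid.grads()
                + self.up1.grads() + self.up2.grads() + self.out.grads())

    def forward(self, x: np.ndarray, train: bool = False) -> np.ndarray:
        """Pixel-wise disc logits (N, H, W) for a (N, 3, H, W) batch."""
        e1 = self.enc1.forward(x, train)
        e2 = self.enc2.forward(e1, train)
        m = self.mid.forward(e2, train)
        u1 = self.up1.forward(m, train) + e1  # skip
        u2 = self.up2.forward(u1, train)
        return self.out.forward(u2, train)[:, 0]

    def backward(self, dy: np.ndarray) -> None:
        d = self.out.backward(dy[:, None])
        d = self.up2.backward(d)  # grad wrt u1 = up1(m) + e1
        d_m = self.up1.backward(d)
        d_e2 = self.mid.backward(d_m)
        d_e1_main = self.enc2.backward(d_e2)
        self.enc1.backward(d_e1_main + d)  # skip path adds d directly

    def predict_proba(self, x: np.ndarray) -> np.ndarray:
        return sigmoid(self.forward(x, train=False))


def disc_truth_mask(sample) -> np.ndarray:
    """Analytic disc mask from a synthetic sample's stored geometry."""
    h, w = sample.truth_mask.shape
    yy, xx = np.mgrid[0:h, 0:w]
    cx, cy = sample.disc_center
    return (((xx - cx) ** 2 + (yy - cy) ** 2) <= sample.disc_radius**2).astype(
        np.uint8
    )


def train_disc_segmenter(
    samples: Sequence,
    epochs: int = 30,
    lr: float = 0.05,
    batch_size: int = 8,
    pos_weight: float = 20.0,
    seed: int = 0,
) -> DiscSegmenter:
    """Train the segmenter with positively-weighted pixel cross-entropy."""
    x = np.stack(
        [np.transpose(s.image, (2, 0, 1)).astype(np.float32) for s in samples]
    )
    t = np.stack([disc_truth_mask(s).astype(np.float64) for s in samples])
    model = DiscSegmenter(seed=seed)
    opt = SGD(model.params(), model.grads(), lr=lr, momentum=0.9)
    rng = np.random.default_rng(seed)
    n = len(x)
    bs = min(batch_size, n)
    for _ in range(epochs):
        order = rng.permutation(n)
        for start in range(0, n, bs):
            idx = order[start : start + bs]
            xb, tb = x[idx], t[idx]
            opt.zero_grad()
            z = model.forward(xb, train=True)
            p = np.clip(sigmoid(z), 1e-7, 1 - 1e-7)
            dz = (pos_weight * tb * (p - 1.0) + (1.0 - tb) * p) / tb.size
            model.backward(dz)
            opt.step()
    model.trained = True
    return model


def segment_disc(image: np.ndarray, model: DiscSegmenter) -> np.ndarray:
    """Binary disc mask for one RGB image (H, W, 3) or (3, H, W)."""
    if not model.trained:
        raise ValueError("disc segmenter has not been trained")
    img = np.asarray(image, dtype=np.float32)
    if img.ndim == 3 and img.shape[-1] == 3 and img.shape[0] != 3:
        img = np.transpose(img, (2, 0, 1))
    p = model.predict_proba(img[None])[0]
    return (p >= 0.5).astype(np.uint8)


def extract_disc_geometry(mask: np.ndarray) -> DiscGeometry:
    """Largest-component centroid + equivalent-circle radius sqrt(area/pi)."""
    mask = np.asarray(mask) != 0
    if not mask.any():
        raise ValueError("empty disc mask: no disc found")
    labels, n = ndimage.label(mask)
    if n > 1:
        sizes = ndimage.sum_labels(np.ones_like(labels), labels, range(1, n + 1))
        keep = int(np.argmax(sizes)) + 1
        mask = labels == keep
    ys, xs = np.nonzero(mask)
    area = float(len(xs))
    return DiscGeometry(
        center=(float(xs.mean()), float(ys.mean())),
        radius=float(np.sqrt(area / np.pi)),
        mask=mask.astype(np.uint8),
    )


def read_landmarks(sidecar: dict) -> Tuple[FoveaAnnotation, Optional[DiscGeometry]]:
    """Parse a landmark sidecar record.

    Expected keys: ``fovea`` ([x, y] or null), optional ``disc_center`` and
    ``disc_radius``.  A missing/null fovea flags a macula-off image.
    """
    if not isinstance(sidecar, dict):
        raise ValueError("sidecar must be a mapping")
    fv = sidecar.get("fovea")
    if fv is None:
        fovea = FoveaAnnotation(position=None, present=False)
    else:
        if len(fv) != 2:
            raise ValueError("fovea must be a length-2 [x, y] coordinate")
        fovea = FoveaAnnotation(position=(float(fv[0]), float(fv[1])), present=True)
    disc = None
    if sidecar.get("disc_center") is not None:
        dc = sidecar["disc_center"]
        radius = sidecar.get("disc_radius")
        if radius is None:
            raise ValueError("disc_center without disc_radius")
        disc = DiscGeometry(center=(float(dc[0]), float(dc[1])), radius=float(radius))
    return fovea, disc
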