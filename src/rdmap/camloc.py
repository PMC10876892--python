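"""Lesion probability maps from stage-4 Grad-CAM and pseudo-mask extraction.

Pipeline per image: ``grad_cam_map`` (ReLU of gradient-weighted stage-4
feature maps) -> ``normalize_map`` (min-max over the ROI support to [0,1];
a constant map normalizes to all zeros, claiming no lesion) ->
``upsample_to_image`` (bilinear, re-masked by the ROI) -> ``pseudo_mask``
(threshold at 0.5, ``>=`` convention).
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Optional, Tuple

import numpy as np
from skimage.transform import resize

from .preprocess import RoiTemplate
from .wsmodel import Backbone

__all__ = [
    "ProbabilityMap",
    "LesionMask",
    "grad_cam_map",
    "normalize_map",
    "upsample_to_image",
    "pseudo_mask",
    "localize",
]


@dataclass
class ProbabilityMap:
    """Per-pixel lesion probability in [0, 1] on some square grid."""

    values: np.ndarray
    source_resolution: int

    def __post_init__(self) -> None:
        v = np.asarray(self.values)
        if v.size and (v.min() < -1e-9 or v.max() > 1 + 1e-9):
            raise ValueError("probability map values must lie in [0, 1]")


@dataclass
class LesionMask:
    """Binary pseudo-mask with the threshold that produced it."""

    mask: np.ndarray
    threshold_used: float


def _roi_at(roi: Optional[RoiTemplate], shape: Tuple[int, int]) -> np.ndarray:
    if roi is None:
        return np.ones(shape, dtype=bool)
    m = roi.mask.astype(bool)
    if m.shape != shape:
        m = resize(m.astype(float), shape, order=0, anti_aliasing=False) > 0.5
    return m


def grad_cam_map(model: Backbone, image: np.ndarray) -> np.ndarray:
    """Raw Grad-CAM activation on the stage-4 grid for the detachment score.

    ``map = ReLU(sum_k w_k A_k)`` with ``w_k`` the spatial mean of the
    gradients of the pre-sigmoid score with respect to stage-4 maps ``A_k``.
    """
    img = np.asarray(image, dtype=np.float32)
    if img.ndim == 3 and img.shape[-1] == 3 and img.shape[0] != 3:
        img = np.transpose(img, (2, 0, 1))
    feats, grads = model.stage4_features_and_grads(img[None])
    weights = grads[0].mean(axis=(1, 2))  # (C,)
    cam = np.tensordot(weights, feats[0], axes=(0, 0))
    return np.maximum(cam, 0.0)


def normalize_map(raw: np.ndarray, roi: Optional[RoiTemplate] = None) -> ProbabilityMap:
    """Min-max normalize a non-negative activation map over the ROI support."""
    raw = np.asarray(raw, dtype=np.float64)
    if np.any(raw < 0):
        raise ValueError("raw activation map must be non-negative")
    support = _roi_at(roi, raw.shape)
    out = np.zeros_like(raw)
    if support.any():
        vals = raw[support]
        lo, hi = float(vals.min()), float(vals.max())
        if hi > lo:
            out[support] = (raw[support] - lo) / (hi - lo)
    return ProbabilityMap(values=out, source_resolution=raw.shape[0])


def upsample_to_image(
    pmap: ProbabilityMap, target_size: int, roi: Optional[RoiTemplate] = None
) -> ProbabilityMap:
    """Bilinear resampling to the original image grid, then ROI re-masking."""
    if target_size <= 0:
        raise ValueError("target_size must be positive")
    v = np.asarray(pmap.values, dtype=np.float64)
    if v.shape != (target_size, target_size):
        v = resize(v, (target_size, target_size), order=1, anti_aliasing=False)
    v = np.clip(v, 0.0, 1.0)
    v = v * _roi_at(roi, v.shape)
    return ProbabilityMap(values=v, source_resolution=pmap.source_resolution)


def pseudo_mask(pmap: ProbabilityMap, threshold: float = 0.5) -> LesionMask:
    """Binary mask: probability >= threshold (monotone in the threshold)."""
    if not 0.0 <= threshold <= 1.0:
        raise ValueError("threshold must be in [0, 1]")
    return LesionMask(
        mask=(np.asarray(pmap.values) >= threshold).astype(np.uint8),
        threshold_used=threshold,
    )


def localize(
    model: Backbone,
    image: np.ndarray,
    target_size: int,
    roi: Optional[RoiTemplate] = None,
    threshold: float = 0.5,
) -> Tuple[ProbabilityMap, LesionMask]:
    """Full chain: Grad-CAM -> normalize -> upsample -> threshold."""
    raw = grad_cam_map(model, image)
    pmap = normalize_map(raw, roi)
    pmap = upsample_to_image(pmap, target_size, roi)
    return pmap, pseudo_mask(pmap, threshold)
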