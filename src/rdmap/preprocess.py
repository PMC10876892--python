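"""Input conditioning: ROI corner erasure and local contrast enhancement.

The four corners of an ultra-widefield capture carry no fundus signal; a
fixed template zeroes them out.  CLAHE is applied deterministically to the
luminance channel of every input, with chroma preserved.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from skimage import exposure

__all__ = [
    "RoiTemplate",
    "build_roi_template",
    "apply_roi_template",
    "clahe_enhance",
]

# Rec. 601 luma weights.
_LUMA = np.array([0.299, 0.587, 0.114])


@dataclass(frozen=True)
class RoiTemplate:
    """Binary keep-mask over the canvas. ``provenance`` is 'generated' for
    the analytic disc template or 'handcrafted' for a user-supplied one."""

    mask: np.ndarray  # (H, W) uint8 in {0, 1}
    provenance: str = "generated"

    def __post_init__(self) -> None:
        m = np.asarray(self.mask)
        if m.ndim != 2:
            raise ValueError("ROI template mask must be 2-D")
        h, w = m.shape
        corners = [m[0, 0], m[0, w - 1], m[h - 1, 0], m[h - 1, w - 1]]
        if any(int(c) != 0 for c in corners):
            raise ValueError("ROI template must erase all four corners")


def build_roi_template(
    canvas_px: int, fundus_radius_fraction: float = 0.48
) -> RoiTemplate:
    """Analytic template: keep the centered disc, erase everything else."""
    if canvas_px < 32:
        raise ValueError("canvas_px must be >= 32")
    if not 0.0 < fundus_radius_fraction <= 0.5:
        raise ValueError("fundus_radius_fraction must be in (0, 0.5]")
    c = (canvas_px - 1) / 2.0
    yy, xx = np.mgrid[0:canvas_px, 0:canvas_px]
    r = fundus_radius_fraction * canvas_px
    mask = ((xx - c) ** 2 + (yy - c) ** 2 <= r * r).astype(np.uint8)
    return RoiTemplate(mask=mask, provenance="generated")


def apply_roi_template(image: np.ndarray, template: RoiTemplate) -> np.ndarray:
    """Zero all channels outside the template support; a projection."""
    image = np.asarray(image)
    if image.shape[:2] != template.mask.shape:
        raise ValueError(
            f"image shape {image.shape[:2]} != template {template.mask.shape}"
        )
    keep = template.mask.astype(image.dtype)
    if image.ndim == 3:
        return image * keep[:, :, None]
    return image * keep


def clahe_enhance(
    image: np.ndarray,
    clip_limit: float = 2.0,
    tile_grid: tuple[int, int] = (8, 8),
) -> np.ndarray:
    """Contrast-limited adaptive histogram equalization on luminance.

    ``clip_limit`` follows the familiar OpenCV-style scale (default 2.0) and
    is mapped to the normalized clip fraction used internally; ``tile_grid``
    is (rows, cols) of contextual tiles.  Chroma offsets are preserved: the
    enhanced luminance delta is added to every channel.  Input and output
    are float arrays in [0, 1].
    """
    if clip_limit <= 0:
        raise ValueError("clip_limit must be positive")
    rows, cols = tile_grid
    if rows <= 0 or cols <= 0:
        raise ValueError("tile_grid entries must be positive")
    image = np.asarray(image, dtype=np.float64)
    if image.size == 0:
        raise ValueError("empty image")
    gray = image.ndim == 2
    luma = image if gray else image @ _LUMA
    if np.ptp(luma) == 0:  # constant image: nothing to equalize
        return image.astype(np.float32).copy()
    kernel = (
        max(1, image.shape[0] // rows),
        max(1, image.shape[1] // cols),
    )
    enhanced = exposure.equalize_adapthist(
        np.clip(luma, 0.0, 1.0), kernel_size=kernel, clip_limit=clip_limit / 100.0
    )
    if gray:
        return enhanced.astype(np.float32)
    out = image + (enhanced - luma)[:, :, None]
    return np.clip(out, 0.0, 1.0).astype(np.float32)
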