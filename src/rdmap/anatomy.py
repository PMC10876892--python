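"""Fovea/disc-calibrated retinal zoning geometry.

The retina is partitioned around the fovea on a clock face calibrated by the
horizontal line through the fovea and optic-disc center:

* four posture zones — superior (10–2 o'clock), right (2–4), inferior (4–8)
  and left (8–10);
* a posterior-pole circle, centered on the fovea and just containing the
  optic disc;
* 48 anatomical partitions: 24 sectors of 15 degrees crossed with the
  inner/outer split at the posterior-pole circle.

Clock angles are measured clockwise from calibrated 12 o'clock in degrees,
``theta in [0, 360)``.  Pixels are 0-based, x rightward, y downward.
"""

from __future__ import annotations

from dataclasses import dataclass, replace
from typing import Tuple

import numpy as np

__all__ = [
    "ZONES",
    "PartitionRule",
    "RetinalFrame",
    "fit_frame",
    "clock_angle",
    "zone_of_angle",
    "zone_of_point",
    "posterior_pole_mask",
    "partition_index",
    "partition_index_map",
    "partition_vector",
    "partition_counts",
    "primary_zone",
    "posterior_involved",
    "zone_of_sector",
]

#: Fixed zone order used for confusion matrices and tie-breaking.
ZONES = ("superior", "right", "inferior", "left")

#: 15-degree sector index -> zone name. Sector s covers [15*s, 15*(s+1)).
_SECTOR_ZONE = (
    ["superior"] * 4      # 0..3   : 0–60 deg   (12–2 o'clock)
    + ["right"] * 4       # 4..7   : 60–120     (2–4)
    + ["inferior"] * 8    # 8..15  : 120–240    (4–8)
    + ["left"] * 4        # 16..19 : 240–300    (8–10)
    + ["superior"] * 4    # 20..23 : 300–360    (10–12)
)

#: Tie-break priority for the primary zone (deterministic, documented).
_ZONE_PRIORITY = ("superior", "inferior", "right", "left")


@dataclass(frozen=True)
class PartitionRule:
    """Pixel-count rule turning per-partition tallies into binary labels.

    A partition bit is 1 iff strictly more than ``min_pixels`` lesion pixels
    fall inside it.  ``min_pixels`` is expressed on the grid given by
    ``evaluation_resolution``; use :meth:`scaled` to keep the rule consistent
    across canvas sizes (area scales quadratically).
    """

    min_pixels: float = 50
    evaluation_resolution: int = 512

    def __post_init__(self) -> None:
        if self.min_pixels < 0:
            raise ValueError("min_pixels must be >= 0")

    def scaled(self, resolution: int) -> "PartitionRule":
        """Return the rule rescaled to another square canvas resolution."""
        factor = (resolution / self.evaluation_resolution) ** 2
        return replace(
            self,
            min_pixels=self.min_pixels * factor,
            evaluation_resolution=resolution,
        )


@dataclass(frozen=True)
class RetinalFrame:
    """Coordinate system anchored at the fovea, calibrated by the disc.

    ``rotation_deg`` is the angle of the calibrated horizontal relative to
    the image x-axis, normalized so it points toward increasing image-x.
    ``posterior_pole_radius`` is the smallest fovea-centered radius that
    contains the whole optic disc.
    """

    fovea: Tuple[float, float]
    disc_center: Tuple[float, float]
    disc_radius: float
    rotation_deg: float
    laterality: str
    posterior_pole_radius: float
    canvas: Tuple[int, int]


def fit_frame(
    fovea: Tuple[float, float],
    disc_center: Tuple[float, float],
    disc_radius: float,
    laterality: str,
    canvas: Tuple[int, int],
) -> RetinalFrame:
    """Build the calibrated frame from the two landmarks.

    Parameters
    ----------
    fovea, disc_center : (x, y) pixel coordinates; must differ.
    disc_radius : optic-disc radius in pixels (> 0).
    laterality : "OD" or "OS".
    canvas : (height, width) of the image grid.
    """
    if laterality not in ("OD", "OS"):
        raise ValueError(f"laterality must be OD or OS, got {laterality!r}")
    if disc_radius <= 0:
        raise ValueError("disc_radius must be positive")
    dx = disc_center[0] - fovea[0]
    dy = disc_center[1] - fovea[1]
    dist = float(np.hypot(dx, dy))
    if dist == 0:
        raise ValueError("fovea and disc center coincide; frame undefined")
    rot = np.degrees(np.arctan2(dy, dx))
    # Normalize so the calibrated horizontal points toward increasing image-x.
    if rot > 90.0 or rot <= -90.0:
        rot -= 180.0 * np.sign(rot)
    return RetinalFrame(
        fovea=(float(fovea[0]), float(fovea[1])),
        disc_center=(float(disc_center[0]), float(disc_center[1])),
        disc_radius=float(disc_radius),
        rotation_deg=float(rot),
        laterality=laterality,
        posterior_pole_radius=dist + float(disc_radius),
        canvas=(int(canvas[0]), int(canvas[1])),
    )


def clock_angle(frame: RetinalFrame, x, y):
    """Clock angle(s) in degrees, clockwise from calibrated 12 o'clock.

    Accepts scalars or arrays. The fovea itself has no defined angle; scalar
    input at the fovea raises ``ValueError``.
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    vx = x - frame.fovea[0]
    vy = y - frame.fovea[1]
    at_fovea = (vx == 0) & (vy == 0)
    if np.ndim(vx) == 0 and bool(at_fovea):
        raise ValueError("clock angle undefined at the fovea")
    rot = np.radians(frame.rotation_deg)
    c, s = np.cos(-rot), np.sin(-rot)
    ux = c * vx - s * vy
    uy = s * vx + c * vy
    # Image y grows downward: 12 o'clock is -y; clockwise passes +x at 90 deg.
    theta = np.degrees(np.arctan2(ux, -uy))
    return np.mod(theta, 360.0)


def zone_of_angle(theta):
    """Map clock angle(s) to zone names; boundaries are half-open.

    Returns a plain string for scalar input, an object array otherwise.
    """
    sector = (np.floor_divide(np.mod(np.asarray(theta), 360.0), 15.0)).astype(int)
    sector = np.clip(sector, 0, 23)
    if sector.ndim == 0:
        return _SECTOR_ZONE[int(sector)]
    return np.asarray(_SECTOR_ZONE, dtype=object)[sector]

def zone_of_sector(sector: int) -> str:
    """Zone name of a 15-degree sector index (0..23)."""
    return _SECTOR_ZONE[sector]


def zone_of_point(frame: RetinalFrame, pixel: Tuple[float, float]) -> str:
    """Four-zone label of a single pixel (error at the fovea)."""
    theta = clock_angle(frame, pixel[0], pixel[1])
    return zone_of_angle(theta)


def posterior_pole_mask(frame: RetinalFrame) -> np.ndarray:
    """Boolean raster of pixels within the posterior-pole circle."""
    h, w = frame.canvas
    yy, xx = np.mgrid[0:h, 0:w]
    r2 = (xx - frame.fovea[0]) ** 2 + (yy - frame.fovea[1]) ** 2
    return r2 <= frame.posterior_pole_radius**2


def partition_index(frame: RetinalFrame, pixel: Tuple[float, float]) -> int:
    """Partition index 0..47 of a single pixel: ring*24 + floor(theta/15)."""
    theta = float(clock_angle(frame, pixel[0], pixel[1]))
    sector = min(int(theta // 15.0), 23)
    dx = pixel[0] - frame.fovea[0]
    dy = pixel[1] - frame.fovea[1]
    ring = 0 if dx * dx + dy * dy <= frame.posterior_pole_radius**2 else 1
    return ring * 24 + sector


def partition_index_map(frame: RetinalFrame) -> np.ndarray:
    """Integer raster of partition indices; the fovea pixel is set to -1."""
    h, w = frame.canvas
    yy, xx = np.mgrid[0:h, 0:w]
    vx = xx - frame.fovea[0]
    vy = yy - frame.fovea[1]
    theta = clock_angle(frame, xx, yy)
    sector = np.minimum((theta // 15.0).astype(int), 23)
    ring = (vx**2 + vy**2 > frame.posterior_pole_radius**2).astype(int)
    idx = ring * 24 + sector
    at_fovea = (vx == 0) & (vy == 0)
    idx[at_fovea] = -1
    return idx


def partition_counts(mask: np.ndarray, frame: RetinalFrame) -> np.ndarray:
    """Per-partition lesion pixel tallies (length-48 integer vector)."""
    mask = np.asarray(mask)
    if mask.shape != tuple(frame.canvas):
        raise ValueError(
            f"mask shape {mask.shape} does not match frame canvas {frame.canvas}"
        )
    idx = partition_index_map(frame)
    sel = (mask != 0) & (idx >= 0)
    return np.bincount(idx[sel].ravel(), minlength=48)[:48]


def partition_vector(
    mask: np.ndarray,
    frame: RetinalFrame,
    rule: PartitionRule | None = None,
) -> np.ndarray:
    """48-length binary vector: bit=1 iff partition tally > rule.min_pixels."""
    rule = rule if rule is not None else PartitionRule()
    counts = partition_counts(mask, frame)
    return (counts > rule.min_pixels).astype(np.uint8)


def primary_zone(mask: np.ndarray, frame: RetinalFrame) -> str | None:
    """Zone with the largest lesion pixel count; ``None`` for an empty mask.

    Ties resolve by the fixed order superior > inferior > right > left.
    """
    mask = np.asarray(mask)
    if mask.shape != tuple(frame.canvas):
        raise ValueError("mask/frame shape mismatch")
    if not mask.any():
        return None
    h, w = frame.canvas
    yy, xx = np.mgrid[0:h, 0:w]
    sel = mask != 0
    # Exclude the fovea pixel itself (angle undefined there).
    sel &= ~((xx == frame.fovea[0]) & (yy == frame.fovea[1]))
    if not sel.any():
        return None
    zones = zone_of_angle(clock_angle(frame, xx[sel], yy[sel]))
    best, best_count = None, -1
    for z in _ZONE_PRIORITY:
        count = int(np.sum(zones == z))
        if count > best_count:
            best, best_count = z, count
    return best


def posterior_involved(
    mask: np.ndarray,
    frame: RetinalFrame,
    rule: PartitionRule | None = None,
) -> bool:
    """True iff lesion pixels inside the posterior pole exceed the rule."""
    rule = rule if rule is not None else PartitionRule()
    mask = np.asarray(mask)
    if mask.shape != tuple(frame.canvas):
        raise ValueError("mask/frame shape mismatch")
    inside = posterior_pole_mask(frame)
    return bool(np.sum((mask != 0) & inside) > rule.min_pixels)
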