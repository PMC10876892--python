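"""Seeded synthetic ultra-widefield-fundus-like image generator.

Produces square RGB canvases with a centered circular fundus field (four
information-free corners), an optic disc placed nasally per laterality, a
foveal dip, and — for detachment-positive samples — a bright corrugated
wedge lesion with an exact ground-truth mask, partition vector and primary
zone.  Everything is deterministic for a fixed seed.

Geometry conventions (all overridable through :class:`SynthConfig`):

* fundus radius = 0.48 x canvas, fovea at the canvas center;
* disc center offset 0.22 x canvas from the fovea along the calibrated
  horizontal (image-right for OD, image-left for OS), radius 0.04 x canvas;
* lesion wedges are specified by a clockwise clock-angle span (degrees from
  calibrated 12 o'clock) and a radial band in fractions of the fundus radius.
"""

from __future__ import annotations

import dataclasses
from dataclasses import dataclass, field
from typing import List, Optional, Sequence, Tuple

import numpy as np
from scipy.ndimage import gaussian_filter

from . import anatomy
from .anatomy import PartitionRule, RetinalFrame, fit_frame

__all__ = [
    "ALLOWED_CANVAS",
    "SynthConfig",
    "SyntheticSample",
    "generate_fundus",
    "generate_dataset",
    "split_dataset",
]

ALLOWED_CANVAS = (128, 256, 512, 1024)

# Base fundus palette (RGB, float in [0,1]).
_FUNDUS_RGB = np.array([0.62, 0.28, 0.12])
_DISC_RGB = np.array([0.95, 0.82, 0.55])


@dataclass(frozen=True)
class SynthConfig:
    """Parameters of one synthetic sample (or a dataset template)."""

    canvas_px: int = 512
    laterality: str = "OD"
    rd_probability: float = 0.10
    lesion_sector_span: Optional[Tuple[float, float]] = None
    lesion_radial_band: Optional[Tuple[float, float]] = None
    shallow: bool = False
    shallow_probability: float = 0.0
    corrugation_period_px: float = 14.0
    corrugation_amplitude: float = 0.25
    lesion_lift: float = 0.30
    shallow_factor: float = 0.3
    artifact_level: float = 0.0
    fundus_radius_fraction: float = 0.48
    disc_offset_fraction: float = 0.22
    disc_radius_fraction: float = 0.04
    noise_sigma: float = 0.015
    seed: int = 0

    def __post_init__(self) -> None:
        if self.canvas_px not in ALLOWED_CANVAS:
            raise ValueError(
                f"canvas_px must be one of {ALLOWED_CANVAS}, got {self.canvas_px}"
            )
        if not 0.0 <= self.rd_probability <= 1.0:
            raise ValueError("rd_probability must be in [0, 1]")
        if self.laterality not in ("OD", "OS"):
            raise ValueError("laterality must be OD or OS")
        if self.lesion_sector_span is not None:
            a, b = self.lesion_sector_span
            if (b - a) % 360.0 == 0.0:
                raise ValueError("lesion_sector_span must be non-degenerate")


@dataclass
class SyntheticSample:
    """One generated image with its exact ground truth."""

    image: np.ndarray  # (H, W, 3) float32 in [0, 1]
    truth_mask: np.ndarray  # (H, W) uint8 in {0, 1}
    fovea: Tuple[float, float]
    disc_center: Tuple[float, float]
    disc_radius: float
    laterality: str
    is_rd: bool
    truth_partitions: np.ndarray  # (48,) uint8
    truth_primary_zone: Optional[str]
    seed: int = 0

    def frame(self) -> RetinalFrame:
        """The anatomical frame implied by the stored landmarks."""
        h, w = self.truth_mask.shape
        return fit_frame(
            self.fovea, self.disc_center, self.disc_radius, self.laterality, (h, w)
        )


def _polar_grids(n: int, fovea: Tuple[float, float]):
    yy, xx = np.mgrid[0:n, 0:n].astype(float)
    vx = xx - fovea[0]
    vy = yy - fovea[1]
    rr = np.hypot(vx, vy)
    # Clockwise clock angle from image 12 o'clock (calibration is horizontal).
    theta = np.mod(np.degrees(np.arctan2(vx, -vy)), 360.0)
    return rr, theta


def _angle_in_span(theta: np.ndarray, span: Tuple[float, float]) -> np.ndarray:
    a = span[0] % 360.0
    b = span[1] % 360.0
    if a < b:
        return (theta >= a) & (theta < b)
    return (theta >= a) | (theta < b)


def _span_width(span: Tuple[float, float]) -> float:
    return (span[1] - span[0]) % 360.0 or 360.0


def _lesion_layer(
    cfg: SynthConfig,
    rr: np.ndarray,
    theta: np.ndarray,
    fundus_r: float,
    span: Tuple[float, float],
    band: Tuple[float, float],
    phase: float,
    shallow: bool,
) -> Tuple[np.ndarray, np.ndarray]:
    """Additive lesion intensity layer and its binary mask.

    The layer is a deterministic function of radius and clock angle only, so
    horizontally mirroring the lesion specification mirrors the layer.
    """
    r_lo, r_hi = band[0] * fundus_r, band[1] * fundus_r
    mask = _angle_in_span(theta, span) & (rr >= r_lo) & (rr < r_hi)
    lift = cfg.lesion_lift * (cfg.shallow_factor if shallow else 1.0)
    # Corrugation: ridges perpendicular to the radial direction.
    ripple = 1.0 + cfg.corrugation_amplitude * np.sin(
        2.0 * np.pi * rr / cfg.corrugation_period_px + phase
    )
    # Radial profile: full amplitude in the band core, fading toward both
    # band edges — emulates detachment that is conspicuous centrally and
    # shallow at the margins (the hard-to-recall part of the lesion).
    t = np.clip((rr - r_lo) / max(r_hi - r_lo, 1e-9), 0.0, 1.0)
    radial = 0.12 + 0.88 * np.sin(np.pi * t) ** 2
    # Angular profile: fade toward the wedge's angular edges.
    width = _span_width(span)
    ang = np.mod(theta - span[0], 360.0) / width
    angular = np.where(mask, 0.12 + 0.88 * np.sin(np.pi * np.clip(ang, 0, 1)) ** 2, 0.0)
    layer = np.where(mask, lift * ripple * radial * angular, 0.0)
    return layer.astype(np.float32), mask.astype(np.uint8)


def generate_fundus(config: SynthConfig) -> SyntheticSample:
    """Generate one synthetic sample; bit-identical for equal configs."""
    n = config.canvas_px
    rng = np.random.default_rng(config.seed)
    center = ((n - 1) / 2.0, (n - 1) / 2.0)
    fundus_r = config.fundus_radius_fraction * n
    disc_r = config.disc_radius_fraction * n
    disc_dx = config.disc_offset_fraction * n

    rr, theta = _polar_grids(n, center)
    fundus = rr <= fundus_r

    # --- canonical background (disc on image-right), random fields first ---
    texture = gaussian_filter(rng.standard_normal((n, n)), sigma=n / 32.0)
    texture = texture / (np.abs(texture).max() + 1e-12)
    grain = rng.standard_normal((n, n)) * config.noise_sigma

    base = np.zeros((n, n, 3), dtype=np.float32)
    falloff = 1.0 - 0.35 * (rr / max(fundus_r, 1e-9)) ** 2
    shade = (falloff + 0.08 * texture + grain) * fundus
    for c in range(3):
        base[:, :, c] = _FUNDUS_RGB[c] * shade

    # Optic disc (canonical: image-right of fovea) with a soft edge.
    disc_c = (center[0] + disc_dx, center[1])
    dd = np.hypot(
        np.arange(n)[None, :] - disc_c[0], np.arange(n)[:, None] - disc_c[1]
    )
    disc_soft = np.clip((disc_r - dd) / (0.25 * disc_r + 1e-9), 0.0, 1.0)
    for c in range(3):
        base[:, :, c] += (_DISC_RGB[c] - base[:, :, c]) * disc_soft * fundus

    # Foveal dip.
    fov_soft = np.clip((0.035 * n - rr) / (0.02 * n), 0.0, 1.0)
    base *= (1.0 - 0.25 * fov_soft)[:, :, None]

    # Optional rim distractors (bright arcs near the fundus edge).
    if config.artifact_level > 0:
        n_arcs = 1 + int(rng.integers(0, 3))
        arc = np.zeros((n, n), dtype=np.float32)
        for _ in range(n_arcs):
            a0 = float(rng.uniform(0, 360))
            aw = float(rng.uniform(15, 50))
            band = (rr > 0.90 * fundus_r) & (rr <= 1.02 * fundus_r)
            arc += (_angle_in_span(theta, (a0, a0 + aw)) & band).astype(np.float32)
        base += (config.artifact_level * np.clip(arc, 0, 1))[:, :, None]

    # --- laterality: mirror the background so the disc sits nasally ---
    if config.laterality == "OS":
        base = base[:, ::-1, :].copy()
        disc_c = ((n - 1) - disc_c[0], disc_c[1])

    # --- lesion (drawn in image space, deterministic in r and theta) ---
    is_rd = bool(rng.random() < config.rd_probability)
    mask = np.zeros((n, n), dtype=np.uint8)
    shallow = bool(config.shallow)
    if is_rd:
        if config.lesion_sector_span is not None:
            span = config.lesion_sector_span
        else:
            start = float(rng.uniform(0, 360))
            span = (start, start + float(rng.uniform(60, 150)))
        if config.lesion_radial_band is not None:
            band = config.lesion_radial_band
        else:
            lo = float(rng.uniform(0.15, 0.45))
            band = (lo, min(lo + float(rng.uniform(0.35, 0.55)), 0.97))
        phase = float(rng.uniform(0, 2 * np.pi))
        if not shallow and config.shallow_probability > 0:
            shallow = bool(rng.random() < config.shallow_probability)
        layer, mask = _lesion_layer(
            config, rr, theta, fundus_r, span, band, phase, shallow
        )
        mask &= fundus.astype(np.uint8)
        base += (layer * fundus)[:, :, None] * np.array(
            [1.0, 0.95, 0.9], dtype=np.float32
        )

    image = np.clip(base, 0.0, 1.0).astype(np.float32)

    frame = fit_frame(center, disc_c, disc_r, config.laterality, (n, n))
    rule = PartitionRule().scaled(n)
    partitions = anatomy.partition_vector(mask, frame, rule)
    zone = anatomy.primary_zone(mask, frame) if is_rd else None

    return SyntheticSample(
        image=image,
        truth_mask=mask,
        fovea=center,
        disc_center=disc_c,
        disc_radius=disc_r,
        laterality=config.laterality,
        is_rd=is_rd,
        truth_partitions=partitions,
        truth_primary_zone=zone,
        seed=config.seed,
    )


def generate_dataset(
    n: int, config_template: SynthConfig, seed: int = 0
) -> List[SyntheticSample]:
    """Generate ``n`` samples with per-sample seeds spawned from ``seed``.

    Laterality alternates on average 50/50; detachment status is an
    independent Bernoulli draw at the template's ``rd_probability``.
    """
    if n < 1:
        raise ValueError("n must be >= 1")
    ss = np.random.SeedSequence(seed)
    child_seeds = ss.generate_state(n, dtype=np.uint32)
    side_rng = np.random.default_rng(ss.spawn(1)[0])
    samples = []
    for i in range(n):
        lat = "OD" if side_rng.random() < 0.5 else "OS"
        cfg = dataclasses.replace(
            config_template, seed=int(child_seeds[i]), laterality=lat
        )
        samples.append(generate_fundus(cfg))
    return samples


def split_dataset(
    samples: Sequence[SyntheticSample], train_fraction: float, seed: int = 0
) -> Tuple[List[SyntheticSample], List[SyntheticSample]]:
    """Shuffled disjoint train/test split; train size = floor(n * fraction)."""
    if not 0.0 < train_fraction < 1.0:
        raise ValueError("train_fraction must be in (0, 1)")
    if len(samples) < 2:
        raise ValueError("need at least 2 samples to split")
    order = np.random.default_rng(seed).permutation(len(samples))
    n_train = int(np.floor(len(samples) * train_fraction))
    train = [samples[i] for i in order[:n_train]]
    test = [samples[i] for i in order[n_train:]]
    return train, test
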