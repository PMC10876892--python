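"""Shared fixtures: synthetic data and a small trained classifier."""

from __future__ import annotations

import math

import numpy as np
import pytest

from rdmap import synthdata, wsmodel


# ---------------------------------------------------------------------------
# independent brute-force geometry oracle (deliberately naive, per pixel)
# ---------------------------------------------------------------------------

def brute_force_geometry(mask, fovea, disc_center, disc_radius):
    """Per-pixel tally oracle: partition counts, zone counts, posterior count.

    Implemented with scalar math on each lesion pixel, independently of the
    vectorized implementation under test.
    """
    rot = math.atan2(disc_center[1] - fovea[1], disc_center[0] - fovea[0])
    if math.cos(rot) < 0:
        rot += math.pi
    ppr = math.hypot(disc_center[0] - fovea[0], disc_center[1] - fovea[1]) + disc_radius
    part_counts = [0] * 48
    zone_counts = {"superior": 0, "right": 0, "inferior": 0, "left": 0}
    posterior_count = 0
    ys, xs = np.nonzero(np.asarray(mask))
    for y, x in zip(ys.tolist(), xs.tolist()):
        vx, vy = x - fovea[0], y - fovea[1]
        if vx == 0 and vy == 0:
            continue
        ux = vx * math.cos(rot) + vy * math.sin(rot)
        uy = -vx * math.sin(rot) + vy * math.cos(rot)
        theta = math.degrees(math.atan2(ux, -uy)) % 360.0
        sector = min(int(theta // 15.0), 23)
        ring = 0 if math.hypot(vx, vy) <= ppr else 1
        part_counts[ring * 24 + sector] += 1
        hour = theta / 30.0
        if hour >= 10 or hour < 2:
            zone_counts["superior"] += 1
        elif hour < 4:
            zone_counts["right"] += 1
        elif hour < 8:
            zone_counts["inferior"] += 1
        else:
            zone_counts["left"] += 1
        if ring == 0:
            posterior_count += 1
    return part_counts, zone_counts, posterior_count


@pytest.fixture(scope="session")
def train_samples():
    cfg = synthdata.SynthConfig(
        canvas_px=128, rd_probability=0.5, shallow_probability=0.25
    )
    return synthdata.generate_dataset(120, cfg, seed=21)


@pytest.fixture(scope="session")
def holdout_samples():
    # clear (non-shallow) lesions: the accuracy contract applies to
    # conspicuous detachment, shallow cases are the documented hard misses
    cfg = synthdata.SynthConfig(canvas_px=128, rd_probability=0.5)
    return synthdata.generate_dataset(60, cfg, seed=22)


@pytest.fixture(scope="session")
def train_config():
    return wsmodel.TrainConfig(
        input_resolution=128,
        epochs_pretrain=10,
        epochs_finetune=3,
        batch_size=16,
        seed=0,
    )


@pytest.fixture(scope="session")
def train_inputs(train_samples, train_config):
    return wsmodel.prepare_inputs(train_samples, train_config.input_resolution)


@pytest.fixture(scope="session")
def holdout_inputs(holdout_samples, train_config):
    return wsmodel.prepare_inputs(holdout_samples, train_config.input_resolution)


@pytest.fixture(scope="session")
def tiny_model(train_config, train_inputs):
    return wsmodel.train_classifier(None, train_config, inputs=train_inputs)
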