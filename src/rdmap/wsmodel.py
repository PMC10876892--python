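"""Staged residual classifier with focal loss and attention modulation.

The detachment/no-detachment classifier is a four-stage residual network
(depth configurable; desk-scale default is tiny) trained in two phases:

1. pretrain with focal loss (alpha 0.65, gamma 1.15) at learning rate 0.01;
2. fine-tune at learning rate 0.001 with attention modulation modules (AMM)
   inserted between every two consecutive stages.

An AMM recalibrates per-channel importance so that minor-but-relevant
channels contribute to the stage-4 activation maps used for localization:
``y = x * (1 + lambda * a_tilde)`` where ``a_tilde`` blends a learned
channel attention with a rank-inverted measured importance (channels with
low pooled activation receive the largest boost).  ``lambda = 0`` is the
identity, recovering the pretrained classifier exactly.
"""

from __future__ import annotations

import json
from dataclasses import dataclass
from typing import List, Optional, Sequence, Tuple

import numpy as np
from skimage.transform import resize

from ._nn import (
    SGD,
    BatchNorm2d,
    Conv2d,
    GlobalAvgPool,
    Layer,
    Linear,
    ReLU,
    Sequential,
    sigmoid,
)
from .preprocess import apply_roi_template, build_roi_template, clahe_enhance

__all__ = [
    "TrainConfig",
    "AmmParams",
    "AMM",
    "Backbone",
    "focal_loss",
    "amm_modulate",
    "channel_importance",
    "prepare_inputs",
    "train_classifier",
    "finetune_with_amm",
    "classify_rd",
    "save_model",
    "load_model",
]

_DEPTHS = {
    # name -> (base width, blocks per stage)
    "tiny": (8, (1, 1, 1, 1)),
    "resnet18-like": (16, (2, 2, 2, 2)),
    "resnet101-like": (32, (3, 4, 23, 3)),
}


@dataclass(frozen=True)
class TrainConfig:
    """Training hyper-parameters; defaults follow the reference protocol."""

    input_resolution: int = 128
    lr_pretrain: float = 0.01
    lr_finetune: float = 0.001
    focal_alpha: float = 0.65
    focal_gamma: float = 1.15
    epochs_pretrain: int = 8
    epochs_finetune: int = 4
    batch_size: int = 16
    backbone_depth: str = "tiny"
    seed: int = 0
    decision_threshold: float = 0.5
    momentum: float = 0.9
    weight_decay: float = 1e-4

    def __post_init__(self) -> None:
        if self.lr_pretrain <= 0 or self.lr_finetune <= 0:
            raise ValueError("learning rates must be positive")
        if not 0.0 < self.focal_alpha < 1.0:
            raise ValueError("focal_alpha must be in (0, 1)")
        if self.focal_gamma < 0:
            raise ValueError("focal_gamma must be >= 0")
        if self.input_resolution not in (64, 128, 256, 512, 1024):
            raise ValueError("input_resolution not in the allowed set")
        if self.backbone_depth not in _DEPTHS:
            raise ValueError(f"unknown backbone_depth {self.backbone_depth!r}")


@dataclass(frozen=True)
class AmmParams:
    """Attention-modulation hyper-parameters; ``lam=0`` disables modulation."""

    reduction_ratio: int = 4
    lam: float = 1.0
    seed: int = 0

    def __post_init__(self) -> None:
        if self.lam < 0:
            raise ValueError("lam must be >= 0")
        if self.reduction_ratio < 1:
            raise ValueError("reduction_ratio must be >= 1")


def focal_loss(p, alpha: float = 0.65, gamma: float = 1.15, positive: bool = True):
    """Focal loss for the true-class probability ``p``: -w (1-p)^gamma log p.

    ``w`` is ``alpha`` for the positive class and ``1 - alpha`` otherwise.
    Reduces to weighted cross-entropy at ``gamma = 0``.
    """
    p = np.asarray(p, dtype=np.float64)
    if np.any(p <= 0) or np.any(p >= 1):
        raise ValueError("p must lie strictly inside (0, 1)")
    w = alpha if positive else 1.0 - alpha
    out = -w * (1.0 - p) ** gamma * np.log(p)
    return float(out) if out.ndim == 0 else out


def channel_importance(x: np.ndarray) -> np.ndarray:
    """Normalized per-channel importance (mean |activation|, summing to 1)."""
    x = np.asarray(x)
    if x.ndim == 3:
        x = x[None]
    s = np.abs(x).mean(axis=(0, 2, 3))
    total = s.sum()
    return s / total if total > 0 else s


class AMM(Layer):
    """Channel attention + rank-inverted recalibration, shape preserving."""

    def __init__(self, c: int, params: AmmParams, rng: Optional[np.random.Generator] = None):
        from ._nn import he_init

        rng = rng or np.random.default_rng(params.seed)
        cr = max(1, c // params.reduction_ratio)
        self.c, self.lam = c, params.lam
        self.w1 = he_init(rng, (cr, c), c)
        self.b1 = np.zeros(cr, dtype=np.float32)
        self.w2 = he_init(rng, (c, cr), cr)
        self.b2 = np.zeros(c, dtype=np.float32)
        self.dw1 = np.zeros_like(self.w1)
        self.db1 = np.zeros_like(self.b1)
        self.dw2 = np.zeros_like(self.w2)
        self.db2 = np.zeros_like(self.b2)

    def params(self):
        return [self.w1, self.b1, self.w2, self.b2]

    def grads(self):
        return [self.dw1, self.db1, self.dw2, self.db2]

    def modulation(self, x: np.ndarray) -> np.ndarray:
        """Per-channel multiplier ``1 + lam * a_tilde`` for input ``x``."""
        s = x.mean(axis=(2, 3))  # (N, C) pooled importance
        z1 = s @ self.w1.T + self.b1
        h = np.maximum(z1, 0.0)
        a = sigmoid(h @ self.w2.T + self.b2)
        # Rank-inverted measured importance: the weakest channel gets 1.
        order = np.argsort(np.argsort(s, axis=1), axis=1)
        inv_rank = 1.0 - order / max(self.c - 1, 1)
        a_tilde = 0.5 * (a + inv_rank)
        self._cache = (x, s, z1, h, a)
        return 1.0 + self.lam * a_tilde

    def forward(self, x, train=False):
        if self.lam == 0.0:
            self._m = None
            return x
        m = self.modulation(x)
        self._m = m.astype(np.float32)
        return x * self._m[:, :, None, None]

    def backward(self, dy):
        if self._m is None:
            return dy
        x, s, z1, h, a = self._cache
        n, c, hh, ww = x.shape
        dx = dy * self._m[:, :, None, None]
        dm = (dy * x).sum(axis=(2, 3))  # (N, C)
        # rank term treated as constant (piecewise-constant in s)
        da = 0.5 * self.lam * dm
        dz2 = da * a * (1.0 - a)
        self.dw2 += (dz2.T @ h).astype(np.float32)
        self.db2 += dz2.sum(axis=0).astype(np.float32)
        dh = dz2 @ self.w2
        dz1 = dh * (z1 > 0)
        self.dw1 += (dz1.T @ s).astype(np.float32)
        self.db1 += dz1.sum(axis=0).astype(np.float32)
        ds = dz1 @ self.w1
        return dx + ds[:, :, None, None] / (hh * ww)


def amm_modulate(features: np.ndarray, params: AmmParams) -> np.ndarray:
    """Standalone attention modulation of a feature tensor.

    Accepts ``(C, H, W)`` or ``(N, C, H, W)``; weights of the transient
    attention bottleneck are seeded from ``params.seed``.
    """
    x = np.asarray(features, dtype=np.float32)
    single = x.ndim == 3
    if single:
        x = x[None]
    if x.ndim != 4 or x.size == 0:
        raise ValueError("features must be a non-empty (N,)C,H,W tensor")
    amm = AMM(x.shape[1], params)
    y = amm.forward(x)
    return y[0] if single else y


class _ResBlock(Layer):
    def __init__(self, cin, cout, stride, rng):
        self.conv1 = Conv2d(cin, cout, 3, stride, rng=rng)
        self.bn1 = BatchNorm2d(cout)
        self.relu1 = ReLU()
        self.conv2 = Conv2d(cout, cout, 3, 1, rng=rng)
        self.bn2 = BatchNorm2d(cout)
        if cin != cout or stride != 1:
            self.proj: Optional[Sequential] = Sequential(
                Conv2d(cin, cout, 1, stride, pad=0, rng=rng), BatchNorm2d(cout)
            )
        else:
            self.proj = None
        self.relu_out = ReLU()

    def params(self):
        ps = self.conv1.params() + self.bn1.params() + self.conv2.params() + self.bn2.params()
        if self.proj is not None:
            ps += self.proj.params()
        return ps

    def grads(self):
        gs = self.conv1.grads() + self.bn1.grads() + self.conv2.grads() + self.bn2.grads()
        if self.proj is not None:
            gs += self.proj.grads()
        return gs

    def forward(self, x, train=False):
        y = self.conv1.forward(x, train)
        y = self.bn1.forward(y, train)
        y = self.relu1.forward(y, train)
        y = self.conv2.forward(y, train)
        y = self.bn2.forward(y, train)
        s = x if self.proj is None else self.proj.forward(x, train)
        return self.relu_out.forward(y + s, train)

    def backward(self, dy):
        d = self.relu_out.backward(dy)
        dmain = self.bn2.backward(d)
        dmain = self.conv2.backward(dmain)
        dmain = self.relu1.backward(dmain)
        dmain = self.bn1.backward(dmain)
        dmain = self.conv1.backward(dmain)
        dskip = d if self.proj is None else self.proj.backward(d)
        return dmain + dskip


class Backbone:
    """Four-stage residual classifier with AMM insertion points.

    The forward path is ``stem -> stage1 [AMM] stage2 [AMM] stage3 [AMM]
    stage4 -> GAP -> linear logit``.  Stage-4 feature maps and their
    gradients are exposed for Grad-CAM.
    """

    def __init__(self, config: TrainConfig):
        self.config = config
        width, blocks = _DEPTHS[config.backbone_depth]
        rng = np.random.default_rng(config.seed)
        w = width
        self.stem = Sequential(
            Conv2d(3, w, 3, 2, rng=rng), BatchNorm2d(w), ReLU()
        )
        widths = [w, 2 * w, 4 * w, 4 * w]
        strides = [2, 2, 2, 1]
        cin = w
        self.stages: List[Sequential] = []
        for cout, stride, nb in zip(widths, strides, blocks):
            layers = [_ResBlock(cin, cout, stride, rng)]
            layers += [_ResBlock(cout, cout, 1, rng) for _ in range(nb - 1)]
            self.stages.append(Sequential(*layers))
            cin = cout
        self.stage_widths = widths
        self.amms: List[Optional[AMM]] = [None, None, None]
        self.gap = GlobalAvgPool()
        self.head = Linear(widths[-1], 1, rng=rng)
        self.train_log: List[dict] = []

    # -- structure ---------------------------------------------------------
    def insert_amms(self, params: AmmParams) -> None:
        rng = np.random.default_rng(params.seed)
        for i in range(3):
            self.amms[i] = AMM(self.stage_widths[i], params, rng=rng)

    def remove_amms(self) -> None:
        self.amms = [None, None, None]

    @property
    def amm_active(self) -> bool:
        return any(a is not None for a in self.amms)

    def params(self):
        ps = self.stem.params()
        for st in self.stages:
            ps += st.params()
        for a in self.amms:
            if a is not None:
                ps += a.params()
        return ps + self.head.params()

    def grads(self):
        gs = self.stem.grads()
        for st in self.stages:
            gs += st.grads()
        for a in self.amms:
            if a is not None:
                gs += a.grads()
        return gs + self.head.grads()

    # -- compute -----------------------------------------------------------
    def _pipeline(self) -> List[Layer]:
        seq: List[Layer] = [self.stem]
        for i, st in enumerate(self.stages):
            seq.append(st)
            if i < 3 and self.amms[i] is not None:
                seq.append(self.amms[i])
        return seq

    def forward(self, x: np.ndarray, train: bool = False) -> np.ndarray:
        """Logits (N,) for a (N, 3, H, W) batch."""
        self._layers = self._pipeline()
        for l in self._layers:
            x = l.forward(x, train=train)
        self._stage4 = x
        p = self.gap.forward(x, train)
        return self.head.forward(p, train)[:, 0]

    def backward(self, dlogit: np.ndarray) -> np.ndarray:
        dy = self.head.backward(dlogit[:, None])
        dy = self.gap.backward(dy)
        for l in reversed(self._layers):
            dy = l.backward(dy)
        return dy

    def stage4_features_and_grads(self, x: np.ndarray) -> Tuple[np.ndarray, np.ndarray]:
        """Stage-4 feature maps and d(logit)/d(features) for one batch."""
        self.forward(x, train=False)
        feats = self._stage4
        ones = np.ones(x.shape[0], dtype=np.float64)
        dy = self.head.backward(ones[:, None])
        dfeats = self.gap.backward(dy)
        # clear parameter grads touched by this probe
        for g in self.head.grads():
            g[...] = 0.0
        return feats, dfeats

    def predict_proba(self, x: np.ndarray) -> np.ndarray:
        return sigmoid(self.forward(x, train=False))


# ---------------------------------------------------------------------------
# training
# ---------------------------------------------------------------------------

def _focal_loss_and_grad(z, y, alpha, gamma):
    """Mean focal loss over a batch of logits + gradient wrt logits."""
    p = np.clip(sigmoid(z), 1e-7, 1.0 - 1e-7)
    q = np.where(y == 1, p, 1.0 - p)
    w = np.where(y == 1, alpha, 1.0 - alpha)
    one_minus_q = 1.0 - q
    loss = float(np.mean(-w * one_minus_q**gamma * np.log(q)))
    if gamma == 0:
        dldq = -w / q
    else:
        dldq = w * (gamma * one_minus_q ** (gamma - 1.0) * np.log(q)
                    - one_minus_q**gamma / q)
    dqdz = np.where(y == 1, 1.0, -1.0) * p * (1.0 - p)
    return loss, (dldq * dqdz) / len(z)


def prepare_inputs(
    samples: Sequence,
    resolution: int,
    clahe: bool = True,
    fundus_radius_fraction: float = 0.48,
) -> Tuple[np.ndarray, np.ndarray]:
    """ROI-mask, CLAHE-enhance and resize samples into (N,3,R,R) + labels."""
    roi = build_roi_template(resolution, fundus_radius_fraction)
    xs, ys = [], []
    for s in samples:
        img = s.image
        if img.shape[0] != resolution:
            img = resize(img, (resolution, resolution), order=1,
                         anti_aliasing=img.shape[0] > resolution,
                         preserve_range=True)
        if clahe:
            img = clahe_enhance(img)
        img = apply_roi_template(img, roi)
        xs.append(np.transpose(img, (2, 0, 1)).astype(np.float32))
        ys.append(1 if s.is_rd else 0)
    return np.stack(xs), np.asarray(ys, dtype=np.int64)


def _train_loop(model, x, y, lr, epochs, config, phase):
    rng = np.random.default_rng(config.seed + (1 if phase == "finetune" else 0))
    if phase == "finetune":
        # Fine-tuning adapts only the modulation parameters; the pretrained
        # extractor (including batch-norm statistics) and head stay frozen
        # so recalibration cannot collapse back onto the most
        # discriminative regions.
        params, grads = [], []
        for a in model.amms:
            if a is not None:
                params += a.params()
                grads += a.grads()
        # the head bias recenters the logit scale shift introduced by the
        # modulation; it does not enter the activation-map weights
        params.append(model.head.b)
        grads.append(model.head.db)
    else:
        params, grads = model.params(), model.grads()
    opt = SGD(params, grads, lr=lr,
              momentum=config.momentum, weight_decay=config.weight_decay)
    n = len(x)
    bs = min(config.batch_size, n)
    train_flag = phase != "finetune"
    for epoch in range(epochs):
        order = rng.permutation(n)
        losses, correct = [], 0
        for start in range(0, n, bs):
            idx = order[start : start + bs]
            xb, yb = x[idx], y[idx]
            opt.zero_grad()
            z = model.forward(xb, train=train_flag)
            loss, dz = _focal_loss_and_grad(
                z, yb, config.focal_alpha, config.focal_gamma
            )
            model.backward(dz)
            opt.step()
            losses.append(loss)
            correct += int(np.sum((sigmoid(z) >= 0.5) == (yb == 1)))
        model.train_log.append(
            {
                "phase": phase,
                "epoch": epoch,
                "loss": float(np.mean(losses)),
                "accuracy": correct / n,
            }
        )
    return model


def train_classifier(train_samples, config: TrainConfig,
                     inputs: Optional[Tuple[np.ndarray, np.ndarray]] = None) -> Backbone:
    """Phase-1 pretraining of the plain classifier (no AMM active)."""
    if inputs is not None:
        x, y = inputs
    else:
        x, y = prepare_inputs(train_samples, config.input_resolution)
    if len(x) == 0:
        raise ValueError("empty training set")
    if len(np.unique(y)) < 2:
        raise ValueError("training set must contain both classes")
    model = Backbone(config)
    return _train_loop(model, x, y, config.lr_pretrain,
                       config.epochs_pretrain, config, "pretrain")


def finetune_with_amm(model: Backbone, train_samples, config: TrainConfig,
                      amm: Optional[AmmParams] = None,
                      inputs: Optional[Tuple[np.ndarray, np.ndarray]] = None) -> Backbone:
    """Phase-2 fine-tuning with AMMs inserted between consecutive stages."""
    if inputs is not None:
        x, y = inputs
    else:
        x, y = prepare_inputs(train_samples, config.input_resolution)
    amm = amm or AmmParams(seed=config.seed)
    model.insert_amms(amm)
    if amm.lam == 0.0:
        # identity modulation: nothing to fine-tune, model is unchanged
        return model
    _train_loop(model, x, y, config.lr_finetune,
                config.epochs_finetune, config, "finetune")
    # Recenter the logit scale: the modulation shifts the mean logit, which
    # the frozen head cannot absorb at desk-scale step counts.  Subtract the
    # mean train-set shift relative to identity modulation (deterministic).
    z_mod = _batched_logits(model, x, config.batch_size)
    lams = [(a, a.lam) for a in model.amms if a is not None]
    for a, _ in lams:
        a.lam = 0.0
    z_plain = _batched_logits(model, x, config.batch_size)
    for a, lam in lams:
        a.lam = lam
    model.head.b -= np.float32(np.mean(z_mod - z_plain))
    return model


def _batched_logits(model: "Backbone", x: np.ndarray, batch_size: int) -> np.ndarray:
    outs = [model.forward(x[i : i + batch_size], train=False)
            for i in range(0, len(x), batch_size)]
    return np.concatenate(outs)


def classify_rd(model: Backbone, image: np.ndarray,
                threshold: float = 0.5) -> Tuple[float, bool]:
    """Probability of detachment and thresholded label for one image.

    ``image`` is (3, R, R) or (R, R, 3) at the model's input resolution;
    the label uses the >= convention at the boundary.
    """
    img = np.asarray(image, dtype=np.float32)
    if img.ndim == 3 and img.shape[-1] == 3 and img.shape[0] != 3:
        img = np.transpose(img, (2, 0, 1))
    if img.shape[1] != model.config.input_resolution:
        raise ValueError(
            f"image resolution {img.shape[1]} != model resolution "
            f"{model.config.input_resolution}"
        )
    prob = float(model.predict_proba(img[None])[0])
    return prob, prob >= threshold


# ---------------------------------------------------------------------------
# serialization
# ---------------------------------------------------------------------------

def save_model(model: Backbone, path: str) -> None:
    """Checkpoint as .npz plus a JSON descriptor alongside."""
    base = str(path)
    if base.endswith(".npz"):
        base = base[:-4]
    arrays = {f"p{i}": p for i, p in enumerate(model.params())}
    bn_state = {}
    i = 0
    for layer in _iter_bn(model):
        bn_state[f"bn{i}_mean"] = layer.running_mean
        bn_state[f"bn{i}_var"] = layer.running_var
        i += 1
    np.savez(base + ".npz", **arrays, **bn_state)
    desc = {
        "config": model.config.__dict__,
        "amm_active": model.amm_active,
        "stage_widths": model.stage_widths,
        "train_log": model.train_log,
    }
    with open(base + ".json", "w") as fh:
        json.dump(desc, fh, indent=1)


def _iter_bn(model: Backbone):
    def walk(layer):
        if isinstance(layer, BatchNorm2d):
            yield layer
        for attr in ("layers",):
            for sub in getattr(layer, attr, []):
                yield from walk(sub)
        for attr in ("conv1", "bn1", "conv2", "bn2", "proj"):
            sub = getattr(layer, attr, None)
            if sub is not None:
                yield from walk(sub)

    yield from walk(model.stem)
    for st in model.stages:
        yield from walk(st)


def load_model(path: str) -> Backbone:
    base = str(path)
    if base.endswith(".npz"):
        base = base[:-4]
    with open(base + ".json") as fh:
        desc = json.load(fh)
    cfg = TrainConfig(**desc["config"])
    model = Backbone(cfg)
    if desc["amm_active"]:
        model.insert_amms(AmmParams(seed=cfg.seed))
    data = np.load(base + ".npz")
    for i, p in enumerate(model.params()):
        p[...] = data[f"p{i}"]
    for i, layer in enumerate(_iter_bn(model)):
        layer.running_mean = data[f"bn{i}_mean"]
        layer.running_var = data[f"bn{i}_var"]
    model.train_log = desc.get("train_log", [])
    return model
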