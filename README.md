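# rdmap

Weakly-supervised localization of retinal detachment (RD) on
ultra-widefield-fundus-like images, with anatomical zoning and preoperative
postural guidance. The package is fully self-contained at desk scale: a
seeded synthetic fundus generator provides images, landmarks and exact
ground-truth lesion masks, so the whole pipeline trains, localizes and
evaluates on one CPU with no external data.

## What it does

1. **synthdata** — generates fundus-like canvases (circular field, four
   information-free corners, laterality-dependent optic disc, foveal dip)
   with optional bright corrugated wedge lesions (including low-contrast
   "shallow" variants) and exact truth masks/partition labels.
2. **preprocess** — analytic ROI template that erases the corners, plus
   CLAHE luminance enhancement.
3. **wsmodel** — a four-stage residual RD/Non-RD classifier (NumPy, manual
   backprop) trained with focal loss (alpha 0.65, gamma 1.15, lr 0.01),
   then fine-tuned (lr 0.001) with attention modulation modules (AMM)
   inserted between consecutive stages. The AMM recalibrates channel
   importance so minor-but-relevant activations survive into the
   localization maps; the pretrained extractor stays frozen during
   fine-tuning.
4. **camloc** — Grad-CAM on stage-4 features, min-max normalization over
   the ROI, bilinear resampling to the image grid, and binary pseudo-masks
   at probability threshold 0.5.
5. **landmarks** — fovea from JSON sidecars (manual annotation stand-in)
   and optic disc from a small encoder-decoder segmentation network,
   reduced to center + equivalent-circle radius.
6. **anatomy** — the fovea/disc-calibrated frame: four clock-hour zones
   (superior 10–2, right 2–4, inferior 4–8, left 8–10), the posterior-pole
   circle (fovea-centered, containing the disc), and 48 partitions
   (24 sectors of 15 degrees x inner/outer ring); a partition is positive
   when it holds more than 50 lesion pixels (at the 512-px reference grid,
   scaled quadratically elsewhere).
7. **guidance** — posture rules (superior → supine, inferior → sitting,
   right/left → lateral decubitus; posterior-pole involvement forces supine
   plus urgent referral) and structured per-image report records.
8. **evalmetrics** — pooled partition precision/recall/F1 with Wilson 95%
   CIs, posterior-pole sensitivity/specificity/accuracy, PR curve and
   average precision, unweighted Cohen's kappa, 4x4 zone confusion matrix,
   mask IoU.

## CLI

```bash
rdmap synth    --out runs/demo --set synth.n=200 --set seed=1
rdmap train    --out runs/demo
rdmap localize --out runs/demo
rdmap zone     --out runs/demo
rdmap guide    --out runs/demo
rdmap eval     --out runs/demo
rdmap report   --out runs/demo
```

Configuration is a single YAML tree (`--config FILE`) with dotted-path
overrides (`--set train.epochs_pretrain=10`). Defaults follow the reference
protocol (focal alpha 0.65 / gamma 1.15, lr 0.01 / 0.001, threshold 0.5,
50-pixel rule) with a desk-scale profile (128-px canvas, tiny backbone).
Every run writes its resolved config next to its artifacts; each stage is
re-entrant and deterministic for a fixed seed.

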