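"""End-to-end orchestration of the localization pipeline stages.

Each stage consumes only declared artifacts from the run directory and is
re-entrant: re-running with the same config and seed reproduces outputs.

Layout of a run directory::

    dataset/               images/, masks/, sidecars/, manifest.csv
    models/                model_baseline.npz(.json), model_amm.npz(.json)
    localization/          maps/*.png (16-bit), pred_masks/*.png, probs.csv
    partitions.csv         image_id, bits, primary_zone, posterior_involved
    guidance.jsonl         one record per image
    eval/                  eval.json, pr_curve.csv, confusion.csv, plots
    report.html
"""

from __future__ import annotations

import json
from pathlib import Path
from typing import Dict, List

import matplotlib

matplotlib.use("Agg")
import matplotlib.pyplot as plt
import numpy as np
import pandas as pd

from . import anatomy, camloc, evalmetrics, guidance, io, landmarks, synthdata, wsmodel
from .anatomy import PartitionRule
from .preprocess import build_roi_template
from .synthdata import SynthConfig

__all__ = [
    "run_synth",
    "run_train",
    "run_localize",
    "run_zone",
    "run_guide",
    "run_eval",
    "run_report",
]


def _rule(cfg: dict) -> PartitionRule:
    base = PartitionRule(
        min_pixels=cfg["anatomy"]["min_pixels"],
        evaluation_resolution=cfg["anatomy"]["reference_resolution"],
    )
    return base.scaled(cfg["synth"]["canvas_px"])


def _train_config(cfg: dict) -> wsmodel.TrainConfig:
    t = cfg["train"]
    return wsmodel.TrainConfig(
        input_resolution=t["input_resolution"],
        lr_pretrain=t["lr_pretrain"],
        lr_finetune=t["lr_finetune"],
        focal_alpha=t["focal_alpha"],
        focal_gamma=t["focal_gamma"],
        epochs_pretrain=t["epochs_pretrain"],
        epochs_finetune=t["epochs_finetune"],
        batch_size=t["batch_size"],
        backbone_depth=t["backbone_depth"],
        seed=cfg["seed"],
        decision_threshold=t["decision_threshold"],
    )


def run_synth(cfg: dict, outdir: str | Path) -> pd.DataFrame:
    out = Path(outdir)
    s = cfg["synth"]
    template = SynthConfig(
        canvas_px=s["canvas_px"],
        rd_probability=s["rd_probability"],
        shallow_probability=s.get("shallow_probability", 0.0),
        artifact_level=s.get("artifact_level", 0.0),
        fundus_radius_fraction=cfg["roi"]["fundus_radius_fraction"],
    )
    samples = synthdata.generate_dataset(s["n"], template, seed=cfg["seed"])
    train, test = synthdata.split_dataset(
        samples, s["train_fraction"], seed=cfg["seed"]
    )
    split_of = {id(x): "train" for x in train}
    split_of.update({id(x): "test" for x in test})
    splits = [split_of[id(x)] for x in samples]
    return io.save_dataset(samples, out / "dataset", splits=splits)


def run_train(cfg: dict, outdir: str | Path) -> Dict[str, str]:
    out = Path(outdir)
    train_samples = io.load_dataset(out / "dataset", split="train")
    tc = _train_config(cfg)
    inputs = wsmodel.prepare_inputs(
        train_samples, tc.input_resolution,
        fundus_radius_fraction=cfg["roi"]["fundus_radius_fraction"],
    )
    (out / "models").mkdir(parents=True, exist_ok=True)
    model = wsmodel.train_classifier(None, tc, inputs=inputs)
    wsmodel.save_model(model, out / "models" / "model_baseline.npz")
    amm = wsmodel.AmmParams(
        reduction_ratio=cfg["amm"]["reduction_ratio"],
        lam=cfg["amm"]["lam"],
        seed=cfg["seed"],
    )
    wsmodel.finetune_with_amm(model, None, tc, amm=amm, inputs=inputs)
    wsmodel.save_model(model, out / "models" / "model_amm.npz")
    pd.DataFrame(model.train_log).to_csv(out / "models" / "train_log.csv", index=False)
    return {
        "baseline": str(out / "models" / "model_baseline.npz"),
        "amm": str(out / "models" / "model_amm.npz"),
    }


def run_localize(cfg: dict, outdir: str | Path, which: str = "amm") -> pd.DataFrame:
    out = Path(outdir)
    model_path = out / "models" / f"model_{which}.npz"
    if not model_path.exists():
        raise FileNotFoundError(f"missing model checkpoint {model_path}; run train")
    model = wsmodel.load_model(model_path)
    test_samples = io.load_dataset(out / "dataset", split="test")
    manifest = pd.read_csv(out / "dataset" / "manifest.csv")
    ids = list(manifest[manifest["split"] == "test"]["image_id"])
    canvas = cfg["synth"]["canvas_px"]
    roi = build_roi_template(canvas, cfg["roi"]["fundus_radius_fraction"])
    maps_dir = out / "localization" / "maps"
    masks_dir = out / "localization" / "pred_masks"
    maps_dir.mkdir(parents=True, exist_ok=True)
    masks_dir.mkdir(parents=True, exist_ok=True)
    x, _ = wsmodel.prepare_inputs(
        test_samples, model.config.input_resolution,
        fundus_radius_fraction=cfg["roi"]["fundus_radius_fraction"],
    )
    rows = []
    thr = cfg["camloc"]["threshold"]
    for sid, xi, sample in zip(ids, x, test_samples):
        prob = float(model.predict_proba(xi[None])[0])
        pmap, mask = camloc.localize(model, xi, canvas, roi=roi, threshold=thr)
        io.save_probability_map(pmap.values, maps_dir / f"{sid}.png")
        io.save_mask(mask.mask, masks_dir / f"{sid}.png")
        rows.append({"image_id": sid, "probability": prob,
                     "predicted_rd": prob >= cfg["train"]["decision_threshold"]})
    probs = pd.DataFrame(rows)
    probs.to_csv(out / "localization" / "probs.csv", index=False)
    return probs


def _frames_for(cfg: dict, outdir: Path, ids: List[str]):
    """Frame per image from sidecar landmarks (optionally a segmented disc)."""
    disc_source = cfg["disc"]["source"]
    seg_model = None
    if disc_source == "segmented":
        train_samples = io.load_dataset(outdir / "dataset", split="train")
        seg_model = landmarks.train_disc_segmenter(
            train_samples[: min(len(train_samples), 40)],
            epochs=cfg["disc"]["epochs"], seed=cfg["seed"],
        )
    frames, sources = {}, {}
    for sid in ids:
        with open(outdir / "dataset" / "sidecars" / f"{sid}.json") as fh:
            sc = json.load(fh)
        fovea, disc = landmarks.read_landmarks(sc)
        if not fovea.present:
            continue  # macula-off: excluded from anatomical evaluation
        source = "sidecar"
        if seg_model is not None:
            sample = io.load_sample(outdir / "dataset", sid)
            try:
                geom = landmarks.extract_disc_geometry(
                    landmarks.segment_disc(sample.image, seg_model)
                )
                disc, source = geom, "segmented"
            except ValueError:
                source = "sidecar-fallback"
        if disc is None:
            continue
        canvas = (cfg["synth"]["canvas_px"], cfg["synth"]["canvas_px"])
        frames[sid] = anatomy.fit_frame(
            fovea.position, disc.center, disc.radius, sc["laterality"], canvas
        )
        sources[sid] = source
    return frames, sources


def run_zone(cfg: dict, outdir: str | Path) -> pd.DataFrame:
    out = Path(outdir)
    masks_dir = out / "localization" / "pred_masks"
    if not masks_dir.exists():
        raise FileNotFoundError("missing localization artifacts; run localize")
    probs = pd.read_csv(out / "localization" / "probs.csv")
    ids = list(probs["image_id"])
    rule = _rule(cfg)
    frames, sources = _frames_for(cfg, out, ids)
    rows = []
    for sid in ids:
        if sid not in frames:
            continue
        mask = io.load_mask(masks_dir / f"{sid}.png")
        frame = frames[sid]
        bits = anatomy.partition_vector(mask, frame, rule)
        zone = anatomy.primary_zone(mask, frame)
        post = anatomy.posterior_involved(mask, frame, rule)
        rows.append(
            {
                "image_id": sid,
                "bits": "".join(str(int(b)) for b in bits),
                "primary_zone": zone if zone is not None else "",
                "posterior_involved": bool(post),
                "landmark_source": sources[sid],
            }
        )
    table = pd.DataFrame(
        rows, columns=["image_id", "bits", "primary_zone",
                       "posterior_involved", "landmark_source"]
    )
    table.to_csv(out / "partitions.csv", index=False)
    return table


def run_guide(cfg: dict, outdir: str | Path) -> List[dict]:
    out = Path(outdir)
    parts = pd.read_csv(out / "partitions.csv", dtype={"bits": str})
    probs = pd.read_csv(out / "localization" / "probs.csv").set_index("image_id")
    records = []
    for _, row in parts.iterrows():
        sid = row["image_id"]
        with open(out / "dataset" / "sidecars" / f"{sid}.json") as fh:
            sc = json.load(fh)
        prob = float(probs.loc[sid, "probability"])
        zone = row["primary_zone"] if isinstance(row["primary_zone"], str) and row["primary_zone"] else None
        is_rd = bool(probs.loc[sid, "predicted_rd"]) and zone is not None
        rec = guidance.guidance_record(
            image_id=sid,
            probability=prob,
            is_rd=is_rd,
            partitions=[int(c) for c in row["bits"]],
            primary_zone=zone if is_rd else None,
            posterior=bool(row["posterior_involved"]) if is_rd else False,
            laterality=sc["laterality"],
            landmark_source=row["landmark_source"],
            threshold=cfg["camloc"]["threshold"],
        )
        records.append(rec)
    with open(out / "guidance.jsonl", "w") as fh:
        for rec in records:
            fh.write(guidance.record_to_json(rec) + "\n")
    return records


def run_eval(cfg: dict, outdir: str | Path) -> dict:
    out = Path(outdir)
    parts = pd.read_csv(out / "partitions.csv", dtype={"bits": str}).set_index("image_id")
    rule = _rule(cfg)
    test_samples = io.load_dataset(out / "dataset", split="test")
    manifest = pd.read_csv(out / "dataset" / "manifest.csv")
    ids = list(manifest[manifest["split"] == "test"]["image_id"])

    preds, truths = [], []
    pm_values, pm_frames, pm_truth = [], [], []
    for sid, sample in zip(ids, test_samples):
        if not sample.is_rd or sid not in parts.index:
            continue  # anatomical evaluation is specific to detachment images
        frame = sample.frame()
        tv = anatomy.partition_vector(sample.truth_mask, frame, rule)
        t_zone = anatomy.primary_zone(sample.truth_mask, frame)
        t_post = anatomy.posterior_involved(sample.truth_mask, frame, rule)
        row = parts.loc[sid]
        pv = np.array([int(c) for c in row["bits"]], dtype=np.uint8)
        p_zone = row["primary_zone"] if isinstance(row["primary_zone"], str) and row["primary_zone"] else None
        preds.append(
            {"image_id": sid, "partitions": pv, "posterior": bool(row["posterior_involved"]),
             "primary_zone": p_zone}
        )
        truths.append(
            {"image_id": sid, "partitions": tv, "posterior": t_post,
             "primary_zone": t_zone}
        )
        map_path = out / "localization" / "maps" / f"{sid}.png"
        if map_path.exists():
            pm_values.append(io.load_probability_map(map_path))
            pm_frames.append(frame)
            pm_truth.append(tv)
    if not preds:
        raise ValueError("no detachment-positive test images to evaluate")

    report = evalmetrics.evaluate_localization(preds, truths, rule)
    if pm_values:
        thr = np.linspace(0.0, 1.0, cfg["eval"]["n_thresholds"])
        curve, ap = evalmetrics.pr_curve_ap(pm_values, pm_frames, pm_truth, rule, thr)
        report.pr_curve = curve
        report.average_precision = ap

    eval_dir = out / "eval"
    eval_dir.mkdir(parents=True, exist_ok=True)
    result = report.to_dict()
    with open(eval_dir / "eval.json", "w") as fh:
        json.dump(result, fh, indent=1)
    if report.pr_curve:
        pd.DataFrame(report.pr_curve).to_csv(eval_dir / "pr_curve.csv", index=False)
        fig, ax = plt.subplots(figsize=(4, 4))
        ax.plot([p["recall"] for p in report.pr_curve],
                [p["precision"] for p in report.pr_curve], marker=".")
        ax.set_xlabel("recall")
        ax.set_ylabel("precision")
        ax.set_title(f"AP = {report.average_precision:.4f}")
        fig.tight_layout()
        fig.savefig(eval_dir / "pr_curve.png", dpi=120)
        plt.close(fig)
    if report.confusion is not None:
        pd.DataFrame(
            report.confusion, index=list(anatomy.ZONES), columns=list(anatomy.ZONES)
        ).to_csv(eval_dir / "confusion.csv")
    return result


def run_report(cfg: dict, outdir: str | Path) -> str:
    out = Path(outdir)
    eval_path = out / "eval" / "eval.json"
    if not eval_path.exists():
        raise FileNotFoundError("missing eval artifacts; run eval")
    with open(eval_path) as fh:
        result = json.load(fh)

    def fmt(m):
        if m is None:
            return "n/a"
        return f"{m['value']:.4f} ({m['ci_low']:.4f}–{m['ci_high']:.4f})"

    part = result["partition"]
    lines = [
        "<html><head><title>Localization report</title></head><body>",
        "<h1>Detachment localization report</h1>",
        f"<p>{result['n_images']} images, "
        f"{result['n_partition_decisions']} partition decisions.</p>",
        "<h2>48-partition localization</h2><ul>",
        f"<li>precision: {fmt(part['precision'])}</li>",
        f"<li>recall: {fmt(part['recall'])}</li>",
        f"<li>F1: {fmt(part['f1'])}</li>",
        f"<li>average precision: {result.get('average_precision')}</li>",
        "</ul>",
    ]
    if result.get("posterior_pole"):
        pp = result["posterior_pole"]
        lines += [
            "<h2>Posterior-pole involvement</h2><ul>",
            f"<li>sensitivity: {fmt(pp['sensitivity'])}</li>",
            f"<li>specificity: {fmt(pp['specificity'])}</li>",
            f"<li>accuracy: {fmt(pp['accuracy'])}</li>",
            "</ul>",
        ]
    if result.get("four_zone"):
        fz = result["four_zone"]
        lines += [
            "<h2>Four-zone agreement</h2><ul>",
            f"<li>kappa: {fmt(fz['kappa'])}</li>",
            f"<li>accuracy: {fmt(fz['accuracy'])}</li>",
            "</ul>",
        ]
    if (out / "eval" / "pr_curve.png").exists():
        lines.append('<img src="eval/pr_curve.png" alt="PR curve"/>')
    lines.append("</body></html>")
    html = "\n".join(lines)
    with open(out / "report.html", "w") as fh:
        fh.write(html)
    return html
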