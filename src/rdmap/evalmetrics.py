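"""Agreement and localization statistics.

Pooled partition-level precision/recall/F1 with Wilson 95% CIs,
posterior-pole sensitivity/specificity/accuracy, precision-recall curve and
average precision (step-wise precision-envelope convention), unweighted
Cohen's kappa with asymptotic CI, the four-zone confusion matrix, and mask
intersection-over-union.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import List, Optional, Sequence, Tuple

import numpy as np
from scipy import stats

from . import anatomy
from .anatomy import ZONES, PartitionRule, RetinalFrame

__all__ = [
    "BinaryCounts",
    "MetricWithCI",
    "EvalReport",
    "wilson_ci",
    "precision_recall_f1",
    "f1_score",
    "sens_spec_acc",
    "pr_curve_ap",
    "average_precision",
    "cohen_kappa",
    "confusion4",
    "iou",
    "evaluate_localization",
]


@dataclass(frozen=True)
class BinaryCounts:
    tp: int = 0
    fp: int = 0
    fn: int = 0
    tn: int = 0

    def __post_init__(self) -> None:
        if min(self.tp, self.fp, self.fn, self.tn) < 0:
            raise ValueError("counts must be non-negative")

    def __add__(self, other: "BinaryCounts") -> "BinaryCounts":
        return BinaryCounts(
            self.tp + other.tp, self.fp + other.fp,
            self.fn + other.fn, self.tn + other.tn,
        )


@dataclass(frozen=True)
class MetricWithCI:
    value: float
    ci_low: float
    ci_high: float

    def __post_init__(self) -> None:
        if not (self.ci_low - 1e-12 <= self.value <= self.ci_high + 1e-12):
            raise ValueError("value must lie inside its confidence interval")

    def as_tuple(self) -> Tuple[float, float, float]:
        return (self.value, self.ci_low, self.ci_high)


def wilson_ci(successes: int, trials: int, level: float = 0.95) -> Tuple[float, float]:
    """Wilson score interval for a binomial proportion."""
    if trials <= 0:
        raise ValueError("trials must be positive")
    if not 0 <= successes <= trials:
        raise ValueError("successes must lie in [0, trials]")
    z = stats.norm.ppf(0.5 + level / 2.0)
    phat = successes / trials
    denom = 1.0 + z * z / trials
    center = (phat + z * z / (2 * trials)) / denom
    half = (z / denom) * np.sqrt(phat * (1 - phat) / trials + z * z / (4 * trials**2))
    return (max(0.0, center - half), min(1.0, center + half))


def _prop(successes: int, trials: int) -> MetricWithCI:
    lo, hi = wilson_ci(successes, trials)
    return MetricWithCI(successes / trials, lo, hi)


def f1_score(precision: float, recall: float) -> float:
    """Harmonic mean 2PR/(P+R)."""
    if precision + recall == 0:
        return 0.0
    return 2.0 * precision * recall / (precision + recall)


def precision_recall_f1(counts: BinaryCounts) -> Tuple[MetricWithCI, MetricWithCI, MetricWithCI]:
    """Pooled precision, recall and F1 with 95% CIs.

    The F1 interval propagates the Wilson bounds of precision and recall
    through the harmonic mean (a documented approximation).
    """
    if counts.tp + counts.fp == 0:
        raise ValueError("precision undefined: no positive predictions")
    if counts.tp + counts.fn == 0:
        raise ValueError("recall undefined: no positive references")
    prec = _prop(counts.tp, counts.tp + counts.fp)
    rec = _prop(counts.tp, counts.tp + counts.fn)
    f1 = MetricWithCI(
        f1_score(prec.value, rec.value),
        f1_score(prec.ci_low, rec.ci_low),
        f1_score(prec.ci_high, rec.ci_high),
    )
    return prec, rec, f1


def sens_spec_acc(counts: BinaryCounts) -> Tuple[MetricWithCI, MetricWithCI, MetricWithCI]:
    """Sensitivity, specificity and accuracy with Wilson 95% CIs."""
    if counts.tp + counts.fn == 0 or counts.tn + counts.fp == 0:
        raise ValueError("both classes must be present")
    sens = _prop(counts.tp, counts.tp + counts.fn)
    spec = _prop(counts.tn, counts.tn + counts.fp)
    total = counts.tp + counts.fp + counts.fn + counts.tn
    acc = _prop(counts.tp + counts.tn, total)
    return sens, spec, acc


def average_precision(precisions: Sequence[float], recalls: Sequence[float]) -> float:
    """Step-wise AP with the precision-envelope convention.

    Points are sorted by recall; the envelope at recall r is the maximum
    precision among points with recall >= r; AP sums envelope precision over
    recall increments starting from recall 0.
    """
    pts = sorted(zip(recalls, precisions))
    if not pts:
        raise ValueError("no precision-recall points")
    rs = np.array([p[0] for p in pts])
    ps = np.array([p[1] for p in pts])
    env = np.maximum.accumulate(ps[::-1])[::-1]  # max precision at recall >= r
    ap, prev_r = 0.0, 0.0
    for r, p in zip(rs, env):
        ap += (r - prev_r) * p
        prev_r = r
    return float(ap)


def pr_curve_ap(
    prob_maps: Sequence[np.ndarray],
    frames: Sequence[RetinalFrame],
    truth_vectors: Sequence[np.ndarray],
    rule: Optional[PartitionRule] = None,
    thresholds: Optional[np.ndarray] = None,
) -> Tuple[List[dict], float]:
    """Precision-recall curve over probability thresholds, plus AP.

    For each threshold the pseudo-masks and 48-partition vectors are
    recomputed and decisions pooled over all images.  Thresholds with no
    positive prediction are assigned precision 1 (zero-recall endpoint).
    """
    if len(prob_maps) != len(frames) or len(frames) != len(truth_vectors):
        raise ValueError("inputs must have matching lengths")
    truth = np.stack([np.asarray(t, dtype=bool) for t in truth_vectors])
    if not truth.any():
        raise ValueError("no positive partitions in the reference")
    rule = rule if rule is not None else PartitionRule()
    if thresholds is None:
        thresholds = np.linspace(0.0, 1.0, 101)
    thresholds = np.asarray(thresholds, dtype=float)
    n_thr = len(thresholds)

    # Per image: counts[partition, threshold] of map pixels >= threshold,
    # computed once via a (partition, threshold-bin) histogram.
    pred_bits = np.zeros((len(prob_maps), n_thr, 48), dtype=bool)
    for i, (pm, frame) in enumerate(zip(prob_maps, frames)):
        values = np.asarray(getattr(pm, "values", pm), dtype=float)
        idx = anatomy.partition_index_map(frame)
        sel = idx >= 0
        part = idx[sel].ravel()
        v = values[sel].ravel()
        # bin b = number of thresholds that v passes (v >= thresholds[:b])
        passes = np.searchsorted(thresholds, v, side="right")
        hist = np.zeros((48, n_thr + 1), dtype=np.int64)
        np.add.at(hist, (part, passes), 1)
        counts_ge = np.cumsum(hist[:, ::-1], axis=1)[:, ::-1]  # >= bin b
        counts = counts_ge[:, 1:]  # pixels passing threshold t
        pred_bits[i] = (counts > rule.min_pixels).T

    curve = []
    precisions, recalls = [], []
    pos_truth = truth.sum()
    for t in range(n_thr):
        pred = pred_bits[:, t, :]
        tp = int(np.sum(pred & truth))
        fp = int(np.sum(pred & ~truth))
        fn = int(np.sum(~pred & truth))
        prec = tp / (tp + fp) if tp + fp > 0 else 1.0
        rec = tp / pos_truth
        curve.append(
            {"threshold": float(thresholds[t]), "precision": prec, "recall": rec}
        )
        precisions.append(prec)
        recalls.append(rec)
    return curve, average_precision(precisions, recalls)


def cohen_kappa(labels_a: Sequence[str], labels_b: Sequence[str],
                categories: Sequence[str] = ZONES) -> MetricWithCI:
    """Unweighted Cohen's kappa with the large-sample asymptotic 95% CI."""
    if len(labels_a) != len(labels_b):
        raise ValueError("label sequences must have equal length")
    n = len(labels_a)
    if n < 2:
        raise ValueError("need at least 2 paired labels")
    cats = list(categories)
    index = {c: i for i, c in enumerate(cats)}
    try:
        ai = np.array([index[a] for a in labels_a])
        bi = np.array([index[b] for b in labels_b])
    except KeyError as exc:
        raise ValueError(f"unknown label {exc.args[0]!r}") from None
    k = len(cats)
    table = np.zeros((k, k))
    np.add.at(table, (ai, bi), 1)
    po = np.trace(table) / n
    pa = table.sum(axis=1) / n
    pb = table.sum(axis=0) / n
    pe = float(pa @ pb)
    if pe >= 1.0:
        raise ValueError("degenerate marginals: chance agreement is 1")
    kappa = (po - pe) / (1.0 - pe)
    se = np.sqrt(po * (1 - po) / (n * (1 - pe) ** 2))
    z = stats.norm.ppf(0.975)
    return MetricWithCI(
        float(kappa),
        float(max(-1.0, kappa - z * se)),
        float(min(1.0, kappa + z * se)),
    )


def confusion4(truth_zones: Sequence[str], predicted_zones: Sequence[str]
               ) -> Tuple[np.ndarray, MetricWithCI]:
    """4x4 confusion matrix (rows = truth) in the fixed zone order, and the
    four-zone accuracy with Wilson CI."""
    if len(truth_zones) != len(predicted_zones):
        raise ValueError("length mismatch")
    index = {z: i for i, z in enumerate(ZONES)}
    mat = np.zeros((4, 4), dtype=np.int64)
    for t, p in zip(truth_zones, predicted_zones):
        if t not in index or p not in index:
            raise ValueError(f"unknown zone label in ({t!r}, {p!r})")
        mat[index[t], index[p]] += 1
    acc = _prop(int(np.trace(mat)), int(mat.sum()))
    return mat, acc


def iou(mask_a: np.ndarray, mask_b: np.ndarray) -> float:
    """Intersection-over-union; 1.0 when both masks are empty."""
    a = np.asarray(mask_a) != 0
    b = np.asarray(mask_b) != 0
    if a.shape != b.shape:
        raise ValueError("mask shapes differ")
    union = np.sum(a | b)
    if union == 0:
        return 1.0
    return float(np.sum(a & b) / union)


@dataclass
class EvalReport:
    """All localization statistics for one matched prediction/reference set."""

    partition_precision: MetricWithCI
    partition_recall: MetricWithCI
    partition_f1: MetricWithCI
    partition_counts: BinaryCounts
    posterior_sensitivity: Optional[MetricWithCI]
    posterior_specificity: Optional[MetricWithCI]
    posterior_accuracy: Optional[MetricWithCI]
    posterior_counts: Optional[BinaryCounts]
    kappa: Optional[MetricWithCI]
    confusion: Optional[np.ndarray]
    zone_accuracy: Optional[MetricWithCI]
    pr_curve: Optional[List[dict]] = None
    average_precision: Optional[float] = None
    n_images: int = 0
    n_partition_decisions: int = 0

    def to_dict(self) -> dict:
        def m(x):
            return None if x is None else {
                "value": x.value, "ci_low": x.ci_low, "ci_high": x.ci_high
            }

        return {
            "n_images": self.n_images,
            "n_partition_decisions": self.n_partition_decisions,
            "partition": {
                "precision": m(self.partition_precision),
                "recall": m(self.partition_recall),
                "f1": m(self.partition_f1),
                "counts": vars(self.partition_counts),
            },
            "posterior_pole": None if self.posterior_counts is None else {
                "sensitivity": m(self.posterior_sensitivity),
                "specificity": m(self.posterior_specificity),
                "accuracy": m(self.posterior_accuracy),
                "counts": vars(self.posterior_counts),
            },
            "four_zone": None if self.kappa is None else {
                "kappa": m(self.kappa),
                "accuracy": m(self.zone_accuracy),
                "confusion": self.confusion.tolist(),
                "zone_order": list(ZONES),
            },
            "pr_curve": self.pr_curve,
            "average_precision": self.average_precision,
        }


def evaluate_localization(
    predictions: Sequence[dict],
    truths: Sequence[dict],
    rule: Optional[PartitionRule] = None,
) -> EvalReport:
    """Pool per-image outputs into one report.

    Each record carries ``partitions`` (48-vector), ``posterior`` (bool) and
    ``primary_zone`` (zone name or None); records are matched by position,
    and ``image_id`` keys, when present, must agree pairwise.
    """
    if len(predictions) != len(truths):
        raise ValueError("prediction/truth set sizes differ")
    for p, t in zip(predictions, truths):
        pid, tid = p.get("image_id"), t.get("image_id")
        if pid is not None and tid is not None and pid != tid:
            raise ValueError(f"mismatched image identifiers: {pid!r} vs {tid!r}")

    part = BinaryCounts()
    post = BinaryCounts()
    zones_t, zones_p = [], []
    have_posterior = True
    for p, t in zip(predictions, truths):
        pv = np.asarray(p["partitions"], dtype=bool)
        tv = np.asarray(t["partitions"], dtype=bool)
        if pv.shape != (48,) or tv.shape != (48,):
            raise ValueError("partition vectors must have length 48")
        part = part + BinaryCounts(
            tp=int(np.sum(pv & tv)), fp=int(np.sum(pv & ~tv)),
            fn=int(np.sum(~pv & tv)), tn=int(np.sum(~pv & ~tv)),
        )
        if "posterior" in p and "posterior" in t:
            pi, ti = bool(p["posterior"]), bool(t["posterior"])
            post = post + BinaryCounts(
                tp=int(pi and ti), fp=int(pi and not ti),
                fn=int(not pi and ti), tn=int(not pi and not ti),
            )
        else:
            have_posterior = False
        if p.get("primary_zone") is not None and t.get("primary_zone") is not None:
            zones_p.append(p["primary_zone"])
            zones_t.append(t["primary_zone"])

    prec, rec, f1 = precision_recall_f1(part)
    sens = spec = acc = None
    if have_posterior and post.tp + post.fn > 0 and post.tn + post.fp > 0:
        sens, spec, acc = sens_spec_acc(post)
    kappa = conf = zacc = None
    if len(zones_t) >= 2:
        if len(set(zones_t) | set(zones_p)) > 1:
            kappa = cohen_kappa(zones_t, zones_p)
        conf, zacc = confusion4(zones_t, zones_p)
    return EvalReport(
        partition_precision=prec,
        partition_recall=rec,
        partition_f1=f1,
        partition_counts=part,
        posterior_sensitivity=sens,
        posterior_specificity=spec,
        posterior_accuracy=acc,
        posterior_counts=post if have_posterior else None,
        kappa=kappa,
        confusion=conf,
        zone_accuracy=zacc,
        n_images=len(predictions),
        n_partition_decisions=48 * len(predictions),
    )
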