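"""Statistics: closed-form examples and independent-library oracles."""

import numpy as np
import pytest
from sklearn.metrics import cohen_kappa_score
from statsmodels.stats.proportion import proportion_confint

from rdmap import anatomy
from rdmap.anatomy import PartitionRule, fit_frame
from rdmap.evalmetrics import (
    BinaryCounts,
    MetricWithCI,
    average_precision,
    cohen_kappa,
    confusion4,
    evaluate_localization,
    f1_score,
    iou,
    pr_curve_ap,
    precision_recall_f1,
    sens_spec_acc,
    wilson_ci,
)


class TestPrecisionRecallF1:
    def test_printed_pair_reproduces_printed_f1(self):
        assert f1_score(0.8642, 0.8327) == pytest.approx(0.8481, abs=0.001)

    def test_hand_computed_counts(self):
        prec, rec, f1 = precision_recall_f1(BinaryCounts(tp=3, fp=1, fn=2, tn=10))
        assert prec.value == pytest.approx(0.75)
        assert rec.value == pytest.approx(0.6)
        assert f1.value == pytest.approx(2 * 0.75 * 0.6 / 1.35)

    def test_perfect_counts(self):
        prec, rec, f1 = precision_recall_f1(BinaryCounts(tp=5, fp=0, fn=0, tn=5))
        assert prec.value == rec.value == f1.value == 1.0
        assert prec.ci_high == 1.0

    def test_zero_denominators_rejected(self):
        with pytest.raises(ValueError):
            precision_recall_f1(BinaryCounts(tp=0, fp=0, fn=3, tn=1))
        with pytest.raises(ValueError):
            precision_recall_f1(BinaryCounts(tp=0, fp=3, fn=0, tn=1))

    def test_ci_brackets_value(self):
        prec, rec, f1 = precision_recall_f1(BinaryCounts(tp=80, fp=12, fn=17, tn=400))
        for m in (prec, rec, f1):
            assert 0 <= m.ci_low <= m.value <= m.ci_high <= 1


class TestWilson:
    def test_endpoints(self):
        assert wilson_ci(10, 10)[1] == pytest.approx(1.0)
        assert wilson_ci(0, 10)[0] == pytest.approx(0.0)

    @pytest.mark.parametrize("k,n", [(83, 100), (1, 7), (250, 500), (0, 3), (9, 9)])
    def test_matches_statsmodels(self, k, n):
        lo, hi = wilson_ci(k, n)
        slo, shi = proportion_confint(k, n, alpha=0.05, method="wilson")
        assert lo == pytest.approx(slo, abs=1e-10)
        assert hi == pytest.approx(shi, abs=1e-10)

    def test_zero_trials_rejected(self):
        with pytest.raises(ValueError):
            wilson_ci(0, 0)


class TestSensSpecAcc:
    def test_hand_computed(self):
        sens, spec, acc = sens_spec_acc(BinaryCounts(tp=80, fn=20, tn=90, fp=10))
        assert sens.value == pytest.approx(0.8)
        assert spec.value == pytest.approx(0.9)
        assert acc.value == pytest.approx(0.85)

    def test_perfect(self):
        sens, spec, acc = sens_spec_acc(BinaryCounts(tp=5, fn=0, tn=5, fp=0))
        assert sens.value == spec.value == acc.value == 1.0

    def test_swapping_convention_swaps_sens_spec(self):
        c = BinaryCounts(tp=80, fn=20, tn=90, fp=10)
        swapped = BinaryCounts(tp=c.tn, fn=c.fp, tn=c.tp, fp=c.fn)
        s1 = sens_spec_acc(c)
        s2 = sens_spec_acc(swapped)
        assert s1[0].value == pytest.approx(s2[1].value)
        assert s1[1].value == pytest.approx(s2[0].value)

    def test_missing_class_rejected(self):
        with pytest.raises(ValueError):
            sens_spec_acc(BinaryCounts(tp=0, fn=0, tn=5, fp=5))


class TestAveragePrecision:
    def test_three_point_hand_computation(self):
        ap = average_precision([1.0, 0.8, 0.6], [0.5, 0.75, 1.0])
        assert ap == pytest.approx(0.5 * 1.0 + 0.25 * 0.8 + 0.25 * 0.6)

    def test_perfect_predictor(self):
        assert average_precision([1.0, 1.0], [0.5, 1.0]) == pytest.approx(1.0)

    def test_envelope_monotone(self):
        # a dip in precision at lower recall is lifted by the envelope
        ap = average_precision([0.5, 0.9, 0.6], [0.2, 0.5, 1.0])
        assert ap == pytest.approx(0.5 * 0.9 + 0.5 * 0.6)


def _toy_frame():
    return fit_frame((64.0, 64.0), (92.0, 64.0), 5.0, "OD", (128, 128))


class TestPrCurveAp:
    def test_grid_refinement_oracle(self):
        rng = np.random.default_rng(0)
        frame = _toy_frame()
        rule = PartitionRule(min_pixels=3, evaluation_resolution=128)
        maps, truths = [], []
        for _ in range(6):
            pm = rng.random((128, 128))
            maps.append(pm)
            truths.append(anatomy.partition_vector(pm > 0.6, frame, rule))
        if not np.any([t.any() for t in truths]):
            pytest.skip("degenerate fixture")
        _, ap_coarse = pr_curve_ap(maps, [frame] * 6, truths, rule,
                                   np.linspace(0, 1, 101))
        _, ap_fine = pr_curve_ap(maps, [frame] * 6, truths, rule,
                                 np.linspace(0, 1, 1001))
        assert ap_coarse == pytest.approx(ap_fine, abs=0.01)

    def test_monotone_transform_invariance(self):
        rng = np.random.default_rng(1)
        frame = _toy_frame()
        rule = PartitionRule(min_pixels=3, evaluation_resolution=128)
        maps = [rng.random((128, 128)) for _ in range(4)]
        truths = [anatomy.partition_vector(pm > 0.55, frame, rule) for pm in maps]
        thresholds = np.linspace(0, 1, 201)
        _, ap1 = pr_curve_ap(maps, [frame] * 4, truths, rule, thresholds)
        # strictly monotone transform of the maps with a matched threshold grid
        maps2 = [pm**2 for pm in maps]
        _, ap2 = pr_curve_ap(maps2, [frame] * 4, truths, rule, thresholds**2)
        assert ap1 == pytest.approx(ap2, abs=1e-9)

    def test_no_positive_truth_rejected(self):
        frame = _toy_frame()
        with pytest.raises(ValueError):
            pr_curve_ap([np.zeros((128, 128))], [frame], [np.zeros(48)],
                        PartitionRule())


class TestCohenKappa:
    def test_identical_sequences(self):
        labels = ["superior", "inferior", "left", "right"] * 5
        assert cohen_kappa(labels, labels).value == pytest.approx(1.0)

    def test_hand_computed_zero(self):
        a = ["superior", "superior", "inferior", "inferior"]
        b = ["superior", "inferior", "superior", "inferior"]
        assert cohen_kappa(a, b).value == pytest.approx(0.0)

    def test_matches_sklearn_on_random_pairs(self):
        rng = np.random.default_rng(2)
        zones = np.array(["superior", "right", "inferior", "left"])
        a = zones[rng.integers(0, 4, 1000)]
        b = zones[rng.integers(0, 4, 1000)]
        ours = cohen_kappa(list(a), list(b)).value
        theirs = cohen_kappa_score(a, b)
        assert ours == pytest.approx(theirs, abs=1e-12)

    def test_relabeling_invariance(self):
        rng = np.random.default_rng(3)
        zones = ["superior", "right", "inferior", "left"]
        a = [zones[i] for i in rng.integers(0, 4, 200)]
        b = [zones[i] for i in rng.integers(0, 4, 200)]
        perm = {"superior": "left", "left": "right", "right": "inferior",
                "inferior": "superior"}
        k1 = cohen_kappa(a, b).value
        k2 = cohen_kappa([perm[x] for x in a], [perm[x] for x in b]).value
        assert k1 == pytest.approx(k2, abs=1e-12)

    def test_length_mismatch_rejected(self):
        with pytest.raises(ValueError):
            cohen_kappa(["superior"], ["superior", "left"])


class TestConfusion4:
    def test_all_correct_diagonal(self):
        zones = ["superior", "right", "inferior", "left"] * 3
        mat, acc = confusion4(zones, zones)
        assert np.trace(mat) == 12
        assert mat.sum() == 12
        assert acc.value == 1.0

    def test_single_disagreement(self):
        t = ["superior"] * 9 + ["inferior"]
        p = ["superior"] * 9 + ["left"]
        _, acc = confusion4(t, p)
        assert acc.value == pytest.approx(0.9)

    def test_marginals_match_histograms(self):
        rng = np.random.default_rng(4)
        zones = np.array(["superior", "right", "inferior", "left"])
        t = zones[rng.integers(0, 4, 100)]
        p = zones[rng.integers(0, 4, 100)]
        mat, _ = confusion4(list(t), list(p))
        for i, z in enumerate(zones):
            assert mat[i].sum() == np.sum(t == z)
            assert mat[:, i].sum() == np.sum(p == z)

    def test_unknown_label_rejected(self):
        with pytest.raises(ValueError):
            confusion4(["superior"], ["central"])


class TestIoU:
    def test_identical_masks(self):
        m = np.zeros((10, 10))
        m[2:5, 2:5] = 1
        assert iou(m, m) == 1.0

    def test_disjoint_masks(self):
        a = np.zeros((10, 10))
        b = np.zeros((10, 10))
        a[0:2, 0:2] = 1
        b[5:7, 5:7] = 1
        assert iou(a, b) == 0.0

    def test_half_overlap(self):
        a = np.zeros((10, 10))
        a[:, :5] = 1
        b = np.ones((10, 10))
        assert iou(a, b) == pytest.approx(0.5)

    def test_both_empty_is_one(self):
        assert iou(np.zeros((4, 4)), np.zeros((4, 4))) == 1.0

    def test_shape_mismatch_rejected(self):
        with pytest.raises(ValueError):
            iou(np.zeros((4, 4)), np.zeros((5, 5)))


def _record(bits, posterior, zone, image_id=None):
    rec = {"partitions": np.asarray(bits, dtype=np.uint8),
           "posterior": posterior, "primary_zone": zone}
    if image_id is not None:
        rec["image_id"] = image_id
    return rec


class TestEvaluateLocalization:
    def test_perfect_predictions_all_ones(self):
        rng = np.random.default_rng(5)
        zones = ["superior", "right", "inferior", "left"]
        truths = []
        for i in range(8):
            bits = (rng.random(48) < 0.2).astype(np.uint8)
            bits[i % 48] = 1
            truths.append(_record(bits, bool(i % 2), zones[i % 4]))
        report = evaluate_localization(truths, truths)
        assert report.partition_precision.value == 1.0
        assert report.partition_recall.value == 1.0
        assert report.partition_f1.value == 1.0
        assert report.posterior_accuracy.value == 1.0
        assert report.kappa.value == pytest.approx(1.0)
        assert report.zone_accuracy.value == 1.0

    def test_constructed_error_injection(self):
        # 4 images x 48 partitions; truth has 50 positive bits; prediction
        # drops 6 of them (fn) and adds 4 spurious ones (fp)
        rng = np.random.default_rng(6)
        truth_bits = np.zeros((4, 48), dtype=np.uint8)
        pos = rng.choice(4 * 48, size=50, replace=False)
        truth_bits.flat[pos] = 1
        pred_bits = truth_bits.copy()
        drop = pos[:6]
        pred_bits.flat[drop] = 0
        neg = np.setdiff1d(np.arange(4 * 48), pos)
        pred_bits.flat[neg[:4]] = 1
        truths = [_record(truth_bits[i], False, "superior") for i in range(4)]
        preds = [_record(pred_bits[i], False, "superior") for i in range(4)]
        report = evaluate_localization(preds, truths)
        assert report.partition_counts.tp == 44
        assert report.partition_counts.fn == 6
        assert report.partition_counts.fp == 4
        assert report.partition_precision.value == pytest.approx(44 / 48)
        assert report.partition_recall.value == pytest.approx(44 / 50)

    def test_pooling_consistency(self):
        rng = np.random.default_rng(7)
        per_image = []
        total = BinaryCounts()
        truths, preds = [], []
        for _ in range(6):
            t = (rng.random(48) < 0.3).astype(np.uint8)
            t[0] = 1
            p = (rng.random(48) < 0.3).astype(np.uint8)
            p[1] = 1
            truths.append(_record(t, False, "superior"))
            preds.append(_record(p, False, "superior"))
            total = total + BinaryCounts(
                tp=int(np.sum(p & t)), fp=int(np.sum(p & ~t.astype(bool))),
                fn=int(np.sum((1 - p) & t)), tn=int(np.sum((1 - p) & (1 - t))),
            )
        report = evaluate_localization(preds, truths)
        assert report.partition_counts == total

    def test_mismatched_ids_rejected(self):
        t = [_record(np.ones(48), False, "superior", image_id="a")]
        p = [_record(np.ones(48), False, "superior", image_id="b")]
        with pytest.raises(ValueError):
            evaluate_localization(p, t)


class TestMetricWithCI:
    def test_value_outside_ci_rejected(self):
        with pytest.raises(ValueError):
            MetricWithCI(value=0.9, ci_low=0.1, ci_high=0.5)
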