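"""Detection metrics vs independent oracles.

The matching oracle enumerates all one-to-one det↔gt assignments and
maximizes the number of IoU-qualified pairs; the AP oracle tabulates
precision/recall at every score cut and sums rectangular areas under the
monotone precision envelope.  Both are deliberately naive.
"""

import itertools

import numpy as np
import pytest

from fruitlabel import (
    BoundingBox,
    Dataset,
    ImageRecord,
    NoGroundTruthError,
    ScoredDetection,
    average_precision,
    evaluate,
    iou,
    match_detections,
    precision_recall_f1,
)
from fruitlabel.evaluation import MatchResult

from conftest import random_box


# ------------------------------------------------------------------ oracles


def max_matching_tp(dets, gts, thr):
    """Maximum number of TP over all one-to-one assignments (brute force)."""
    qualified = {
        (i, j): iou(d.box, g)
        for i, d in enumerate(dets)
        for j, g in enumerate(gts)
        if iou(d.box, g) >= thr
    }
    best = 0
    js = list(range(len(gts)))
    for k in range(min(len(dets), len(gts)), 0, -1):
        for det_subset in itertools.combinations(range(len(dets)), k):
            for gt_perm in itertools.permutations(js, k):
                if all((i, j) in qualified for i, j in zip(det_subset, gt_perm)):
                    return k
    return best


def ap_cut_oracle(dets_per_img, gts_per_img, thr):
    """AP from explicit P/R points at every score cut."""
    all_scores = sorted(
        {d.score for ds in dets_per_img.values() for d in ds}, reverse=True
    )
    n_gt = sum(len(g) for g in gts_per_img.values())
    points = []
    for cut in all_scores:
        tp = fp = 0
        for img, gts in gts_per_img.items():
            kept = [d for d in dets_per_img.get(img, []) if d.score >= cut]
            m = match_detections(kept, gts, thr)
            tp, fp = tp + m.tp, fp + m.fp
        points.append((tp / n_gt, tp / (tp + fp) if tp + fp else 0.0))
    points.sort(key=lambda p: p[0])
    ap, prev_r = 0.0, 0.0
    for k, (r, _) in enumerate(points):
        if r == prev_r:
            continue
        best_p = max(p for rr, p in points if rr >= r)
        ap += (r - prev_r) * best_p
        prev_r = r
    return ap


def random_instance(rng, max_items=5, size=60, distinct_scores=True):
    n_det = int(rng.integers(0, max_items + 1))
    n_gt = int(rng.integers(0, max_items + 1))
    gts = [random_box(rng, size) for _ in range(n_gt)]
    if distinct_scores:
        scores = rng.choice(np.linspace(0.05, 0.95, 50), size=n_det, replace=False)
    else:
        scores = rng.uniform(0.05, 0.95, n_det)
    dets = [
        ScoredDetection(box=random_box(rng, size), score=float(s)) for s in scores
    ]
    return dets, gts


# ----------------------------------------------------------------- matching


class TestMatchDetections:
    def test_perfect_match(self):
        g = BoundingBox(10, 10, 30, 30)
        m = match_detections([ScoredDetection(box=g, score=0.9)], [g], 0.5)
        assert (m.tp, m.fp, m.fn) == (1, 0, 0)

    def test_duplicate_detection_is_fp(self):
        g = BoundingBox(10, 10, 30, 30)
        dets = [
            ScoredDetection(box=g, score=0.9),
            ScoredDetection(box=BoundingBox(12, 10, 32, 30), score=0.8),
        ]
        m = match_detections(dets, [g], 0.5)
        assert (m.tp, m.fp, m.fn) == (1, 1, 0)

    def test_empty_inputs(self):
        m = match_detections([], [], 0.5)
        assert (m.tp, m.fp, m.fn) == (0, 0, 0)
        m = match_detections([], [BoundingBox(0, 0, 5, 5)], 0.5)
        assert (m.tp, m.fp, m.fn) == (0, 0, 1)

    def test_invalid_threshold(self):
        with pytest.raises(ValueError):
            match_detections([], [], 0.0)

    def test_greedy_counts_vs_exhaustive_oracle(self):
        """Greedy matching equals the optimal assignment on nearly all
        random small instances; greedy can never exceed the optimum."""
        rng = np.random.default_rng(7)
        agree = diverge = 0
        for _ in range(150):
            dets, gts = random_instance(rng)
            m = match_detections(dets, gts, 0.5)
            opt = max_matching_tp(dets, gts, 0.5)
            assert m.tp <= opt
            assert m.tp + m.fp == len(dets)
            assert m.tp + m.fn == len(gts)
            if m.tp == opt:
                agree += 1
            else:
                diverge += 1  # known greedy-vs-optimal divergence
        assert agree > diverge * 10

    def test_ground_truth_matched_at_most_once(self):
        rng = np.random.default_rng(19)
        for _ in range(50):
            dets, gts = random_instance(rng)
            m = match_detections(dets, gts, 0.3)
            assert sum(m.gt_matched) == m.tp


# ------------------------------------------------------------------ P/R/F1


class TestPrecisionRecallF1:
    @pytest.mark.parametrize(
        "precision,recall,f1",
        [
            (0.886, 0.923, 0.904),
            (0.803, 0.808, 0.805),
            (0.913, 0.941, 0.927),
            (0.828, 0.836, 0.832),
        ],
    )
    def test_f1_is_harmonic_mean(self, precision, recall, f1):
        """F1 reproduces published detection-benchmark rows at 3 dp."""
        computed = 2 * precision * recall / (precision + recall)
        assert round(computed, 3) == f1

    def test_counts_to_fractions(self):
        p, r, f1 = precision_recall_f1(MatchResult(tp=8, fp=2, fn=8))
        assert p == pytest.approx(0.8)
        assert r == pytest.approx(0.5)
        assert f1 == pytest.approx(2 * 0.8 * 0.5 / 1.3)

    def test_degenerate_zero_over_zero(self):
        p, r, f1 = precision_recall_f1(MatchResult(tp=0, fp=0, fn=5))
        assert (p, r, f1) == (0.0, 0.0, 0.0)

    def test_f1_bounds(self):
        rng = np.random.default_rng(3)
        for _ in range(100):
            tp, fp, fn = rng.integers(0, 20, 3)
            p, r, f1 = precision_recall_f1(MatchResult(tp=int(tp), fp=int(fp), fn=int(fn)))
            assert f1 <= 2 * min(p, r) + 1e-12
            assert f1 <= max(p, r) + 1e-12
            if p == r:
                assert f1 == pytest.approx(p)


# --------------------------------------------------------------------- AP


class TestAveragePrecision:
    def test_perfect_single_detection(self):
        g = BoundingBox(5, 5, 25, 25)
        ap = average_precision(
            {"a": [ScoredDetection(box=g, score=0.8)]}, {"a": [g]}, 0.5
        )
        assert ap == 1.0

    def test_all_false_positives(self):
        ap = average_precision(
            {"a": [ScoredDetection(box=BoundingBox(50, 50, 60, 60), score=0.9)]},
            {"a": [BoundingBox(0, 0, 10, 10)]},
            0.5,
        )
        assert ap == 0.0

    def test_no_ground_truth_is_an_error(self):
        with pytest.raises(NoGroundTruthError):
            average_precision({"a": []}, {"a": []}, 0.5)

    def test_hand_built_instance_matches_cut_oracle(self):
        g1, g2 = BoundingBox(0, 0, 20, 20), BoundingBox(40, 40, 60, 60)
        g3 = BoundingBox(0, 0, 20, 20)
        dets = {
            "a": [
                ScoredDetection(box=g1, score=0.95),                       # TP
                ScoredDetection(box=BoundingBox(70, 70, 80, 80), score=0.9),  # FP
                ScoredDetection(box=g2, score=0.6),                        # TP
            ],
            "b": [
                ScoredDetection(box=g3, score=0.8),                        # TP
                ScoredDetection(box=BoundingBox(30, 0, 40, 10), score=0.5),   # FP
                ScoredDetection(box=BoundingBox(5, 5, 22, 22), score=0.4),    # dup
            ],
        }
        gts = {"a": [g1, g2], "b": [g3]}
        expected = ap_cut_oracle(dets, gts, 0.5)
        assert average_precision(dets, gts, 0.5) == pytest.approx(expected)

    def test_random_instances_match_cut_oracle(self):
        rng = np.random.default_rng(23)
        checked = 0
        while checked < 60:
            dets, gts = random_instance(rng)
            if not gts:
                continue
            ap = average_precision({"x": dets}, {"x": gts}, 0.5)
            assert ap == pytest.approx(ap_cut_oracle({"x": dets}, {"x": gts}, 0.5))
            checked += 1

    def test_invariant_to_image_permutation_and_score_rescale(self):
        rng = np.random.default_rng(5)
        dets_a, gts_a = random_instance(rng)
        dets_b, gts_b = random_instance(rng)
        while not (gts_a or gts_b):
            dets_b, gts_b = random_instance(rng)
        d1 = {"a": dets_a, "b": dets_b}
        g1 = {"a": gts_a, "b": gts_b}
        ap = average_precision(d1, g1, 0.5)
        # image order permuted
        ap_perm = average_precision(
            {"b": dets_b, "a": dets_a}, {"b": gts_b, "a": gts_a}, 0.5
        )
        assert ap_perm == pytest.approx(ap)
        # strictly monotone score rescale: s -> s**3 stays in [0,1]
        d_rescaled = {
            k: [ScoredDetection(box=d.box, score=d.score**3) for d in v]
            for k, v in d1.items()
        }
        assert average_precision(d_rescaled, g1, 0.5) == pytest.approx(ap)

    def test_removing_fp_never_decreases_ap(self):
        rng = np.random.default_rng(31)
        done = 0
        while done < 30:
            dets, gts = random_instance(rng)
            if not gts or not dets:
                continue
            ap = average_precision({"x": dets}, {"x": gts}, 0.5)
            m = match_detections(dets, gts, 0.5)
            fp_ranks = [r for r, flag in enumerate(m.det_is_tp) if not flag]
            if not fp_ranks:
                continue
            drop = m.order[fp_ranks[0]]
            smaller = [d for i, d in enumerate(dets) if i != drop]
            ap2 = average_precision({"x": smaller}, {"x": gts}, 0.5)
            assert ap2 >= ap - 1e-12
            done += 1


# ---------------------------------------------------------------- evaluate


def _as_datasets(dets_per_img, gts_per_img):
    truth = Dataset(
        records=[
            ImageRecord(image_id=k, annotations=list(v))
            for k, v in gts_per_img.items()
        ],
        labeled="ground_truth",
    )
    pred = Dataset(
        records=[
            ImageRecord(image_id=k, pseudo_labels=list(dets_per_img.get(k, [])))
            for k in gts_per_img
        ],
        labeled="pseudo",
    )
    return pred, truth


class TestEvaluate:
    def test_oracle_detector_scores_perfectly(self, labeled_dataset):
        gts = {r.image_id: list(r.annotations) for r in labeled_dataset.records}
        dets = {
            k: [ScoredDetection(box=b, score=1.0) for b in v] for k, v in gts.items()
        }
        pred, truth = _as_datasets(dets, gts)
        rep = evaluate(pred, truth, 0.5, 0.5)
        assert rep.precision == rep.recall == rep.f1 == rep.map == 1.0

    def test_empty_predictions(self, labeled_dataset):
        gts = {r.image_id: list(r.annotations) for r in labeled_dataset.records}
        pred, truth = _as_datasets({}, gts)
        rep = evaluate(pred, truth, 0.5, 0.5)
        assert (rep.precision, rep.recall, rep.map) == (0.0, 0.0, 0.0)

    def test_image_id_mismatch_lists_offenders(self):
        pred, truth = _as_datasets(
            {"a": []}, {"a": [BoundingBox(0, 0, 5, 5)]}
        )
        pred.records.append(ImageRecord(image_id="zzz"))
        with pytest.raises(ValueError, match="zzz"):
            evaluate(pred, truth, 0.5, 0.5)

    def test_single_class_map_equals_ap(self, labeled_dataset):
        gts = {r.image_id: list(r.annotations) for r in labeled_dataset.records}
        rng = np.random.default_rng(2)
        dets = {
            k: [
                ScoredDetection(box=b, score=float(s))
                for b, s in zip(v, rng.uniform(0.2, 0.95, len(v)))
            ]
            for k, v in gts.items()
        }
        pred, truth = _as_datasets(dets, gts)
        rep = evaluate(pred, truth, 0.5, 0.5)
        assert rep.map == pytest.approx(rep.ap_per_class["fruit"])

    def test_report_recomputable_from_formulas(self, labeled_dataset):
        """The packaged report must equal a from-scratch recomputation
        using only the matching primitive and the metric formulas."""
        gts = {r.image_id: list(r.annotations) for r in labeled_dataset.records}
        rng = np.random.default_rng(8)
        dets = {}
        for k, v in gts.items():
            d = [
                ScoredDetection(box=b, score=float(s))
                for b, s in zip(v[:-1], rng.uniform(0.3, 0.95, max(len(v) - 1, 0)))
            ]
            d.append(ScoredDetection(box=random_box(rng, 90), score=0.55))
            dets[k] = d
        pred, truth = _as_datasets(dets, gts)
        rep = evaluate(pred, truth, 0.5, score_threshold=0.4)

        tp = fp = fn = 0
        for k, gt in gts.items():
            kept = [d for d in dets[k] if d.score >= 0.4]
            m = match_detections(kept, gt, 0.5)
            tp, fp, fn = tp + m.tp, fp + m.fp, fn + m.fn
        p = tp / (tp + fp) if tp + fp else 0.0
        r = tp / (tp + fn) if tp + fn else 0.0
        assert rep.precision == pytest.approx(p)
        assert rep.recall == pytest.approx(r)
        assert rep.f1 == pytest.approx(2 * p * r / (p + r) if p + r else 0.0)
        assert rep.map == pytest.approx(ap_cut_oracle(dets, gts, 0.5))
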