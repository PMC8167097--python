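"""Detection metrics: TP/FP/FN matching, precision/recall/F1, AP and mAP.

Matching follows the standard VOC protocol: detections are visited in
descending score order and each claims the unmatched ground-truth box of
highest IoU at or above the threshold; every ground truth is consumable
once.  Precision = Tp/(Tp+Fp), Recall = Tp/(Tp+Fn), F1 is their harmonic
mean, and AP is the exact (all-point) area under the precision envelope
of the cumulative precision-recall curve.  mAP averages AP over classes,
which collapses to AP in the single-class fruit setting.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np

from .core import BoundingBox, Dataset, ScoredDetection, iou

__all__ = [
    "MatchResult",
    "EvalReport",
    "NoGroundTruthError",
    "match_detections",
    "precision_recall_f1",
    "f1_score",
    "average_precision",
    "evaluate",
]

log = logging.getLogger(__name__)


class NoGroundTruthError(ValueError):
    """AP requested with zero ground-truth boxes — undefined, not 0."""


@dataclass
class MatchResult:
    """Outcome of matching one image's detections against ground truth.

    ``det_is_tp[i]`` flags the i-th detection *in descending score
    order* (the order returned in ``order``); ``gt_matched[j]`` flags
    ground truth j.
    """

    tp: int
    fp: int
    fn: int
    det_is_tp: list[bool] = field(default_factory=list)
    gt_matched: list[bool] = field(default_factory=list)
    order: list[int] = field(default_factory=list)


@dataclass
class EvalReport:
    """Single-operating-point detection report plus threshold-free AP."""

    tp: int
    fp: int
    fn: int
    precision: float
    recall: float
    f1: float
    ap_per_class: dict[str, float]
    map: float
    iou_threshold: float
    score_threshold: float

    def to_dict(self) -> dict:
        return {
            "Tp": self.tp,
            "Fp": self.fp,
            "Fn": self.fn,
            "precision": self.precision,
            "recall": self.recall,
            "f1": self.f1,
            "ap_per_class": dict(self.ap_per_class),
            "mAP": self.map,
            "iou_threshold": self.iou_threshold,
            "score_threshold": self.score_threshold,
        }


def _score_order(dets: list[ScoredDetection], gts: list[BoundingBox]) -> list[int]:
    # descending score; ties broken by larger best-IoU against any gt,
    # then by insertion order — deterministic across runs
    def key(i: int):
        d = dets[i]
        best = max((iou(d.box, g) for g in gts), default=0.0)
        return (-d.score, -best, i)

    return sorted(range(len(dets)), key=key)


def match_detections(
    dets: list[ScoredDetection],
    gts: list[BoundingBox],
    iou_threshold: float = 0.5,
) -> MatchResult:
    """Greedily match scored detections to ground-truth boxes.

    A detection is a true positive if its IoU with some still-unmatched
    ground truth reaches ``iou_threshold``; duplicate hits on the same
    fruit count as false positives; unmatched ground truths are misses.
    """
    if not (0.0 < iou_threshold <= 1.0):
        raise ValueError(f"iou_threshold {iou_threshold} outside (0, 1]")
    order = _score_order(dets, gts)
    gt_matched = [False] * len(gts)
    det_is_tp: list[bool] = []
    for i in order:
        d = dets[i]
        best_j, best_iou = -1, 0.0
        for j, g in enumerate(gts):
            if gt_matched[j]:
                continue
            v = iou(d.box, g)
            if v > best_iou:
                best_j, best_iou = j, v
        if best_j >= 0 and best_iou >= iou_threshold:
            gt_matched[best_j] = True
            det_is_tp.append(True)
        else:
            det_is_tp.append(False)
    tp = sum(det_is_tp)
    return MatchResult(
        tp=tp,
        fp=len(dets) - tp,
        fn=len(gts) - tp,
        det_is_tp=det_is_tp,
        gt_matched=gt_matched,
        order=order,
    )


def f1_score(precision: float, recall: float) -> float:
    """Harmonic mean of precision and recall; 0 when both are 0."""
    if precision + recall == 0:
        return 0.0
    return 2 * precision * recall / (precision + recall)


def precision_recall_f1(m: MatchResult) -> tuple[float, float, float]:
    """Precision, recall and F1 from match counts; 0/0 conventions → 0."""
    if m.tp + m.fp == 0:
        log.info("precision 0/0 (no detections): returning 0 by convention")
        precision = 0.0
    else:
        precision = m.tp / (m.tp + m.fp)
    if m.tp + m.fn == 0:
        log.info("recall 0/0 (no ground truth): returning 0 by convention")
        recall = 0.0
    else:
        recall = m.tp / (m.tp + m.fn)
    return precision, recall, f1_score(precision, recall)


def average_precision(
    dets_per_image: dict[str, list[ScoredDetection]],
    gts_per_image: dict[str, list[BoundingBox]],
    iou_threshold: float = 0.5,
) -> float:
    """Dataset-wide average precision at one IoU threshold.

    All detections are pooled, sorted by descending score, matched
    greedily per image, and the area under the monotone precision
    envelope of the cumulative P-R curve is integrated exactly (no
    11-point interpolation).

    Raises
    ------
    NoGroundTruthError
        If there are no ground-truth boxes at all.
    """
    n_gt = sum(len(g) for g in gts_per_image.values())
    if n_gt == 0:
        raise NoGroundTruthError("AP undefined: no ground-truth boxes")

    # per-image greedy matching gives each detection its TP/FP flag in
    # descending-score order within the image; pooling those flags and
    # re-sorting globally by score reproduces the global sweep because
    # matching only ever depends on higher-scored detections
    flagged: list[tuple[float, int, bool]] = []  # (score, tiebreak, is_tp)
    serial = 0
    for image_id in gts_per_image:
        dets = dets_per_image.get(image_id, [])
        m = match_detections(dets, gts_per_image[image_id], iou_threshold)
        for rank, i in enumerate(m.order):
            flagged.append((dets[i].score, serial + rank, m.det_is_tp[rank]))
        serial += len(dets)
    flagged.sort(key=lambda t: (-t[0], t[1]))

    if not flagged:
        return 0.0
    is_tp = np.array([f[2] for f in flagged], dtype=float)
    tp_cum = np.cumsum(is_tp)
    fp_cum = np.cumsum(1.0 - is_tp)
    recall = tp_cum / n_gt
    precision = tp_cum / (tp_cum + fp_cum)
    # monotone non-increasing precision envelope, right to left
    envelope = np.maximum.accumulate(precision[::-1])[::-1]
    # rectangular area between consecutive recall levels
    prev_r = np.concatenate([[0.0], recall[:-1]])
    return float(np.sum((recall - prev_r) * envelope))


def evaluate(
    detector_output: Dataset,
    truth: Dataset,
    iou_threshold: float = 0.5,
    score_threshold: float = 0.5,
) -> EvalReport:
    """Full detection report of pseudo/predicted labels against truth.

    Precision/recall/F1 are computed at the ``score_threshold``
    operating point (detections below it are discarded first); AP/mAP
    use all scored detections regardless of the operating point.
    """
    truth_ids = {r.image_id for r in truth.records}
    pred_ids = {r.image_id for r in detector_output.records}
    if truth_ids != pred_ids:
        missing = sorted(truth_ids ^ pred_ids)
        raise ValueError(f"image_id mismatch between prediction and truth: {missing}")

    classes = sorted(
        {b.class_label for r in truth.records for b in r.annotations}
    ) or ["fruit"]

    tp = fp = fn = 0
    ap_per_class: dict[str, float] = {}
    for cls in classes:
        dets_all: dict[str, list[ScoredDetection]] = {}
        dets_cut: dict[str, list[ScoredDetection]] = {}
        gts: dict[str, list[BoundingBox]] = {}
        for tr in truth.records:
            pr = detector_output.by_id(tr.image_id)
            gts[tr.image_id] = [b for b in tr.annotations if b.class_label == cls]
            d = [s for s in pr.pseudo_labels if s.box.class_label == cls]
            dets_all[tr.image_id] = d
            dets_cut[tr.image_id] = [s for s in d if s.score >= score_threshold]
        for image_id, g in gts.items():
            m = match_detections(dets_cut[image_id], g, iou_threshold)
            tp, fp, fn = tp + m.tp, fp + m.fp, fn + m.fn
        n_gt = sum(len(g) for g in gts.values())
        ap_per_class[cls] = (
            average_precision(dets_all, gts, iou_threshold) if n_gt else 0.0
        )

    m = MatchResult(tp=tp, fp=fp, fn=fn)
    precision, recall, f1 = precision_recall_f1(m)
    return EvalReport(
        tp=tp,
        fp=fp,
        fn=fn,
        precision=precision,
        recall=recall,
        f1=f1,
        ap_per_class=ap_per_class,
        map=float(np.mean(list(ap_per_class.values()))),
        iou_threshold=iou_threshold,
        score_threshold=score_threshold,
    )
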