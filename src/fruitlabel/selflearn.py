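"""Cyclic pseudo-label self-learning and the threshold-sweep harness.

Each round of the loop (1) runs the current detector over the unlabeled
target images at confidence threshold θ, (2) filters the candidate boxes
against the dataset-wide mean score S_aver, (3) attaches the survivors
as the round's pseudo-labeled training set — replacing, never
accumulating, the previous round's labels — and (4) fine-tunes the
detector on it, warm-starting from its current state.  The loop is fully
deterministic given the detector's initial state and the config.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from typing import Callable, Protocol, runtime_checkable

import numpy as np

from .core import Dataset, ImageRecord, ScoredDetection
from .evaluation import EvalReport, evaluate
from .pseudolabel import (
    attach_pseudo_labels,
    filter_by_mean,
    generate_pseudo_labels,
    mean_score,
)

__all__ = [
    "Detector",
    "SelfLearnConfig",
    "RoundRecord",
    "SelfLearnTrace",
    "SelfLearnAbort",
    "predict",
    "evaluate_detector",
    "self_learning_loop",
    "threshold_sweep",
    "SweepRow",
]

log = logging.getLogger(__name__)

# score floor used when collecting detections for threshold-free AP
EVAL_DETECT_FLOOR = 0.0


@runtime_checkable
class Detector(Protocol):
    """Contract any detector must satisfy to enter the loop."""

    def detect(self, image: np.ndarray, theta: float) -> list[ScoredDetection]: ...

    def fine_tune(self, ds: Dataset, rounds: int): ...


class SelfLearnAbort(RuntimeError):
    """A round produced zero pseudo labels; θ is too high for this data."""


@dataclass(frozen=True)
class SelfLearnConfig:
    """Knobs of the self-learning loop.

    theta
        Confidence threshold θ for pseudo-label candidates, in (0, 1).
    n_updates
        Number N of pseudo-label update rounds (≥ 1).
    finetune_rounds_per_update
        Detector refits per round between label updates.
    """

    theta: float
    n_updates: int = 3
    finetune_rounds_per_update: int = 1
    seed: int = 0
    drop_empty_pseudo_images: bool = False

    def __post_init__(self) -> None:
        if not (0.0 < self.theta < 1.0):
            raise ValueError(f"theta {self.theta} outside (0, 1)")
        if self.n_updates < 1:
            raise ValueError(f"n_updates must be >= 1, got {self.n_updates}")
        if self.finetune_rounds_per_update < 1:
            raise ValueError("finetune_rounds_per_update must be >= 1")


@dataclass
class RoundRecord:
    round: int
    s_aver: float
    boxes_before_filter: int
    boxes_after_filter: int
    report: EvalReport | None = None

    def to_dict(self) -> dict:
        d = {
            "round": self.round,
            "s_aver": self.s_aver,
            "boxes_before_filter": self.boxes_before_filter,
            "boxes_after_filter": self.boxes_after_filter,
        }
        if self.report is not None:
            d["report"] = self.report.to_dict()
        return d


@dataclass
class SelfLearnTrace:
    config: SelfLearnConfig
    rounds: list[RoundRecord] = field(default_factory=list)

    def to_dict(self) -> dict:
        return {
            "config": {
                "theta": self.config.theta,
                "n_updates": self.config.n_updates,
                "finetune_rounds_per_update": self.config.finetune_rounds_per_update,
                "seed": self.config.seed,
                "drop_empty_pseudo_images": self.config.drop_empty_pseudo_images,
            },
            "rounds": [r.to_dict() for r in self.rounds],
        }


def predict(detector: Detector, ds: Dataset, theta: float = EVAL_DETECT_FLOOR) -> Dataset:
    """Run the detector over a dataset, returning a pseudo-labeled copy.

    Used for evaluation: with the default floor θ all emitted detections
    are kept so AP can integrate over every score cut.
    """
    records = []
    for record in ds.records:
        dets = detector.detect(record.load_pixels(), theta)
        records.append(
            ImageRecord(
                image_id=record.image_id,
                pixels=record.pixels,
                annotations=[],
                pseudo_labels=list(dets),
            )
        )
    return Dataset(records=records, labeled="pseudo" if records else "unlabeled")


def _strip_labels(ds: Dataset) -> Dataset:
    """Unlabeled view of a dataset (pixels only)."""
    return Dataset(
        records=[
            ImageRecord(image_id=r.image_id, pixels=r.pixels) for r in ds.records
        ],
        labeled="unlabeled",
    )


def evaluate_detector(
    detector: Detector,
    test: Dataset,
    iou_threshold: float = 0.5,
    score_threshold: float = 0.5,
) -> EvalReport:
    """Evaluate a detector on a labeled test set.

    The detector only ever sees the stripped (pixels-only) view of the
    test images; ground truth is consulted exclusively by the metric.
    """
    preds = predict(detector, _strip_labels(test))
    return evaluate(preds, test, iou_threshold, score_threshold)


def self_learning_loop(
    detector: Detector,
    unlabeled: Dataset,
    cfg: SelfLearnConfig,
    test: Dataset | None = None,
) -> tuple[Dataset, Detector, SelfLearnTrace]:
    """Run N rounds of pseudo-label self-learning (cyclic update).

    Returns the final pseudo-labeled dataset, the adapted detector, and
    a per-round trace (S_aver, box counts, held-out report when ``test``
    is given).

    Raises
    ------
    SelfLearnAbort
        If any round yields zero pseudo-label candidates.
    """
    trace = SelfLearnTrace(config=cfg)
    labeled: Dataset | None = None
    for n in range(1, cfg.n_updates + 1):
        batch = generate_pseudo_labels(detector, unlabeled, cfg.theta)
        if batch.empty:
            raise SelfLearnAbort(
                f"round {n}: no detections scored >= theta={cfg.theta}; "
                "consider lowering theta"
            )
        s_aver = mean_score(batch)
        filtered = filter_by_mean(batch)
        labeled = attach_pseudo_labels(
            unlabeled, filtered, drop_empty=cfg.drop_empty_pseudo_images
        )
        detector.fine_tune(labeled, rounds=cfg.finetune_rounds_per_update)
        record = RoundRecord(
            round=n,
            s_aver=s_aver,
            boxes_before_filter=batch.total,
            boxes_after_filter=filtered.total,
        )
        if test is not None:
            record.report = evaluate_detector(detector, test, score_threshold=cfg.theta)
        trace.rounds.append(record)
        log.info(
            "round %d: S_aver=%.4f, boxes %d -> %d",
            n, s_aver, batch.total, filtered.total,
        )
    assert labeled is not None
    return labeled, detector, trace


@dataclass
class SweepRow:
    """One cell of the threshold sweep; ``theta`` None is the baseline."""

    theta: float | None
    report: EvalReport | None
    aborted: bool = False
    trace: SelfLearnTrace | None = None

    def to_dict(self) -> dict:
        return {
            "theta": self.theta,
            "aborted": self.aborted,
            "report": self.report.to_dict() if self.report else None,
        }


def threshold_sweep(
    detector_factory: Callable[[], Detector],
    unlabeled: Dataset,
    test: Dataset,
    thetas: list[float],
    n_updates: int = 3,
    finetune_rounds_per_update: int = 1,
    seed: int = 0,
    iou_threshold: float = 0.5,
) -> list[SweepRow]:
    """Self-learn at each θ from an identical initial detector state.

    The first row is the no-pseudo-label baseline (the initialized
    detector evaluated directly); remaining rows are ordered by θ.
    Cells whose loop aborts (no candidates at that θ) are flagged rather
    than raising.
    """
    baseline = evaluate_detector(
        detector_factory(), test, iou_threshold, score_threshold=0.5
    )
    rows = [SweepRow(theta=None, report=baseline)]
    for theta in sorted(thetas):
        cfg = SelfLearnConfig(
            theta=theta,
            n_updates=n_updates,
            finetune_rounds_per_update=finetune_rounds_per_update,
            seed=seed,
        )
        detector = detector_factory()
        try:
            _, detector, trace = self_learning_loop(detector, unlabeled, cfg, test=None)
        except SelfLearnAbort:
            rows.append(SweepRow(theta=theta, report=None, aborted=True))
            continue
        report = evaluate_detector(detector, test, iou_threshold, score_threshold=theta)
        rows.append(SweepRow(theta=theta, report=report, trace=trace))
    return rows
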