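"""Pseudo-label generation and dataset-wide mean-score noise filtering.

A detector run over every unlabeled target image at confidence threshold
θ yields candidate boxes; the dataset-wide arithmetic mean of all
candidate scores, S_aver, then acts as an adaptive noise cutoff: only
boxes scoring at least S_aver survive.  Because the maximum of a set is
never below its mean, a non-empty candidate batch always keeps at least
one box.  S_aver is computed over the whole dataset (pooling all images)
by default; a per-image variant exists for ablation only.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

from .core import Dataset, ScoredDetection

__all__ = [
    "PseudoLabelBatch",
    "NoDetectionsError",
    "generate_pseudo_labels",
    "mean_score",
    "filter_by_mean",
    "attach_pseudo_labels",
]

log = logging.getLogger(__name__)


class NoDetectionsError(ValueError):
    """Mean score requested on a batch with zero detections."""


@dataclass
class PseudoLabelBatch:
    """Per-image pseudo-label candidates from one generation pass.

    ``per_image`` maps image_id → list of scored boxes (all ≥ theta).
    """

    per_image: dict[str, list[ScoredDetection]] = field(default_factory=dict)
    theta: float = 0.0

    @property
    def counts(self) -> dict[str, int]:
        """Per-image box counts N_i."""
        return {k: len(v) for k, v in self.per_image.items()}

    @property
    def total(self) -> int:
        """Total box count Σ N_i over the dataset."""
        return sum(len(v) for v in self.per_image.values())

    @property
    def empty(self) -> bool:
        return self.total == 0

    def all_scores(self) -> list[float]:
        return [d.score for dets in self.per_image.values() for d in dets]


def generate_pseudo_labels(detector, ds: Dataset, theta: float) -> PseudoLabelBatch:
    """Run ``detector`` on every image of ``ds`` keeping scores ≥ θ.

    ``ds`` must not carry ground-truth annotations (those are never an
    input to pseudo-labeling); unlabeled or previously pseudo-labeled
    datasets are accepted.  An empty result is a valid batch — callers
    decide whether that aborts a self-learning round.
    """
    if not (0.0 < theta < 1.0):
        raise ValueError(f"theta {theta} outside (0, 1)")
    if ds.labeled == "ground_truth":
        raise ValueError("pseudo-label generation must not consume ground truth")
    per_image: dict[str, list[ScoredDetection]] = {}
    for record in ds.records:
        try:
            dets = detector.detect(record.load_pixels(), theta)
        except Exception as e:
            raise RuntimeError(
                f"detector failed on image {record.image_id!r}: {e}"
            ) from e
        per_image[record.image_id] = [d for d in dets if d.score >= theta]
    batch = PseudoLabelBatch(per_image=per_image, theta=theta)
    if batch.empty:
        log.warning("pseudo-label generation at theta=%.3g produced no boxes", theta)
    return batch


def mean_score(batch: PseudoLabelBatch) -> float:
    """S_aver: arithmetic mean of all box scores pooled over the dataset."""
    if batch.empty:
        raise NoDetectionsError("no detections: S_aver undefined")
    scores = batch.all_scores()
    return sum(scores) / len(scores)


def filter_by_mean(batch: PseudoLabelBatch, per_image: bool = False) -> PseudoLabelBatch:
    """Drop boxes scoring below the batch mean S_aver; ties survive.

    With ``per_image=True`` each image is filtered against its own mean
    (ablation variant); the default pools all scores first.  Empty input
    propagates unchanged.  The comparison carries a tiny absolute
    tolerance so accumulated rounding in the mean can never delete a
    batch of identical scores (the maximum is mathematically ≥ the mean).
    """
    eps = 1e-9
    if batch.empty:
        return PseudoLabelBatch(per_image=dict(batch.per_image), theta=batch.theta)
    if per_image:
        kept = {}
        for k, v in batch.per_image.items():
            if not v:
                kept[k] = []
                continue
            m = sum(x.score for x in v) / len(v)
            kept[k] = [d for d in v if d.score >= m - eps]
    else:
        s_aver = mean_score(batch)
        kept = {
            k: [d for d in v if d.score >= s_aver - eps]
            for k, v in batch.per_image.items()
        }
    return PseudoLabelBatch(per_image=kept, theta=batch.theta)


def attach_pseudo_labels(
    ds: Dataset, batch: PseudoLabelBatch, drop_empty: bool = False
) -> Dataset:
    """Build the pseudo-labeled dataset D_T from a filtered batch.

    Records keep their pixels; pseudo labels replace any previous ones.
    With ``drop_empty`` images left without a single surviving box are
    excluded; otherwise they stay as background-only training images.
    """
    records = []
    for record in ds.records:
        dets = batch.per_image.get(record.image_id, [])
        if drop_empty and not dets:
            continue
        records.append(
            type(record)(
                image_id=record.image_id,
                pixels=record.pixels,
                annotations=[],
                pseudo_labels=list(dets),
            )
        )
    return Dataset(records=records, labeled="pseudo")
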