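"""Shared fixtures: tiny seeded scenes and scripted detectors."""

from dataclasses import replace

import numpy as np
import pytest

from fruitlabel import (
    BoundingBox,
    Dataset,
    ImageRecord,
    SceneSpec,
    ScoredDetection,
    generate_scene,
)


@pytest.fixture(scope="session")
def small_spec() -> SceneSpec:
    """Compact clean spec for fast unit tests: no occlusion, no clutter."""
    return SceneSpec(
        width=96,
        height=96,
        fruit_count=(2, 4),
        radius_mean=10.0,
        radius_sd=1.5,
        occlusion_prob=0.0,
        distractor_count=(0, 0),
    )


@pytest.fixture(scope="session")
def small_scene(small_spec):
    return generate_scene(small_spec, seed=11)


@pytest.fixture(scope="session")
def labeled_dataset(small_spec) -> Dataset:
    records = [
        generate_scene(small_spec, seed=100 + i, image_id=f"img_{i:03d}")
        for i in range(3)
    ]
    return Dataset(records=records, labeled="ground_truth")


class ScriptedDetector:
    """Detector stub replaying per-image detections; records its calls."""

    def __init__(self, per_image: dict[str, list[ScoredDetection]]):
        self.per_image = per_image
        self.by_pixels: dict[bytes, str] = {}
        self.fine_tune_calls: list[Dataset] = []

    @classmethod
    def from_dataset(cls, ds: Dataset, scores_fn=lambda i, j: 0.9):
        """Replays each record's ground truth as scored detections."""
        per_image = {}
        det = cls(per_image)
        for i, record in enumerate(ds.records):
            dets = [
                ScoredDetection(box=b, score=float(scores_fn(i, j)))
                for j, b in enumerate(record.annotations)
            ]
            per_image[record.image_id] = dets
            det.by_pixels[record.load_pixels().tobytes()] = record.image_id
        return det

    def detect(self, image: np.ndarray, theta: float):
        image_id = self.by_pixels[np.asarray(image).tobytes()]
        return [d for d in self.per_image[image_id] if d.score >= theta]

    def fine_tune(self, ds: Dataset, rounds: int = 1):
        self.fine_tune_calls.append(ds)
        return self


def random_box(rng: np.random.Generator, size: int = 100) -> BoundingBox:
    x0, y0 = rng.integers(0, size - 2, 2)
    w, hgt = rng.integers(1, size // 2, 2)
    return BoundingBox(
        float(x0), float(y0),
        float(min(x0 + w, size)), float(min(y0 + hgt, size)),
    )
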