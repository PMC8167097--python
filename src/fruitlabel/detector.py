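"""Trainable color-likelihood blob detector.

This is the packaged reference implementation of the detector contract:
it models fruit appearance as an independent per-channel Gaussian in HSV
space (circular in hue), scores every pixel by the normalized Gaussian
likelihood ``exp(-z²/2)`` averaged over channels, segments the score map
at a fixed gate, and emits one tight box per connected component with
confidence equal to the component's mean pixel score.  Fine-tuning
re-estimates the color model from the pixels under (pseudo-)label boxes
and blends it with the current model, so repeated rounds walk the model
toward the statistics of the images it is being adapted to.

It deliberately has the failure mode that motivates domain adaptation:
a model fitted on one species' colors scores another species' pixels
near zero and detects nothing.
"""

from __future__ import annotations

import json
from dataclasses import asdict, dataclass
from pathlib import Path

import numpy as np
from scipy import ndimage
from skimage.color import rgb2hsv
from skimage.feature import peak_local_max
from skimage.segmentation import watershed

from .core import BoundingBox, Dataset, ScoredDetection

__all__ = ["ColorModel", "ColorLikelihoodDetector", "circular_distance"]

_MIN_SD = 0.01


def circular_distance(a, b):
    """Distance on the unit hue circle, in [0, 0.5]."""
    d = np.abs(np.asarray(a, dtype=float) - b) % 1.0
    return np.minimum(d, 1.0 - d)


def _mad(dev: np.ndarray) -> float:
    """Median absolute deviation scaled to the normal sd."""
    return float(1.4826 * np.median(np.abs(dev)))


def _circular_mean(h: np.ndarray) -> float:
    ang = 2 * np.pi * h
    return float((np.arctan2(np.sin(ang).mean(), np.cos(ang).mean()) / (2 * np.pi)) % 1.0)


@dataclass(frozen=True)
class ColorModel:
    """Per-channel mean/spread of fruit pixels in HSV; hue is circular."""

    h_mean: float
    h_sd: float
    s_mean: float
    s_sd: float
    v_mean: float
    v_sd: float

    @classmethod
    def estimate(cls, h: np.ndarray, s: np.ndarray, v: np.ndarray) -> "ColorModel":
        """Robust location/scale per channel (median / scaled MAD).

        Label boxes inevitably contain some background and occluder
        pixels; median/MAD keeps that contamination from widening the
        model, which would blur the very color specificity the detector
        relies on.
        """
        hm = _circular_mean(h)
        dev = ((h - hm + 0.5) % 1.0) - 0.5
        hm = (hm + float(np.median(dev))) % 1.0
        dev = ((h - hm + 0.5) % 1.0) - 0.5
        return cls(
            h_mean=hm,
            h_sd=max(_mad(dev), _MIN_SD),
            s_mean=float(np.median(s)),
            s_sd=max(_mad(s - np.median(s)), _MIN_SD),
            v_mean=float(np.median(v)),
            v_sd=max(_mad(v - np.median(v)), _MIN_SD),
        )

    def blend(self, other: "ColorModel", lam: float) -> "ColorModel":
        """Convex combination: ``lam`` of ``other``, ``1-lam`` of self.

        Hue means are interpolated along the shorter arc of the circle.
        """
        dev = ((other.h_mean - self.h_mean + 0.5) % 1.0) - 0.5
        return ColorModel(
            h_mean=(self.h_mean + lam * dev) % 1.0,
            h_sd=(1 - lam) * self.h_sd + lam * other.h_sd,
            s_mean=(1 - lam) * self.s_mean + lam * other.s_mean,
            s_sd=(1 - lam) * self.s_sd + lam * other.s_sd,
            v_mean=(1 - lam) * self.v_mean + lam * other.v_mean,
            v_sd=(1 - lam) * self.v_sd + lam * other.v_sd,
        )


def _inscribed_ellipse_pixels(hsv: np.ndarray, box: BoundingBox) -> np.ndarray:
    """HSV pixels inside the ellipse inscribed in a box.

    Fruits are round, so the ellipse inscribed in a tight box covers the
    fruit while excluding the box corners, which are background.
    """
    H, W = hsv.shape[:2]
    x0, x1 = int(np.floor(box.x_min)), int(np.ceil(box.x_max))
    y0, y1 = int(np.floor(box.y_min)), int(np.ceil(box.y_max))
    x0, y0 = max(x0, 0), max(y0, 0)
    x1, y1 = min(x1, W), min(y1, H)
    if x1 <= x0 or y1 <= y0:
        return np.empty((0, 3))
    sub = hsv[y0:y1, x0:x1]
    hh, ww = sub.shape[:2]
    yy, xx = np.mgrid[0:hh, 0:ww]
    cy, cx = (hh - 1) / 2, (ww - 1) / 2
    a, b = max(ww / 2, 0.5), max(hh / 2, 0.5)
    mask = ((xx - cx) / a) ** 2 + ((yy - cy) / b) ** 2 <= 1.0
    return sub[mask].reshape(-1, 3)


class ColorLikelihoodDetector:
    """Fruit detector driven by a per-channel HSV Gaussian color model.

    Parameters
    ----------
    pixel_gate
        Minimum per-pixel likelihood for a pixel to count as fruit when
        segmenting the score map.
    min_area
        Connected components smaller than this many pixels are dropped
        (detector hygiene against speckle).
    blend_weight
        λ of :meth:`fine_tune`: weight given to the statistics of the
        new (pseudo-)labels when blending into the current model.
    """

    def __init__(
        self,
        model: ColorModel | None = None,
        pixel_gate: float = 0.15,
        min_area: int = 9,
        blend_weight: float = 0.5,
    ) -> None:
        self.model = model
        self.pixel_gate = pixel_gate
        self.min_area = min_area
        self.blend_weight = blend_weight

    # -------------------------------------------------------------- fitting

    @staticmethod
    def _collect_box_pixels(ds: Dataset) -> np.ndarray:
        chunks = []
        for record in ds.records:
            boxes = [b for b in record.annotations] + [
                d.box for d in record.pseudo_labels
            ]
            if not boxes:
                continue
            hsv = rgb2hsv(record.load_pixels())
            for box in boxes:
                px = _inscribed_ellipse_pixels(hsv, box)
                if len(px):
                    chunks.append(px)
        if not chunks:
            raise ValueError("no labeled boxes to estimate a color model from")
        return np.concatenate(chunks, axis=0)

    def fit(self, ds: Dataset) -> "ColorLikelihoodDetector":
        """Estimate the color model from all labeled boxes in ``ds``."""
        px = self._collect_box_pixels(ds)
        self.model = ColorModel.estimate(px[:, 0], px[:, 1], px[:, 2])
        return self

    def fine_tune(self, ds: Dataset, rounds: int = 1) -> "ColorLikelihoodDetector":
        """Blend the current model toward the statistics of ``ds``'s boxes.

        Each round re-estimates a model from the (pseudo-)label regions
        and moves the current model a ``blend_weight`` fraction of the
        way there.
        """
        if self.model is None:
            raise ValueError("fine_tune requires an initialized model; call fit first")
        if rounds < 1:
            raise ValueError("rounds must be >= 1")
        for _ in range(rounds):
            px = self._collect_box_pixels(ds)
            est = ColorModel.estimate(px[:, 0], px[:, 1], px[:, 2])
            self.model = self.model.blend(est, self.blend_weight)
        return self

    # ------------------------------------------------------------ inference

    def score_map(self, image: np.ndarray) -> np.ndarray:
        """Per-pixel likelihood in [0, 1] under the current color model."""
        if self.model is None:
            raise ValueError("detector has no color model; call fit first")
        if image.ndim != 3 or image.shape[2] != 3:
            raise ValueError(f"expected H×W×3 image, got shape {image.shape}")
        m = self.model
        hsv = rgb2hsv(image)
        zh = circular_distance(hsv[..., 0], m.h_mean) / m.h_sd
        zs = (hsv[..., 1] - m.s_mean) / m.s_sd
        zv = (hsv[..., 2] - m.v_mean) / m.v_sd
        z2 = (zh**2 + zs**2 + zv**2) / 3.0
        return np.exp(-0.5 * z2)

    def _segment(self, mask: np.ndarray) -> tuple[np.ndarray, int]:
        """Split the fruit mask into blobs, separating touching fruits.

        Connected components are refined by a distance-transform
        watershed — the standard recipe for clusters of round objects —
        so two tangent fruits yield two blobs instead of one.
        """
        mask = ndimage.binary_closing(mask, structure=np.ones((3, 3), dtype=bool))
        mask = ndimage.binary_fill_holes(mask)
        labels, n = ndimage.label(mask, structure=np.ones((3, 3), dtype=int))
        if n == 0:
            return labels, 0
        dist = ndimage.distance_transform_edt(mask)
        smooth = ndimage.gaussian_filter(dist, sigma=2.0)
        # only strong, well-separated cores split a component
        peaks = peak_local_max(
            smooth, min_distance=12, threshold_abs=3.0,
            labels=labels, exclude_border=False,
        )
        markers = np.zeros(mask.shape, dtype=np.int32)
        seeded: set[int] = set()
        mid = 0
        for r, c in peaks:
            mid += 1
            markers[r, c] = mid
            seeded.add(int(labels[r, c]))
        if mid <= n and len(seeded) == n:
            return labels, n
        for comp in range(1, n + 1):
            if comp in seeded:
                continue
            ys, xs = np.nonzero(labels == comp)
            k = int(np.argmax(dist[ys, xs]))
            mid += 1
            markers[ys[k], xs[k]] = mid
        ws = watershed(-smooth, markers=markers, mask=mask)
        return ws, int(ws.max())

    def detect(self, image: np.ndarray, theta: float = 0.0) -> list[ScoredDetection]:
        """Detect fruit blobs with confidence ≥ ``theta``.

        Deterministic given the model state and image: the score map is
        gated at ``pixel_gate``, split into blobs (watershed over the
        distance transform so touching fruits separate), blobs below
        ``min_area`` are dropped, and each box's confidence is the mean
        pixel likelihood over its blob.
        """
        scores = self.score_map(image)
        mask = scores >= self.pixel_gate
        labels, n = self._segment(mask)
        out: list[ScoredDetection] = []
        for comp in range(1, n + 1):
            ys, xs = np.nonzero(labels == comp)
            if len(ys) < self.min_area:
                continue
            conf = float(np.clip(scores[ys, xs].mean(), 0.0, 1.0))
            if conf < theta:
                continue
            box = BoundingBox(
                float(xs.min()), float(ys.min()),
                float(xs.max() + 1), float(ys.max() + 1),
            )
            out.append(ScoredDetection(box=box, score=conf))
        out.sort(key=lambda d: (-d.score, d.box.x_min, d.box.y_min))
        return out

    # -------------------------------------------------------- serialization

    def clone(self) -> "ColorLikelihoodDetector":
        return ColorLikelihoodDetector(
            model=self.model,
            pixel_gate=self.pixel_gate,
            min_area=self.min_area,
            blend_weight=self.blend_weight,
        )

    def to_dict(self) -> dict:
        return {
            "model": asdict(self.model) if self.model else None,
            "pixel_gate": self.pixel_gate,
            "min_area": self.min_area,
            "blend_weight": self.blend_weight,
        }

    def save(self, path: Path | str) -> None:
        Path(path).write_text(json.dumps(self.to_dict(), indent=1))

    @classmethod
    def load(cls, path: Path | str) -> "ColorLikelihoodDetector":
        doc = json.loads(Path(path).read_text())
        model = ColorModel(**doc["model"]) if doc.get("model") else None
        return cls(
            model=model,
            pixel_gate=doc.get("pixel_gate", 0.15),
            min_area=doc.get("min_area", 9),
            blend_weight=doc.get("blend_weight", 0.5),
        )
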