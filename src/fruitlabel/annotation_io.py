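"""Read and write detection annotations in VOC XML, YOLO txt, COCO JSON.

On-disk layout (shared by all formats)::

    root/
      images/            *.png or *.jpg, one per record
      annotations/       VOC: one <image_id>.xml per image
      labels/            YOLO: one <image_id>.txt per image
      annotations.json   COCO: single file

Dialects and conversions to the internal 0-based half-open convention:

* **VOC XML** is 1-based with an inclusive max corner, the de-facto
  dialect: disk ``(xmin, ymin, xmax, ymax)`` maps to internal
  ``(xmin-1, ymin-1, xmax, ymax)`` and back.  Confidence scores, when
  requested, go into a non-standard ``<score>`` child of ``<object>``.
* **YOLO txt** lines are ``class cx cy w h [score]`` with coordinates
  normalized by image size; converted to pixel corners on read.
* **COCO JSON** boxes are ``[x, y, width, height]`` in pixels; category
  id 1 is "fruit"; scores go into the standard ``score`` field.

Records are ordered by lexicographic image filename, so reading is
stable.  Images with no annotation file read back as unlabeled records.
"""

from __future__ import annotations

import json
import logging
import warnings
from enum import Enum
from pathlib import Path

import numpy as np
from lxml import etree
from PIL import Image

from .core import (
    BoundingBox,
    Dataset,
    EmptyBoxError,
    ImageRecord,
    ScoredDetection,
    clip_box,
)

__all__ = ["AnnotationFormat", "read_dataset", "write_dataset"]

log = logging.getLogger(__name__)

IMAGE_EXTENSIONS = (".png", ".jpg", ".jpeg")


class AnnotationFormat(str, Enum):
    voc_xml = "voc_xml"
    yolo_txt = "yolo_txt"
    coco_json = "coco_json"


class AnnotationParseError(ValueError):
    """Malformed annotation file; message names the file and field."""


def _image_files(root: Path) -> list[Path]:
    img_dir = root / "images"
    if not img_dir.is_dir():
        raise FileNotFoundError(f"no images/ directory under {root}")
    return sorted(
        p for p in img_dir.iterdir() if p.suffix.lower() in IMAGE_EXTENSIONS
    )


def _image_size(path: Path) -> tuple[int, int]:
    with Image.open(path) as im:
        return im.size  # (width, height)


def _safe_clip(box: BoundingBox, w: int, h: int, source: str) -> BoundingBox | None:
    if 0 <= box.x_min and 0 <= box.y_min and box.x_max <= w and box.y_max <= h:
        return box
    warnings.warn(f"{source}: box extends outside {w}x{h} image; clipping")
    try:
        return clip_box(box, w, h)
    except EmptyBoxError:
        warnings.warn(f"{source}: box entirely outside image; dropped")
        return None


# ---------------------------------------------------------------- VOC XML


def _read_voc(path: Path, w: int, h: int) -> tuple[list[BoundingBox], list[float | None]]:
    try:
        tree = etree.parse(str(path))
    except etree.XMLSyntaxError as e:
        raise AnnotationParseError(f"{path}: malformed XML: {e}") from e
    boxes, scores = [], []
    for obj in tree.findall(".//object"):
        name_el = obj.find("name")
        name = name_el.text.strip() if name_el is not None and name_el.text else "fruit"
        bnd = obj.find("bndbox")
        if bnd is None:
            raise AnnotationParseError(f"{path}: <object> without <bndbox>")
        vals = {}
        for key in ("xmin", "ymin", "xmax", "ymax"):
            el = bnd.find(key)
            if el is None or el.text is None:
                raise AnnotationParseError(f"{path}: <bndbox> missing <{key}>")
            try:
                vals[key] = float(el.text)
            except ValueError as e:
                raise AnnotationParseError(
                    f"{path}: non-numeric <{key}> value {el.text!r}"
                ) from e
        box = BoundingBox(
            vals["xmin"] - 1.0, vals["ymin"] - 1.0, vals["xmax"], vals["ymax"],
            class_label=name,
        )
        box = _safe_clip(box, w, h, str(path))
        if box is None:
            continue
        score_el = obj.find("score")
        boxes.append(box)
        scores.append(float(score_el.text) if score_el is not None else None)
    return boxes, scores


def _write_voc(record: ImageRecord, path: Path, w: int, h: int,
               boxes: list[BoundingBox], scores: list[float | None]) -> None:
    root = etree.Element("annotation")
    etree.SubElement(root, "filename").text = record.image_id
    size = etree.SubElement(root, "size")
    etree.SubElement(size, "width").text = str(w)
    etree.SubElement(size, "height").text = str(h)
    etree.SubElement(size, "depth").text = "3"
    for box, score in zip(boxes, scores):
        obj = etree.SubElement(root, "object")
        etree.SubElement(obj, "name").text = box.class_label
        bnd = etree.SubElement(obj, "bndbox")
        etree.SubElement(bnd, "xmin").text = repr(box.x_min + 1.0)
        etree.SubElement(bnd, "ymin").text = repr(box.y_min + 1.0)
        etree.SubElement(bnd, "xmax").text = repr(box.x_max)
        etree.SubElement(bnd, "ymax").text = repr(box.y_max)
        if score is not None:
            etree.SubElement(obj, "score").text = repr(score)
    path.write_bytes(etree.tostring(root, pretty_print=True))


# ---------------------------------------------------------------- YOLO txt


def _read_yolo(path: Path, w: int, h: int) -> tuple[list[BoundingBox], list[float | None]]:
    boxes, scores = [], []
    for ln, line in enumerate(path.read_text().splitlines(), start=1):
        line = line.strip()
        if not line:
            continue
        parts = line.split()
        if len(parts) not in (5, 6):
            raise AnnotationParseError(
                f"{path}:{ln}: expected 'class cx cy w h [score]', got {line!r}"
            )
        try:
            cx, cy, bw, bh = (float(p) for p in parts[1:5])
        except ValueError as e:
            raise AnnotationParseError(f"{path}:{ln}: non-numeric field") from e
        box = BoundingBox(
            (cx - bw / 2) * w, (cy - bh / 2) * h,
            (cx + bw / 2) * w, (cy + bh / 2) * h,
        )
        box = _safe_clip(box, w, h, f"{path}:{ln}")
        if box is None:
            continue
        boxes.append(box)
        scores.append(float(parts[5]) if len(parts) == 6 else None)
    return boxes, scores


def _write_yolo(path: Path, w: int, h: int,
                boxes: list[BoundingBox], scores: list[float | None]) -> None:
    lines = []
    for box, score in zip(boxes, scores):
        cx = (box.x_min + box.x_max) / 2 / w
        cy = (box.y_min + box.y_max) / 2 / h
        fields = [
            "0",
            repr(cx), repr(cy), repr(box.width / w), repr(box.height / h),
        ]
        if score is not None:
            fields.append(repr(score))
        lines.append(" ".join(fields))
    path.write_text("\n".join(lines) + ("\n" if lines else ""))


# --------------------------------------------------------------- COCO JSON


def _read_coco(path: Path, sizes: dict[str, tuple[int, int]]):
    try:
        doc = json.loads(path.read_text())
    except json.JSONDecodeError as e:
        raise AnnotationParseError(f"{path}: malformed JSON: {e}") from e
    for key in ("images", "annotations", "categories"):
        if key not in doc:
            raise AnnotationParseError(f"{path}: missing top-level '{key}'")
    cat_names = {c["id"]: c.get("name", "fruit") for c in doc["categories"]}
    id_to_name: dict[int, str] = {}
    for im in doc["images"]:
        stem = Path(im["file_name"]).stem
        id_to_name[im["id"]] = stem
    per_image: dict[str, tuple[list[BoundingBox], list[float | None]]] = {
        n: ([], []) for n in id_to_name.values()
    }
    for ann in doc["annotations"]:
        image_id = ann.get("image_id")
        if image_id not in id_to_name:
            raise AnnotationParseError(
                f"{path}: annotation {ann.get('id')} references unknown image_id {image_id}"
            )
        stem = id_to_name[image_id]
        try:
            x, y, bw, bh = ann["bbox"]
        except (KeyError, ValueError) as e:
            raise AnnotationParseError(
                f"{path}: annotation {ann.get('id')}: bad 'bbox' field"
            ) from e
        w, h = sizes[stem]
        box = BoundingBox(x, y, x + bw, y + bh,
                          class_label=cat_names.get(ann.get("category_id", 1), "fruit"))
        box = _safe_clip(box, w, h, f"{path}#ann{ann.get('id')}")
        if box is None:
            continue
        per_image[stem][0].append(box)
        per_image[stem][1].append(ann.get("score"))
    return per_image


def _write_coco(path: Path, records, sizes, all_boxes, all_scores) -> None:
    images, annotations = [], []
    ann_id = 1
    for idx, record in enumerate(records, start=1):
        w, h = sizes[record.image_id]
        images.append(
            {"id": idx, "file_name": f"{record.image_id}.png", "width": w, "height": h}
        )
        for box, score in zip(all_boxes[record.image_id], all_scores[record.image_id]):
            ann = {
                "id": ann_id,
                "image_id": idx,
                "category_id": 1,
                "bbox": [box.x_min, box.y_min, box.width, box.height],
                "area": box.area,
                "iscrowd": 0,
            }
            if score is not None:
                ann["score"] = score
            annotations.append(ann)
            ann_id += 1
    doc = {
        "images": images,
        "annotations": annotations,
        "categories": [{"id": 1, "name": "fruit"}],
    }
    path.write_text(json.dumps(doc, indent=1))


# ----------------------------------------------------------------- public


def read_dataset(root: Path | str, format: AnnotationFormat | str) -> Dataset:
    """Load a dataset from ``root`` in the given annotation format.

    Images with no annotation file yield records with empty annotation
    lists.  The returned dataset is flagged ``ground_truth`` when boxes
    without scores are present, ``pseudo`` when every box is scored, and
    ``unlabeled`` when there are no boxes at all.
    """
    root = Path(root)
    fmt = AnnotationFormat(format)
    files = _image_files(root)
    sizes = {p.stem: _image_size(p) for p in files}

    coco = None
    if fmt is AnnotationFormat.coco_json:
        coco_path = root / "annotations.json"
        coco = _read_coco(coco_path, sizes) if coco_path.exists() else {}

    records = []
    any_plain = any_scored = False
    for p in files:
        w, h = sizes[p.stem]
        if fmt is AnnotationFormat.voc_xml:
            ann = root / "annotations" / f"{p.stem}.xml"
            boxes, scores = _read_voc(ann, w, h) if ann.exists() else ([], [])
        elif fmt is AnnotationFormat.yolo_txt:
            ann = root / "labels" / f"{p.stem}.txt"
            boxes, scores = _read_yolo(ann, w, h) if ann.exists() else ([], [])
        else:
            boxes, scores = coco.get(p.stem, ([], []))
        record = ImageRecord(image_id=p.stem, pixels=p)
        for box, score in zip(boxes, scores):
            if score is None:
                record.annotations.append(box)
                any_plain = True
            else:
                record.pseudo_labels.append(ScoredDetection(box=box, score=score))
                any_scored = True
        records.append(record)

    labeled = "ground_truth" if any_plain else ("pseudo" if any_scored else "unlabeled")
    return Dataset(records=records, labeled=labeled)


def write_dataset(
    ds: Dataset,
    root: Path | str,
    format: AnnotationFormat | str,
    include_scores: bool = False,
    write_images: bool = True,
) -> None:
    """Write a dataset (images + annotations) under ``root``.

    Ground-truth boxes are written scoreless.  Pseudo labels are written
    with their confidence when ``include_scores`` is set and scoreless
    otherwise.  Files written by this function read back to an equal
    dataset via :func:`read_dataset`.
    """
    root = Path(root)
    fmt = AnnotationFormat(format)
    (root / "images").mkdir(parents=True, exist_ok=True)

    sizes: dict[str, tuple[int, int]] = {}
    all_boxes: dict[str, list[BoundingBox]] = {}
    all_scores: dict[str, list[float | None]] = {}
    for record in ds.records:
        arr = record.load_pixels()
        sizes[record.image_id] = (arr.shape[1], arr.shape[0])
        if write_images:
            Image.fromarray(arr).save(root / "images" / f"{record.image_id}.png")
        boxes: list[BoundingBox] = list(record.annotations)
        scores: list[float | None] = [None] * len(record.annotations)
        for det in record.pseudo_labels:
            boxes.append(det.box)
            scores.append(det.score if include_scores else None)
        all_boxes[record.image_id] = boxes
        all_scores[record.image_id] = scores

    if fmt is AnnotationFormat.coco_json:
        _write_coco(root / "annotations.json", ds.records, sizes, all_boxes, all_scores)
        return
    sub = "annotations" if fmt is AnnotationFormat.voc_xml else "labels"
    (root / sub).mkdir(exist_ok=True)
    for record in ds.records:
        w, h = sizes[record.image_id]
        boxes, scores = all_boxes[record.image_id], all_scores[record.image_id]
        if not boxes:
            # no annotation file for an unlabeled record, mirroring read
            continue
        if fmt is AnnotationFormat.voc_xml:
            _write_voc(record, root / sub / f"{record.image_id}.xml", w, h, boxes, scores)
        else:
            _write_yolo(root / sub / f"{record.image_id}.txt", w, h, boxes, scores)
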