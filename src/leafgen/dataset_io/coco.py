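"""COCO instance-segmentation JSON export/import.

Masks are stored either as uncompressed COCO RLE (column-major run lengths,
first run counting zeros — always lossless) or as boundary-traced polygons
(pixel-corner coordinates; exact for hole-free instances, holes are filled
on encode, matching common COCO practice). Bounding boxes are COCO
``[x, y, w, h]``; ``area`` is the decoded mask's pixel count. Category ids:
leaf = 1, branch = 2.

Amodal masks, when present, go to a parallel annotation file with the
``.amodal.json`` suffix so the visible file stays standard-compliant.
"""

from __future__ import annotations

import json
from pathlib import Path

import numpy as np
import shapely
from PIL import Image

from ..render import InstanceMaskSet

__all__ = [
    "encode_rle",
    "decode_rle",
    "encode_polygon",
    "decode_polygon",
    "write_coco",
    "read_coco",
    "CocoFormatError",
]

CATEGORIES = [
    {"id": 1, "name": "leaf", "supercategory": "plant"},
    {"id": 2, "name": "branch", "supercategory": "plant"},
]


class CocoFormatError(ValueError):
    pass


def encode_rle(mask: np.ndarray) -> dict:
    """Uncompressed COCO RLE: column-major runs, starting with the 0-run."""
    m = np.asarray(mask, np.uint8)
    h, w = m.shape
    flat = m.flatten(order="F")
    if flat.size == 0:
        return {"size": [h, w], "counts": []}
    change = np.flatnonzero(flat[1:] != flat[:-1]) + 1
    bounds = np.concatenate([[0], change, [flat.size]])
    counts = np.diff(bounds).tolist()
    if flat[0] == 1:
        counts = [0] + counts
    return {"size": [h, w], "counts": [int(c) for c in counts]}


def decode_rle(rle: dict) -> np.ndarray:
    h, w = rle["size"]
    flat = np.zeros(h * w, dtype=np.uint8)
    pos, val = 0, 0
    for count in rle["counts"]:
        if val:
            flat[pos : pos + count] = 1
        pos += count
        val ^= 1
    if pos != h * w:
        raise CocoFormatError(f"RLE counts sum to {pos}, expected {h * w}")
    return flat.reshape((h, w), order="F")


def encode_polygon(mask: np.ndarray) -> list[list[float]]:
    """Trace each connected component's outer boundary as a pixel-corner
    polygon (holes filled). Coordinates are (x, y) at pixel corners."""
    m = np.asarray(mask, bool)
    ys, xs = np.nonzero(m)
    if len(ys) == 0:
        return []
    boxes = shapely.box(xs.astype(float), ys.astype(float), xs + 1.0, ys + 1.0)
    geom = shapely.union_all(boxes)
    polys = getattr(geom, "geoms", [geom])
    rings = []
    for poly in polys:
        coords = np.asarray(poly.exterior.coords)[:-1]  # drop closing vertex
        rings.append([float(v) for xy in coords for v in xy])
    return rings


def decode_polygon(rings: list[list[float]], size: tuple[int, int]) -> np.ndarray:
    """Rasterize polygon rings by testing pixel centers for containment;
    multiple rings are unioned."""
    h, w = size
    mask = np.zeros((h, w), dtype=np.uint8)
    if not rings:
        return mask
    cx, cy = np.meshgrid(np.arange(w) + 0.5, np.arange(h) + 0.5)
    for ring in rings:
        pts = np.asarray(ring, float).reshape(-1, 2)
        poly = shapely.Polygon(pts)
        inside = shapely.contains_xy(poly, cx.ravel(), cy.ravel()).reshape(h, w)
        mask |= inside.astype(np.uint8)
    return mask


def _annotation(ann_id, image_id, instance_id, mask, category_id, fmt, visibility=None):
    mask = np.asarray(mask, np.uint8)
    area = int(mask.sum())
    ys, xs = np.nonzero(mask)
    if area:
        x0, y0 = int(xs.min()), int(ys.min())
        bw, bh = int(xs.max()) - x0 + 1, int(ys.max()) - y0 + 1
    else:
        x0 = y0 = bw = bh = 0
    if fmt == "rle":
        seg = encode_rle(mask)
    elif fmt == "polygon":
        seg = encode_polygon(mask)
    else:
        raise CocoFormatError(f"unknown segmentation format {fmt!r}")
    ann = {
        "id": ann_id,
        "image_id": image_id,
        "category_id": category_id,
        "segmentation": seg,
        "bbox": [x0, y0, bw, bh],
        "area": area,
        "iscrowd": 0,
        "instance_id": int(instance_id),
    }
    if visibility is not None:
        ann["visibility"] = float(visibility)
    return ann


def write_coco(
    records,
    path: str | Path,
    *,
    segmentation_format: str = "rle",
    write_images: bool = True,
    amodal: str = "auto",
) -> Path:
    """Write dataset records as a COCO annotation file plus PNG images.

    ``records`` iterates over objects with ``image_id``, ``image`` (HxWx3
    uint8 or None) and ``masks`` (:class:`InstanceMaskSet`). ``amodal`` of
    ``"auto"`` writes the parallel ``.amodal.json`` file whenever any record
    carries amodal masks; ``"never"`` suppresses it.
    Returns the annotation file path.
    """
    path = Path(path)
    path.parent.mkdir(parents=True, exist_ok=True)
    img_dir = path.parent / "images"

    images, annotations, amodal_annotations = [], [], []
    ann_id = 1
    has_amodal = False
    for idx, rec in enumerate(records):
        image_id = idx + 1
        masks: InstanceMaskSet = rec.masks
        h, w = masks.image_size
        file_name = f"images/{rec.image_id}.png"
        images.append({"id": image_id, "file_name": file_name, "height": h, "width": w})
        if write_images and rec.image is not None:
            img_dir.mkdir(parents=True, exist_ok=True)
            Image.fromarray(np.asarray(rec.image, np.uint8)).save(path.parent / file_name)
        for k in masks.instance_ids:
            mask = masks.visible_masks[k]
            if not mask.any():
                continue
            annotations.append(
                _annotation(
                    ann_id, image_id, k, mask, 1, segmentation_format,
                    visibility=masks.visibility.get(k),
                )
            )
            ann_id += 1
        for k in sorted(masks.amodal_masks):
            has_amodal = True
            amodal_annotations.append(
                _annotation(
                    len(amodal_annotations) + 1, image_id, k,
                    masks.amodal_masks[k], 1, segmentation_format,
                )
            )

    doc = {"images": images, "annotations": annotations, "categories": CATEGORIES}
    path.write_text(json.dumps(doc))
    if has_amodal and amodal == "auto":
        amodal_doc = {
            "images": images,
            "annotations": amodal_annotations,
            "categories": CATEGORIES,
        }
        path.with_suffix(".amodal.json").write_text(json.dumps(amodal_doc))
    return path


def read_coco(path: str | Path, *, load_images: bool = True):
    """Inverse of :func:`write_coco`: returns a list of loaded records.

    Each record is a simple namespace with ``image_id``, ``image`` and
    ``masks`` (:class:`InstanceMaskSet` with visible masks, bboxes and any
    amodal masks found in the parallel ``.amodal.json`` file).
    """
    from types import SimpleNamespace

    path = Path(path)
    try:
        doc = json.loads(path.read_text())
    except json.JSONDecodeError as exc:
        raise CocoFormatError(f"not valid JSON: {path}: {exc}") from exc
    for key in ("images", "annotations", "categories"):
        if key not in doc:
            raise CocoFormatError(f"missing top-level key {key!r} in {path}")

    amodal_doc = None
    amodal_path = path.with_suffix(".amodal.json")
    if amodal_path.exists():
        amodal_doc = json.loads(amodal_path.read_text())

    def decode(seg, size):
        if isinstance(seg, dict):
            return decode_rle(seg)
        return decode_polygon(seg, size)

    records = []
    anns_by_image: dict[int, list[dict]] = {}
    for ann in doc["annotations"]:
        anns_by_image.setdefault(ann["image_id"], []).append(ann)
    amodal_by_image: dict[int, list[dict]] = {}
    if amodal_doc:
        for ann in amodal_doc["annotations"]:
            amodal_by_image.setdefault(ann["image_id"], []).append(ann)

    for img in doc["images"]:
        h, w = img["height"], img["width"]
        image = None
        if load_images:
            img_path = path.parent / img["file_name"]
            if not img_path.exists():
                raise CocoFormatError(
                    f"image file missing for image id {img['id']}: {img_path}"
                )
            image = np.asarray(Image.open(img_path).convert("RGB"))
        visible, bboxes, visibility = {}, {}, {}
        label = np.zeros((h, w), dtype=np.int32)
        for ann in anns_by_image.get(img["id"], []):
            k = int(ann.get("instance_id", ann["id"]))
            mask = decode(ann["segmentation"], (h, w))
            visible[k] = mask
            x, y, bw, bh = ann["bbox"]
            bboxes[k] = (int(x), int(y), int(x + bw), int(y + bh))
            if "visibility" in ann:
                visibility[k] = ann["visibility"]
            label[mask.astype(bool)] = k
        amodal = {}
        for ann in amodal_by_image.get(img["id"], []):
            k = int(ann.get("instance_id", ann["id"]))
            amodal[k] = decode(ann["segmentation"], (h, w))
        mask_set = InstanceMaskSet(
            label_image=label,
            visible_masks=visible,
            amodal_masks=amodal,
            bboxes=bboxes,
            visibility=visibility,
        )
        stem = Path(img["file_name"]).stem
        records.append(SimpleNamespace(image_id=stem, image=image, masks=mask_set))
    return records
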