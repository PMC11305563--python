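"""16-keypoint cattle annotation schema and format interchange.

Annotations travel in two dialects:

* Labelme-style JSON: one document per image with rectangle shapes for boxes
  and named point shapes for keypoints, grouped per instance via ``group_id``.
  An occluded-but-labeled keypoint carries ``flags: {"occluded": true}``.
* YOLO-pose text: one line per instance,
  ``class cx cy w h  x1 y1 v1 ... x16 y16 v16`` (53 space-separated fields),
  all coordinates normalized to [0, 1].  Visibility follows the COCO
  convention: 0 = not labeled (x = y = 0), 1 = labeled but occluded,
  2 = visible.

Coordinates are 0-based, pixel-continuous, origin top-left; normalization
divides by image width/height.  Conversion is lossless for in-frame keypoints
to 1e-6 normalized units.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path
from typing import Optional, Sequence

import numpy as np

from .types import KeypointInstance

KEYPOINT_NAMES = (
    "head top", "neck", "spine",
    "right front thigh root", "right front knee", "right front hoof",
    "left front thigh root", "left front knee", "left front hoof",
    "coccyx",
    "right hind thigh root", "right hind knee", "right hind hoof",
    "left hind thigh root", "left hind knee", "left hind hoof",
)
NUM_KEYPOINTS = len(KEYPOINT_NAMES)
_NAME_INDEX = {n: i for i, n in enumerate(KEYPOINT_NAMES)}

YOLO_FIELDS = 5 + 3 * NUM_KEYPOINTS  # 53


class FormatError(ValueError):
    """Structurally malformed document (missing image size, bad JSON...)."""


class ValidationError(ValueError):
    """Well-formed document violating the keypoint schema."""


@dataclass
class LabelmeInstance:
    """One annotated cattle: pixel box corners and named keypoints."""

    box: tuple[float, float, float, float]  # x1, y1, x2, y2 (two corners)
    # name -> (x, y, occluded); absent names mean keypoint not labeled
    points: dict[str, tuple[float, float, bool]] = field(default_factory=dict)

    def __post_init__(self):
        for name in self.points:
            if name not in _NAME_INDEX:
                raise ValidationError(
                    f"unknown keypoint name {name!r}; allowed: "
                    + ", ".join(KEYPOINT_NAMES))


@dataclass
class LabelmeDocument:
    image_path: str
    width: int
    height: int
    channels: int = 3
    instances: list[LabelmeInstance] = field(default_factory=list)


@dataclass
class YoloPoseRecord:
    """One normalized text record; class 0 = cattle."""

    class_id: int
    cx: float
    cy: float
    w: float
    h: float
    keypoints: tuple  # 16 x (x, y, v)

    def to_line(self) -> str:
        vals = [f"{self.class_id:d}"]
        vals += [f"{v:.6f}" for v in (self.cx, self.cy, self.w, self.h)]
        for x, y, v in self.keypoints:
            vals += [f"{x:.6f}", f"{y:.6f}", f"{int(v):d}"]
        return " ".join(vals)

    @classmethod
    def from_line(cls, line: str) -> "YoloPoseRecord":
        parts = line.split()
        if len(parts) != YOLO_FIELDS:
            raise FormatError(f"expected {YOLO_FIELDS} fields, got {len(parts)}")
        cid = int(parts[0])
        cx, cy, w, h = map(float, parts[1:5])
        kpts = []
        for i in range(NUM_KEYPOINTS):
            x, y, v = parts[5 + 3 * i: 8 + 3 * i]
            kpts.append((float(x), float(y), int(float(v))))
        return cls(cid, cx, cy, w, h, tuple(kpts))


# ---------------------------------------------------------------------------
# Labelme JSON
# ---------------------------------------------------------------------------

def read_labelme(path) -> LabelmeDocument:
    try:
        raw = json.loads(Path(path).read_text())
    except json.JSONDecodeError as e:
        raise FormatError(f"invalid JSON: {e}") from e
    return parse_labelme(raw)


def parse_labelme(raw: dict) -> LabelmeDocument:
    for key in ("imageWidth", "imageHeight"):
        if key not in raw:
            raise FormatError(f"missing {key}")
    doc = LabelmeDocument(
        image_path=raw.get("imagePath", ""),
        width=int(raw["imageWidth"]), height=int(raw["imageHeight"]),
        channels=int(raw.get("imageChannels", 3)))
    groups: dict[int, dict] = {}
    for shape in raw.get("shapes", []):
        gid = shape.get("group_id") or 0
        entry = groups.setdefault(gid, {"box": None, "points": {}})
        stype = shape.get("shape_type")
        if stype == "rectangle":
            (x1, y1), (x2, y2) = shape["points"]
            entry["box"] = (min(x1, x2), min(y1, y2), max(x1, x2), max(y1, y2))
        elif stype == "point":
            name = shape["label"]
            if name not in _NAME_INDEX:
                raise ValidationError(
                    f"unknown keypoint name {name!r}; allowed: "
                    + ", ".join(KEYPOINT_NAMES))
            if name in entry["points"]:
                raise ValidationError(f"duplicate keypoint {name!r} in one instance")
            (x, y), = shape["points"]
            occluded = bool(shape.get("flags", {}).get("occluded", False))
            entry["points"][name] = (float(x), float(y), occluded)
        else:
            raise FormatError(f"unsupported shape_type {stype!r}")
    for gid in sorted(groups):
        entry = groups[gid]
        if entry["box"] is None:
            raise ValidationError(f"instance {gid} has no bounding box")
        doc.instances.append(LabelmeInstance(entry["box"], entry["points"]))
    return doc


def labelme_to_json(doc: LabelmeDocument) -> dict:
    shapes = []
    for gid, inst in enumerate(doc.instances):
        x1, y1, x2, y2 = inst.box
        shapes.append({"label": "cattle", "shape_type": "rectangle",
                       "points": [[x1, y1], [x2, y2]], "group_id": gid,
                       "flags": {}})
        for name in KEYPOINT_NAMES:
            if name not in inst.points:
                continue
            x, y, occluded = inst.points[name]
            shapes.append({"label": name, "shape_type": "point",
                           "points": [[x, y]], "group_id": gid,
                           "flags": {"occluded": occluded}})
    return {"version": "5.0.0", "flags": {}, "shapes": shapes,
            "imagePath": doc.image_path, "imageData": None,
            "imageHeight": doc.height, "imageWidth": doc.width,
            "imageChannels": doc.channels}


def write_labelme(doc: LabelmeDocument, path) -> None:
    Path(path).write_text(json.dumps(labelme_to_json(doc), indent=1))


# ---------------------------------------------------------------------------
# conversion
# ---------------------------------------------------------------------------

def labelme_to_yolo(doc: LabelmeDocument) -> list[YoloPoseRecord]:
    """Convert corner boxes and named keypoints to normalized pose records.

    In-frame visible keypoints get v=2, occluded ones v=1; missing or
    out-of-frame keypoints become (0, 0, 0).
    """
    if doc.width <= 0 or doc.height <= 0:
        raise FormatError("image size must be positive")
    records = []
    for inst in doc.instances:
        x1, y1, x2, y2 = inst.box
        bw, bh = x2 - x1, y2 - y1
        if bw <= 0 or bh <= 0:
            raise ValidationError("zero-area bounding box")
        cx, cy = (x1 + x2) / 2 / doc.width, (y1 + y2) / 2 / doc.height
        kpts = []
        for name in KEYPOINT_NAMES:
            if name not in inst.points:
                kpts.append((0.0, 0.0, 0))
                continue
            x, y, occluded = inst.points[name]
            if not (0 <= x < doc.width and 0 <= y < doc.height):
                kpts.append((0.0, 0.0, 0))
                continue
            kpts.append((x / doc.width, y / doc.height, 1 if occluded else 2))
        records.append(YoloPoseRecord(0, cx, cy, bw / doc.width,
                                      bh / doc.height, tuple(kpts)))
    return records


def yolo_to_labelme(records: Sequence[YoloPoseRecord], image_path: str,
                    width: int, height: int) -> LabelmeDocument:
    doc = LabelmeDocument(image_path, width, height)
    for rec in records:
        bw, bh = rec.w * width, rec.h * height
        x1, y1 = rec.cx * width - bw / 2, rec.cy * height - bh / 2
        points = {}
        for name, (x, y, v) in zip(KEYPOINT_NAMES, rec.keypoints):
            if v == 0:
                continue
            points[name] = (x * width, y * height, v == 1)
        doc.instances.append(LabelmeInstance((x1, y1, x1 + bw, y1 + bh), points))
    return doc


def write_yolo(records: Sequence[YoloPoseRecord], path) -> None:
    Path(path).write_text("".join(r.to_line() + "\n" for r in records))


def read_yolo(path) -> list[YoloPoseRecord]:
    lines = [ln for ln in Path(path).read_text().splitlines() if ln.strip()]
    return [YoloPoseRecord.from_line(ln) for ln in lines]


def record_to_instance(rec: YoloPoseRecord, width: int, height: int,
                       score: float = 1.0) -> KeypointInstance:
    """Denormalize a pose record into a pixel-space instance (for metrics)."""
    bw, bh = rec.w * width, rec.h * height
    kp = np.array([(x * width, y * height, v) for x, y, v in rec.keypoints])
    return KeypointInstance(
        box=(rec.cx * width - bw / 2, rec.cy * height - bh / 2, bw, bh),
        score=score, keypoints=kp)


def instance_to_record(inst: KeypointInstance, width: int, height: int) -> YoloPoseRecord:
    x, y, bw, bh = inst.box
    kpts = []
    for kx, ky, v in inst.keypoints:
        if v <= 0:
            kpts.append((0.0, 0.0, 0))
        else:
            kpts.append((kx / width, ky / height, int(round(min(v, 2)))))
    return YoloPoseRecord(0, (x + bw / 2) / width, (y + bh / 2) / height,
                          bw / width, bh / height, tuple(kpts))


# ---------------------------------------------------------------------------
# dataset splitting
# ---------------------------------------------------------------------------

def split_dataset(manifest: Sequence[str], ratio: float, seed: int
                  ) -> tuple[list[str], list[str]]:
    """Deterministic disjoint train/validation split of a path manifest."""
    if not manifest:
        raise ValueError("empty manifest")
    if not 0 < ratio < 1:
        raise ValueError("ratio must lie in (0, 1)")
    rng = np.random.default_rng(seed)
    order = rng.permutation(len(manifest))
    n_train = int(round(len(manifest) * ratio))
    train = [manifest[i] for i in order[:n_train]]
    val = [manifest[i] for i in order[n_train:]]
    return train, val
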