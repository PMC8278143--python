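"""Domain types and file formats for per-frame bounding-box cell annotations.

A time-lapse phase-contrast video is represented as a :class:`VideoAnnotation`:
an ordered list of frames, each holding rectangular boxes tagged with one of
four morphology classes — ``liv`` (attached, "fried-egg" shaped living cell),
``round`` (detached, high-edge-contrast mitotic cell), ``div`` (actively
separating cell pair) and ``dead``.  The first three classes together make up
the *vital* cells.

Boxes are 0-based, half-open pixel rectangles ``[x_min, x_max) x [y_min,
y_max)`` with x growing right and y growing down (raster convention), which
keeps area and overlap arithmetic unambiguous.

Three on-disk dialects are supported and round-trip losslessly:

``via``
    Region JSON in the style of the VGG Image Annotator (rect shape
    attributes, one region attribute carrying the class).  Frame and video
    metadata travel in ``file_attributes`` / a ``_video_meta`` block.
``coco``
    Detection-style JSON: ``bbox`` as ``[x, y, w, h]``, ``category_id``
    mapped 1..4 in the order liv, round, div, dead, ``score`` for the
    confidence.
``csv``
    One row per object with columns ``frame,time_min,x_min,y_min,x_max,
    y_max,class,confidence,object_id``; video metadata in leading ``#``
    comment lines.
"""

from __future__ import annotations

import csv
import json
import logging
import math
from dataclasses import dataclass, field, replace
from enum import Enum
from pathlib import Path
from typing import Iterable, Optional, Sequence, Union

logger = logging.getLogger(__name__)

__all__ = [
    "CellClass",
    "VITAL_CLASSES",
    "Box",
    "LabelledObject",
    "FrameAnnotation",
    "VideoAnnotation",
    "SampleMeta",
    "AnnotationError",
    "FormatError",
    "ValidationError",
    "parse_class",
    "read_annotations",
    "write_annotations",
    "validate_frame",
]


class AnnotationError(Exception):
    """Base class for annotation-layer failures."""


class FormatError(AnnotationError):
    """A file does not parse in the named dialect."""


class ValidationError(AnnotationError):
    """Parsed content violates a domain invariant."""


class CellClass(str, Enum):
    """The four morphology classes of the lifecycle state machine."""

    LIV = "liv"
    ROUND = "round"
    DIV = "div"
    DEAD = "dead"

    def __str__(self) -> str:  # pragma: no cover - cosmetic
        return self.value


#: Classes counted as alive; ``vital = liv + round + div``.
VITAL_CLASSES = frozenset({CellClass.LIV, CellClass.ROUND, CellClass.DIV})

#: Fixed class order used for confusion matrices and COCO category ids.
CLASS_ORDER = (CellClass.LIV, CellClass.ROUND, CellClass.DIV, CellClass.DEAD)

# Hand-labelled tags vary; matching is case-insensitive over this table.
CLASS_ALIASES = {
    "liv": CellClass.LIV,
    "living": CellClass.LIV,
    "live": CellClass.LIV,
    "round": CellClass.ROUND,
    "div": CellClass.DIV,
    "dividing": CellClass.DIV,
    "division": CellClass.DIV,
    "dead": CellClass.DEAD,
}


def parse_class(tag: str) -> CellClass:
    """Map a free-text class tag onto a :class:`CellClass`.

    Raises :class:`ValidationError` for tags outside the alias table rather
    than silently dropping the object.
    """
    try:
        return CLASS_ALIASES[str(tag).strip().lower()]
    except KeyError:
        raise ValidationError(
            f"unknown class tag {tag!r}; known tags: {sorted(CLASS_ALIASES)}"
        ) from None


@dataclass(frozen=True, order=True)
class Box:
    """Axis-aligned rectangle in half-open pixel coordinates."""

    x_min: float
    y_min: float
    x_max: float
    y_max: float

    def __post_init__(self) -> None:
        if not (self.x_max > self.x_min and self.y_max > self.y_min):
            raise ValidationError(
                f"box must have strictly positive area, got "
                f"({self.x_min}, {self.y_min}, {self.x_max}, {self.y_max})"
            )

    @property
    def width(self) -> float:
        return self.x_max - self.x_min

    @property
    def height(self) -> float:
        return self.y_max - self.y_min

    @property
    def area(self) -> float:
        return self.width * self.height


@dataclass(frozen=True)
class LabelledObject:
    """A classified box; ground truth carries confidence 1.0.

    Ground-truth objects use confidence 1.0 so that a single matching code
    path serves both truth-vs-prediction and truth-vs-truth comparisons.
    ``object_id`` is an optional stable identity used for lineage and the
    dead-cell census.
    """

    box: Box
    cls: CellClass
    confidence: float = 1.0
    object_id: Optional[str] = None

    def __post_init__(self) -> None:
        if not (0.0 <= self.confidence <= 1.0):
            raise ValidationError(
                f"confidence must be in [0, 1], got {self.confidence}"
            )


@dataclass
class FrameAnnotation:
    """All labelled objects of one video frame.

    ``time_min`` is minutes since imaging start; at the usual 5-minute
    cadence frame 1 corresponds to timepoint 5 min.
    """

    frame_index: int
    time_min: float
    objects: list[LabelledObject] = field(default_factory=list)
    image_size: tuple[int, int] = (1388, 1040)

    def __post_init__(self) -> None:
        if self.frame_index < 1:
            raise ValidationError(f"frame_index must be >= 1, got {self.frame_index}")
        w, h = self.image_size
        if w <= 0 or h <= 0:
            raise ValidationError(f"image_size must be positive, got {self.image_size}")

    def count(self, cls: CellClass) -> int:
        return sum(1 for o in self.objects if o.cls is cls)


@dataclass(frozen=True)
class SampleMeta:
    """Acquisition metadata of one sample (one well of one experiment)."""

    sample_id: str = "sample"
    dose_gy: float = 0.0
    irradiated: bool = False

    def __post_init__(self) -> None:
        if self.dose_gy < 0:
            raise ValidationError(f"dose_gy must be >= 0, got {self.dose_gy}")


@dataclass
class VideoAnnotation:
    """A complete annotated video: frames plus sample metadata."""

    frames: list[FrameAnnotation]
    frame_interval_min: float = 5.0
    sample_meta: SampleMeta = field(default_factory=SampleMeta)

    def __post_init__(self) -> None:
        if self.frame_interval_min <= 0:
            raise ValidationError(
                f"frame_interval_min must be > 0, got {self.frame_interval_min}"
            )
        indices = [f.frame_index for f in self.frames]
        if any(b <= a for a, b in zip(indices, indices[1:])):
            raise ValidationError("frame indices must be strictly increasing")
        for f in self.frames:
            expected = f.frame_index * self.frame_interval_min
            if not math.isclose(f.time_min, expected, rel_tol=1e-9, abs_tol=1e-6):
                raise ValidationError(
                    f"frame {f.frame_index}: time_min {f.time_min} inconsistent "
                    f"with interval {self.frame_interval_min} (expected {expected})"
                )

    @property
    def n_frames(self) -> int:
        return len(self.frames)

    def class_counts(self) -> dict[CellClass, int]:
        """Total object count per class over the whole video."""
        counts = {c: 0 for c in CLASS_ORDER}
        for f in self.frames:
            for o in f.objects:
                counts[o.cls] += 1
        return counts


# ---------------------------------------------------------------------------
# Frame validation / clipping


def validate_frame(frame: FrameAnnotation, clip: bool = False) -> FrameAnnotation:
    """Check that all boxes lie inside the image; optionally clip at borders.

    With ``clip`` on, boxes intersecting the image border are clipped to the
    image and boxes left with zero area are removed (and reported through the
    module logger).  With ``clip`` off, any out-of-bounds box raises
    :class:`ValidationError`.
    """
    w, h = frame.image_size
    kept: list[LabelledObject] = []
    changed = False
    for i, obj in enumerate(frame.objects):
        b = obj.box
        inside = 0 <= b.x_min and b.x_max <= w and 0 <= b.y_min and b.y_max <= h
        if inside:
            kept.append(obj)
            continue
        if not clip:
            raise ValidationError(
                f"frame {frame.frame_index}, object {i}: box "
                f"({b.x_min}, {b.y_min}, {b.x_max}, {b.y_max}) exceeds image "
                f"{w}x{h}"
            )
        x0, y0 = max(b.x_min, 0.0), max(b.y_min, 0.0)
        x1, y1 = min(b.x_max, float(w)), min(b.y_max, float(h))
        changed = True
        if x1 <= x0 or y1 <= y0:
            logger.warning(
                "frame %d, object %d: zero area after clipping, removed",
                frame.frame_index,
                i,
            )
            continue
        kept.append(replace(obj, box=Box(x0, y0, x1, y1)))
    if not changed and len(kept) == len(frame.objects):
        return frame
    return FrameAnnotation(
        frame_index=frame.frame_index,
        time_min=frame.time_min,
        objects=kept,
        image_size=frame.image_size,
    )


# ---------------------------------------------------------------------------
# Readers / writers

_FORMATS = ("via", "coco", "csv")


def read_annotations(path: Union[str, Path], format: str) -> VideoAnnotation:
    """Read a :class:`VideoAnnotation` from ``path`` in the named dialect.

    Parameters
    ----------
    path:
        Input file.
    format:
        One of ``"via"``, ``"coco"``, ``"csv"``.
    """
    path = Path(path)
    if format not in _FORMATS:
        raise ValueError(f"format must be one of {_FORMATS}, got {format!r}")
    if not path.exists():
        raise FileNotFoundError(path)
    reader = {"via": _read_via, "coco": _read_coco, "csv": _read_csv}[format]
    return reader(path)


def write_annotations(video: VideoAnnotation, path: Union[str, Path], format: str) -> None:
    """Write ``video`` to ``path``; the result re-reads losslessly."""
    path = Path(path)
    if format not in _FORMATS:
        raise ValueError(f"format must be one of {_FORMATS}, got {format!r}")
    writer = {"via": _write_via, "coco": _write_coco, "csv": _write_csv}[format]
    writer(video, path)


def _meta_dict(video: VideoAnnotation) -> dict:
    return {
        "frame_interval_min": video.frame_interval_min,
        "sample_id": video.sample_meta.sample_id,
        "dose_gy": video.sample_meta.dose_gy,
        "irradiated": video.sample_meta.irradiated,
    }


def _meta_from_dict(d: dict) -> tuple[float, SampleMeta]:
    return (
        float(d.get("frame_interval_min", 5.0)),
        SampleMeta(
            sample_id=str(d.get("sample_id", "sample")),
            dose_gy=float(d.get("dose_gy", 0.0)),
            irradiated=bool(d.get("irradiated", False)),
        ),
    )


# -- VIA ---------------------------------------------------------------------


def _write_via(video: VideoAnnotation, path: Path) -> None:
    img_meta = {}
    for f in video.frames:
        key = f"frame_{f.frame_index:06d}.png"
        regions = []
        for obj in f.objects:
            region_attributes = {
                "class": obj.cls.value,
                "confidence": obj.confidence,
            }
            if obj.object_id is not None:
                region_attributes["object_id"] = obj.object_id
            regions.append(
                {
                    "shape_attributes": {
                        "name": "rect",
                        "x": obj.box.x_min,
                        "y": obj.box.y_min,
                        "width": obj.box.width,
                        "height": obj.box.height,
                    },
                    "region_attributes": region_attributes,
                }
            )
        img_meta[key] = {
            "filename": key,
            "size": -1,
            "regions": regions,
            "file_attributes": {
                "frame_index": f.frame_index,
                "time_min": f.time_min,
                "image_width": f.image_size[0],
                "image_height": f.image_size[1],
            },
        }
    doc = {"_via_img_metadata": img_meta, "_video_meta": _meta_dict(video)}
    path.write_text(json.dumps(doc, indent=1))


def _read_via(path: Path) -> VideoAnnotation:
    try:
        doc = json.loads(path.read_text())
    except json.JSONDecodeError as exc:
        raise FormatError(f"{path}: not valid JSON: {exc}") from exc
    if not isinstance(doc, dict):
        raise FormatError(f"{path}: VIA document must be a JSON object")
    img_meta = doc.get("_via_img_metadata", doc)
    interval, meta = _meta_from_dict(doc.get("_video_meta", {}))
    frames = []
    for key, entry in img_meta.items():
        if key.startswith("_"):
            continue
        if not isinstance(entry, dict) or "regions" not in entry:
            raise FormatError(f"{path}: entry {key!r} has no regions list")
        fattr = entry.get("file_attributes", {})
        try:
            frame_index = int(fattr["frame_index"])
            time_min = float(fattr["time_min"])
        except KeyError as exc:
            raise FormatError(
                f"{path}: entry {key!r} missing file attribute {exc}"
            ) from exc
        image_size = (
            int(fattr.get("image_width", 1388)),
            int(fattr.get("image_height", 1040)),
        )
        objects = []
        for j, region in enumerate(entry["regions"]):
            shape = region.get("shape_attributes", {})
            if shape.get("name") != "rect":
                raise ValidationError(
                    f"{path}: frame {frame_index}, region {j}: non-rectangular "
                    f"shape {shape.get('name')!r}"
                )
            try:
                x, y = float(shape["x"]), float(shape["y"])
                w, h = float(shape["width"]), float(shape["height"])
            except KeyError as exc:
                raise FormatError(
                    f"{path}: frame {frame_index}, region {j}: missing {exc}"
                ) from exc
            rattr = region.get("region_attributes", {})
            if "class" not in rattr:
                raise ValidationError(
                    f"{path}: frame {frame_index}, region {j}: no class tag"
                )
            try:
                cls = parse_class(rattr["class"])
            except ValidationError as exc:
                raise ValidationError(
                    f"{path}: frame {frame_index}, region {j}: {exc}"
                ) from None
            objects.append(
                LabelledObject(
                    box=Box(x, y, x + w, y + h),
                    cls=cls,
                    confidence=float(rattr.get("confidence", 1.0)),
                    object_id=(
                        str(rattr["object_id"]) if "object_id" in rattr else None
                    ),
                )
            )
        frames.append(
            FrameAnnotation(
                frame_index=frame_index,
                time_min=time_min,
                objects=objects,
                image_size=image_size,
            )
        )
    frames.sort(key=lambda f: f.frame_index)
    return VideoAnnotation(frames=frames, frame_interval_min=interval, sample_meta=meta)


# -- COCO --------------------------------------------------------------------

_CATEGORY_IDS = {cls: i + 1 for i, cls in enumerate(CLASS_ORDER)}
_CATEGORY_NAMES = {i + 1: cls for i, cls in enumerate(CLASS_ORDER)}


def _write_coco(video: VideoAnnotation, path: Path) -> None:
    images, annotations = [], []
    ann_id = 1
    for f in video.frames:
        images.append(
            {
                "id": f.frame_index,
                "file_name": f"frame_{f.frame_index:06d}.png",
                "width": f.image_size[0],
                "height": f.image_size[1],
                "time_min": f.time_min,
            }
        )
        for obj in f.objects:
            ann = {
                "id": ann_id,
                "image_id": f.frame_index,
                "category_id": _CATEGORY_IDS[obj.cls],
                "bbox": [obj.box.x_min, obj.box.y_min, obj.box.width, obj.box.height],
                "area": obj.box.area,
                "score": obj.confidence,
                "iscrowd": 0,
            }
            if obj.object_id is not None:
                ann["object_id"] = obj.object_id
            annotations.append(ann)
            ann_id += 1
    doc = {
        "info": _meta_dict(video),
        "images": images,
        "annotations": annotations,
        "categories": [
            {"id": i, "name": cls.value} for i, cls in _CATEGORY_NAMES.items()
        ],
    }
    path.write_text(json.dumps(doc, indent=1))


def _read_coco(path: Path) -> VideoAnnotation:
    try:
        doc = json.loads(path.read_text())
    except json.JSONDecodeError as exc:
        raise FormatError(f"{path}: not valid JSON: {exc}") from exc
    for section in ("images", "annotations"):
        if section not in doc:
            raise FormatError(f"{path}: missing COCO section {section!r}")
    cat_map = dict(_CATEGORY_NAMES)
    for cat in doc.get("categories", []):
        cat_map[int(cat["id"])] = parse_class(cat["name"])
    interval, meta = _meta_from_dict(doc.get("info", {}))
    frames: dict[int, FrameAnnotation] = {}
    for img in doc["images"]:
        fi = int(img["id"])
        frames[fi] = FrameAnnotation(
            frame_index=fi,
            time_min=float(img.get("time_min", fi * interval)),
            objects=[],
            image_size=(int(img.get("width", 1388)), int(img.get("height", 1040))),
        )
    for ann in doc["annotations"]:
        fi = int(ann["image_id"])
        if fi not in frames:
            raise FormatError(
                f"{path}: annotation {ann.get('id')} references unknown image {fi}"
            )
        cid = int(ann["category_id"])
        if cid not in cat_map:
            raise ValidationError(
                f"{path}: annotation {ann.get('id')}: unknown category_id {cid}"
            )
        x, y, w, h = (float(v) for v in ann["bbox"])
        frames[fi].objects.append(
            LabelledObject(
                box=Box(x, y, x + w, y + h),
                cls=cat_map[cid],
                confidence=float(ann.get("score", 1.0)),
                object_id=(str(ann["object_id"]) if "object_id" in ann else None),
            )
        )
    ordered = [frames[k] for k in sorted(frames)]
    return VideoAnnotation(frames=ordered, frame_interval_min=interval, sample_meta=meta)


# -- CSV ---------------------------------------------------------------------

_CSV_COLUMNS = [
    "frame",
    "time_min",
    "x_min",
    "y_min",
    "x_max",
    "y_max",
    "class",
    "confidence",
    "object_id",
]


def _write_csv(video: VideoAnnotation, path: Path) -> None:
    with open(path, "w", newline="") as fh:
        for k, v in _meta_dict(video).items():
            fh.write(f"# {k}={v}\n")
        for f in video.frames:
            fh.write(
                f"# frame_meta={f.frame_index},{f.image_size[0]},{f.image_size[1]}\n"
            )
        writer = csv.writer(fh)
        writer.writerow(_CSV_COLUMNS)
        for f in video.frames:
            for obj in f.objects:
                writer.writerow(
                    [
                        f.frame_index,
                        repr(float(f.time_min)),
                        repr(float(obj.box.x_min)),
                        repr(float(obj.box.y_min)),
                        repr(float(obj.box.x_max)),
                        repr(float(obj.box.y_max)),
                        obj.cls.value,
                        repr(float(obj.confidence)),
                        obj.object_id if obj.object_id is not None else "",
                    ]
                )


def _read_csv(path: Path) -> VideoAnnotation:
    meta_kv: dict[str, str] = {}
    frame_meta: dict[int, tuple[int, int]] = {}
    rows: list[dict[str, str]] = []
    with open(path, newline="") as fh:
        data_lines = []
        for line in fh:
            if line.startswith("#"):
                body = line[1:].strip()
                if "=" in body:
                    k, v = body.split("=", 1)
                    if k.strip() == "frame_meta":
                        fi, w, h = (int(x) for x in v.split(","))
                        frame_meta[fi] = (w, h)
                    else:
                        meta_kv[k.strip()] = v.strip()
                continue
            data_lines.append(line)
        reader = csv.DictReader(data_lines)
        if reader.fieldnames is None or set(_CSV_COLUMNS) - set(reader.fieldnames):
            raise FormatError(
                f"{path}: CSV header must contain columns {_CSV_COLUMNS}"
            )
        rows = list(reader)
    if "irradiated" in meta_kv:
        meta_kv["irradiated"] = meta_kv["irradiated"] in ("True", "true", "1")  # type: ignore[assignment]
    interval, meta = _meta_from_dict(meta_kv)
    frames: dict[int, FrameAnnotation] = {
        fi: FrameAnnotation(
            frame_index=fi, time_min=fi * interval, objects=[], image_size=size
        )
        for fi, size in frame_meta.items()
    }
    for i, row in enumerate(rows):
        try:
            fi = int(row["frame"])
            time_min = float(row["time_min"])
            box = Box(
                float(row["x_min"]),
                float(row["y_min"]),
                float(row["x_max"]),
                float(row["y_max"]),
            )
            cls = parse_class(row["class"])
            conf = float(row["confidence"])
        except (ValueError, KeyError) as exc:
            raise FormatError(f"{path}: data row {i + 1}: {exc}") from exc
        oid = row.get("object_id") or None
        if fi not in frames:
            frames[fi] = FrameAnnotation(
                frame_index=fi, time_min=time_min, objects=[]
            )
        frames[fi].objects.append(
            LabelledObject(box=box, cls=cls, confidence=conf, object_id=oid)
        )
    ordered = [frames[k] for k in sorted(frames)]
    return VideoAnnotation(frames=ordered, frame_interval_min=interval, sample_meta=meta)
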