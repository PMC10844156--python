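"""Box geometry, annotation containers, file I/O and descriptive statistics.

The atomic object is an axis-aligned :class:`BoundingBox` in continuous pixel
coordinates (origin top-left, x rightward, y downward).  Annotations are
grouped per annotator into an :class:`AnnotationSet` mapping image ids to box
collections, and a :class:`Dataset` bundles the image frames with the
annotation sets of every annotator on those frames.

Supported on-disk formats:

* CVAT "for images 1.1" XML — one file per annotation task / annotator;
* COCO detection JSON — annotator grouping via category name or a custom
  annotation field;
* a canonical JSON dump of a whole :class:`Dataset`, round-tripping
  coordinates bit-exactly.
"""

from __future__ import annotations

import json
import math
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Mapping, Sequence

from lxml import etree

__all__ = [
    "BoundingBox",
    "ImageFrame",
    "AnnotationSet",
    "Dataset",
    "AnnotationStats",
    "ValidationError",
    "iou",
    "intersection_area",
    "annotation_stats",
    "read_cvat_xml",
    "write_cvat_xml",
    "read_coco_json",
    "write_coco_json",
    "read_dataset_json",
    "write_dataset_json",
]


class ValidationError(ValueError):
    """Raised when an annotation file or box violates a structural invariant."""


@dataclass(frozen=True, order=True)
class BoundingBox:
    """Axis-aligned rectangle with strictly positive area.

    Coordinates are continuous pixels; intervals are closed, so centroid
    containment (used by the correspondence relation) is boundary-inclusive.
    The dataclass ordering is lexicographic on (xmin, ymin, xmax, ymax),
    which is the deterministic tie-break order used throughout the matching
    algorithms.
    """

    xmin: float
    ymin: float
    xmax: float
    ymax: float

    def __post_init__(self) -> None:
        if not (self.xmin < self.xmax and self.ymin < self.ymax):
            raise ValidationError(
                f"degenerate box ({self.xmin}, {self.ymin}, {self.xmax}, {self.ymax}): "
                "xmin < xmax and ymin < ymax required"
            )

    @property
    def width(self) -> float:
        return self.xmax - self.xmin

    @property
    def height(self) -> float:
        return self.ymax - self.ymin

    @property
    def area(self) -> float:
        return self.width * self.height

    @property
    def centroid(self) -> tuple[float, float]:
        return ((self.xmin + self.xmax) / 2.0, (self.ymin + self.ymax) / 2.0)

    def contains_point(self, x: float, y: float) -> bool:
        """Boundary-inclusive point containment."""
        return self.xmin <= x <= self.xmax and self.ymin <= y <= self.ymax

    def as_tuple(self) -> tuple[float, float, float, float]:
        return (self.xmin, self.ymin, self.xmax, self.ymax)

    def as_xywh(self) -> tuple[float, float, float, float]:
        """COCO-style (x, y, width, height)."""
        return (self.xmin, self.ymin, self.width, self.height)

    @classmethod
    def from_xywh(cls, x: float, y: float, w: float, h: float) -> "BoundingBox":
        if w <= 0 or h <= 0:
            raise ValidationError(f"non-positive bbox size w={w}, h={h}")
        return cls(x, y, x + w, y + h)


def intersection_area(b: BoundingBox, b2: BoundingBox) -> float:
    """Area of the overlap |b ∩ b2|; 0 when the boxes are disjoint."""
    iw = min(b.xmax, b2.xmax) - max(b.xmin, b2.xmin)
    ih = min(b.ymax, b2.ymax) - max(b.ymin, b2.ymin)
    if iw <= 0 or ih <= 0:
        return 0.0
    return iw * ih


def iou(b: BoundingBox, b2: BoundingBox) -> float:
    """Intersection over union, in [0, 1]."""
    inter = intersection_area(b, b2)
    return inter / (b.area + b2.area - inter)


@dataclass(frozen=True)
class ImageFrame:
    """An image identified by an opaque string id, with pixel dimensions."""

    image_id: str
    width: float
    height: float

    def __post_init__(self) -> None:
        if self.width <= 0 or self.height <= 0:
            raise ValidationError(f"frame {self.image_id!r}: non-positive dimensions")

    def contains_box(self, b: BoundingBox) -> bool:
        return 0 <= b.xmin and 0 <= b.ymin and b.xmax <= self.width and b.ymax <= self.height


@dataclass
class AnnotationSet:
    """All boxes drawn by one annotator, keyed by image id.

    An image absent from ``boxes_by_image`` means the annotator examined it
    and found nothing: :meth:`boxes_for` returns an empty tuple rather than
    raising.
    """

    annotator_id: str
    boxes_by_image: dict[str, list[BoundingBox]] = field(default_factory=dict)

    def boxes_for(self, image_id: str) -> tuple[BoundingBox, ...]:
        return tuple(self.boxes_by_image.get(image_id, ()))

    def all_boxes(self) -> list[BoundingBox]:
        return [b for boxes in self.boxes_by_image.values() for b in boxes]

    @property
    def n_boxes(self) -> int:
        return sum(len(v) for v in self.boxes_by_image.values())

    def add(self, image_id: str, box: BoundingBox) -> None:
        self.boxes_by_image.setdefault(image_id, []).append(box)


@dataclass
class Dataset:
    """Image frames plus the annotation sets of every annotator on them."""

    frames: dict[str, ImageFrame] = field(default_factory=dict)
    annotations: dict[str, AnnotationSet] = field(default_factory=dict)

    @property
    def image_ids(self) -> list[str]:
        return list(self.frames)

    @property
    def annotator_ids(self) -> list[str]:
        return list(self.annotations)

    def boxes(self, annotator_id: str, image_id: str) -> tuple[BoundingBox, ...]:
        return self.annotations[annotator_id].boxes_for(image_id)

    def add_annotator(self, aset: AnnotationSet) -> None:
        if aset.annotator_id in self.annotations:
            raise ValidationError(f"duplicate annotator id {aset.annotator_id!r}")
        self.annotations[aset.annotator_id] = aset

    def validate(self) -> None:
        """Check that every box lies inside its image frame."""
        for aid, aset in self.annotations.items():
            for image_id, boxes in aset.boxes_by_image.items():
                if image_id not in self.frames:
                    raise ValidationError(
                        f"annotator {aid!r} references unknown image {image_id!r}"
                    )
                frame = self.frames[image_id]
                for b in boxes:
                    if not frame.contains_box(b):
                        raise ValidationError(
                            f"annotator {aid!r}, image {image_id!r}: box {b.as_tuple()} "
                            f"outside frame {frame.width}x{frame.height}"
                        )


# ---------------------------------------------------------------------------
# Descriptive statistics (Table-1 style)
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class AnnotationStats:
    """Box count and pooled side-length statistics for one annotator.

    ``mean_side`` and ``std_side`` are computed over the pooled sample of all
    widths AND all heights (2·n_boxes values), yielding one number per
    annotator.  They are ``None`` (not 0) when the annotator drew no boxes.
    ``ddof`` records the variance convention used (0 = population, default;
    1 = sample).
    """

    annotator_id: str
    n_boxes: int
    mean_side: float | None
    std_side: float | None
    ddof: int = 0


def annotation_stats(s: AnnotationSet, ddof: int = 0) -> AnnotationStats:
    """Count boxes and summarise side lengths pooled over widths and heights."""
    sides: list[float] = []
    n = 0
    for boxes in s.boxes_by_image.values():
        for b in boxes:
            sides.append(b.width)
            sides.append(b.height)
            n += 1
    if n == 0:
        return AnnotationStats(s.annotator_id, 0, None, None, ddof)
    mean = sum(sides) / len(sides)
    denom = len(sides) - ddof
    var = sum((x - mean) ** 2 for x in sides) / denom if denom > 0 else float("nan")
    return AnnotationStats(s.annotator_id, n, mean, math.sqrt(var), ddof)


# ---------------------------------------------------------------------------
# CVAT "for images 1.1" XML
# ---------------------------------------------------------------------------


def read_cvat_xml(path: str | Path, annotator_id: str | None = None) -> tuple[AnnotationSet, dict[str, ImageFrame]]:
    """Read one CVAT-for-images annotation task.

    One task is one annotator; ``annotator_id`` defaults to the task name in
    the file's meta section, falling back to the file stem.  Coordinates are
    passed through unmodified.

    Raises
    ------
    ValidationError
        On malformed XML (naming the offending element) or a degenerate box
        (``xbr <= xtl`` or ``ybr <= ytl``), naming the image.
    """
    path = Path(path)
    try:
        tree = etree.parse(str(path))
    except etree.XMLSyntaxError as exc:
        raise ValidationError(f"malformed CVAT XML in {path.name}: {exc}") from exc
    root = tree.getroot()
    if root.tag != "annotations":
        raise ValidationError(f"{path.name}: expected <annotations> root, got <{root.tag}>")

    if annotator_id is None:
        name_el = root.find("meta/task/name")
        annotator_id = name_el.text.strip() if name_el is not None and name_el.text else path.stem

    aset = AnnotationSet(annotator_id)
    frames: dict[str, ImageFrame] = {}
    for image_el in root.iter("image"):
        image_id = image_el.get("name") or image_el.get("id")
        if image_id is None:
            raise ValidationError(f"{path.name}: <image> element lacks name and id")
        try:
            frame = ImageFrame(image_id, float(image_el.get("width")), float(image_el.get("height")))
        except (TypeError, ValueError) as exc:
            raise ValidationError(f"{path.name}: <image {image_id!r}> bad width/height") from exc
        frames[image_id] = frame
        aset.boxes_by_image.setdefault(image_id, [])
        for box_el in image_el.iter("box"):
            try:
                coords = tuple(float(box_el.get(k)) for k in ("xtl", "ytl", "xbr", "ybr"))
            except (TypeError, ValueError) as exc:
                raise ValidationError(f"{path.name}, image {image_id!r}: <box> bad coordinates") from exc
            try:
                aset.add(image_id, BoundingBox(*coords))
            except ValidationError as exc:
                raise ValidationError(f"{path.name}, image {image_id!r}: {exc}") from exc
    return aset, frames


def write_cvat_xml(
    path: str | Path,
    aset: AnnotationSet,
    frames: Mapping[str, ImageFrame],
    label: str = "lesion",
) -> None:
    """Write an AnnotationSet in the CVAT "for images 1.1" dialect."""
    root = etree.Element("annotations")
    etree.SubElement(root, "version").text = "1.1"
    meta = etree.SubElement(root, "meta")
    task = etree.SubElement(meta, "task")
    etree.SubElement(task, "name").text = aset.annotator_id
    for idx, (image_id, frame) in enumerate(frames.items()):
        image_el = etree.SubElement(
            root,
            "image",
            id=str(idx),
            name=image_id,
            width=repr(frame.width),
            height=repr(frame.height),
        )
        for b in aset.boxes_for(image_id):
            etree.SubElement(
                image_el,
                "box",
                label=label,
                occluded="0",
                xtl=repr(b.xmin),
                ytl=repr(b.ymin),
                xbr=repr(b.xmax),
                ybr=repr(b.ymax),
            )
    etree.ElementTree(root).write(str(path), xml_declaration=True, encoding="utf-8", pretty_print=True)


# ---------------------------------------------------------------------------
# COCO detection JSON
# ---------------------------------------------------------------------------


def read_coco_json(
    path: str | Path,
    annotator_key: str = "category",
) -> tuple[list[AnnotationSet], dict[str, ImageFrame]]:
    """Read COCO detection JSON, grouping annotations into annotator sets.

    ``annotator_key="category"`` maps the COCO category name to the annotator
    id (one category per annotator); any other value is taken as a custom
    per-annotation field holding the annotator id directly.
    """
    path = Path(path)
    with open(path) as fh:
        doc = json.load(fh)

    frames: dict[str, ImageFrame] = {}
    id_to_image: dict[int, str] = {}
    for im in doc.get("images", []):
        image_id = str(im.get("file_name") or im["id"])
        id_to_image[im["id"]] = image_id
        frames[image_id] = ImageFrame(image_id, float(im["width"]), float(im["height"]))

    cat_names = {c["id"]: c["name"] for c in doc.get("categories", [])}
    sets: dict[str, AnnotationSet] = {}
    if annotator_key == "category":
        # a declared category with no annotations is still an annotator
        for name in cat_names.values():
            sets[name] = AnnotationSet(name)
    for ann in doc.get("annotations", []):
        if ann["image_id"] not in id_to_image:
            raise ValidationError(f"{path.name}: annotation {ann.get('id')} references missing image {ann['image_id']}")
        image_id = id_to_image[ann["image_id"]]
        if annotator_key == "category":
            annot = cat_names.get(ann["category_id"], str(ann["category_id"]))
        else:
            if annotator_key not in ann:
                raise ValidationError(f"{path.name}: annotation {ann.get('id')} lacks field {annotator_key!r}")
            annot = str(ann[annotator_key])
        x, y, w, h = ann["bbox"]
        if w <= 0 or h <= 0:
            raise ValidationError(
                f"{path.name}, image {image_id!r}: non-positive bbox size w={w}, h={h}"
            )
        sets.setdefault(annot, AnnotationSet(annot)).add(image_id, BoundingBox.from_xywh(x, y, w, h))

    for aset in sets.values():
        for image_id in frames:
            aset.boxes_by_image.setdefault(image_id, [])
    return list(sets.values()), frames


def write_coco_json(
    path: str | Path,
    annotation_sets: Sequence[AnnotationSet],
    frames: Mapping[str, ImageFrame],
) -> None:
    """Write annotation sets as COCO detection JSON, one category per annotator."""
    images = []
    image_num = {}
    for k, (image_id, frame) in enumerate(frames.items(), start=1):
        image_num[image_id] = k
        images.append({"id": k, "file_name": image_id, "width": frame.width, "height": frame.height})
    categories = [{"id": j, "name": aset.annotator_id} for j, aset in enumerate(annotation_sets, start=1)]
    annotations = []
    next_id = 1
    for j, aset in enumerate(annotation_sets, start=1):
        for image_id, boxes in aset.boxes_by_image.items():
            for b in boxes:
                x, y, w, h = b.as_xywh()
                annotations.append(
                    {
                        "id": next_id,
                        "image_id": image_num[image_id],
                        "category_id": j,
                        "bbox": [x, y, w, h],
                        "area": b.area,
                        "iscrowd": 0,
                    }
                )
                next_id += 1
    with open(path, "w") as fh:
        json.dump({"images": images, "annotations": annotations, "categories": categories}, fh, indent=1)


# ---------------------------------------------------------------------------
# Canonical JSON dump
# ---------------------------------------------------------------------------


def write_dataset_json(path: str | Path, dataset: Dataset) -> None:
    """Serialise a whole Dataset; floats round-trip bit-exactly via repr."""
    doc = {
        "frames": {fid: [f.width, f.height] for fid, f in dataset.frames.items()},
        "annotators": {
            aid: {
                image_id: [list(b.as_tuple()) for b in boxes]
                for image_id, boxes in aset.boxes_by_image.items()
            }
            for aid, aset in dataset.annotations.items()
        },
    }
    with open(path, "w") as fh:
        json.dump(doc, fh)


def read_dataset_json(path: str | Path) -> Dataset:
    with open(path) as fh:
        doc = json.load(fh)
    ds = Dataset()
    for fid, (w, h) in doc["frames"].items():
        ds.frames[fid] = ImageFrame(fid, w, h)
    for aid, images in doc["annotators"].items():
        aset = AnnotationSet(aid)
        for image_id, boxes in images.items():
            aset.boxes_by_image[image_id] = [BoundingBox(*b) for b in boxes]
        ds.add_annotator(aset)
    return ds


def dataset_from_sets(
    frames: Mapping[str, ImageFrame] | Iterable[ImageFrame],
    annotation_sets: Iterable[AnnotationSet],
) -> Dataset:
    """Assemble a Dataset from frames and per-annotator sets."""
    ds = Dataset()
    if isinstance(frames, Mapping):
        ds.frames.update(frames)
    else:
        for f in frames:
            ds.frames[f.image_id] = f
    for aset in annotation_sets:
        ds.add_annotator(aset)
    return ds
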