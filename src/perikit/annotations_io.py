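"""Data model and readers/writers for the COCO-dialect annotation files.

Ground truth is a COCO keypoint-annotation JSON (``images`` / ``annotations`` /
``categories``); predictions are a COCO keypoint-results JSON extended with a
``keypoint_scores`` array.  This module is the single source of truth for the
six-landmark schema: left/right marginal bone level, left/right implant apex,
left/right implant top, in that fixed order.  The order matters because the
per-keypoint tolerance vector sigma is indexed by it.

Visibility flags follow the COCO convention: ``v = 0`` not labeled, ``v = 1``
labeled but not visible, ``v = 2`` labeled and visible.  Keypoints with
``v = 0`` carry no coordinate meaning and are ignored by every metric.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path
from typing import Sequence

from perikit.errors import (
    ParseError,
    ReferentialError,
    SchemaError,
    ValidationError,
)

#: Fixed landmark order; index i of the sigma vector lives here.
KEYPOINT_NAMES = (
    "Lt bone level",
    "Rt bone level",
    "Lt apex",
    "Rt apex",
    "Lt implant top",
    "Rt implant top",
)

#: Left-right landmark pairs (1-based, COCO skeleton convention).
SKELETON = ((1, 2), (3, 4), (5, 6))

JAW_LABELS = ("upper", "lower")


@dataclass(frozen=True)
class KeypointSchema:
    """Ordered landmark names plus reverse lookup."""

    names: tuple[str, ...] = KEYPOINT_NAMES

    def __post_init__(self) -> None:
        if len(self.names) != 6:
            raise SchemaError(f"keypoint schema must have 6 names, got {len(self.names)}")

    def index_of(self, name: str) -> int:
        try:
            return self.names.index(name)
        except ValueError:
            raise SchemaError(f"unknown keypoint name {name!r}") from None


DEFAULT_SCHEMA = KeypointSchema()


@dataclass(frozen=True)
class Keypoint:
    """One landmark: pixel coordinates and a visibility flag."""

    x: float
    y: float
    v: int

    def __post_init__(self) -> None:
        if self.v not in (0, 1, 2):
            raise ValidationError(f"visibility flag must be 0, 1 or 2, got {self.v}")

    @property
    def labeled(self) -> bool:
        return self.v > 0


def _check_bbox(bbox: Sequence[float], where: str) -> tuple[float, float, float, float]:
    if len(bbox) != 4:
        raise ValidationError(f"{where}: bbox must have 4 entries, got {len(bbox)}")
    x, y, w, h = (float(b) for b in bbox)
    if w <= 0 or h <= 0:
        raise ValidationError(f"{where}: bbox width and height must be positive, got {w} x {h}")
    return (x, y, w, h)


def keypoints_from_flat(flat: Sequence[float], where: str = "keypoints") -> tuple[Keypoint, ...]:
    """Regroup the flat 18-value ``[x1, y1, v1, ..., x6, y6, v6]`` array."""
    if len(flat) != 18:
        raise SchemaError(f"{where}: keypoint array must have 18 values, got {len(flat)}")
    return tuple(
        Keypoint(float(flat[3 * i]), float(flat[3 * i + 1]), int(flat[3 * i + 2]))
        for i in range(6)
    )


def keypoints_to_flat(keypoints: Sequence[Keypoint]) -> list[float]:
    flat: list[float] = []
    for kp in keypoints:
        flat.extend((kp.x, kp.y, kp.v))
    return flat


@dataclass(frozen=True)
class ImplantAnnotation:
    """One ground-truth implant instance.

    ``area`` is the segmented implant area in squared pixels; its square root
    is the implant scale ``s`` that normalizes OKS displacements.
    """

    annotation_id: int
    image_id: int
    bbox: tuple[float, float, float, float]  # x, y, w, h
    area: float
    keypoints: tuple[Keypoint, ...]

    def __post_init__(self) -> None:
        _check_bbox(self.bbox, f"annotation {self.annotation_id}")
        if self.area <= 0:
            raise ValidationError(
                f"annotation {self.annotation_id}: area must be positive, got {self.area}"
            )
        if len(self.keypoints) != 6:
            raise SchemaError(
                f"annotation {self.annotation_id}: expected 6 keypoints, got {len(self.keypoints)}"
            )

    @property
    def n_labeled(self) -> int:
        return sum(1 for kp in self.keypoints if kp.labeled)


@dataclass(frozen=True)
class ImplantPrediction:
    """One detected implant: box + box score, six keypoints, per-keypoint scores.

    Detectors emit no visibility information, so ``v`` is stored as 2 for every
    predicted keypoint; metrics consult ground-truth visibility only.
    """

    image_id: int
    bbox: tuple[float, float, float, float]
    box_score: float
    keypoints: tuple[Keypoint, ...]
    keypoint_scores: tuple[float, ...]

    def __post_init__(self) -> None:
        _check_bbox(self.bbox, f"prediction on image {self.image_id}")
        if not 0.0 <= self.box_score <= 1.0:
            raise ValidationError(
                f"prediction on image {self.image_id}: box_score {self.box_score} outside [0, 1]"
            )
        if len(self.keypoints) != 6:
            raise SchemaError(
                f"prediction on image {self.image_id}: expected 6 keypoints, "
                f"got {len(self.keypoints)}"
            )
        if len(self.keypoint_scores) != 6:
            raise SchemaError(
                f"prediction on image {self.image_id}: expected 6 keypoint scores, "
                f"got {len(self.keypoint_scores)}"
            )
        for s in self.keypoint_scores:
            if not 0.0 <= s <= 1.0:
                raise ValidationError(
                    f"prediction on image {self.image_id}: keypoint score {s} outside [0, 1]"
                )

    def ranking_score(self, source: str = "keypoint_score", aggregation: str = "mean") -> float:
        """Confidence used to rank detections: the box score, or the per-implant
        aggregate (mean or max) of the six keypoint scores."""
        if source == "box_score":
            return self.box_score
        if source == "keypoint_score":
            if aggregation == "mean":
                return float(sum(self.keypoint_scores) / 6.0)
            if aggregation == "max":
                return float(max(self.keypoint_scores))
            raise _config_error(f"unknown keypoint-score aggregation {aggregation!r}")
        raise _config_error(f"unknown ranking source {source!r}")


def _config_error(msg: str):
    from perikit.errors import ConfigurationError

    return ConfigurationError(msg)


@dataclass(frozen=True)
class ImageRecord:
    image_id: int
    width: int
    height: int
    jaw: str

    def __post_init__(self) -> None:
        if self.jaw not in JAW_LABELS:
            raise ValidationError(
                f"image {self.image_id}: jaw must be one of {JAW_LABELS}, got {self.jaw!r}"
            )
        if self.width <= 0 or self.height <= 0:
            raise ValidationError(f"image {self.image_id}: non-positive dimensions")


@dataclass
class DatasetBundle:
    """Validated ground-truth container: image records plus implant annotations."""

    images: list[ImageRecord]
    annotations: list[ImplantAnnotation]
    schema: KeypointSchema = field(default_factory=lambda: DEFAULT_SCHEMA)

    def __post_init__(self) -> None:
        image_ids = {im.image_id for im in self.images}
        if len(image_ids) != len(self.images):
            raise ReferentialError("duplicate image ids")
        ann_ids = [a.annotation_id for a in self.annotations]
        if len(set(ann_ids)) != len(ann_ids):
            raise ReferentialError("duplicate annotation ids")
        for ann in self.annotations:
            if ann.image_id not in image_ids:
                raise ReferentialError(
                    f"annotation {ann.annotation_id} references unknown image {ann.image_id}"
                )

    @property
    def image_ids(self) -> set[int]:
        return {im.image_id for im in self.images}

    def image(self, image_id: int) -> ImageRecord:
        for im in self.images:
            if im.image_id == image_id:
                return im
        raise ReferentialError(f"unknown image id {image_id}")

    def annotations_for(self, image_id: int) -> list[ImplantAnnotation]:
        return [a for a in self.annotations if a.image_id == image_id]

    def subset_by_jaw(self, jaw: str) -> "DatasetBundle":
        if jaw not in JAW_LABELS:
            raise ValidationError(f"jaw must be one of {JAW_LABELS}, got {jaw!r}")
        images = [im for im in self.images if im.jaw == jaw]
        ids = {im.image_id for im in images}
        anns = [a for a in self.annotations if a.image_id in ids]
        return DatasetBundle(images=images, annotations=anns, schema=self.schema)


def _read_json(path: str | Path):
    path = Path(path)
    try:
        with open(path) as fh:
            return json.load(fh)
    except FileNotFoundError:
        raise ParseError(f"no such file: {path}") from None
    except json.JSONDecodeError as exc:
        raise ParseError(f"{path}: malformed JSON ({exc})") from None


def load_ground_truth(path: str | Path) -> DatasetBundle:
    """Load a ground-truth COCO-dialect file into a validated bundle.

    The category block, when present, must carry the six landmark names in the
    schema order — a misordered file fails loudly rather than silently
    permuting the sigma vector.
    """
    doc = _read_json(path)
    if not isinstance(doc, dict):
        raise ParseError(f"{path}: expected a JSON object at top level")
    for key in ("images", "annotations"):
        if key not in doc or not isinstance(doc[key], list):
            raise ParseError(f"{path}: missing or non-list {key!r} section")

    for cat in doc.get("categories", []):
        names = tuple(cat.get("keypoints", ()))
        if names and names != KEYPOINT_NAMES:
            raise SchemaError(
                f"{path}: category keypoint names {list(names)} do not match the "
                f"required order {list(KEYPOINT_NAMES)}"
            )

    images = []
    for rec in doc["images"]:
        try:
            images.append(
                ImageRecord(
                    image_id=int(rec["id"]),
                    width=int(rec["width"]),
                    height=int(rec["height"]),
                    jaw=str(rec["jaw"]),
                )
            )
        except KeyError as exc:
            raise SchemaError(f"{path}: image record missing field {exc}") from None

    annotations = []
    for rec in doc["annotations"]:
        try:
            ann_id = int(rec["id"])
            annotations.append(
                ImplantAnnotation(
                    annotation_id=ann_id,
                    image_id=int(rec["image_id"]),
                    bbox=_check_bbox(rec["bbox"], f"annotation {ann_id}"),
                    area=float(rec["area"]),
                    keypoints=keypoints_from_flat(
                        rec["keypoints"], f"annotation {ann_id}"
                    ),
                )
            )
        except KeyError as exc:
            raise SchemaError(f"{path}: annotation record missing field {exc}") from None

    return DatasetBundle(images=images, annotations=annotations)


def load_predictions(path: str | Path, bundle: DatasetBundle) -> list[ImplantPrediction]:
    """Load a COCO-results-dialect prediction file, resolving image ids against
    ``bundle``.  Scores outside [0, 1] are an error, never clamped."""
    doc = _read_json(path)
    if not isinstance(doc, list):
        raise ParseError(f"{path}: expected a JSON array of prediction records")
    known = bundle.image_ids
    preds = []
    for i, rec in enumerate(doc):
        try:
            image_id = int(rec["image_id"])
            if image_id not in known:
                raise ReferentialError(
                    f"{path}: prediction {i} references unknown image {image_id}"
                )
            preds.append(
                ImplantPrediction(
                    image_id=image_id,
                    bbox=_check_bbox(rec["bbox"], f"prediction {i}"),
                    box_score=float(rec["score"]),
                    keypoints=keypoints_from_flat(rec["keypoints"], f"prediction {i}"),
                    keypoint_scores=tuple(float(s) for s in rec["keypoint_scores"]),
                )
            )
        except KeyError as exc:
            raise SchemaError(f"{path}: prediction {i} missing field {exc}") from None
    return preds


def bundle_to_dict(bundle: DatasetBundle) -> dict:
    return {
        "images": [
            {"id": im.image_id, "width": im.width, "height": im.height, "jaw": im.jaw}
            for im in bundle.images
        ],
        "annotations": [
            {
                "id": a.annotation_id,
                "image_id": a.image_id,
                "category_id": 1,
                "bbox": list(a.bbox),
                "area": a.area,
                "keypoints": keypoints_to_flat(a.keypoints),
                "num_keypoints": a.n_labeled,
                "iscrowd": 0,
            }
            for a in sorted(bundle.annotations, key=lambda a: a.annotation_id)
        ],
        "categories": [
            {
                "id": 1,
                "name": "implant",
                "keypoints": list(bundle.schema.names),
                "skeleton": [list(p) for p in SKELETON],
            }
        ],
    }


def predictions_to_dicts(preds: Sequence[ImplantPrediction]) -> list[dict]:
    return [
        {
            "image_id": p.image_id,
            "category_id": 1,
            "bbox": list(p.bbox),
            "score": p.box_score,
            "keypoints": keypoints_to_flat(p.keypoints),
            "keypoint_scores": list(p.keypoint_scores),
        }
        for p in preds
    ]


def write_bundle(bundle: DatasetBundle, path: str | Path) -> None:
    """Write a bundle so that :func:`load_ground_truth` reproduces it
    value-identically (annotations sorted by id for bit-stable output)."""
    # Re-validate: a bundle mutated after construction must not hit disk.
    DatasetBundle(bundle.images, bundle.annotations, bundle.schema)
    with open(path, "w") as fh:
        json.dump(bundle_to_dict(bundle), fh, indent=1)
        fh.write("\n")


def write_predictions(preds: Sequence[ImplantPrediction], path: str | Path) -> None:
    with open(path, "w") as fh:
        json.dump(predictions_to_dicts(preds), fh, indent=1)
        fh.write("\n")
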