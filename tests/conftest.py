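import math

import pytest

from perikit.annotations_io import (
    DatasetBundle,
    ImageRecord,
    ImplantAnnotation,
    ImplantPrediction,
    Keypoint,
)


def kps(coords, v=2):
    """Six keypoints from (x, y) pairs."""
    assert len(coords) == 6
    return tuple(Keypoint(float(x), float(y), v) for x, y in coords)


def vertical_implant_kps(cx=100.0, apex_y=300.0, top_y=100.0, half_width=30.0, loss=0.25):
    """Landmarks of an upright rectangular implant with the given loss fraction."""
    bone_y = top_y + loss * (apex_y - top_y)
    return kps(
        [
            (cx - half_width, bone_y),
            (cx + half_width, bone_y),
            (cx - half_width, apex_y),
            (cx + half_width, apex_y),
            (cx - half_width, top_y),
            (cx + half_width, top_y),
        ]
    )


def make_annotation(ann_id=1, image_id=1, loss=0.25, cx=100.0, **kw):
    keypoints = kw.pop("keypoints", None)
    if keypoints is None:
        keypoints = vertical_implant_kps(cx=cx, loss=loss)
    xs = [k.x for k in keypoints]
    ys = [k.y for k in keypoints]
    bbox = kw.pop("bbox", (min(xs), min(ys), max(xs) - min(xs) or 1.0, max(ys) - min(ys) or 1.0))
    area = kw.pop("area", 60.0 * 200.0)
    return ImplantAnnotation(
        annotation_id=ann_id, image_id=image_id, bbox=bbox, area=area, keypoints=keypoints
    )


def make_bundle(annotations, n_images=None, width=1000, height=800):
    image_ids = sorted({a.image_id for a in annotations}) or [1]
    images = [
        ImageRecord(i, width, height, "upper" if i % 2 else "lower") for i in image_ids
    ]
    return DatasetBundle(images=images, annotations=list(annotations))


def prediction_from(ann, box_score=0.95, keypoint_scores=(0.9,) * 6, dx=0.0, dy=0.0):
    """Prediction echoing an annotation, optionally shifted."""
    return ImplantPrediction(
        image_id=ann.image_id,
        bbox=ann.bbox,
        box_score=box_score,
        keypoints=tuple(Keypoint(k.x + dx, k.y + dy, 2) for k in ann.keypoints),
        keypoint_scores=tuple(keypoint_scores),
    )


def displaced_prediction(ann, multiplier, sigma, box_score=0.95, angle=0.3):
    """Prediction with every landmark displaced by exactly
    multiplier * sigma_i * s at a fixed angle."""
    s = math.sqrt(ann.area)
    new = []
    for i, k in enumerate(ann.keypoints):
        d = multiplier * sigma.sigma[i] * s
        new.append(Keypoint(k.x + d * math.cos(angle), k.y + d * math.sin(angle), 2))
    return ImplantPrediction(
        image_id=ann.image_id,
        bbox=ann.bbox,
        box_score=box_score,
        keypoints=tuple(new),
        keypoint_scores=(0.9,) * 6,
    )


@pytest.fixture
def simple_bundle():
    anns = [make_annotation(1, 1, loss=0.25, cx=100), make_annotation(2, 1, loss=0.60, cx=400)]
    return make_bundle(anns)
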