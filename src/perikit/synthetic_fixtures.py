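"""Synthetic radiograph annotations and noisy detector outputs.

The generator places each implant as a rotated rectangle inside a virtual
periapical radiograph and derives the six landmarks from it exactly: the two
apex corners, the two most-coronal-thread corners (implant top), and the two
marginal bone-level points placed at the sampled bone-loss fraction along each
side between top and apex.  The segmented area is the rectangle area and the
box is the axis-aligned envelope, so every geometric relation the metrics
assume holds by construction — ``measure_bone_loss`` on generated landmarks
returns the sampled percentage to machine precision.

Prediction noise is calibrated to the OKS normalization: per-axis Gaussian
displacement with standard deviation ``s * sigma_i / sqrt(2)`` makes
``E[d^2/s^2] = sigma_i^2`` exact, so sigma calibration on redundant synthetic
annotations is a parameter-recovery experiment.  A fixed-magnitude mode
displaces every landmark by exactly ``m * sigma_i * s`` in a uniform random
direction, which pins each implant's OKS to ``exp(-m^2/8)`` — the exact
inverse of the analytic mean-OKS interpretation.

Randomness discipline: one independent stream per (purpose, image), keyed by
``(seed, purpose, image index)``, so enlarging ``n_images`` never reshuffles
earlier images and ground truth, predictions and redundant annotations are
mutually independent.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, replace
from typing import Sequence

import numpy as np

from perikit.annotations_io import (
    DatasetBundle,
    ImageRecord,
    ImplantAnnotation,
    ImplantPrediction,
    Keypoint,
)
from perikit.errors import GenerationError, ValidationError
from perikit.similarity_metrics import PAPER_SIGMA_VALUES

_STREAM_TRUTH = 0
_STREAM_PRED = 1
_STREAM_REDUNDANT = 2

#: Severity-bin edges the loss mixture samples over, in percent.
_LOSS_BINS = ((0.0, 10.0), (10.0, 25.0), (25.0, 50.0), (50.0, 100.0))


@dataclass(frozen=True)
class SyntheticConfig:
    """Study conditions for the synthetic generator.

    Geometry defaults emulate implants on periapical radiographs: roughly
    1000 x 800 px films, implants 200–400 px long and 60–120 px wide, tilted
    up to 20 degrees from vertical, one to three implants per film, balanced
    upper/lower jaws.  The bone-loss mixture weights the four severity bins
    toward the milder end; ``sigma_true`` defaults to the published
    calibration so displacement noise has realistic per-landmark structure.
    """

    n_images: int = 50
    implants_per_image: tuple[int, int] = (1, 3)
    p_upper: float = 0.5
    image_size: tuple[int, int] = (1000, 800)  # width, height in px
    length_range: tuple[float, float] = (200.0, 400.0)
    width_range: tuple[float, float] = (60.0, 120.0)
    tilt_range_deg: tuple[float, float] = (-20.0, 20.0)
    severity_weights: tuple[float, float, float, float] = (0.4, 0.3, 0.2, 0.1)
    loss_range: tuple[float, float] | None = None  # overrides the mixture when set
    sigma_true: tuple[float, ...] = PAPER_SIGMA_VALUES
    tp_score_range: tuple[float, float] = (0.75, 1.0)
    fp_score_range: tuple[float, float] = (0.1, 0.6)
    fp_rate: float = 0.05
    fn_rate: float = 0.05
    displacement_mode: str = "gaussian"  # or "fixed": |d| = multiplier*sigma*s exactly
    displacement_multiplier: float = 1.0
    score_mode: str = "independent"  # or "correlated": score decreasing in d/s
    box_jitter: float = 0.01  # relative box corner/size jitter for predictions
    seed: int = 0

    def __post_init__(self) -> None:
        for rate in (self.fp_rate, self.fn_rate, self.p_upper):
            if not 0.0 <= rate <= 1.0:
                raise ValidationError(f"rates must be in [0, 1], got {rate}")
        if abs(sum(self.severity_weights) - 1.0) > 1e-9:
            raise ValidationError("severity weights must sum to 1")
        if self.seed < 0:
            raise ValidationError("seed must be non-negative")
        for lo, hi in (
            self.implants_per_image,
            self.length_range,
            self.width_range,
            self.tp_score_range,
            self.fp_score_range,
        ):
            if hi < lo:
                raise ValidationError(f"degenerate range ({lo}, {hi})")
        if self.displacement_mode not in ("gaussian", "fixed"):
            raise ValidationError(f"unknown displacement mode {self.displacement_mode!r}")
        if self.score_mode not in ("independent", "correlated"):
            raise ValidationError(f"unknown score mode {self.score_mode!r}")
        if len(self.sigma_true) != 6:
            raise ValidationError("sigma_true must have 6 entries")


@dataclass(frozen=True)
class SyntheticBundle:
    """Generated truth and predictions plus generation provenance."""

    truth: DatasetBundle
    predictions: tuple[ImplantPrediction, ...]
    true_loss_percentages: dict[int, float]  # annotation_id -> sampled loss %
    config: SyntheticConfig = field(compare=False)


def _rng(config: SyntheticConfig, stream: int, image_index: int) -> np.random.Generator:
    return np.random.default_rng((config.seed, stream, image_index))


def _sample_loss_percent(rng: np.random.Generator, config: SyntheticConfig) -> float:
    if config.loss_range is not None:
        lo, hi = config.loss_range
        return float(rng.uniform(lo, hi)) if hi > lo else float(lo)
    bin_idx = rng.choice(4, p=config.severity_weights)
    lo, hi = _LOSS_BINS[bin_idx]
    return float(rng.uniform(lo, hi))


def _sample_implant(rng: np.random.Generator, config: SyntheticConfig):
    """Rotated-rectangle implant geometry: returns the 6 landmarks, bbox, area
    and the sampled loss percentage."""
    img_w, img_h = config.image_size
    length = float(rng.uniform(*config.length_range))
    width = float(rng.uniform(*config.width_range))
    tilt = math.radians(float(rng.uniform(*config.tilt_range_deg)))

    half_diag = 0.5 * math.hypot(length, width)
    if 2.0 * half_diag >= min(img_w, img_h):
        raise GenerationError(
            f"implant (length {length:.0f}, width {width:.0f}) does not fit a "
            f"{img_w} x {img_h} image"
        )
    cx = float(rng.uniform(half_diag, img_w - half_diag))
    cy = float(rng.uniform(half_diag, img_h - half_diag))

    # Long axis points from coronal (top) to apical end; w is the left->right
    # perpendicular.
    u = (math.sin(tilt), math.cos(tilt))
    w = (math.cos(tilt), -math.sin(tilt))
    apex_c = (cx + 0.5 * length * u[0], cy + 0.5 * length * u[1])
    top_c = (cx - 0.5 * length * u[0], cy - 0.5 * length * u[1])

    def corner(center, side):
        return (center[0] + side * 0.5 * width * w[0], center[1] + side * 0.5 * width * w[1])

    apex_l, apex_r = corner(apex_c, -1), corner(apex_c, +1)
    top_l, top_r = corner(top_c, -1), corner(top_c, +1)

    loss = _sample_loss_percent(rng, config)
    f = loss / 100.0
    bone_l = (top_l[0] + f * (apex_l[0] - top_l[0]), top_l[1] + f * (apex_l[1] - top_l[1]))
    bone_r = (top_r[0] + f * (apex_r[0] - top_r[0]), top_r[1] + f * (apex_r[1] - top_r[1]))

    pts = [bone_l, bone_r, apex_l, apex_r, top_l, top_r]
    keypoints = tuple(Keypoint(x, y, 2) for x, y in pts)
    corners = (apex_l, apex_r, top_l, top_r)
    xs = [p[0] for p in corners]
    ys = [p[1] for p in corners]
    bbox = (min(xs), min(ys), max(xs) - min(xs), max(ys) - min(ys))
    return keypoints, bbox, length * width, loss


def _generate(config: SyntheticConfig) -> tuple[DatasetBundle, dict[int, float]]:
    images = []
    annotations = []
    loss_map: dict[int, float] = {}
    lo, hi = config.implants_per_image
    for idx in range(config.n_images):
        rng = _rng(config, _STREAM_TRUTH, idx)
        image_id = idx + 1
        jaw = "upper" if rng.random() < config.p_upper else "lower"
        images.append(
            ImageRecord(image_id, config.image_size[0], config.image_size[1], jaw)
        )
        n_implants = int(rng.integers(lo, hi + 1))
        for k in range(n_implants):
            keypoints, bbox, area, loss = _sample_implant(rng, config)
            ann_id = image_id * 100 + k
            annotations.append(
                ImplantAnnotation(
                    annotation_id=ann_id,
                    image_id=image_id,
                    bbox=bbox,
                    area=area,
                    keypoints=keypoints,
                )
            )
            loss_map[ann_id] = loss
    return DatasetBundle(images=images, annotations=annotations), loss_map


def generate_ground_truth(config: SyntheticConfig) -> DatasetBundle:
    """Deterministic synthetic ground truth for the given config and seed."""
    return _generate(config)[0]


def _displace(
    rng: np.random.Generator,
    keypoints: Sequence[Keypoint],
    scale: float,
    config: SyntheticConfig,
) -> tuple[tuple[Keypoint, ...], np.ndarray]:
    """Displace the six landmarks; returns new keypoints and d/(s*sigma_i)."""
    mult = config.displacement_multiplier
    new = []
    rel = np.zeros(6)
    for i, kp in enumerate(keypoints):
        sig = config.sigma_true[i]
        if config.displacement_mode == "fixed":
            d = mult * sig * scale
            phi = rng.uniform(0.0, 2.0 * math.pi)
            dx, dy = d * math.cos(phi), d * math.sin(phi)
        else:
            std = scale * sig * mult / math.sqrt(2.0)
            dx, dy = rng.normal(0.0, std, 2) if std > 0 else (0.0, 0.0)
        new.append(Keypoint(kp.x + dx, kp.y + dy, 2))
        rel[i] = math.hypot(dx, dy) / (scale * sig) if sig > 0 else 0.0
    return tuple(new), rel


def _scores(
    rng: np.random.Generator, rel: np.ndarray, config: SyntheticConfig
) -> tuple[float, tuple[float, ...]]:
    lo, hi = config.tp_score_range
    box_score = float(rng.uniform(lo, hi))
    if config.score_mode == "correlated":
        # Score decays with normalized displacement; box scores stay high and
        # uninformative, mirroring detectors whose detection confidence does
        # not track keypoint quality.
        kp_scores = tuple(
            float(np.clip(hi - (hi - lo) * r / 3.0 - rng.uniform(0, 0.02), 0.0, 1.0))
            for r in rel
        )
    else:
        kp_scores = tuple(float(s) for s in rng.uniform(lo, hi, 6))
    return box_score, kp_scores


def perturb_to_predictions(
    truth: DatasetBundle, config: SyntheticConfig
) -> list[ImplantPrediction]:
    """Noisy detector output for a generated ground truth: keypoint
    displacement, box jitter, confidence scores, plus dropped implants
    (``fn_rate``) and spurious detections (``fp_rate``)."""
    preds: list[ImplantPrediction] = []
    for idx, image in enumerate(truth.images):
        rng = _rng(config, _STREAM_PRED, idx)
        anns = truth.annotations_for(image.image_id)
        for ann in anns:
            if rng.random() < config.fn_rate:
                continue
            s = math.sqrt(ann.area)
            keypoints, rel = _displace(rng, ann.keypoints, s, config)
            x, y, w, h = ann.bbox
            j = config.box_jitter
            if j > 0:
                x += float(rng.normal(0, j * w))
                y += float(rng.normal(0, j * h))
                w = max(w * float(1 + rng.normal(0, j)), 1e-3)
                h = max(h * float(1 + rng.normal(0, j)), 1e-3)
            box_score, kp_scores = _scores(rng, rel, config)
            preds.append(
                ImplantPrediction(
                    image_id=image.image_id,
                    bbox=(x, y, w, h),
                    box_score=box_score,
                    keypoints=keypoints,
                    keypoint_scores=kp_scores,
                )
            )
        # spurious detections with random implant-like geometry
        for _ in range(len(anns)):
            if rng.random() < config.fp_rate:
                keypoints, bbox, _, _ = _sample_implant(rng, config)
                lo, hi = config.fp_score_range
                preds.append(
                    ImplantPrediction(
                        image_id=image.image_id,
                        bbox=bbox,
                        box_score=float(rng.uniform(lo, hi)),
                        keypoints=keypoints,
                        keypoint_scores=tuple(float(v) for v in rng.uniform(lo, hi, 6)),
                    )
                )
    return preds


def redundant_annotations(
    truth: DatasetBundle, config: SyntheticConfig
) -> tuple[list[ImplantAnnotation], dict[int, int]]:
    """A second annotation pass over every implant (no drops, no spurious
    additions): landmarks displaced at ``sigma_true``, identity pairing.
    Ready to feed :func:`perikit.similarity_metrics.calibrate_sigma`."""
    gaussian = replace(config, displacement_mode="gaussian", displacement_multiplier=1.0)
    second: list[ImplantAnnotation] = []
    pairing: dict[int, int] = {}
    for idx, image in enumerate(truth.images):
        rng = _rng(config, _STREAM_REDUNDANT, idx)
        for ann in truth.annotations_for(image.image_id):
            s = math.sqrt(ann.area)
            keypoints, _ = _displace(rng, ann.keypoints, s, gaussian)
            second.append(
                ImplantAnnotation(
                    annotation_id=ann.annotation_id,
                    image_id=ann.image_id,
                    bbox=ann.bbox,
                    area=ann.area,
                    keypoints=keypoints,
                )
            )
            pairing[ann.annotation_id] = ann.annotation_id
    return second, pairing


def generate(config: SyntheticConfig) -> SyntheticBundle:
    """Ground truth plus matching noisy predictions, with provenance."""
    truth, loss_map = _generate(config)
    preds = perturb_to_predictions(truth, config)
    return SyntheticBundle(
        truth=truth,
        predictions=tuple(preds),
        true_loss_percentages=loss_map,
        config=config,
    )
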