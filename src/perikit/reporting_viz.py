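"""Keypoint-logit heatmaps and annotated prediction overlays.

Per-implant keypoint logit grids (height x width x 6, aligned to an image
region) are min–max normalized per channel to [0, 1], combined across
channels by per-pixel maximum, colormapped, and alpha-blended onto the
radiograph.  Prediction overlays draw the box, the six landmarks, the three
midpoints, the two measured segments and a text readout of the bone-loss
percentage, severity and confidence scores.

Rendering is pure: the same inputs produce a byte-identical raster (the text
overlay uses the bundled bitmap font, never a system font).
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Sequence

import numpy as np
from matplotlib import colormaps
from PIL import Image, ImageDraw

from perikit.annotations_io import ImplantPrediction
from perikit.bone_loss import BoneLossMeasurement
from perikit.errors import GeometryError, ValidationError

DEFAULT_COLORMAP = "viridis"


@dataclass(frozen=True)
class HeatmapGrid:
    """Keypoint logits over an image region: (height, width, 6) array plus the
    region's pixel offset in the full image."""

    logits: np.ndarray
    origin: tuple[int, int] = (0, 0)  # (x, y) offset

    def __post_init__(self) -> None:
        arr = np.asarray(self.logits, dtype=float)
        if arr.ndim != 3 or arr.shape[2] != 6:
            raise ValidationError(
                f"heatmap grid must be (height, width, 6), got {arr.shape}"
            )
        object.__setattr__(self, "logits", arr)


@dataclass(frozen=True)
class RenderedOverlay:
    """RGB raster plus the legend metadata needed to reproduce it."""

    image: np.ndarray  # (H, W, 3) uint8
    legend: dict

    def to_pil(self) -> Image.Image:
        return Image.fromarray(self.image)

    def save(self, path) -> None:
        self.to_pil().save(path, format="PNG")


def normalize_logits(grid: HeatmapGrid) -> HeatmapGrid:
    """Min–max scale each channel to [0, 1].

    A constant channel maps to all zeros: a channel with no signal should not
    paint the image.  Non-finite logits are an error, never silently dropped.
    """
    arr = grid.logits
    if not np.isfinite(arr).all():
        raise ValidationError("heatmap grid contains non-finite logits")
    lo = arr.min(axis=(0, 1), keepdims=True)
    hi = arr.max(axis=(0, 1), keepdims=True)
    span = hi - lo
    out = np.where(span > 0, (arr - lo) / np.where(span > 0, span, 1.0), 0.0)
    return HeatmapGrid(out, grid.origin)


def combine_channels(grid: HeatmapGrid) -> np.ndarray:
    """Per-pixel maximum across the six normalized channels."""
    return np.asarray(grid.logits).max(axis=2)


def _as_rgb_float(image) -> np.ndarray:
    arr = np.asarray(image)
    if arr.dtype == np.uint8:
        arr = arr.astype(float) / 255.0
    else:
        arr = arr.astype(float)
    if arr.ndim == 2:
        arr = np.stack([arr] * 3, axis=2)
    if arr.ndim != 3 or arr.shape[2] < 3:
        raise ValidationError(f"expected a grayscale or RGB raster, got shape {arr.shape}")
    return arr[:, :, :3]


def render_overlay(
    image,
    grid: HeatmapGrid,
    colormap: str = DEFAULT_COLORMAP,
    alpha: float = 0.5,
) -> RenderedOverlay:
    """Blend the combined, colormapped heatmap onto the image.

    The blend weight at a pixel is ``alpha`` times the combined heatmap value,
    so zero-valued pixels (and an all-zero grid) leave the radiograph
    untouched and ``alpha = 0`` is the identity.
    """
    if not 0.0 <= alpha <= 1.0:
        raise ValidationError(f"alpha {alpha} outside [0, 1]")
    base = _as_rgb_float(image)
    h, w = grid.logits.shape[:2]
    x0, y0 = grid.origin
    if x0 < 0 or y0 < 0 or y0 + h > base.shape[0] or x0 + w > base.shape[1]:
        raise GeometryError(
            f"grid region {w}x{h} at ({x0}, {y0}) exceeds image "
            f"{base.shape[1]}x{base.shape[0]}"
        )
    arr = grid.logits
    lo = arr.min(axis=(0, 1))
    hi = arr.max(axis=(0, 1))
    normalized = normalize_logits(grid)
    combined = combine_channels(normalized)
    cmap = colormaps[colormap]
    colors = cmap(combined)[:, :, :3]
    weight = (alpha * combined)[:, :, None]
    out = base.copy()
    region = out[y0 : y0 + h, x0 : x0 + w]
    out[y0 : y0 + h, x0 : x0 + w] = region * (1.0 - weight) + colors * weight
    return RenderedOverlay(
        image=(np.clip(out, 0, 1) * 255).round().astype(np.uint8),
        legend={
            "colormap": colormap,
            "alpha": alpha,
            "channel_min": [float(v) for v in lo],
            "channel_max": [float(v) for v in hi],
        },
    )


_KEYPOINT_COLORS = (
    (228, 26, 28),   # Lt bone level
    (255, 127, 0),   # Rt bone level
    (55, 126, 184),  # Lt apex
    (152, 78, 163),  # Rt apex
    (77, 175, 74),   # Lt implant top
    (166, 86, 40),   # Rt implant top
)


def render_prediction(
    image,
    pred: ImplantPrediction,
    measurement: BoneLossMeasurement,
    radius: int = 4,
) -> RenderedOverlay:
    """Annotated overlay: box, six landmarks, the three midpoints, the two
    measured segments, and a label with percentage, severity and scores."""
    base = (_as_rgb_float(image) * 255).round().astype(np.uint8)
    img = Image.fromarray(base)
    draw = ImageDraw.Draw(img)

    x, y, w, h = pred.bbox
    draw.rectangle((x, y, x + w, y + h), outline=(255, 255, 0), width=2)

    for kp, color in zip(pred.keypoints, _KEYPOINT_COLORS):
        draw.ellipse(
            (kp.x - radius, kp.y - radius, kp.x + radius, kp.y + radius),
            outline=color,
            width=2,
        )

    apex, top, bone = (
        measurement.apex_midpoint,
        measurement.top_midpoint,
        measurement.bone_level_midpoint,
    )
    draw.line((apex[0], apex[1], top[0], top[1]), fill=(255, 255, 255), width=2)
    draw.line((top[0], top[1], bone[0], bone[1]), fill=(255, 0, 0), width=3)
    for p in (apex, top, bone):
        draw.ellipse((p[0] - 2, p[1] - 2, p[0] + 2, p[1] + 2), fill=(255, 255, 255))

    kp_mean = sum(pred.keypoint_scores) / 6.0
    label = (
        f"{measurement.percentage:.1f}% {measurement.severity}"
        f" | box {pred.box_score:.2f} kp {kp_mean:.2f}"
    )
    tx = max(0.0, min(x, img.width - 10))
    ty = max(0.0, y - 12)
    draw.text((tx, ty), label, fill=(255, 255, 0))

    return RenderedOverlay(
        image=np.asarray(img),
        legend={
            "label": label,
            "percentage": measurement.percentage,
            "severity": measurement.severity,
        },
    )


def load_heatmap_grid(path) -> HeatmapGrid:
    """Read a grid from an ``.npz`` tensor file with arrays ``logits``
    (H x W x 6) and optional ``origin`` (x, y)."""
    with np.load(path) as data:
        logits = data["logits"]
        origin = tuple(int(v) for v in data["origin"]) if "origin" in data else (0, 0)
    return HeatmapGrid(logits, origin)


def save_heatmap_grid(grid: HeatmapGrid, path) -> None:
    np.savez(path, logits=grid.logits, origin=np.asarray(grid.origin))
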