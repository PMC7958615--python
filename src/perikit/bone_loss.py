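"""Radiographic bone-loss ratio and peri-implantitis severity from six landmarks.

Total implant length runs from the midpoint of the two apex landmarks to the
midpoint of the two implant-top landmarks (the most coronal thread).  The
defect length runs from the top midpoint to the midpoint of the two marginal
bone-level landmarks.  The bone-loss percentage is defect over total, and the
severity is binned: normal (<=10%), early (>10–25%), moderate (>25–50%),
severe (>50%).

Two geometric corrections the raw distances need:

* A bone level at or coronal to the implant top means bone *gain*, not loss;
  the unsigned distance would misread it.  The bone-level midpoint is
  projected onto the apex-to-top axis and the defect is clamped to zero when
  it falls at or above the top.
* A bone level apical to the apex midpoint yields a percentage above 100;
  such radiographs exist, so the value is clamped to 100 and flagged rather
  than rejected.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Sequence

from perikit.annotations_io import Keypoint
from perikit.errors import DegenerateImplantError, MeasurementError, ValidationError

DEFAULT_THRESHOLDS = (10.0, 25.0, 50.0)
DEFAULT_LABELS = ("normal", "early", "moderate", "severe")


@dataclass(frozen=True)
class SeverityScale:
    """Percentage cut points and the class labels they separate.

    Bins are closed on the right: a percentage exactly at a cut point takes
    the milder class (10% is still normal, 50% still moderate)."""

    thresholds: tuple[float, ...] = DEFAULT_THRESHOLDS
    labels: tuple[str, ...] = DEFAULT_LABELS

    def __post_init__(self) -> None:
        if len(self.labels) != len(self.thresholds) + 1:
            raise ValidationError("need exactly one more label than threshold")
        if list(self.thresholds) != sorted(self.thresholds):
            raise ValidationError("thresholds must be strictly increasing")
        for t in self.thresholds:
            if not 0.0 < t < 100.0:
                raise ValidationError(f"threshold {t} outside (0, 100)")
        if len(set(self.thresholds)) != len(self.thresholds):
            raise ValidationError("thresholds must be strictly increasing")


DEFAULT_SCALE = SeverityScale()


def classify_severity(percentage: float, scale: SeverityScale = DEFAULT_SCALE) -> str:
    """Map a bone-loss percentage to its severity label."""
    if not 0.0 <= percentage <= 100.0:
        raise ValidationError(f"percentage {percentage} outside [0, 100]")
    for t, label in zip(scale.thresholds, scale.labels):
        if percentage <= t:
            return label
    return scale.labels[-1]


def keypoint_midpoint(left: Keypoint, right: Keypoint) -> tuple[float, float]:
    """Arithmetic midpoint of a left/right landmark pair."""
    if not left.labeled:
        raise MeasurementError("left keypoint is not labeled")
    if not right.labeled:
        raise MeasurementError("right keypoint is not labeled")
    return ((left.x + right.x) / 2.0, (left.y + right.y) / 2.0)


@dataclass(frozen=True)
class BoneLossMeasurement:
    total_length: float  # apex midpoint to top midpoint, pixels
    defect_length: float  # top midpoint to bone-level midpoint, pixels
    percentage: float  # 100 * defect / total, clamped to [0, 100]
    severity: str
    apex_midpoint: tuple[float, float]
    top_midpoint: tuple[float, float]
    bone_level_midpoint: tuple[float, float]
    clamped: bool = False  # True when raw percentage fell outside [0, 100]

    def summary(self) -> str:
        flag = " (clamped)" if self.clamped else ""
        return (
            f"total {self.total_length:.1f} px, defect {self.defect_length:.1f} px, "
            f"bone loss {self.percentage:.1f}% -> {self.severity}{flag}"
        )


def measure_bone_loss(
    keypoints: Sequence[Keypoint], scale: SeverityScale = DEFAULT_SCALE
) -> BoneLossMeasurement:
    """Measure total length, defect length, percentage and severity from the
    six landmarks of one implant (all must be labeled)."""
    if len(keypoints) != 6:
        raise MeasurementError(f"expected 6 keypoints, got {len(keypoints)}")
    bone_l, bone_r, apex_l, apex_r, top_l, top_r = keypoints
    bone_mid = keypoint_midpoint(bone_l, bone_r)
    apex_mid = keypoint_midpoint(apex_l, apex_r)
    top_mid = keypoint_midpoint(top_l, top_r)

    total = math.dist(apex_mid, top_mid)
    if total == 0.0:
        raise DegenerateImplantError("apex and top midpoints coincide: zero implant length")

    # Signed position of the bone level along the top->apex axis: negative
    # means coronal to the top (bone gain), which clamps the defect to zero.
    axis = ((apex_mid[0] - top_mid[0]) / total, (apex_mid[1] - top_mid[1]) / total)
    proj = (bone_mid[0] - top_mid[0]) * axis[0] + (bone_mid[1] - top_mid[1]) * axis[1]
    defect = 0.0 if proj <= 0.0 else math.dist(top_mid, bone_mid)

    raw_pct = 100.0 * defect / total
    clamped = proj < 0.0 or raw_pct > 100.0
    pct = min(raw_pct, 100.0)
    return BoneLossMeasurement(
        total_length=total,
        defect_length=defect,
        percentage=pct,
        severity=classify_severity(pct, scale),
        apex_midpoint=apex_mid,
        top_midpoint=top_mid,
        bone_level_midpoint=bone_mid,
        clamped=clamped,
    )


def absolute_bone_loss(percentage: float, implant_length_mm: float) -> float:
    """Absolute bone loss in millimetres given the implant's real length."""
    if implant_length_mm <= 0:
        raise ValidationError(f"implant length must be positive, got {implant_length_mm}")
    if not 0.0 <= percentage <= 100.0:
        raise ValidationError(f"percentage {percentage} outside [0, 100]")
    return percentage / 100.0 * implant_length_mm
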