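"""Mean-OKS observer agreement and its normal-model interpretation.

Because a human annotator emits no confidence scores, model-versus-human
comparison cannot use precision–recall machinery.  Instead, detections with a
box confidence above a single threshold (default 0.7) are matched one-to-one
to ground truth by highest OKS, and the matched OKS values are averaged.

A mean OKS admits an analytic reading.  For a single landmark displaced by
``d`` the similarity is ``exp(-d^2/(2 s^2 k^2))`` with ``k = 2 sigma``;
inverting at a given OKS yields the equivalent displacement multiplier
``m = d/(s sigma) = sqrt(-8 ln OKS)``.  Modelling the signed 1-D projection
of scale-normalized human annotation error as standard normal (after dividing
by ``s sigma``), the share of human annotations landing closer than the
model's equivalent displacement is ``2 Phi(m) - 1`` — e.g. a mean OKS of
0.8885 corresponds to m = 0.9725 and places about 66.92% of human annotations
closer to ground truth than the model.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Sequence

import numpy as np
from scipy import stats

from perikit.annotations_io import DatasetBundle, ImplantPrediction
from perikit.errors import EmptyReportError, StatisticsError, ValidationError
from perikit.similarity_metrics import (
    DEFAULT_K_CONSTANT,
    PAPER_SIGMA,
    SigmaVector,
    oks,
)

#: Detection-confidence threshold for mean-OKS agreement.
DEFAULT_DETECTION_THRESHOLD = 0.7


@dataclass(frozen=True)
class AgreementReport:
    """Per-implant OKS of detections surviving the confidence threshold."""

    oks_values: tuple[float, ...]
    mean_oks: float
    n_detected: int
    detection_threshold: float
    sigma: SigmaVector

    def summary(self) -> str:
        return (
            f"mean OKS = {self.mean_oks:.4f} over {self.n_detected} detected implants "
            f"(box score > {self.detection_threshold})"
        )


def mean_oks(
    gt: DatasetBundle,
    preds: Sequence[ImplantPrediction],
    sigma: SigmaVector = PAPER_SIGMA,
    detection_threshold: float = DEFAULT_DETECTION_THRESHOLD,
    k_constant: float = DEFAULT_K_CONSTANT,
) -> AgreementReport:
    """Average OKS of threshold-surviving detections matched to ground truth.

    Matching keeps, per image, highest-OKS pairs one-to-one (prediction input
    order breaks exact ties).  Implants with no labeled keypoint are skipped —
    their OKS is undefined, not zero.
    """
    if not 0.0 <= detection_threshold <= 1.0:
        raise ValidationError(f"detection threshold {detection_threshold} outside [0, 1]")
    surviving = [(i, p) for i, p in enumerate(preds) if p.box_score > detection_threshold]
    if not surviving:
        raise EmptyReportError(
            f"no predictions with box score above {detection_threshold}"
        )
    values: list[float] = []
    for image in gt.images:
        anns = [a for a in gt.annotations_for(image.image_id) if a.n_labeled > 0]
        image_preds = [(i, p) for i, p in surviving if p.image_id == image.image_id]
        if not anns or not image_preds:
            continue
        pairs = []
        for ann in anns:
            for order, (i, p) in enumerate(image_preds):
                pairs.append((oks(ann, p.keypoints, sigma, k_constant), order, ann.annotation_id))
        pairs.sort(key=lambda t: (-t[0], t[1]))
        used_ann: set[int] = set()
        used_pred: set[int] = set()
        for value, order, ann_id in pairs:
            if ann_id in used_ann or order in used_pred:
                continue
            used_ann.add(ann_id)
            used_pred.add(order)
            values.append(value)
    if not values:
        raise EmptyReportError("no surviving prediction could be matched to a ground truth")
    return AgreementReport(
        oks_values=tuple(values),
        mean_oks=float(np.mean(values)),
        n_detected=len(values),
        detection_threshold=detection_threshold,
        sigma=sigma,
    )


def oks_to_sigma_multiplier(oks_value: float) -> float:
    """Equivalent displacement multiplier m with d/s = m*sigma at the given
    single-keypoint OKS: m = sqrt(-8 ln OKS)."""
    if not 0.0 < oks_value <= 1.0:
        raise ValidationError(f"OKS value must be in (0, 1], got {oks_value}")
    return math.sqrt(-8.0 * math.log(oks_value))


def fraction_better(oks_value: float) -> float:
    """Percentage of human annotations expected to land closer to ground truth
    than a prediction with this OKS, under the standard-normal error model:
    100 * (2*Phi(m) - 1) with m = sqrt(-8 ln OKS)."""
    m = oks_to_sigma_multiplier(oks_value)
    return float(100.0 * (2.0 * stats.norm.cdf(m) - 1.0))


@dataclass(frozen=True)
class ComparisonResult:
    """Two-sample t-test between two observers' per-implant OKS values.

    Sign convention: t > 0 when group A's mean OKS exceeds group B's."""

    t_statistic: float
    df: float
    p_value: float
    label_a: str
    label_b: str
    n_a: int
    n_b: int
    test: str

    @property
    def significant(self) -> bool:
        return self.p_value < 0.05

    def summary(self) -> str:
        return (
            f"{self.label_a} (n={self.n_a}) vs {self.label_b} (n={self.n_b}): "
            f"t = {self.t_statistic:.4f}, df = {self.df:.1f}, p = {self.p_value:.4f} "
            f"({self.test})"
        )


def compare_observers(
    oks_a: Sequence[float],
    oks_b: Sequence[float],
    test: str = "welch",
    label_a: str = "A",
    label_b: str = "B",
) -> ComparisonResult:
    """Independent two-sample t-test on per-implant OKS values.

    Welch (unequal variances) by default; ``test="pooled"`` gives the
    equal-variance Student test.  Two-sided p value; whether p < 0.05 counts
    as significant is the caller's reading.
    """
    if len(oks_a) < 2 or len(oks_b) < 2:
        raise StatisticsError("each group needs at least 2 OKS values")
    if test == "welch":
        equal_var = False
    elif test == "pooled":
        equal_var = True
    else:
        raise ValidationError(f"unknown test {test!r}; expected 'welch' or 'pooled'")
    res = stats.ttest_ind(np.asarray(oks_a, float), np.asarray(oks_b, float), equal_var=equal_var)
    return ComparisonResult(
        t_statistic=float(res.statistic),
        df=float(res.df),
        p_value=float(res.pvalue),
        label_a=label_a,
        label_b=label_b,
        n_a=len(oks_a),
        n_b=len(oks_b),
        test=test,
    )
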