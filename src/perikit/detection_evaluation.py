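"""Greedy detection matching and the AP/AR/PR protocol.

Predictions are matched one-to-one to ground-truth implants per image, in
descending confidence order; each prediction takes the highest-similarity
still-unmatched ground truth with similarity at or above the threshold, else
it is a false positive.  Unmatched ground truths are false negatives.  The
similarity is box IoU for the detection task and implant OKS for the keypoint
task.

AP follows the 101-point interpolated convention of the COCO evaluator
lineage; AR at a threshold is recall with every prediction retained (no score
floor, no maximum-detections cap — implant counts per radiograph are small).
``ap_all`` / ``ar_all`` average the ten thresholds 0.50, 0.55, ..., 0.95.

One deliberate subtlety: the published precision–recall curves show one point
per confidence-score threshold, so :func:`pr_curve` collapses tied scores to a
single operating point.  AP inside :func:`evaluate` is computed from the
uncollapsed per-detection cumulative points instead, which is the convention
the COCO evaluator uses and differs from the collapsed curve only when scores
tie exactly.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
import pandas as pd

from perikit.annotations_io import DatasetBundle, ImplantAnnotation, ImplantPrediction
from perikit.errors import ConfigurationError, UndefinedRecallError
from perikit.similarity_metrics import (
    DEFAULT_K_CONSTANT,
    PAPER_SIGMA,
    SigmaVector,
    iou,
    oks,
)

#: Similarity thresholds of the standard protocol: 0.50 to 0.95 step 0.05.
DEFAULT_THRESHOLDS = tuple(np.round(np.arange(0.50, 0.96, 0.05), 2))

SIMILARITIES = ("iou", "oks")
RANKINGS = ("box_score", "keypoint_score")
TASKS = ("bbox", "keypoints")


@dataclass(frozen=True)
class MatchRow:
    """One ranked prediction with its match outcome."""

    prediction: ImplantPrediction
    matched_annotation_id: int | None
    similarity: float  # similarity to the matched GT; 0.0 for false positives
    score: float  # ranking score used to order detections

    @property
    def is_tp(self) -> bool:
        return self.matched_annotation_id is not None


@dataclass(frozen=True)
class MatchSet:
    """Ranked match outcomes plus the ground-truth count they are scored against."""

    rows: tuple[MatchRow, ...]
    n_ground_truth: int


def _similarity_fn(similarity: str, sigma: SigmaVector, k_constant: float):
    if similarity == "iou":
        return lambda gt, pred: iou(gt.bbox, pred.bbox)
    if similarity == "oks":
        return lambda gt, pred: oks(gt, pred.keypoints, sigma, k_constant)
    raise ConfigurationError(f"unknown similarity {similarity!r}; expected one of {SIMILARITIES}")


def match_detections(
    gts: DatasetBundle | Sequence[ImplantAnnotation],
    preds: Sequence[ImplantPrediction],
    similarity: str = "oks",
    threshold: float = 0.5,
    ranking: str = "keypoint_score",
    sigma: SigmaVector = PAPER_SIGMA,
    k_constant: float = DEFAULT_K_CONSTANT,
    aggregation: str = "mean",
) -> MatchSet:
    """Greedy one-to-one assignment of predictions to ground truths.

    Matching never crosses images.  Ties in ranking score break by
    (image_id, input order) so replays are deterministic; ties in similarity
    keep the earliest ground truth in input order.  Ground truths with no
    labeled keypoint are excluded from the keypoint task entirely (their OKS
    is undefined).
    """
    if ranking not in RANKINGS:
        raise ConfigurationError(f"unknown ranking {ranking!r}; expected one of {RANKINGS}")
    annotations = gts.annotations if isinstance(gts, DatasetBundle) else list(gts)
    if similarity == "oks":
        annotations = [a for a in annotations if a.n_labeled > 0]
    sim_fn = _similarity_fn(similarity, sigma, k_constant)

    gts_by_image: dict[int, list[ImplantAnnotation]] = {}
    for ann in annotations:
        gts_by_image.setdefault(ann.image_id, []).append(ann)

    ranked = sorted(
        enumerate(preds),
        key=lambda ip: (-ip[1].ranking_score(ranking, aggregation), ip[1].image_id, ip[0]),
    )

    matched_gt: set[int] = set()
    rows = []
    for _, pred in ranked:
        score = pred.ranking_score(ranking, aggregation)
        best_id, best_sim = None, -1.0
        for ann in gts_by_image.get(pred.image_id, ()):
            if ann.annotation_id in matched_gt:
                continue
            s = sim_fn(ann, pred)
            if s >= threshold and s > best_sim:
                best_id, best_sim = ann.annotation_id, s
        if best_id is not None:
            matched_gt.add(best_id)
            rows.append(MatchRow(pred, best_id, best_sim, score))
        else:
            rows.append(MatchRow(pred, None, 0.0, score))
    return MatchSet(rows=tuple(rows), n_ground_truth=len(annotations))


@dataclass(frozen=True)
class PRCurve:
    """Operating points (score threshold, precision, recall) at one similarity
    threshold, sorted by descending score threshold."""

    points: tuple[tuple[float, float, float], ...]
    similarity_threshold: float

    @property
    def recalls(self) -> np.ndarray:
        return np.array([p[2] for p in self.points])

    @property
    def precisions(self) -> np.ndarray:
        return np.array([p[1] for p in self.points])


def pr_curve(matches: MatchSet, similarity_threshold: float = 0.5, collapse_ties: bool = True) -> PRCurve:
    """Sweep the confidence threshold over the ranked detections.

    At each threshold the retained set is every detection scoring at least
    that much; precision = TP/(TP+FP) and recall = TP/n_ground_truth within
    it.  With ``collapse_ties`` (the default, matching how the published
    curves draw one point per score threshold) detections with equal scores
    form a single point; without it every detection contributes a cumulative
    point, the convention AP integration expects.
    """
    if matches.n_ground_truth == 0:
        raise UndefinedRecallError("recall undefined with zero ground-truth implants")
    points = []
    tp = fp = 0
    rows = matches.rows
    for i, row in enumerate(rows):
        if row.is_tp:
            tp += 1
        else:
            fp += 1
        if collapse_ties and i + 1 < len(rows) and rows[i + 1].score == row.score:
            continue
        points.append((row.score, tp / (tp + fp), tp / matches.n_ground_truth))
    return PRCurve(points=tuple(points), similarity_threshold=similarity_threshold)


def average_precision(curve: PRCurve) -> float:
    """101-point interpolated AP: mean over recall levels 0.00, 0.01, ..., 1.00
    of the interpolated precision max{p(r') : r' >= r} (0 where unattained)."""
    if not curve.points:
        return 0.0
    rec = curve.recalls
    prec = curve.precisions
    # i/100 exactly, so a recall that ties a level compares consistently
    levels = np.arange(101) / 100.0
    interp = np.zeros(101)
    for i, r in enumerate(levels):
        attained = prec[rec >= r]
        if attained.size:
            interp[i] = attained.max()
    return float(interp.mean())


@dataclass(frozen=True)
class EvalSummary:
    """AP/AR aggregates over the similarity-threshold grid for one task and
    one jaw stratum ('all' pools both jaws)."""

    task: str
    jaw: str
    ap_all: float
    ap_50: float
    ap_75: float
    ar_all: float
    table: pd.DataFrame = field(compare=False, repr=False)
    n_ground_truth: int = 0
    n_predictions: int = 0

    def summary(self) -> str:
        lines = [
            f"task={self.task} jaw={self.jaw} "
            f"(n_gt={self.n_ground_truth}, n_pred={self.n_predictions})",
            f"  AP(all)={self.ap_all:.4f}  AP(50)={self.ap_50:.4f}  "
            f"AP(75)={self.ap_75:.4f}  AR(all)={self.ar_all:.4f}",
        ]
        return "\n".join(lines)


def _evaluate_one(
    bundle: DatasetBundle,
    preds: Sequence[ImplantPrediction],
    task: str,
    jaw: str,
    sigma: SigmaVector,
    ranking: str,
    thresholds: Sequence[float],
    k_constant: float,
    aggregation: str,
) -> EvalSummary:
    similarity = "iou" if task == "bbox" else "oks"
    records = []
    for t in thresholds:
        matches = match_detections(
            bundle, preds, similarity, t, ranking, sigma, k_constant, aggregation
        )
        if matches.rows:
            curve = pr_curve(matches, t, collapse_ties=False)
            ap = average_precision(curve)
            ar = curve.points[-1][2]  # recall with all detections retained
        else:
            ap, ar = 0.0, 0.0
        records.append({"threshold": float(t), "ap": ap, "ar": ar})
    table = pd.DataFrame.from_records(records)
    by_t = {r["threshold"]: r for r in records}
    return EvalSummary(
        task=task,
        jaw=jaw,
        ap_all=float(table["ap"].mean()),
        ap_50=by_t.get(0.50, {"ap": float("nan")})["ap"],
        ap_75=by_t.get(0.75, {"ap": float("nan")})["ap"],
        ar_all=float(table["ar"].mean()),
        table=table,
        n_ground_truth=len(bundle.annotations),
        n_predictions=len(preds),
    )


def evaluate(
    gt: DatasetBundle,
    preds: Sequence[ImplantPrediction],
    task: str = "keypoints",
    sigma: SigmaVector = PAPER_SIGMA,
    ranking: str = "keypoint_score",
    thresholds: Sequence[float] = DEFAULT_THRESHOLDS,
    k_constant: float = DEFAULT_K_CONSTANT,
    aggregation: str = "mean",
) -> dict[str, EvalSummary]:
    """Run the full AP/AR protocol, pooled and stratified by jaw.

    Returns summaries keyed by stratum: ``"all"`` always, plus ``"upper"`` /
    ``"lower"`` for strata that contain ground-truth implants.
    """
    if task not in TASKS:
        raise ConfigurationError(f"unknown task {task!r}; expected one of {TASKS}")
    out = {
        "all": _evaluate_one(
            gt, preds, task, "all", sigma, ranking, thresholds, k_constant, aggregation
        )
    }
    for jaw in ("upper", "lower"):
        sub = gt.subset_by_jaw(jaw)
        if not sub.annotations:
            continue
        ids = sub.image_ids
        sub_preds = [p for p in preds if p.image_id in ids]
        out[jaw] = _evaluate_one(
            sub, sub_preds, task, jaw, sigma, ranking, thresholds, k_constant, aggregation
        )
    return out
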