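import itertools
import math

import numpy as np
import pytest

from perikit.detection_evaluation import (
    DEFAULT_THRESHOLDS,
    MatchSet,
    average_precision,
    evaluate,
    match_detections,
    pr_curve,
)
from perikit.errors import ConfigurationError, UndefinedRecallError
from perikit.similarity_metrics import PAPER_SIGMA, oks
from perikit.synthetic_fixtures import SyntheticConfig, generate
from tests._reference_eval import ref_ap_by_definition, ref_evaluate
from tests.conftest import make_annotation, make_bundle, prediction_from


class TestMatchDetections:
    def test_single_true_positive(self, simple_bundle):
        preds = [prediction_from(simple_bundle.annotations[0])]
        m = match_detections(simple_bundle, preds, "oks", 0.5)
        assert [r.is_tp for r in m.rows] == [True]
        assert m.n_ground_truth == 2

    def test_no_predictions_all_false_negatives(self, simple_bundle):
        m = match_detections(simple_bundle, [], "oks", 0.5)
        assert m.rows == ()
        assert m.n_ground_truth == 2

    def test_higher_scored_prediction_wins_single_gt(self):
        bundle = make_bundle([make_annotation(1, 1)])
        ann = bundle.annotations[0]
        preds = [prediction_from(ann, box_score=0.6), prediction_from(ann, box_score=0.9)]
        m = match_detections(bundle, preds, "oks", 0.5, ranking="box_score")
        assert [r.score for r in m.rows] == [0.9, 0.6]
        assert [r.is_tp for r in m.rows] == [True, False]

    def test_greedy_agrees_with_brute_force_on_small_instances(self):
        # enumerate all one-to-one assignments and replay the greedy rule by
        # hand on a 3-pred / 2-gt instance
        bundle = make_bundle([make_annotation(1, 1, cx=100), make_annotation(2, 1, cx=400)])
        anns = bundle.annotations
        preds = [
            prediction_from(anns[0], box_score=0.9, dx=2.0),
            prediction_from(anns[1], box_score=0.8, dx=1.0),
            prediction_from(anns[0], box_score=0.7, dx=30.0),
        ]
        threshold = 0.5
        m = match_detections(bundle, preds, "oks", threshold, ranking="box_score")

        sim = [
            [oks(a, p.keypoints, PAPER_SIGMA) for a in anns] for p in preds
        ]
        order = sorted(range(3), key=lambda i: -preds[i].box_score)
        taken, expected = set(), {}
        for i in order:
            cands = [
                (sim[i][g], g) for g in range(2)
                if g not in taken and sim[i][g] >= threshold
            ]
            if cands:
                g = max(cands)[1]
                taken.add(g)
                expected[i] = anns[g].annotation_id
            else:
                expected[i] = None
        got = {order[j]: m.rows[j].matched_annotation_id for j in range(3)}
        assert got == expected
        # one-to-one: no gt matched twice in any valid assignment
        matched = [r.matched_annotation_id for r in m.rows if r.is_tp]
        assert len(matched) == len(set(matched))
        # and the greedy TP count equals the max attainable with >= threshold
        best = 0
        for perm in itertools.permutations(range(2)):
            for preds_subset in itertools.combinations(range(3), 2):
                count = sum(
                    sim[p][g] >= threshold for p, g in zip(preds_subset, perm)
                )
                best = max(best, count)
        assert sum(r.is_tp for r in m.rows) == best

    def test_unknown_names_rejected(self, simple_bundle):
        with pytest.raises(ConfigurationError):
            match_detections(simple_bundle, [], "dice", 0.5)
        with pytest.raises(ConfigurationError):
            match_detections(simple_bundle, [], "oks", 0.5, ranking="altitude")

    def test_matching_never_crosses_images(self):
        import dataclasses

        bundle = make_bundle([make_annotation(1, 1), make_annotation(2, 2)])
        # prediction geometrically identical to gt 1 but placed on image 2
        stray = dataclasses.replace(prediction_from(bundle.annotations[0]), image_id=2)
        m = match_detections(bundle, [stray], "oks", 0.5)
        # on image 2 the only gt sits elsewhere; cross-image match is forbidden
        assert m.rows[0].matched_annotation_id in (None, 2)
        assert m.rows[0].matched_annotation_id != 1


class TestPRCurve:
    def test_all_true_positives_precision_one(self, simple_bundle):
        preds = [prediction_from(a, box_score=0.9 - 0.1 * i)
                 for i, a in enumerate(simple_bundle.annotations)]
        m = match_detections(simple_bundle, preds, "oks", 0.5, ranking="box_score")
        curve = pr_curve(m)
        assert all(p == pytest.approx(1.0) for _, p, _ in curve.points)

    def test_hand_computed_points(self):
        bundle = make_bundle([make_annotation(1, 1, cx=100)])
        ann = bundle.annotations[0]
        fp = prediction_from(ann, box_score=0.9, dx=500.0)  # far off: FP
        tp = prediction_from(ann, box_score=0.8)
        m = match_detections(bundle, [fp, tp], "oks", 0.5, ranking="box_score")
        curve = pr_curve(m)
        assert curve.points == ((0.9, 0.0, 0.0), (0.8, 0.5, 1.0))

    def test_tied_scores_collapse_to_one_point(self, simple_bundle):
        preds = [prediction_from(a, box_score=0.9) for a in simple_bundle.annotations]
        m = match_detections(simple_bundle, preds, "oks", 0.5, ranking="box_score")
        curve = pr_curve(m)
        assert len(curve.points) == 1
        assert curve.points[0] == (0.9, 1.0, 1.0)

    def test_zero_ground_truth_recall_undefined(self):
        with pytest.raises(UndefinedRecallError):
            pr_curve(MatchSet(rows=(), n_ground_truth=0))

    def test_recall_monotone_in_score_threshold(self, simple_bundle):
        preds = [prediction_from(a, box_score=0.9 - 0.2 * i, dx=3.0 * i)
                 for i, a in enumerate(simple_bundle.annotations)]
        curve = pr_curve(match_detections(simple_bundle, preds, "oks", 0.5,
                                          ranking="box_score"))
        recalls = [r for _, _, r in curve.points]  # descending score threshold
        assert recalls == sorted(recalls)


class TestAveragePrecision:
    def test_perfect_single_point(self):
        from perikit.detection_evaluation import PRCurve

        assert average_precision(PRCurve(((0.9, 1.0, 1.0),), 0.5)) == pytest.approx(1.0)

    def test_fp_then_tp_gives_half(self):
        from perikit.detection_evaluation import PRCurve

        curve = PRCurve(((0.9, 0.0, 0.0), (0.8, 0.5, 1.0)), 0.5)
        assert average_precision(curve) == pytest.approx(0.5)

    def test_empty_detections_zero(self):
        from perikit.detection_evaluation import PRCurve

        assert average_precision(PRCurve((), 0.5)) == 0.0


class TestEvaluate:
    def test_perfect_detector_both_tasks(self, simple_bundle):
        preds = [prediction_from(a, box_score=1.0, keypoint_scores=(1.0,) * 6)
                 for a in simple_bundle.annotations]
        for task in ("bbox", "keypoints"):
            summary = evaluate(simple_bundle, preds, task=task)["all"]
            assert summary.ap_all == pytest.approx(1.0)
            assert summary.ar_all == pytest.approx(1.0)

    def test_small_perturbation_keeps_ap50_perfect(self):
        # displacement small enough that every OKS clears even the 0.95 bar
        config = SyntheticConfig(n_images=6, displacement_multiplier=0.05,
                                 fp_rate=0.0, fn_rate=0.0, seed=2)
        bundle = generate(config)
        summary = evaluate(bundle.truth, list(bundle.predictions), task="keypoints")["all"]
        assert summary.ap_50 == pytest.approx(1.0)
        assert summary.ap_all == pytest.approx(1.0)

    def test_ap_ar_non_increasing_in_threshold(self):
        config = SyntheticConfig(n_images=8, displacement_multiplier=2.5,
                                 fp_rate=0.2, fn_rate=0.1, seed=7)
        bundle = generate(config)
        summary = evaluate(bundle.truth, list(bundle.predictions))["all"]
        aps = summary.table["ap"].to_numpy()
        ars = summary.table["ar"].to_numpy()
        assert (np.diff(aps) <= 1e-12).all()
        assert (np.diff(ars) <= 1e-12).all()

    def test_removing_a_false_positive_never_decreases_ap(self):
        config = SyntheticConfig(n_images=6, displacement_multiplier=2.0,
                                 fp_rate=0.4, fn_rate=0.0, seed=9)
        bundle = generate(config)
        preds = list(bundle.predictions)
        m = match_detections(bundle.truth, preds, "oks", 0.5)
        fp_rows = [r for r in m.rows if not r.is_tp]
        assert fp_rows, "fixture must contain at least one false positive"
        pruned = [p for p in preds if p is not fp_rows[0].prediction]
        before = evaluate(bundle.truth, preds)["all"].ap_all
        after = evaluate(bundle.truth, pruned)["all"].ap_all
        assert after >= before - 1e-12

    def test_jaw_strata_are_consistent_with_pooled_counts(self):
        config = SyntheticConfig(n_images=10, seed=4)
        bundle = generate(config)
        out = evaluate(bundle.truth, list(bundle.predictions))
        n_strat = sum(s.n_ground_truth for j, s in out.items() if j != "all")
        assert n_strat == out["all"].n_ground_truth


def _to_reference_dialect(bundle, preds):
    images = []
    for image in bundle.images:
        gts = [
            {
                "keypoints": [v for k in a.keypoints for v in (k.x, k.y, k.v)],
                "area": a.area,
                "bbox": list(a.bbox),
            }
            for a in bundle.annotations_for(image.image_id)
        ]
        dets = [
            {
                "keypoints": [v for k in p.keypoints for v in (k.x, k.y, 2)],
                "bbox": list(p.bbox),
                "score": p.box_score,
            }
            for p in preds
            if p.image_id == image.image_id
        ]
        images.append({"gts": gts, "dets": dets})
    return images


class TestReferenceOracleEquivalence:
    """The package's evaluator against an independent plain-loop
    implementation of the COCO-style protocol, on randomized small fixtures."""

    @pytest.mark.parametrize("seed", range(20))
    def test_keypoint_task_matches_reference(self, seed):
        config = SyntheticConfig(
            n_images=3,
            implants_per_image=(1, 3),
            displacement_multiplier=2.0,
            fp_rate=0.3,
            fn_rate=0.2,
            seed=100 + seed,
        )
        bundle = generate(config)
        preds = list(bundle.predictions)
        ref_images = _to_reference_dialect(bundle.truth, preds)
        summary = evaluate(bundle.truth, preds, task="keypoints",
                           ranking="box_score")["all"]
        for _, row in summary.table.iterrows():
            ap_ref, ar_ref = ref_evaluate(ref_images, row["threshold"], "keypoints",
                                          PAPER_SIGMA.sigma)
            assert row["ap"] == pytest.approx(ap_ref, abs=1e-6)
            assert row["ar"] == pytest.approx(ar_ref, abs=1e-6)

    @pytest.mark.parametrize("seed", [0, 1, 2, 3, 4])
    def test_bbox_task_matches_reference(self, seed):
        config = SyntheticConfig(n_images=3, fp_rate=0.3, fn_rate=0.2,
                                 box_jitter=0.05, seed=200 + seed)
        bundle = generate(config)
        preds = list(bundle.predictions)
        ref_images = _to_reference_dialect(bundle.truth, preds)
        summary = evaluate(bundle.truth, preds, task="bbox", ranking="box_score")["all"]
        for _, row in summary.table.iterrows():
            ap_ref, ar_ref = ref_evaluate(ref_images, row["threshold"], "bbox",
                                          PAPER_SIGMA.sigma)
            assert row["ap"] == pytest.approx(ap_ref, abs=1e-6)
            assert row["ar"] == pytest.approx(ar_ref, abs=1e-6)

    @pytest.mark.parametrize("seed", [0, 1, 2])
    def test_reference_ap_agrees_with_direct_definition(self, seed):
        # third route: the reference envelope AP versus a brute-force
        # max-precision scan, on tiny pooled lists
        rng = np.random.default_rng(seed)
        pooled = [(float(rng.random()), bool(rng.random() < 0.6)) for _ in range(6)]
        n_gt = 4
        tp = fp = 0
        recalls, precisions = [], []
        for score, is_tp in sorted(pooled, key=lambda t: -t[0]):
            tp, fp = tp + is_tp, fp + (not is_tp)
            recalls.append(tp / n_gt)
            precisions.append(tp / (tp + fp))
        for i in range(len(precisions) - 2, -1, -1):
            precisions[i] = max(precisions[i], precisions[i + 1])
        ap_env = sum(
            next((q for r, q in zip(recalls, precisions) if r >= i / 100.0), 0.0)
            for i in range(101)
        ) / 101.0
        assert ap_env == pytest.approx(ref_ap_by_definition(pooled, n_gt), abs=1e-12)
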