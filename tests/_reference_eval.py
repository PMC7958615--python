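"""Independent reference implementation of the COCO-style detection protocol.

Used as the oracle in tests; deliberately written as plain nested loops with
no shared code, data structures or vectorization tricks from the package
under test.  It follows the published COCO evaluation conventions directly:

* per image, detections sorted by score match the unmatched ground truth of
  highest similarity at or above the threshold;
* all detections pooled across images, sorted by score, yield cumulative
  TP/FP counts; precision is made monotone non-increasing from the right
  ("envelope") and sampled at the 101 recall levels 0.00, 0.01, ..., 1.00;
* AR at a threshold is the final recall with every detection kept.

OKS here is recomputed from scratch (independent exp/square arithmetic).
"""

import math


def ref_oks(gt_keypoints, gt_area, det_keypoints, sigmas, k_const=2.0):
    """gt_keypoints: flat [x1,y1,v1,...]; det_keypoints: flat [x,y,score...]."""
    num = 0.0
    den = 0
    for i in range(6):
        v = gt_keypoints[3 * i + 2]
        if v <= 0:
            continue
        dx = gt_keypoints[3 * i] - det_keypoints[3 * i]
        dy = gt_keypoints[3 * i + 1] - det_keypoints[3 * i + 1]
        k = k_const * sigmas[i]
        num += math.exp(-(dx * dx + dy * dy) / (2.0 * gt_area * k * k))
        den += 1
    if den == 0:
        raise ValueError("no labeled keypoints")
    return num / den


def ref_iou(boxA, boxB):
    ax, ay, aw, ah = boxA
    bx, by, bw, bh = boxB
    ix = max(0.0, min(ax + aw, bx + bw) - max(ax, bx))
    iy = max(0.0, min(ay + ah, by + bh) - max(ay, by))
    inter = ix * iy
    return inter / (aw * ah + bw * bh - inter) if inter > 0 else 0.0


def _match_one_image(gts, dets, sim_matrix, threshold):
    """gts/dets: lists; sim_matrix[d][g]; returns per-det matched gt index or -1.

    Detections are visited in descending score (stable on input order)."""
    order = sorted(range(len(dets)), key=lambda d: (-dets[d]["score"], d))
    gt_taken = [False] * len(gts)
    match = {}
    for d in order:
        best, best_sim = -1, -1.0
        for g in range(len(gts)):
            if gt_taken[g]:
                continue
            s = sim_matrix[d][g]
            if s >= threshold and s > best_sim:
                best, best_sim = g, s
        if best >= 0:
            gt_taken[best] = True
        match[d] = best
    return match


def ref_evaluate(images, threshold, task, sigmas, k_const=2.0):
    """images: list of dicts with keys 'gts' (list of {'keypoints', 'area',
    'bbox'}) and 'dets' (list of {'keypoints', 'bbox', 'score'}).  Returns
    (ap, ar) at one similarity threshold."""
    pooled = []  # (score, is_tp)
    n_gt = 0
    for img in images:
        gts = img["gts"]
        if task == "keypoints":
            gts = [g for g in gts if any(g["keypoints"][3 * i + 2] > 0 for i in range(6))]
        dets = img["dets"]
        n_gt += len(gts)
        sim = []
        for det in dets:
            row = []
            for gt in gts:
                if task == "keypoints":
                    row.append(ref_oks(gt["keypoints"], gt["area"], det["keypoints"],
                                       sigmas, k_const))
                else:
                    row.append(ref_iou(gt["bbox"], det["bbox"]))
            sim.append(row)
        match = _match_one_image(gts, dets, sim, threshold)
        for d, det in enumerate(dets):
            pooled.append((det["score"], match[d] >= 0))
    if n_gt == 0:
        raise ValueError("no ground truth")
    pooled.sort(key=lambda t: -t[0])

    recalls, precisions = [], []
    tp = fp = 0
    for score, is_tp in pooled:
        if is_tp:
            tp += 1
        else:
            fp += 1
        precisions.append(tp / (tp + fp))
        recalls.append(tp / n_gt)
    ar = recalls[-1] if recalls else 0.0

    # envelope: precision monotone non-increasing from the right
    for i in range(len(precisions) - 2, -1, -1):
        if precisions[i] < precisions[i + 1]:
            precisions[i] = precisions[i + 1]
    # sample at the 101 recall levels: first point with recall >= level
    total = 0.0
    for level_idx in range(101):
        level = level_idx / 100.0
        p = 0.0
        for r, q in zip(recalls, precisions):
            if r >= level:
                p = q
                break
        total += p
    return total / 101.0, ar


def ref_ap_by_definition(pooled, n_gt):
    """Third route for AP on tiny instances: direct max-precision scan at each
    recall level over all prefixes of the score-ranked detection list."""
    pooled = sorted(pooled, key=lambda t: -t[0])
    prefix_stats = []
    tp = fp = 0
    for score, is_tp in pooled:
        tp, fp = tp + is_tp, fp + (not is_tp)
        prefix_stats.append((tp / n_gt, tp / (tp + fp)))
    total = 0.0
    for level_idx in range(101):
        level = level_idx / 100.0
        best = 0.0
        for rec, prec in prefix_stats:
            if rec >= level and prec > best:
                best = prec
        total += best
    return total / 101.0
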