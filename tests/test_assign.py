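"""IoU, SimOTA and task-aligned (lead/aux) assignment behaviour."""

import itertools

import numpy as np
import pytest

from gmacorn.assign import (assign_aux, assign_lead, iou, iou_matrix,
                            simota_assign)


# ---------------------------------------------------------------------------
# IoU
# ---------------------------------------------------------------------------

def test_iou_basic_geometry():
    assert iou((0, 0, 2, 2), (0, 0, 2, 2)) == 1.0
    assert iou((0, 0, 1, 1), (5, 5, 6, 6)) == 0.0
    # unit squares offset by half a side: inter 0.5, union 1.5
    assert iou((0, 0, 1, 1), (0.5, 0, 1.5, 1)) == pytest.approx(1 / 3)
    assert iou((0, 0, 1, 1, ), (0.25, 0, 1.25, 1), fmt="xyxy") == \
        pytest.approx(0.75 / 1.25)


def test_iou_center_format():
    assert iou((1, 1, 2, 2), (1, 1, 2, 2), fmt="cxcywh") == 1.0


def test_iou_zero_area_rejected():
    with pytest.raises(ValueError):
        iou((0, 0, 0, 1), (0, 0, 1, 1))


# ---------------------------------------------------------------------------
# SimOTA
# ---------------------------------------------------------------------------

def test_simota_single_forced_match():
    res = simota_assign(np.array([[0.3]]), np.array([[0.8]]))
    assert res.gt_index.tolist() == [0]
    assert res.n_positive == 1


def test_simota_shared_candidate_goes_to_cheaper_gt():
    costs = np.array([[0.2, 5.0, 5.0], [0.4, 6.0, 6.0]])
    ious = np.array([[0.6, 0.0, 0.0], [0.6, 0.0, 0.0]])
    res = simota_assign(costs, ious)
    assert res.gt_index[0] == 0          # cheaper claim wins
    assert (res.gt_index == 1).sum() <= 1


def test_simota_matches_bruteforce_minimum_cost():
    """Frozen 3x8 instance: greedy dynamic-k selection equals exhaustive
    minimum-cost assignment under the same per-GT k."""
    costs = np.array([
        [2.11, 2.47, 1.10, 0.23, 1.76, 0.52, 2.18, 1.10],
        [1.43, 2.93, 2.37, 2.55, 1.71, 2.83, 0.15, 2.68],
        [1.23, 0.77, 1.65, 2.84, 1.06, 2.74, 1.46, 2.91]])
    ious = np.array([
        [0.53, 0.55, 0.25, 0.41, 0.17, 0.56, 0.18, 0.47],
        [0.05, 0.17, 0.25, 0.12, 0.18, 0.14, 0.03, 0.24],
        [0.33, 0.29, 0.63, 0.06, 0.44, 0.24, 0.02, 0.54]])

    # independent oracle: enumerate all feasible candidate subsets
    ks = [int(np.clip(round(float(np.sort(ious[g])[::-1].sum())), 1, 8))
          for g in range(3)]
    best, best_cost = None, np.inf
    for sets in itertools.product(
            *[itertools.combinations(range(8), k) for k in ks]):
        flat = [c for s in sets for c in s]
        if len(set(flat)) != len(flat):
            continue
        tot = sum(costs[g, c] for g, s in enumerate(sets) for c in s)
        if tot < best_cost:
            best_cost, best = tot, sets
    assert best == ((2, 3, 5), (6,), (0, 1, 4))   # frozen oracle output

    res = simota_assign(costs, ious)
    got = tuple(tuple(int(c) for c in np.where(res.gt_index == g)[0])
                for g in range(3))
    assert got == best


def test_simota_uniqueness_and_bounds(rng):
    for _ in range(50):
        g, c = rng.integers(1, 5), rng.integers(1, 12)
        costs = rng.uniform(0, 3, size=(g, c))
        ious = rng.uniform(0, 1, size=(g, c))
        res = simota_assign(costs, ious)
        assert res.n_positive <= c
        # no candidate assigned to two GTs by construction of gt_index
        assert res.gt_index.shape == (c,)
        assert np.all((res.gt_index >= -1) & (res.gt_index < g))


def test_simota_rejects_negative_costs():
    with pytest.raises(ValueError):
        simota_assign(np.array([[-1.0]]), np.array([[0.5]]))


# ---------------------------------------------------------------------------
# Task-aligned lead / aux assignment
# ---------------------------------------------------------------------------

from conftest import toy_grid as _toy_grid, toy_scene as _toy_scene


def test_lead_positives_are_local_to_the_gt(rng):
    scores, boxes, pts, gts, cls = _toy_scene(rng)
    res = assign_lead(scores, boxes, pts, gts, cls)
    assert res.n_positive > 0
    x1, y1, x2, y2 = gts[0]
    pos = pts[res.positive]
    assert np.all((pos[:, 0] >= x1) & (pos[:, 0] <= x2)
                  & (pos[:, 1] >= y1) & (pos[:, 1] <= y2))


def test_no_gt_yields_all_background(rng):
    scores, boxes, pts, _, _ = _toy_scene(rng)
    for fn in (assign_lead, assign_aux):
        res = fn(scores, boxes, pts, np.zeros((0, 4)), np.zeros(0, dtype=int))
        assert res.n_positive == 0
        assert np.all(res.gt_index == -1)
        assert res.target_scores.sum() == 0


def test_lead_matches_independent_ranking_oracle(rng):
    """Fixed toy input: the assignment equals a from-scratch implementation
    of the score^a * iou^b top-k ranking rule."""
    scores, boxes, pts, gts, cls = _toy_scene(rng, n_gt=2)
    res = assign_lead(scores, boxes, pts, gts, cls, topk=10)

    # independent oracle
    alpha, beta, topk = 0.5, 6.0, 10
    a = len(pts)
    metric = np.zeros((len(gts), a))
    for g, gt in enumerate(gts):
        for i in range(a):
            inside = (gt[0] <= pts[i, 0] <= gt[2]
                      and gt[1] <= pts[i, 1] <= gt[3])
            if not inside:
                continue
            iw = max(0, min(gt[2], boxes[i, 2]) - max(gt[0], boxes[i, 0]))
            ih = max(0, min(gt[3], boxes[i, 3]) - max(gt[1], boxes[i, 1]))
            inter = iw * ih
            ua = ((gt[2] - gt[0]) * (gt[3] - gt[1])
                  + (boxes[i, 2] - boxes[i, 0]) * (boxes[i, 3] - boxes[i, 1])
                  - inter)
            metric[g, i] = (scores[i, 0] ** alpha) * ((inter / ua) ** beta)
    cand = np.zeros_like(metric, dtype=bool)
    for g in range(len(gts)):
        top = np.argsort(-metric[g], kind="stable")[:topk]
        cand[g, top[metric[g, top] > 0]] = True
    expect_pos = cand.any(axis=0)
    expect_gt = np.where(expect_pos,
                         np.argmax(np.where(cand, metric, -1), axis=0), -1)
    assert np.array_equal(res.positive, expect_pos)
    assert np.array_equal(res.gt_index, expect_gt)


def test_aux_positives_superset_of_lead_on_random_scenes(rng):
    """Coarse (aux) assignment keeps every fine (lead) positive on 100
    random toy scenes."""
    for _ in range(100):
        n_gt = int(rng.integers(1, 4))
        scores, boxes, pts, gts, cls = _toy_scene(rng, n_gt=n_gt)
        lead = assign_lead(scores, boxes, pts, gts, cls)
        aux = assign_aux(scores, boxes, pts, gts, cls)
        assert np.all(aux.positive[lead.positive])
        assert aux.n_positive >= lead.n_positive


def test_border_gt_positives_stay_on_valid_anchors(rng):
    pts = _toy_grid(8, 8.0)
    scores = np.full((64, 1), 0.5)
    boxes = np.concatenate([pts - 8, pts + 8], axis=1)
    gts = np.array([[-10.0, -10.0, 6.0, 6.0]])   # mostly outside the image
    res = assign_aux(scores, boxes, pts, gts, np.array([0]))
    assert res.n_positive >= 1
    assert np.all(pts[res.positive] >= 0)
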