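"""Detection and field-trial metric computations."""

import numpy as np
import pytest
from hypothesis import given, strategies as st

from gmacorn.metrics import (ConfusionCounts, FieldTrialCounts,
                             average_precision, delivery_metrics, map50,
                             precision_recall, summarize_trials)


# ---------------------------------------------------------------------------
# Precision / recall / AP
# ---------------------------------------------------------------------------

def test_precision_recall_cases():
    assert precision_recall(ConfusionCounts(10, 0, 0)) == (1.0, 1.0)
    assert precision_recall(ConfusionCounts(0, 5, 5)) == (0.0, 0.0)
    assert precision_recall(ConfusionCounts(3, 1, 2)) == (0.75, 0.6)
    with pytest.warns(UserWarning):
        p, r = precision_recall(ConfusionCounts(0, 0, 3))
    assert p == 0.0


def _unit_box(i):
    return (10.0 * i, 0.0, 10.0 * i + 8, 8.0)


def test_ap_perfect_detector():
    gts = [(0, _unit_box(i)) for i in range(4)]
    dets = [(0.9 - 0.1 * i, 0, _unit_box(i)) for i in range(4)]
    assert average_precision(dets, gts) == pytest.approx(1.0)


def test_ap_hand_integrated_example():
    """Ranking [TP, FP, TP] over 2 GTs: PR points (1, 0.5), (2/3, 1)
    integrate to 5/6 with all-point interpolation."""
    gts = [(0, _unit_box(0)), (0, _unit_box(1))]
    dets = [(0.9, 0, _unit_box(0)),            # TP
            (0.8, 0, (100, 100, 108, 108)),    # FP
            (0.7, 0, _unit_box(1))]            # TP
    assert average_precision(dets, gts) == pytest.approx(5 / 6)


def test_ap_tie_break_is_deterministic():
    gts = [(0, _unit_box(i)) for i in range(3)]
    dets = [(0.5, 0, _unit_box(i)) for i in range(3)]
    vals = {average_precision(list(np.random.default_rng(s).permutation(
        np.array(dets, dtype=object))), gts) for s in range(5)}
    # equal-confidence ties are broken by detection index, so any input
    # ordering of the same (conf, box) multiset gives the same AP
    assert len({round(v, 12) for v in vals}) == 1


def test_ap_invariant_under_confidence_rescaling():
    gts = [(0, _unit_box(i)) for i in range(4)]
    dets = [(c, 0, _unit_box(i)) for i, c in enumerate((0.9, 0.5, 0.4, 0.2))]
    dets_scaled = [(c / 2, img, b) for c, img, b in dets]
    assert average_precision(dets, gts) == \
        average_precision(dets_scaled, gts)


def test_ap_requires_ground_truth():
    with pytest.raises(ValueError):
        average_precision([(0.9, 0, _unit_box(0))], [])


def test_ap_matches_bruteforce_threshold_oracle(rng):
    """All-point interpolated AP equals an independent enumerate-all-
    thresholds step integration on 100 random small instances."""
    for _ in range(100):
        n_gt = int(rng.integers(1, 5))
        n_det = int(rng.integers(1, 11))
        gts = [(0, _unit_box(i)) for i in range(n_gt)]
        dets = []
        for _ in range(n_det):
            conf = float(rng.uniform(0.05, 1.0))
            if rng.random() < 0.6:
                i = int(rng.integers(0, n_gt))
                x1, y1, x2, y2 = _unit_box(i)
                d = float(rng.uniform(0, 3))
                dets.append((conf, 0, (x1 + d, y1, x2 + d, y2)))
            else:
                dets.append((conf, 0, (500.0, 500.0, 507.0, 507.0)))
        got = average_precision(dets, gts)

        # oracle: greedy matching (same rule), then enumerate thresholds
        order = sorted(range(n_det), key=lambda i: (-dets[i][0], i))
        matched = [False] * n_gt
        flags = []
        for i in order:
            conf, _, (x1, y1, x2, y2) = dets[i]
            best, best_iou = -1, 0.5
            for j in range(n_gt):
                if matched[j]:
                    continue
                gx1, gy1, gx2, gy2 = _unit_box(j)
                iw = max(0, min(x2, gx2) - max(x1, gx1))
                ih = max(0, min(y2, gy2) - max(y1, gy1))
                inter = iw * ih
                u = (x2 - x1) * (y2 - y1) + 64 - inter
                v = inter / u
                if v >= best_iou:
                    best, best_iou = j, v
            if best >= 0:
                matched[best] = True
            flags.append(best >= 0)
        # step-integrate precision over recall with envelope interpolation
        rec, prec = [0.0], [1.0]
        tp = fp = 0
        for f in flags:
            tp, fp = tp + f, fp + (not f)
            rec.append(tp / n_gt)
            prec.append(tp / (tp + fp))
        expect = 0.0
        for k in range(1, len(rec)):
            if rec[k] > rec[k - 1]:
                expect += (rec[k] - rec[k - 1]) * max(prec[k:])
        assert got == pytest.approx(expect, abs=1e-9)


def test_map50():
    assert map50([0.7]) == 0.7
    assert map50([1.0, 0.0]) == 0.5
    vals = np.random.default_rng(1).uniform(size=5)
    assert map50(vals) == pytest.approx(vals.mean())
    with pytest.raises(ValueError):
        map50([])


# ---------------------------------------------------------------------------
# Field-trial metrics
# ---------------------------------------------------------------------------

TABLE5 = [(45, 42, 40), (50, 45, 43), (50, 46, 42), (50, 44, 41),
          (50, 46, 40), (50, 47, 44), (50, 45, 40), (50, 46, 43),
          (50, 45, 41)]


def test_delivery_metrics_worked_rows():
    assert delivery_metrics(FieldTrialCounts(45, 42, 40)) == \
        (88.9, 93.3, 95.2)
    assert delivery_metrics(FieldTrialCounts(445, 406, 374)) == \
        (84.0, 91.2, 92.1)
    assert delivery_metrics(FieldTrialCounts(30, 30, 30)) == \
        (100.0, 100.0, 100.0)


def test_delivery_metrics_validation():
    with pytest.raises(ValueError):
        FieldTrialCounts(10, 5, 7)       # success > identified
    with pytest.raises(ValueError):
        delivery_metrics(FieldTrialCounts(10, 0, 0))


@given(st.integers(1, 500), st.integers(0, 500), st.integers(0, 500))
def test_rate_identity_exact(nt, ni, ns):
    ni = min(ni, nt)
    ns = min(ns, ni)
    if ni == 0:
        return
    rate, acc, prec = delivery_metrics(FieldTrialCounts(nt, ni, ns),
                                       rounded=False)
    assert rate == pytest.approx(acc * prec / 100.0, abs=1e-12)


def test_summary_mean_within_group_range():
    s = summarize_trials([FieldTrialCounts(*t) for t in TABLE5])
    for ts in s.values():
        assert min(ts.per_group) <= ts.mean <= max(ts.per_group)
        assert ts.sd >= 0


def test_summary_of_identical_groups_has_zero_sd():
    s = summarize_trials([FieldTrialCounts(50, 45, 40)] * 4)
    assert all(ts.sd == 0.0 for ts in s.values())


def test_summary_needs_two_groups():
    with pytest.raises(ValueError):
        summarize_trials([FieldTrialCounts(50, 45, 40)])
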