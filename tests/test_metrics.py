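import itertools

import numpy as np
import pytest

import weaktrack as wt
from weaktrack.metrics import WEIGHTS
from weaktrack.tracker import TrackGraph


def _frame_with_blobs(positions, size=4, shape=(64, 64)):
    frame = np.zeros(shape, np.uint16)
    for label, (r, c) in enumerate(positions, start=1):
        frame[r : r + size, c : c + size] = label
    return frame


def _chain_graph(n_frames, label=1):
    g = TrackGraph()
    for t in range(n_frames):
        g.add_node(t, label, 16)
    for t in range(n_frames - 1):
        g.add_edge((t, label), (t + 1, label))
    return g


def brute_force_match(gt, pred):
    """Independent per-pixel evaluation of the majority-coverage rule."""
    gt_labels = sorted(set(gt.ravel()) - {0})
    pred_labels = sorted(set(pred.ravel()) - {0})
    matches = {}
    for g in gt_labels:
        g_pix = {tuple(p) for p in np.argwhere(gt == g)}
        for p in pred_labels:
            p_pix = {tuple(q) for q in np.argwhere(pred == p)}
            if len(g_pix & p_pix) > 0.5 * len(g_pix):
                matches[g] = p
    fn = [g for g in gt_labels if g not in matches]
    fp = [p for p in pred_labels if p not in set(matches.values())]
    splits = sum(
        c - 1 for c in np.unique(list(matches.values()), return_counts=True)[1]
    ) if matches else 0
    return matches, fn, fp, splits


class TestMatchMarkers:
    def test_identical_frames_are_clean(self):
        frame = _frame_with_blobs([(5, 5), (20, 20), (40, 40)])
        m = wt.match_markers(frame, frame)
        assert not m.fn and not m.fp and m.splits == 0 and m.tp == 3

    def test_forty_percent_coverage_is_fn(self):
        gt = np.zeros((16, 16), np.uint16)
        gt[0:10, 0:1] = 1  # area 10
        pred = np.zeros((16, 16), np.uint16)
        pred[0:4, 0:1] = 1  # covers 4 of 10
        m = wt.match_markers(gt, pred)
        assert m.fn == [1] and m.fp == [1]

    def test_split_detected_by_brute_force_comparison(self):
        gt = _frame_with_blobs([(4, 4), (4, 10), (20, 20)], size=5)
        pred = np.zeros_like(gt)
        pred[4:9, 4:15] = 1  # one prediction swallowing gt 1 and 2
        pred[20:25, 20:25] = 2
        m = wt.match_markers(gt, pred)
        _, fn, fp, splits = brute_force_match(gt, pred)
        assert m.splits == splits == 1
        assert m.fn == fn and m.fp == fp

    @pytest.mark.parametrize("seed", range(5))
    def test_agrees_with_brute_force_on_random_frames(self, seed):
        rng = np.random.default_rng(seed)
        gt = np.zeros((48, 48), np.uint16)
        pred = np.zeros((48, 48), np.uint16)
        for label in range(1, int(rng.integers(2, 7))):
            r, c = rng.integers(0, 40, 2)
            gt[r : r + 6, c : c + 6] = label
        for label in range(1, int(rng.integers(2, 7))):
            r, c = rng.integers(0, 40, 2)
            pred[r : r + int(rng.integers(4, 9)), c : c + int(rng.integers(4, 9))] = label
        m = wt.match_markers(gt, pred)
        bf_matches, bf_fn, bf_fp, bf_splits = brute_force_match(gt, pred)
        assert m.gt_to_pred == bf_matches
        assert m.fn == bf_fn and m.fp == bf_fp and m.splits == bf_splits


class TestDetScore:
    def test_hand_example_two_fn_one_fp(self):
        # 10 GT markers in one frame; prediction misses 2 and invents 1:
        # AOGM-D = 10*2 + 1*1 = 21, AOGM-D0 = 100, DET = 0.79
        positions = [(r, c) for r in (5, 15, 25, 35, 45) for c in (5, 30)]
        gt = _frame_with_blobs(positions)[None]
        pred = gt.copy()
        pred[0][pred[0] == 9] = 0
        pred[0][pred[0] == 10] = 0
        pred[0][58:62, 58:62] = 11
        assert wt.det_score(gt, pred) == pytest.approx(0.79)

    def test_perfect_prediction(self, small_movie):
        assert wt.det_score(small_movie.masks, small_movie.masks) == 1.0

    def test_empty_prediction_clamps_to_zero(self, small_movie):
        empty = np.zeros_like(small_movie.masks)
        assert wt.det_score(small_movie.masks, empty) == 0.0

    def test_empty_ground_truth_signalled(self):
        empty = np.zeros((2, 8, 8), np.uint16)
        with pytest.raises(ValueError):
            wt.det_score(empty, empty)

    def test_one_lost_matched_prediction_costs_exactly_ten(self):
        positions = [(5, 5), (5, 30), (30, 5), (30, 30)]
        gt = _frame_with_blobs(positions)[None]
        pred = gt.copy()
        base_cost = (1 - wt.det_score(gt, pred)) * 10 * 4
        pred[0][pred[0] == 3] = 0
        cost = (1 - wt.det_score(gt, pred)) * 10 * 4
        assert cost - base_cost == pytest.approx(10.0)

    def test_scale_invariance_under_upsampling(self, small_movie):
        labels = wt.subsample_labels(small_movie.masks, 0.7, seed=3)
        det1 = wt.det_score(small_movie.masks, labels)
        up = lambda m: np.kron(m, np.ones((1, 2, 2), m.dtype))
        det2 = wt.det_score(up(small_movie.masks), up(labels))
        assert det1 == pytest.approx(det2)


class TestTraScore:
    def test_perfect_graph(self, small_movie):
        g = wt.build_tracks(small_movie.masks, wt.RunConfig())
        tra = wt.tra_score(small_movie.masks, small_movie.tracks, small_movie.masks, g)
        assert tra == 1.0

    def test_one_missing_edge_hand_value(self):
        # chain of 10 nodes / 9 edges; prediction misses one edge:
        # AOGM = 1.5, AOGM0 = 10*10 + 1.5*9 = 113.5
        masks = np.zeros((10, 16, 16), np.uint16)
        for t in range(10):
            masks[t, 4:8, 4:8] = 1
        gt_graph = _chain_graph(10)
        pred_graph = TrackGraph()
        for t in range(10):
            pred_graph.add_node(t, 1, 16)
        for t in range(9):
            if t != 4:  # edge 4 -> 5 missing
                pred_graph.add_edge((t, 1), (t + 1, 1))
        tra = wt.tra_score(masks, gt_graph, masks, pred_graph)
        assert tra == pytest.approx(1 - 1.5 / 113.5)

    def test_wrong_semantics_costs_one(self):
        # prediction links parent->child as a plain track edge instead of a
        # division: the two graphs disagree on edge kind
        masks = np.zeros((2, 32, 32), np.uint16)
        masks[0, 4:10, 4:10] = 1
        masks[1, 2:7, 2:7] = 2
        masks[1, 8:13, 8:13] = 3
        gt = TrackGraph()
        for t, lab in [(0, 1), (1, 2), (1, 3)]:
            gt.add_node(t, lab, 25)
        gt.add_edge((0, 1), (1, 2))
        gt.add_edge((0, 1), (1, 3))  # division: kind 'parent'
        pred = TrackGraph()
        for t, lab in [(0, 1), (1, 2), (1, 3)]:
            pred.add_node(t, lab, 25)
        pred.add_edge((0, 1), (1, 2))  # single child: kind 'track'
        # expected: edge (0,1)->(1,3) missing (EA 1.5), edge (0,1)->(1,2)
        # has wrong semantics (EC 1.0); AOGM0 = 30 + 3.0
        tra = wt.tra_score(masks, gt, masks, pred)
        assert tra == pytest.approx(1 - 2.5 / 33.0)

    def test_tra_not_above_det_on_imperfect_tracking(self, small_movie):
        labels = wt.subsample_labels(small_movie.masks, 0.6, seed=5)
        pred_graph = wt.build_tracks(labels, wt.RunConfig())
        det = wt.det_score(small_movie.masks, labels)
        tra = wt.tra_score(small_movie.masks, small_movie.tracks, labels, pred_graph)
        assert tra <= det


class TestDetectionStats:
    def test_arithmetic_example(self):
        # TP=8, FP=1, FN=2 over 2 frames
        positions = [(r, c) for r in (5, 15, 25, 35, 45) for c in (5, 30)]
        gt = np.stack([_frame_with_blobs(positions[:5]), _frame_with_blobs(positions[5:])])
        pred = gt.copy()
        pred[0][pred[0] == 1] = 0
        pred[1][pred[1] == 2] = 0
        pred[0][58:62, 58:62] = 9
        precision, recall, f, nfn, nfp = wt.detection_stats(gt, pred)
        assert precision == pytest.approx(8 / 9)
        assert recall == pytest.approx(0.8)
        assert f == pytest.approx(2 * (8 / 9) * 0.8 / (8 / 9 + 0.8))
        assert nfn == 1.0 and nfp == 0.5

    def test_perfect(self, small_movie):
        p, r, f, nfn, nfp = wt.detection_stats(small_movie.masks, small_movie.masks)
        assert p == r == f == 1.0 and nfn == nfp == 0.0

    def test_empty_prediction_defined_as_zero(self, small_movie):
        empty = np.zeros_like(small_movie.masks)
        with pytest.warns(UserWarning):
            p, r, f, nfn, nfp = wt.detection_stats(small_movie.masks, empty)
        assert p == r == f == 0.0 and nfp == 0.0 and nfn > 0

    def test_f_measure_is_harmonic_mean(self, small_movie):
        labels = wt.subsample_labels(small_movie.masks, 0.5, seed=1)
        p, r, f, _, _ = wt.detection_stats(small_movie.masks, labels)
        assert f == pytest.approx(2 * p * r / (p + r))


class TestWeights:
    def test_error_weights(self):
        assert WEIGHTS["fn_node"] == 10.0
        assert WEIGHTS["fp_node"] == 1.0
        assert WEIGHTS["edge_delete"] == 1.0
        assert WEIGHTS["edge_add"] == 1.5
        assert WEIGHTS["edge_semantics"] == 1.0
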