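import numpy as np
import pytest

import weaktrack as wt
from weaktrack.detector import DetectorConfig


class TestWeightedSumPrediction:
    def test_single_factor_equals_plain_prediction(self, small_movie, constant_mask_model_cls):
        model = constant_mask_model_cls(
            small_movie.brightfield, small_movie.masks, factors=(1.0,)
        )
        params = wt.ContrastParams((1.0,))
        labels, fused = wt.weighted_sum_prediction(
            model, small_movie.brightfield[0], params, 0.5
        )
        direct = wt.predict_prob(model, small_movie.brightfield[0])
        assert np.allclose(fused, direct, atol=1e-6)
        assert set(np.unique(labels)) - {0} != set()

    def test_fused_map_is_convex_combination(self, small_movie, constant_mask_model_cls):
        model = constant_mask_model_cls(small_movie.brightfield, small_movie.masks)
        params = wt.ContrastParams()
        _, fused = wt.weighted_sum_prediction(
            model, small_movie.brightfield[0], params, 0.5
        )
        probs = [
            wt.predict_prob(model, wt.apply_contrast(small_movie.brightfield[0], f))
            for f in params.factors
        ]
        stack = np.stack(probs)
        assert (fused <= stack.max(0) + 1e-6).all()
        assert (fused >= stack.min(0) - 1e-6).all()
        assert np.allclose(fused, stack.mean(0), atol=1e-6)  # weights 1/8 each

    def test_empty_factor_list_rejected(self, small_movie, constant_mask_model_cls):
        model = constant_mask_model_cls(small_movie.brightfield, small_movie.masks)
        params = wt.ContrastParams((1.0,))
        params.factors = ()  # bypass dataclass validation deliberately
        with pytest.raises(ValueError):
            wt.weighted_sum_prediction(model, small_movie.brightfield[0], params, 0.5)


class TestUnionLabels:
    def test_empty_prediction_is_identity_up_to_relabelling(self):
        pseudo = np.zeros((32, 32), np.uint16)
        pseudo[4:8, 4:8] = 7
        pseudo[20:24, 20:24] = 9
        out = wt.union_labels(pseudo, np.zeros_like(pseudo))
        assert set(np.unique(out)) == {0, 1, 2}
        assert np.array_equal(out > 0, pseudo > 0)

    def test_disjoint_sets_add_up(self):
        a = np.zeros((64, 64), np.uint16)
        b = np.zeros((64, 64), np.uint16)
        for i in range(5):
            a[10 * i : 10 * i + 4, 2:6] = i + 1
        for i in range(3):
            b[10 * i : 10 * i + 4, 40:44] = i + 1
        out = wt.union_labels(a, b)
        assert out.max() == 8

    def test_touching_markers_merge(self):
        a = np.zeros((16, 16), np.uint16)
        b = np.zeros((16, 16), np.uint16)
        a[4:8, 4:8] = 1
        b[6:10, 6:10] = 1
        out = wt.union_labels(a, b)
        assert out.max() == 1


class TestRunTraining:
    def _setup(self, n_iterations=2):
        cfg = wt.SimConfig(
            width=64,
            height=64,
            n_frames=4,
            n_cells=3,
            division_prob=0.0,
            impurity_count=0,
            impurity_lifetime=1,
            seed=17,
        )
        movie = wt.simulate_movie(cfg)
        run = wt.RunConfig(
            n_iterations=n_iterations,
            max_updates_per_iteration=3,
            batch_size=2,
            contrast_params=(0.9, 1.0, 1.1),
            seed=0,
        )
        dcfg = DetectorConfig(depth=2, base_channels=4, input_size=32)
        return movie, run, dcfg

    def test_history_has_initial_plus_one_per_iteration(self):
        movie, run, dcfg = self._setup(n_iterations=2)
        _, history, records = wt.run_training(
            movie.brightfield, movie.masks, run, detector_config=dcfg
        )
        assert len(history) == 3
        assert [r.iteration for r in records] == [0, 1, 2]

    def test_without_tracks_removes_nothing(self):
        movie, run, dcfg = self._setup(n_iterations=2)
        _, _, records = wt.run_training(
            movie.brightfield,
            movie.masks,
            run,
            detector_config=dcfg,
            with_tracks=False,
        )
        assert all(r.markers_removed == 0 for r in records)

    def test_union_keeps_existing_markers_without_tracking(self):
        movie, run, dcfg = self._setup(n_iterations=2)
        _, history, _ = wt.run_training(
            movie.brightfield,
            movie.masks,
            run,
            detector_config=dcfg,
            with_tracks=False,
        )
        for before, after in zip(history, history[1:]):
            assert ((before > 0) <= (after > 0)).all()

    def test_zero_iterations_rejected(self):
        movie, run, dcfg = self._setup()
        run.n_iterations = 0
        with pytest.raises(ValueError):
            wt.run_training(movie.brightfield, movie.masks, run, detector_config=dcfg)

    def test_snapshots_written(self, tmp_path):
        movie, run, dcfg = self._setup(n_iterations=1)
        wt.run_training(
            movie.brightfield,
            movie.masks,
            run,
            detector_config=dcfg,
            snapshot_dir=tmp_path,
        )
        assert (tmp_path / "pseudo_gt_iter01.npy").exists()
        assert (tmp_path / "model_iter01.ckpt").exists()


class TestRunInference:
    def test_perfect_detector_recovers_gt(self, small_movie, constant_mask_model_cls):
        model = constant_mask_model_cls(small_movie.brightfield, small_movie.masks)
        run = wt.RunConfig()
        masks, graph = wt.run_inference(model, small_movie.brightfield, run)
        assert wt.det_score(small_movie.masks, masks) == 1.0

    def test_deterministic(self, small_movie, constant_mask_model_cls):
        model = constant_mask_model_cls(small_movie.brightfield, small_movie.masks)
        run = wt.RunConfig()
        a, _ = wt.run_inference(model, small_movie.brightfield, run)
        b, _ = wt.run_inference(model, small_movie.brightfield, run)
        assert np.array_equal(a, b)

    def test_empty_movie_empty_outputs(self, small_movie, constant_mask_model_cls):
        model = constant_mask_model_cls(small_movie.brightfield, small_movie.masks)
        empty = np.zeros((0, 64, 64), np.uint8)
        masks, graph = wt.run_inference(model, empty, wt.RunConfig())
        assert masks.shape[0] == 0 and graph.nodes == []

    def test_tracking_assistance_prunes_impurities(self, constant_mask_model_cls):
        cfg = wt.SimConfig(
            width=128,
            height=128,
            n_frames=12,
            n_cells=6,
            division_prob=0.0,
            impurity_count=0,
            seed=23,
        )
        movie = wt.simulate_movie(cfg)
        noisy = movie.masks.copy()
        # inject a 2-frame impurity detection mid-movie, away from cells
        spot = None
        for r in range(30, 90, 10):
            for c in range(30, 90, 10):
                if not (movie.masks[5:7, r - 6 : r + 10, c - 6 : c + 10] > 0).any():
                    spot = (r, c)
                    break
            if spot:
                break
        r, c = spot
        noisy[5, r : r + 5, c : c + 5] = 200  # above the noise-size cutoff
        noisy[6, r : r + 5, c : c + 5] = 200
        model = constant_mask_model_cls(movie.brightfield, noisy)
        run = wt.RunConfig()
        with_masks, _ = wt.run_inference(model, movie.brightfield, run, with_tracking=True)
        wo_masks, _ = wt.run_inference(model, movie.brightfield, run, with_tracking=False)
        _, _, _, _, nfp_with = wt.detection_stats(movie.masks, with_masks)
        _, _, _, _, nfp_without = wt.detection_stats(movie.masks, wo_masks)
        assert nfp_with < nfp_without
        # tracking assistance never costs true positives here
        _, rec_with, _, _, _ = wt.detection_stats(movie.masks, with_masks)
        _, rec_without, _, _, _ = wt.detection_stats(movie.masks, wo_masks)
        assert rec_with >= rec_without
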