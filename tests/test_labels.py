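import numpy as np
import pytest
from scipy import ndimage, stats

import weaktrack as wt
from weaktrack.labels import binarize_frame


def _entropy(img, bins=64):
    hist, _ = np.histogram(img, bins=bins, range=(0, 1), density=False)
    p = hist / hist.sum()
    p = p[p > 0]
    return -np.sum(p * np.log2(p))


class TestClahe:
    def test_constant_frame_stays_constant(self):
        frame = np.full((64, 64), 37, np.uint8)
        out = wt.clahe_equalize(frame, clip=0.02, tile=16)
        assert np.ptp(out) == 0

    def test_flattens_point_light_histogram(self):
        # radial illumination falloff concentrates the histogram; CLAHE spreads it
        yy, xx = np.mgrid[0:128, 0:128]
        d2 = (yy - 64.0) ** 2 + (xx - 64.0) ** 2
        frame = (200 * np.exp(-d2 / (2 * 30.0**2))).astype(np.uint8)
        out = wt.clahe_equalize(frame, clip=0.02, tile=32)
        assert _entropy(out) > _entropy(frame / 255.0)

    def test_deterministic(self):
        rng = np.random.default_rng(0)
        frame = rng.integers(0, 255, (64, 64), dtype=np.uint8)
        a = wt.clahe_equalize(frame, 0.02, 16)
        b = wt.clahe_equalize(frame, 0.02, 16)
        assert np.array_equal(a, b)

    def test_tile_larger_than_frame_rejected(self):
        with pytest.raises(ValueError):
            wt.clahe_equalize(np.zeros((32, 32), np.uint8), 0.02, 64)


class TestBilateral:
    def test_constant_frame_unchanged(self):
        frame = np.full((32, 32), 0.4)
        out = wt.bilateral_denoise(frame, 5, 0.1, 2.0)
        assert np.allclose(out, 0.4)

    def test_denoises_interior_but_keeps_edges(self):
        rng = np.random.default_rng(1)
        clean = np.zeros((64, 64))
        clean[16:48, 16:48] = 0.8
        noisy = clean + rng.normal(0, 0.03, clean.shape)
        out = wt.bilateral_denoise(noisy, 7, 0.2, 2.0)
        interior = (slice(24, 40), slice(24, 40))
        assert out[interior].std() < noisy[interior].std()
        # edge magnitude preserved within 10% of the clean step
        grad_out = np.abs(np.diff(out[32, :]).max())
        grad_clean = np.abs(np.diff(clean[32, :]).max())
        assert grad_out > 0.9 * grad_clean

    def test_large_sigma_color_approaches_gaussian(self):
        rng = np.random.default_rng(2)
        frame = rng.random((48, 48)) * 0.2 + 0.4
        # with flat range weights the filter degenerates to plain spatial
        # Gaussian smoothing; window discretisation keeps the match inexact
        bil = wt.bilateral_denoise(frame, 13, sigma_color=50.0, sigma_space=2.0)
        gauss = ndimage.gaussian_filter(frame, 2.0)
        interior = (slice(8, -8), slice(8, -8))
        diff_gauss = np.abs(bil[interior] - gauss[interior]).max()
        diff_raw = np.abs(bil[interior] - frame[interior]).max()
        assert diff_gauss < 0.05
        assert diff_gauss < 0.5 * diff_raw  # far closer to the blur than to the input

    def test_nonpositive_sigma_rejected(self):
        with pytest.raises(ValueError):
            wt.bilateral_denoise(np.zeros((8, 8)), 5, -1.0, 2.0)


class TestRemoveSmallObjects:
    def test_area_cutoff_is_strict(self):
        mask = np.zeros((32, 96), bool)
        mask[2:3, 2:5] = True  # area 3
        mask[10:15, 10:20] = True  # area 50
        mask[20:30, 40:52] = True  # area 120
        out = wt.remove_small_objects(mask, 20)
        labels = ndimage.label(out)[1]
        assert labels == 2
        assert not out[2, 2] and out[12, 12] and out[25, 45]

    def test_min_area_one_is_identity(self):
        rng = np.random.default_rng(3)
        mask = rng.random((32, 32)) > 0.7
        assert np.array_equal(wt.remove_small_objects(mask, 1), mask)

    def test_all_noise_frame_empties(self):
        mask = np.zeros((32, 32), bool)
        mask[::8, ::8] = True  # isolated pixels
        assert not wt.remove_small_objects(mask, 2).any()


class TestMakeInitialLabels:
    def test_blank_fluorescence_yields_no_markers(self):
        fluor = np.full((3, 64, 64), 5, np.uint8)
        labels = wt.make_initial_labels(fluor)
        assert labels.max() == 0

    def test_full_transfection_high_snr_recall(self, small_movie):
        labels = wt.make_initial_labels(small_movie.fluorescence)
        _, recall, _, _, _ = wt.detection_stats(small_movie.masks, labels)
        assert recall >= 0.95

    def test_precision_against_truth(self, small_movie):
        labels = wt.make_initial_labels(small_movie.fluorescence)
        precision, _, _, _, _ = wt.detection_stats(small_movie.masks, labels)
        assert precision >= 0.9

    def test_partial_transfection_recall_tracks_fraction(self):
        cfg = wt.SimConfig(
            width=128,
            height=128,
            n_frames=6,
            n_cells=12,
            division_prob=0.0,
            transfection_fraction=0.5,
            light_sigma=80.0,
            impurity_count=0,
            seed=21,
        )
        movie = wt.simulate_movie(cfg)
        labels = wt.make_initial_labels(movie.fluorescence)
        expected = sum(
            wt.count_fluorescent_markers(movie, t) for t in range(movie.n_frames)
        )
        found = sum(
            np.count_nonzero(np.unique(labels[t])) for t in range(movie.n_frames)
        )
        assert abs(found - expected) <= 0.1 * max(expected, 1)
        _, recall, _, _, _ = wt.detection_stats(movie.masks, labels)
        frac = expected / sum(
            np.count_nonzero(np.unique(movie.masks[t]))
            for t in range(movie.n_frames)
        )
        assert abs(recall - frac) <= 0.1


class TestSubsampleLabels:
    def test_keep_all_is_identity(self, small_movie):
        out = wt.subsample_labels(small_movie.masks, 1.0, seed=0)
        assert np.array_equal(out, small_movie.masks)

    def test_never_creates_markers(self, small_movie):
        out = wt.subsample_labels(small_movie.masks, 0.4, seed=1)
        for t in range(small_movie.n_frames):
            kept = set(np.unique(out[t])) - {0}
            orig = set(np.unique(small_movie.masks[t])) - {0}
            assert kept <= orig
            for label in kept:  # surviving markers keep their exact pixels
                assert np.array_equal(
                    out[t] == label, small_movie.masks[t] == label
                )

    def test_kept_count_within_binomial_interval(self):
        # 1000 markers across frames, keep 10%
        masks = np.zeros((10, 128, 128), np.uint16)
        for t in range(10):
            k = 1
            for i in range(10):
                for j in range(10):
                    masks[t, 3 + 12 * i : 7 + 12 * i, 3 + 12 * j : 7 + 12 * j] = k
                    k += 1
        out = wt.subsample_labels(masks, 0.1, seed=4)
        kept = sum(np.count_nonzero(np.unique(out[t])) for t in range(10))
        lo, hi = stats.binom.interval(0.99, 1000, 0.1)
        assert lo <= kept <= hi

    def test_out_of_range_fraction_rejected(self, small_movie):
        for bad in (0.0, -0.1, 1.5):
            with pytest.raises(ValueError):
                wt.subsample_labels(small_movie.masks, bad, seed=0)

    def test_deterministic_given_seed(self, small_movie):
        a = wt.subsample_labels(small_movie.masks, 0.5, seed=9)
        b = wt.subsample_labels(small_movie.masks, 0.5, seed=9)
        assert np.array_equal(a, b)
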