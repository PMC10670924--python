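import numpy as np
import pytest

import weaktrack as wt


@pytest.fixture(scope="session")
def small_movie():
    """Shared small synthetic movie: 10 frames, 10 founder cells, no division."""
    cfg = wt.SimConfig(
        width=128,
        height=128,
        n_frames=10,
        n_cells=10,
        division_prob=0.0,
        transfection_fraction=1.0,
        light_sigma=80.0,
        impurity_count=0,
        seed=7,
    )
    return wt.simulate_movie(cfg)


@pytest.fixture()
def run_config():
    return wt.RunConfig()


class ConstantMaskModel:
    """Stand-in detector that 'predicts' a fixed mask sequence perfectly.

    ``forward`` ignores training mode and maps each input frame to large
    +/- logits according to the stored masks, keyed by frame content.
    Lets the inference/tracking plumbing be tested without training.
    """

    depth = 1

    def __init__(
        self,
        movie: np.ndarray,
        masks: np.ndarray,
        factors=wt.DEFAULT_CONTRAST_FACTORS,
    ) -> None:
        self._lookup = {}
        for t in range(movie.shape[0]):
            for f in factors:  # recognise every contrast variant of the frame
                key = wt.apply_contrast(movie[t], f).tobytes()
                self._lookup[key] = masks[t] > 0

    def forward(self, x: np.ndarray, train: bool = False) -> np.ndarray:
        out = np.empty_like(x, dtype=np.float32)
        for n in range(x.shape[0]):
            frame = x[n, 0]
            arr = (frame * 255.0).round().astype(np.uint8)
            fg = self._lookup.get(arr.tobytes())
            if fg is None:
                fg = np.zeros(frame.shape, bool)
            h, w = fg.shape
            logits = np.full(frame.shape, -10.0, np.float32)
            logits[:h, :w][fg] = 10.0
            out[n, 0] = logits
        return out


@pytest.fixture()
def constant_mask_model_cls():
    return ConstantMaskModel


def impurity_fixture(seed=31):
    """GT detections plus injected 2-frame impurity markers."""
    cfg = wt.SimConfig(
        width=128,
        height=128,
        n_frames=16,
        n_cells=8,
        division_prob=0.0,
        step_sigma=1.0,
        impurity_count=0,
        seed=seed,
    )
    movie = wt.simulate_movie(cfg)
    masks = movie.masks.copy()
    rng = np.random.default_rng(seed + 1)
    impurity_nodes = []
    next_label = int(masks.max()) + 1
    placed_sites: list[tuple[int, int]] = []
    attempts = 0
    while len(placed_sites) < 6 and attempts < 500:
        attempts += 1
        t = int(rng.integers(2, 12))
        r, c = (int(v) for v in rng.integers(24, 96, 2))
        # distinct physical impurities: keep sites well separated so the
        # gap-closing search cannot chain one onto another
        if any(abs(r - rr) + abs(c - cc) < 24 for rr, cc in placed_sites):
            continue
        region = (slice(t, t + 2), slice(r - 8, r + 12), slice(c - 8, c + 12))
        if (masks[region] > 0).any():
            continue
        for dt in range(2):  # lifetime 2 < alpha 3
            masks[t + dt, r : r + 4, c : c + 4] = next_label
            impurity_nodes.append((t + dt, next_label))
        next_label += 1
        placed_sites.append((r, c))
    assert len(placed_sites) >= 4, "fixture could not place impurities"
    return movie, masks, impurity_nodes
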