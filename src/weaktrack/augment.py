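"""Contrast augmentation of brightfield frames.

Each frame is multiplied pixelwise by every factor of a fixed ladder
(default 0.8, 0.9, …, 1.5 — eight factors, so the dataset grows 8×) and
clipped to the valid intensity range.  Labels are never transformed:
changing contrast is label-preserving.  The same ladder is reused at
prediction time for the weighted-sum fusion.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .config import DEFAULT_CONTRAST_FACTORS


@dataclass
class ContrastParams:
    factors: tuple = DEFAULT_CONTRAST_FACTORS

    def __post_init__(self) -> None:
        self.factors = tuple(float(f) for f in self.factors)
        if not self.factors:
            raise ValueError("factor list must be nonempty")
        if any(f <= 0 for f in self.factors):
            raise ValueError("contrast factors must be positive")
        if len(set(self.factors)) != len(self.factors):
            raise ValueError("contrast factors must be distinct")


def apply_contrast(frame: np.ndarray, factor: float) -> np.ndarray:
    """Multiply by ``factor`` and clip to the frame's valid intensity range.

    Integer frames are computed in float and rounded half-to-even on the
    way back; float frames are assumed to live in [0, 1].
    """
    if factor <= 0:
        raise ValueError("contrast factor must be positive")
    frame = np.asarray(frame)
    if np.issubdtype(frame.dtype, np.integer):
        ceiling = np.iinfo(frame.dtype).max
        scaled = np.rint(frame.astype(np.float64) * factor)
        return np.clip(scaled, 0, ceiling).astype(frame.dtype)
    return np.clip(frame * factor, 0.0, 1.0).astype(frame.dtype)


def contrast_variants(frame: np.ndarray, params: ContrastParams) -> list[np.ndarray]:
    """One contrast-scaled copy per factor, in factor order."""
    return [apply_contrast(frame, f) for f in params.factors]


class AugmentedDataset:
    """Lazy (frame × factor) training dataset.

    Item ``i`` maps to frame ``i // n_factors`` under factor
    ``i % n_factors`` and pairs the contrast-scaled frame (float32 in
    [0, 1]) with the *unmodified* binary label of its source frame.
    """

    def __init__(
        self,
        movie: np.ndarray,
        labels: np.ndarray,
        params: ContrastParams | None = None,
    ) -> None:
        movie = np.asarray(movie)
        labels = np.asarray(labels)
        if movie.shape[0] != labels.shape[0]:
            raise ValueError("movie and labels must have the same frame count")
        if movie.shape[1:] != labels.shape[1:]:
            raise ValueError("movie and labels must share frame geometry")
        self.movie = movie
        self.labels = labels
        self.params = params if params is not None else ContrastParams()

    @property
    def n_factors(self) -> int:
        return len(self.params.factors)

    def __len__(self) -> int:
        return self.movie.shape[0] * self.n_factors

    def __getitem__(self, i: int) -> tuple[np.ndarray, np.ndarray]:
        if not 0 <= i < len(self):
            raise IndexError(i)
        t, k = divmod(i, self.n_factors)
        frame = apply_contrast(self.movie[t], self.params.factors[k])
        if np.issubdtype(frame.dtype, np.integer):
            x = frame.astype(np.float32) / np.iinfo(frame.dtype).max
        else:
            x = frame.astype(np.float32)
        y = (self.labels[t] > 0).astype(np.float32)
        return x, y


def build_augmented_dataset(
    movie: np.ndarray,
    labels: np.ndarray,
    params: ContrastParams | None = None,
) -> AugmentedDataset:
    """Dataset of size ``n_frames × n_factors`` (e.g. 233 × 8 = 1864)."""
    return AugmentedDataset(movie, labels, params)
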