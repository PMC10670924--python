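"""Pluggable foreground/background cell detector (default: numpy U-Net).

The detector is a binary segmenter: cells are foreground (label 1),
everything else background.  Any object exposing ``forward(x, train)``,
``backward(dlogits)`` and ``params()`` can stand in for the default U-Net,
so alternative encoders plug in without touching the rest of the loop.

Training runs in shuffled mini-batches of random square crops, with the
number of optimiser updates per refinement iteration capped (the full-scale
setting keeps it below 100).  ``updates_per_epoch`` reproduces the
epoch arithmetic of the full-scale runs: 1864 items at batch 24 → 78
updates, 736 items at batch 8 → 92.
"""

from __future__ import annotations

import math
import pickle
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np

from .augment import AugmentedDataset
from .config import RunConfig
from .nnet import Adam, UNet, bce_with_logits, sigmoid


@dataclass
class DetectorConfig:
    """U-Net hyperparameters.

    The desk-scale default (depth 4, 8 base channels, 256 px crops) trains
    on one CPU; the full-scale preset uses 736×736 inputs.
    Loss is binary cross-entropy and the optimiser Adam, fixed by design.
    """

    depth: int = 4
    base_channels: int = 8
    input_size: int = 256
    learning_rate: float = 1e-4

    def __post_init__(self) -> None:
        if self.base_channels < 2:
            raise ValueError("base_channels must be >= 2")
        if self.depth < 1:
            raise ValueError("depth must be >= 1")
        if self.input_size % 2**self.depth != 0:
            raise ValueError(
                f"input_size must be divisible by 2^depth = {2**self.depth}"
            )


def build_unet(config: DetectorConfig, seed: int = 0) -> UNet:
    """Instantiate the U-Net with He-normal initialisation from ``seed``."""
    return UNet(config.depth, config.base_channels, seed=seed)


def count_parameters(config: DetectorConfig) -> int:
    """Analytic trainable-parameter count of the architecture."""
    chans = [config.base_channels * 2**i for i in range(config.depth + 1)]

    def block(cin, cout):
        return (cin * 9 + 1) * cout + (cout * 9 + 1) * cout

    total = 0
    cin = 1
    for i in range(config.depth):
        total += block(cin, chans[i])
        cin = chans[i]
    total += block(cin, chans[config.depth])
    for i in reversed(range(config.depth)):
        total += (chans[i + 1] * 4 + 1) * chans[i]  # deconv
        total += block(2 * chans[i], chans[i])
    total += chans[0] + 1  # 1x1 head
    return total


@dataclass
class TrainState:
    """Model + optimiser + bookkeeping for the iterative training loop."""

    model: UNet
    optimizer: Adam
    config: DetectorConfig
    rng: np.random.Generator
    iteration: int = 0
    update_count: int = 0
    loss_history: list = field(default_factory=list)


def init_train_state(
    config: DetectorConfig, run: RunConfig, seed: int | None = None
) -> TrainState:
    if seed is None:
        seed = run.seed
    model = build_unet(config, seed=seed)
    return TrainState(
        model=model,
        optimizer=Adam(model, lr=run.learning_rate),
        config=config,
        rng=np.random.default_rng(seed + 1),
    )


def updates_per_epoch(n_items: int, batch_size: int) -> int:
    """Optimiser updates in one pass over the dataset (final partial batch counts)."""
    if n_items < 0 or batch_size < 1:
        raise ValueError("need n_items >= 0 and batch_size >= 1")
    return math.ceil(n_items / batch_size)


def _crop_or_pad(x: np.ndarray, y: np.ndarray, size: int, rng) -> tuple:
    """Random crop to (size, size); reflect-pad if the frame is smaller."""
    h, w = x.shape
    if h < size or w < size:
        ph, pw = max(0, size - h), max(0, size - w)
        pad = ((0, ph), (0, pw))
        x = np.pad(x, pad, mode="reflect")
        y = np.pad(y, pad, mode="reflect")
        h, w = x.shape
    r = int(rng.integers(0, h - size + 1))
    c = int(rng.integers(0, w - size + 1))
    return x[r : r + size, c : c + size], y[r : r + size, c : c + size]


def train_iteration(
    state: TrainState, dataset: AugmentedDataset, run: RunConfig
) -> TrainState:
    """One refinement iteration: ≤ ``run.max_updates_per_iteration`` Adam
    updates over shuffled mini-batches (one capped epoch).

    Raises on an empty dataset, and aborts with a diagnostic if the loss
    goes non-finite.
    """
    n = len(dataset)
    if n == 0:
        raise ValueError("cannot train on an empty dataset")
    order = state.rng.permutation(n)
    size = state.config.input_size
    n_updates = min(updates_per_epoch(n, run.batch_size), run.max_updates_per_iteration)
    losses = []
    for u in range(n_updates):
        idx = order[u * run.batch_size : (u + 1) * run.batch_size]
        xs, ys = [], []
        for i in idx:
            x, y = dataset[int(i)]
            x, y = _crop_or_pad(x, y, size, state.rng)
            xs.append(x)
            ys.append(y)
        xb = np.stack(xs)[:, None].astype(np.float32)
        yb = np.stack(ys)[:, None].astype(np.float32)
        logits = state.model.forward(xb, train=True)
        loss, dlogits = bce_with_logits(logits, yb)
        if not np.isfinite(loss):
            raise RuntimeError(
                f"non-finite loss at iteration {state.iteration}, update {u}"
            )
        state.model.backward(dlogits)
        state.optimizer.step()
        state.update_count += 1
        losses.append(loss)
    state.iteration += 1
    state.loss_history.append(losses)
    return state


def predict_prob(model: UNet, frame: np.ndarray) -> np.ndarray:
    """Per-pixel foreground probability for one frame of any size.

    The frame is normalised to [0, 1], reflect-padded to a multiple of
    2^depth, run through the network in eval mode, and cropped back.
    """
    frame = np.asarray(frame)
    if np.issubdtype(frame.dtype, np.integer):
        x = frame.astype(np.float32) / np.iinfo(frame.dtype).max
    else:
        x = frame.astype(np.float32)
    h, w = x.shape
    mult = 2**model.depth
    ph = (-h) % mult
    pw = (-w) % mult
    if ph or pw:
        x = np.pad(x, ((0, ph), (0, pw)), mode="reflect")
    logits = model.forward(x[None, None], train=False)
    prob = sigmoid(logits[0, 0])
    return prob[:h, :w].astype(np.float32)


def save_checkpoint(state: TrainState, path: str | Path) -> None:
    """Versioned model checkpoint (weights + optimiser + RNG state)."""
    payload = {
        "format_version": 1,
        "config": state.config,
        "weights": [p.copy() for p, _ in state.model.params()],
        "adam": {"t": state.optimizer.t, "m": state.optimizer.m, "v": state.optimizer.v},
        "iteration": state.iteration,
        "update_count": state.update_count,
        "rng_state": state.rng.bit_generator.state,
        "loss_history": state.loss_history,
    }
    Path(path).write_bytes(pickle.dumps(payload))


def load_checkpoint(path: str | Path, run: RunConfig) -> TrainState:
    payload = pickle.loads(Path(path).read_bytes())
    if payload.get("format_version") != 1:
        raise ValueError("unsupported checkpoint version")
    state = init_train_state(payload["config"], run)
    for (p, _), saved in zip(state.model.params(), payload["weights"]):
        p[...] = saved
    state.optimizer.t = payload["adam"]["t"]
    state.optimizer.m = payload["adam"]["m"]
    state.optimizer.v = payload["adam"]["v"]
    state.iteration = payload["iteration"]
    state.update_count = payload["update_count"]
    state.rng.bit_generator.state = payload["rng_state"]
    state.loss_history = payload["loss_history"]
    return state
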