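"""Run-level configuration shared by the tracking, correction and refinement stages."""

from __future__ import annotations

from dataclasses import dataclass, field, fields, replace

DEFAULT_CONTRAST_FACTORS = (0.8, 0.9, 1.0, 1.1, 1.2, 1.3, 1.4, 1.5)


@dataclass
class RunConfig:
    """Hyperparameters of one refinement run.

    Defaults target the point-light (iPS-like) regime: ten
    training iterations, at most 100 optimiser updates per iteration,
    Adam with learning rate 1e-4, overlap-threshold 0.1 linking, and
    trajectory pruning with ``alpha`` = 3 / ``beta`` = 5.  The
    GOWT1-like preset overrides ``beta`` to 8.
    """

    n_iterations: int = 10
    max_updates_per_iteration: int = 100
    learning_rate: float = 1e-4
    batch_size: int = 8
    contrast_params: tuple = DEFAULT_CONTRAST_FACTORS
    overlap_threshold: float = 0.1
    alpha: int = 3
    beta: int = 5
    border_margin: float | None = None  # None -> 2 x median marker radius
    fuse_threshold: float = 0.5
    min_marker_area: int = 20  # px², noise-size cutoff for predicted markers
    max_union_fraction: float = 0.5  # reject predicted frames above this fg fraction
    dilation_iters: int = 1
    gap_dilation_iters: int = 3
    seed: int = 0

    def __post_init__(self) -> None:
        if not 0.0 < self.overlap_threshold < 1.0:
            raise ValueError("overlap_threshold must lie in (0, 1)")
        if self.alpha < 1:
            raise ValueError("alpha must be >= 1")
        if self.beta < self.alpha:
            raise ValueError("beta must be >= alpha")
        if len(tuple(self.contrast_params)) == 0:
            raise ValueError("contrast_params must be nonempty")
        if self.n_iterations < 0:
            raise ValueError("n_iterations must be >= 0")
        if self.batch_size < 1:
            raise ValueError("batch_size must be >= 1")
        self.contrast_params = tuple(float(f) for f in self.contrast_params)


def gowt1_preset(**overrides) -> RunConfig:
    """Configuration matching the strong-contrast GOWT1-like regime (beta = 8)."""
    params = {"beta": 8, "batch_size": 8}
    params.update(overrides)
    return RunConfig(**params)


def ips_preset(**overrides) -> RunConfig:
    """Point-light iPS-like configuration (beta = 5, batch size 24)."""
    params = {"beta": 5, "batch_size": 24}
    params.update(overrides)
    return RunConfig(**params)


def config_from_mapping(mapping: dict) -> RunConfig:
    """Build a RunConfig from a flat key/value mapping (e.g. parsed TOML).

    Unknown keys raise ``ValueError`` so that typos in config files fail loudly.
    """
    known = {f.name for f in fields(RunConfig)}
    unknown = set(mapping) - known
    if unknown:
        raise ValueError(f"unknown config keys: {sorted(unknown)}")
    return RunConfig(**mapping)


__all__ = [
    "RunConfig",
    "DEFAULT_CONTRAST_FACTORS",
    "gowt1_preset",
    "ips_preset",
    "config_from_mapping",
    "replace",
]
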