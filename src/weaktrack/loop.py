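"""Iterative weakly supervised refinement: train → predict (fused) → union
→ track → prune → updated pseudo-ground truth.

Each iteration trains the detector on the current pseudo-GT (over the
contrast-augmented dataset), predicts every frame as an equal-weight
average over the contrast ladder (weight 1/8 for the default eight
factors), binarises the fused probability, takes the pixelwise union with
the current pseudo-GT (so existing annotations are never lost), and —
when tracking assistance is on — builds the lineage graph of the union
and prunes short spurious trajectories.  The result seeds the next
iteration.  Iteration 0 denotes the initial labels.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path

import numpy as np
from skimage import measure

from .augment import ContrastParams, apply_contrast, build_augmented_dataset
from .config import RunConfig
from .correction import remove_false_positives
from .labels import remove_small_objects
from .detector import (
    DetectorConfig,
    TrainState,
    init_train_state,
    predict_prob,
    save_checkpoint,
    train_iteration,
)
from .metrics import MetricsReport, evaluate_sequences
from .tracker import TrackGraph, build_tracks


@dataclass
class IterationRecord:
    iteration: int  # 0 = initial labels
    marker_count: int
    markers_added: int
    markers_removed: int
    report: MetricsReport | None = None


def _count_markers(masks: np.ndarray) -> int:
    return int(
        sum(
            np.unique(masks[t])[np.unique(masks[t]) != 0].size
            for t in range(masks.shape[0])
        )
    )


def weighted_sum_prediction(
    model,
    frame: np.ndarray,
    params: ContrastParams,
    fuse_threshold: float,
    min_marker_area: int = 0,
) -> tuple[np.ndarray, np.ndarray]:
    """Equal-weight fusion of per-contrast-variant predictions.

    Returns ``(labels, fused_probability)`` where the labels are the
    8-connected components of the fused map thresholded at
    ``fuse_threshold``.  Components smaller than ``min_marker_area``
    are discarded — the same "noise smaller than a nucleus" cutoff the
    initial-label pipeline applies, here protecting the pseudo-GT from
    speckle while the detector is still half-trained.
    """
    if not params.factors:
        raise ValueError("contrast factor list must be nonempty")
    weight = 1.0 / len(params.factors)
    fused = np.zeros(frame.shape, np.float64)
    for f in params.factors:
        fused += weight * predict_prob(model, apply_contrast(frame, f))
    binary = fused >= fuse_threshold
    if min_marker_area > 1:
        binary = remove_small_objects(binary, min_marker_area)
    labels = measure.label(binary, connectivity=2).astype(np.uint16)
    return labels, fused.astype(np.float32)


def union_labels(
    pseudo_gt_frame: np.ndarray, fused_prediction_frame: np.ndarray
) -> np.ndarray:
    """Pixelwise OR of the two foregrounds, freshly component-labelled.

    Every pseudo-GT marker survives (possibly merged with a touching
    predicted marker into one component)."""
    combined = (np.asarray(pseudo_gt_frame) > 0) | (
        np.asarray(fused_prediction_frame) > 0
    )
    return measure.label(combined, connectivity=2).astype(np.uint16)


def run_training(
    movie: np.ndarray,
    initial_labels: np.ndarray,
    run: RunConfig,
    detector_config: DetectorConfig | None = None,
    with_tracks: bool = True,
    reference_gt: np.ndarray | None = None,
    snapshot_dir: str | Path | None = None,
) -> tuple[TrainState, list[np.ndarray], list[IterationRecord]]:
    """Run the full refinement loop.

    Parameters
    ----------
    movie : (T, H, W) brightfield frames.
    initial_labels : incomplete pseudo-GT produced from fluorescence (or
        by thinning reference labels).
    with_tracks : when False, the track/prune stage is skipped (the
        ablation setting); removal counts are then all zero.
    reference_gt : optional instance masks used only to score each
        iteration's pseudo-GT.
    snapshot_dir : when given, pseudo-GT masks and a model checkpoint are
        saved there every iteration.

    Returns ``(state, label_history, records)`` with ``label_history[0]``
    the initial labels and one entry per completed iteration.
    """
    if detector_config is None:
        detector_config = DetectorConfig()
    if run.n_iterations < 1:
        raise ValueError("n_iterations must be >= 1 for training")
    movie = np.asarray(movie)
    pseudo = np.asarray(initial_labels).copy()
    params = ContrastParams(run.contrast_params)
    state = init_train_state(detector_config, run)
    history = [pseudo.copy()]
    records = [
        IterationRecord(
            0,
            _count_markers(pseudo),
            0,
            0,
            _maybe_report(pseudo, reference_gt),
        )
    ]
    snap = Path(snapshot_dir) if snapshot_dir is not None else None
    if snap is not None:
        snap.mkdir(parents=True, exist_ok=True)

    for it in range(1, run.n_iterations + 1):
        dataset = build_augmented_dataset(movie, pseudo, params)
        try:
            state = train_iteration(state, dataset, run)
            union = np.zeros_like(pseudo, dtype=np.uint16)
            for t in range(movie.shape[0]):
                pred, _ = weighted_sum_prediction(
                    state.model,
                    movie[t],
                    params,
                    run.fuse_threshold,
                    run.min_marker_area,
                )
                # a half-trained detector can flood a frame; cells never
                # cover more than half the field, so such frames are
                # degenerate and contribute nothing to the union
                if np.count_nonzero(pred) > run.max_union_fraction * pred.size:
                    pred = np.zeros_like(pred)
                union[t] = union_labels(pseudo[t], pred)
            n_before = _count_markers(pseudo)
            n_union = _count_markers(union)
            removed = 0
            if with_tracks:
                graph = build_tracks(union, run)
                union, removal_log = remove_false_positives(union, graph, run)
                removed = len(removal_log)
            pseudo = union
        except Exception:
            if snap is not None:  # keep the last good pseudo-GT on failure
                np.save(snap / "last_good_pseudo_gt.npy", pseudo)
            raise
        history.append(pseudo.copy())
        records.append(
            IterationRecord(
                it,
                _count_markers(pseudo),
                max(n_union - n_before, 0),
                removed,
                _maybe_report(pseudo, reference_gt),
            )
        )
        if snap is not None:
            np.save(snap / f"pseudo_gt_iter{it:02d}.npy", pseudo)
            save_checkpoint(state, snap / f"model_iter{it:02d}.ckpt")
    return state, history, records


def _maybe_report(pseudo, reference_gt) -> MetricsReport | None:
    if reference_gt is None:
        return None
    return evaluate_sequences(reference_gt, pseudo)


def run_inference(
    state_or_model,
    movie: np.ndarray,
    run: RunConfig,
    with_tracking: bool = True,
) -> tuple[np.ndarray, TrackGraph]:
    """Detect and track a movie with a trained model.

    Applies the weighted-sum fused prediction per frame; with tracking
    assistance on, short spurious trajectories are pruned from the
    predictions before output.  Deterministic given model and movie.
    """
    model = getattr(state_or_model, "model", state_or_model)
    movie = np.asarray(movie)
    params = ContrastParams(run.contrast_params)
    masks = np.zeros(movie.shape, np.uint16)
    for t in range(movie.shape[0]):
        masks[t], _ = weighted_sum_prediction(
            model, movie[t], params, run.fuse_threshold, run.min_marker_area
        )
    graph = build_tracks(masks, run)
    if with_tracking:
        masks, _ = remove_false_positives(masks, graph, run)
        graph = build_tracks(masks, run)
    return masks, graph
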