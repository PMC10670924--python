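"""Tracking-assisted removal of false-positive detections.

Impurities and bubbles that resemble cells produce detections whose
trajectories are much shorter than real cells'.  A track is a
false-positive candidate when it spans fewer than ``alpha`` frames,
touches neither the first nor the last frame of the movie (tracks
truncated by the movie boundary are exempt), stays clear of the image
border, and is not already associated with the lineage (no parent, no
daughters).  Before removal, each candidate gets one rescue attempt: its
last mask is dilated ``gap_dilation_iters`` times and the following
``beta`` frames are scanned for an orphan marker overlapping it by at
least the overlap threshold; the earliest such marker is spliced onto the
track (closing a short detection gap) and the merged track is re-measured
against ``alpha``.  Whatever remains unrescued is zeroed out of the masks.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import ndimage

from .config import RunConfig
from .tracker import Node, TrackGraph, TrackRecord, _STRUCT3


@dataclass(frozen=True)
class RemovalEntry:
    frame: int
    marker_id: int
    track_id: int
    reason: str


def default_border_margin(masks: np.ndarray) -> float:
    """Twice the median equivalent marker radius, the width of the border band."""
    masks = np.asarray(masks)
    areas = []
    for t in range(masks.shape[0]):
        counts = np.bincount(masks[t].ravel())
        areas.extend(counts[1:][counts[1:] > 0])
    if not areas:
        return 0.0
    median_radius = float(np.sqrt(np.median(areas) / np.pi))
    return 2.0 * median_radius


def _track_chains(graph: TrackGraph) -> dict[int, list[Node]]:
    """track id -> ordered node chain."""
    _, node_track = graph.compile_tracks()
    chains: dict[int, list[Node]] = {}
    for node, tid in node_track.items():
        chains.setdefault(tid, []).append(node)
    for chain in chains.values():
        chain.sort()
    return chains


def find_short_tracks(graph: TrackGraph, alpha: int) -> list[TrackRecord]:
    """Tracks spanning fewer than ``alpha`` frames, excluding movie-boundary
    tracks and tracks already linked into a lineage (parent or daughters)."""
    records, node_track = graph.compile_tracks()
    chains = _track_chains(graph)
    last_frame = graph.n_frames - 1
    out = []
    for rec in records:
        if rec.end - rec.begin + 1 >= alpha:
            continue
        if rec.begin == 0 or rec.end == last_frame:
            continue
        if rec.parent_id != 0:
            continue
        tail = chains[rec.track_id][-1]
        if graph.children(tail):
            continue
        out.append(rec)
    return out


def is_border_track(
    nodes: list[Node], masks: np.ndarray, border_margin: float
) -> bool:
    """True when any of the track's masks intersects the border band."""
    m = int(np.ceil(border_margin))
    if m <= 0:
        return False
    h, w = masks.shape[1:]
    for t, label in nodes:
        blob = masks[t] == label
        band = np.zeros((h, w), bool)
        band[:m, :] = band[-m:, :] = True
        band[:, :m] = band[:, -m:] = True
        if np.logical_and(blob, band).any():
            return True
    return False


def gap_associate(
    nodes: list[Node],
    masks: np.ndarray,
    graph: TrackGraph,
    run: RunConfig,
) -> Node | None:
    """Search the ``beta`` frames after a track's end for an orphan successor.

    The track's last mask is dilated ``run.gap_dilation_iters`` times and
    overlap (relative to the dilated area) is computed against every
    parentless marker in each subsequent frame; the earliest qualifying
    frame wins, best overlap inside it, lower label on ties.
    """
    t_end, label = nodes[-1]
    blob = masks[t_end] == label
    if not blob.any():
        return None
    blob = ndimage.binary_dilation(
        blob, structure=_STRUCT3, iterations=run.gap_dilation_iters
    )
    area = float(blob.sum())
    n_frames = masks.shape[0]
    for t in range(t_end + 1, min(t_end + 1 + run.beta, n_frames)):
        counts = np.bincount(masks[t][blob])
        best: tuple[float, int] | None = None
        for cand in np.nonzero(counts)[0]:
            if cand == 0:
                continue
            node = (t, int(cand))
            if graph.parent(node) is not None:
                continue
            ov = counts[cand] / area
            if ov < run.overlap_threshold:
                continue
            if best is None or ov > best[0] or (ov == best[0] and cand < best[1]):
                best = (float(ov), int(cand))
        if best is not None:
            return (t, best[1])
    return None


def remove_false_positives(
    masks: np.ndarray,
    graph: TrackGraph,
    run: RunConfig,
) -> tuple[np.ndarray, list[RemovalEntry]]:
    """Prune unrescued short interior tracks from masks and graph.

    Returns the cleaned mask sequence and a removal log.  The operation
    is idempotent: a second application removes nothing further (modulo
    newly spliced tracks, which are kept).  It never adds markers.
    """
    masks = np.asarray(masks).copy()
    margin = (
        run.border_margin
        if run.border_margin is not None
        else default_border_margin(masks)
    )
    log: list[RemovalEntry] = []
    handled: set[tuple[Node, ...]] = set()  # chains already inspected this run
    while True:
        chains = _track_chains(graph)
        candidates = find_short_tracks(graph, run.alpha)
        changed = False
        for rec in candidates:
            nodes = chains[rec.track_id]
            key = tuple(nodes)
            if key in handled:
                continue
            if is_border_track(nodes, masks, margin):
                handled.add(key)
                continue
            successor = gap_associate(nodes, masks, graph, run)
            if successor is not None:
                graph.add_edge(nodes[-1], successor)  # splice across the gap
            else:
                for t, label in nodes:
                    masks[t][masks[t] == label] = 0
                    log.append(RemovalEntry(t, label, rec.track_id, "short_track"))
                    graph.remove_node((t, label))
            # track ids shift after any mutation: recompile before continuing
            changed = True
            break
        if not changed:
            break
    return masks, log


def write_removal_log(log: list[RemovalEntry], path) -> None:
    """Tab-separated audit log of removed markers."""
    with open(path, "w") as fh:
        fh.write("frame\tmarker_id\ttrack_id\treason\n")
        for entry in log:
            fh.write(
                f"{entry.frame}\t{entry.marker_id}\t{entry.track_id}\t{entry.reason}\n"
            )
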