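"""On-disk artifacts in the Cell Tracking Challenge layout.

Mask sequences are directories of per-frame 16-bit instance-labelled
TIFFs with zero-padded frame numbers; lineages are plain-text track files
with one ``<id> <begin> <end> <parent>`` line per track.  Readers order
frames by their parsed numbers (never by directory listing order), check
contiguity, and preserve labels exactly; writers are exact inverses.
"""

from __future__ import annotations

import re
import tomllib
from dataclasses import fields
from pathlib import Path

import numpy as np
import tifffile

from .config import RunConfig, config_from_mapping
from .metrics import MetricsReport, evaluate_sequences
from .tracker import TrackGraph, TrackRecord, relabel_by_tracks


class GapError(ValueError):
    """A frame number is missing from a sequence directory."""


class FormatError(ValueError):
    """A file violates the expected on-disk format."""


_FRAME_RE = re.compile(r"(\d+)\.tiff?$", re.IGNORECASE)


def _indexed_files(directory: Path) -> list[tuple[int, Path]]:
    found = []
    for path in directory.iterdir():
        m = _FRAME_RE.search(path.name)
        if m:
            found.append((int(m.group(1)), path))
    if not found:
        raise FormatError(f"no numbered TIFF frames in {directory}")
    found.sort(key=lambda item: item[0])
    numbers = [n for n, _ in found]
    if len(set(numbers)) != len(numbers):
        raise FormatError(f"duplicate frame numbers in {directory}")
    expected = list(range(numbers[0], numbers[0] + len(numbers)))
    if numbers != expected:
        missing = sorted(set(expected) - set(numbers))
        raise GapError(f"missing frame number(s) {missing} in {directory}")
    return found


def write_image_sequence(
    directory: str | Path, frames: np.ndarray, prefix: str = "t", start: int = 0
) -> None:
    directory = Path(directory)
    directory.mkdir(parents=True, exist_ok=True)
    frames = np.asarray(frames)
    digits = max(3, len(str(start + frames.shape[0] - 1)))
    for t in range(frames.shape[0]):
        tifffile.imwrite(
            directory / f"{prefix}{start + t:0{digits}d}.tif", frames[t]
        )


def read_image_sequence(directory: str | Path) -> np.ndarray:
    """Stack the numbered frames of a directory; raises ``GapError`` on gaps."""
    files = _indexed_files(Path(directory))
    frames = [tifffile.imread(path) for _, path in files]
    return np.stack(frames)


def write_mask_sequence(
    directory: str | Path, masks: np.ndarray, prefix: str = "man_track", start: int = 0
) -> None:
    masks = np.asarray(masks)
    if not np.issubdtype(masks.dtype, np.integer):
        raise FormatError("instance masks must have an integer dtype")
    write_image_sequence(directory, masks.astype(np.uint16), prefix, start)


def read_mask_sequence(directory: str | Path) -> np.ndarray:
    """Read per-frame 16-bit instance masks, labels preserved exactly."""
    masks = read_image_sequence(directory)
    if not np.issubdtype(masks.dtype, np.integer):
        raise FormatError("instance masks must have an integer pixel type")
    return masks


def write_track_file(graph_or_records, path: str | Path) -> None:
    """CTC text track file, one record per line, sorted by track id."""
    if isinstance(graph_or_records, TrackGraph):
        records = graph_or_records.records()
    else:
        records = list(graph_or_records)
    ids = {r.track_id for r in records}
    for r in records:
        if r.parent_id != 0 and r.parent_id not in ids:
            raise FormatError(f"track {r.track_id} references missing parent {r.parent_id}")
    with open(path, "w") as fh:
        for r in sorted(records, key=lambda r: r.track_id):
            fh.write(f"{r.track_id} {r.begin} {r.end} {r.parent_id}\n")


def read_track_file(path: str | Path) -> list[TrackRecord]:
    records = []
    with open(path) as fh:
        for line_no, line in enumerate(fh, 1):
            parts = line.split()
            if not parts:
                continue
            if len(parts) != 4:
                raise FormatError(f"{path}:{line_no}: expected 4 fields")
            tid, begin, end, parent = map(int, parts)
            records.append(TrackRecord(tid, begin, end, parent))
    by_id = {r.track_id: r for r in records}
    for r in records:
        if r.parent_id != 0:
            parent = by_id.get(r.parent_id)
            if parent is None:
                raise FormatError(f"dangling parent id {r.parent_id}")
            if parent.end >= r.begin:
                raise FormatError(
                    f"parent {r.parent_id} must end before child {r.track_id} begins"
                )
    return records


def graph_from_ctc(masks: np.ndarray, records: list[TrackRecord]) -> TrackGraph:
    """Rebuild a lineage graph from CTC masks + track records.

    Mask labels are assumed to carry track ids (the CTC convention).
    Within a track, consecutive *present* frames are linked (masks may
    skip a frame inside the track interval); parent links join the
    parent's last frame to the child's first.
    """
    masks = np.asarray(masks)
    graph = TrackGraph()
    present: dict[int, list[int]] = {}
    for t in range(masks.shape[0]):
        counts = np.bincount(masks[t].ravel())
        for label in np.nonzero(counts)[0]:
            if label == 0:
                continue
            graph.add_node(t, int(label), int(counts[label]))
            present.setdefault(int(label), []).append(t)
    graph._n_frames = masks.shape[0]
    for rec in records:
        frames = present.get(rec.track_id, [])
        for a, b in zip(frames, frames[1:]):
            graph.add_edge((a, rec.track_id), (b, rec.track_id))
    for rec in records:
        if rec.parent_id == 0:
            continue
        parent_frames = present.get(rec.parent_id, [])
        child_frames = present.get(rec.track_id, [])
        if parent_frames and child_frames:
            graph.add_edge(
                (parent_frames[-1], rec.parent_id), (child_frames[0], rec.track_id)
            )
    return graph


def write_ctc_result(
    directory: str | Path, masks: np.ndarray, graph: TrackGraph
) -> None:
    """CTC result layout: track-id-labelled masks plus ``res_track.txt``."""
    directory = Path(directory)
    relabelled, records = relabel_by_tracks(np.asarray(masks), graph)
    write_mask_sequence(directory, relabelled, prefix="mask")
    write_track_file(records, directory / "res_track.txt")


def load_ctc_directory(directory: str | Path) -> tuple[np.ndarray, TrackGraph]:
    """Read a CTC-layout directory (masks + single ``*_track.txt`` file)."""
    directory = Path(directory)
    masks = read_mask_sequence(directory)
    track_files = sorted(directory.glob("*track*.txt"))
    if not track_files:
        raise FormatError(f"no track file in {directory}")
    records = read_track_file(track_files[0])
    return masks, graph_from_ctc(masks, records)


def evaluate_dirs(gt_dir: str | Path, res_dir: str | Path) -> MetricsReport:
    """Score a result directory against a ground-truth directory."""
    gt_masks, gt_graph = load_ctc_directory(gt_dir)
    res_masks, res_graph = load_ctc_directory(res_dir)
    return evaluate_sequences(gt_masks, res_masks, gt_graph, res_graph)


def load_run_config(path: str | Path) -> RunConfig:
    """Read a flat TOML run-configuration file."""
    with open(path, "rb") as fh:
        data = tomllib.load(fh)
    if "contrast_params" in data:
        data["contrast_params"] = tuple(data["contrast_params"])
    return config_from_mapping(data)


def save_run_config(run: RunConfig, path: str | Path) -> None:
    lines = []
    for f in fields(run):
        value = getattr(run, f.name)
        if value is None:
            continue
        if isinstance(value, tuple):
            value = "[" + ", ".join(repr(v) for v in value) + "]"
        elif isinstance(value, str):
            value = repr(value)
        lines.append(f"{f.name} = {value}")
    Path(path).write_text("\n".join(lines) + "\n")
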