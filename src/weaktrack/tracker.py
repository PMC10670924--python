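"""Overlap-based tracking-by-detection.

Markers in consecutive frames are linked when the earlier marker's
(dilated) mask overlaps a candidate in the next frame by at least the
overlap threshold,

    overlap = |A_t ∩ A_{t+1}| / |A_t|,

normalised by the earlier mask's area (after dilation).  A marker may
acquire at most two successors — a division — and every marker has at
most one parent.  Assignment is greedy by descending overlap, with the
lower marker id winning ties, which makes linking deterministic.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import ndimage

from .config import RunConfig

Node = tuple[int, int]  # (frame index, mask label)

_STRUCT3 = np.ones((3, 3), bool)


@dataclass(frozen=True)
class TrackRecord:
    """One lineage-table row: ``track_id begin end parent_id`` (0 = no parent)."""

    track_id: int
    begin: int
    end: int
    parent_id: int = 0

    def __post_init__(self) -> None:
        if self.begin > self.end:
            raise ValueError("track begin must be <= end")
        if self.parent_id == self.track_id:
            raise ValueError("a track cannot be its own parent")


class TrackGraph:
    """Acyclic oriented graph of markers across frames.

    Nodes are ``(frame, label)`` pairs; directed edges run strictly
    forward in time.  A node has at most one parent and at most two
    children; exactly two children constitute a division.  Tracks in
    the CTC sense (maximal single-child chains) are compiled on demand.
    """

    def __init__(self) -> None:
        self._area: dict[Node, int] = {}
        self._children: dict[Node, list[Node]] = {}
        self._parent: dict[Node, Node] = {}
        self._n_frames: int = 0

    # -- construction -------------------------------------------------

    def add_node(self, frame: int, label: int, area: int = 0) -> None:
        if label <= 0:
            raise ValueError("labels must be positive")
        node = (frame, label)
        if node in self._area:
            raise ValueError(f"duplicate node {node}")
        self._area[node] = int(area)
        self._children[node] = []
        self._n_frames = max(self._n_frames, frame + 1)

    def add_edge(self, u: Node, v: Node) -> None:
        if u not in self._area or v not in self._area:
            raise KeyError("both endpoints must be nodes")
        if v[0] <= u[0]:
            raise ValueError("edges must go strictly forward in time")
        if v in self._parent:
            raise ValueError(f"{v} already has a parent")
        if len(self._children[u]) >= 2:
            raise ValueError(f"{u} already has two children")
        self._children[u].append(v)
        self._parent[v] = u

    def remove_node(self, node: Node) -> None:
        for child in self._children.pop(node, []):
            del self._parent[child]
        parent = self._parent.pop(node, None)
        if parent is not None:
            self._children[parent].remove(node)
        del self._area[node]

    # -- queries -------------------------------------------------------

    @property
    def nodes(self) -> list[Node]:
        return sorted(self._area)

    @property
    def n_frames(self) -> int:
        return self._n_frames

    def area(self, node: Node) -> int:
        return self._area[node]

    def children(self, node: Node) -> tuple[Node, ...]:
        return tuple(self._children[node])

    def parent(self, node: Node) -> Node | None:
        return self._parent.get(node)

    def has_node(self, node: Node) -> bool:
        return node in self._area

    def has_edge(self, u: Node, v: Node) -> bool:
        return v in self._children.get(u, ())

    def edges(self) -> list[tuple[Node, Node]]:
        return sorted(
            (u, v) for u, kids in self._children.items() for v in kids
        )

    def edge_kind(self, u: Node, v: Node) -> str:
        """'parent' for a division edge (two children), else 'track'."""
        if not self.has_edge(u, v):
            raise KeyError((u, v))
        return "parent" if len(self._children[u]) == 2 else "track"

    def nodes_in_frame(self, frame: int) -> list[Node]:
        return sorted(n for n in self._area if n[0] == frame)

    # -- track compilation --------------------------------------------

    def _track_starts(self) -> list[Node]:
        starts = [n for n in self._area if n not in self._parent]
        starts += [
            child
            for node, kids in self._children.items()
            if len(kids) == 2
            for child in kids
        ]
        return sorted(set(starts))

    def compile_tracks(self) -> tuple[list[TrackRecord], dict[Node, int]]:
        """Assign CTC-style track ids; return records and node->id mapping."""
        node_track: dict[Node, int] = {}
        chains: list[list[Node]] = []
        for start in self._track_starts():
            chain = [start]
            node = start
            while len(self._children[node]) == 1:
                node = self._children[node][0]
                chain.append(node)
            chains.append(chain)
        chains.sort(key=lambda c: (c[0][0], c[0][1]))
        for tid, chain in enumerate(chains, start=1):
            for node in chain:
                node_track[node] = tid
        records = []
        for tid, chain in enumerate(chains, start=1):
            parent = self._parent.get(chain[0])
            parent_id = node_track[parent] if parent is not None else 0
            records.append(
                TrackRecord(tid, chain[0][0], chain[-1][0], parent_id)
            )
        return records, node_track

    def records(self) -> list[TrackRecord]:
        return self.compile_tracks()[0]


def overlap(mask_t: np.ndarray, mask_t1: np.ndarray) -> float:
    """Fraction of the earlier mask covered by the later one (Jaccard-free).

    Raises ``ValueError`` when the earlier mask is empty, for which the
    ratio is undefined.
    """
    mask_t = np.asarray(mask_t, bool)
    mask_t1 = np.asarray(mask_t1, bool)
    if mask_t.shape != mask_t1.shape:
        raise ValueError("masks must share frame geometry")
    area_t = int(mask_t.sum())
    if area_t == 0:
        raise ValueError("overlap undefined for an empty earlier mask")
    return float(np.logical_and(mask_t, mask_t1).sum()) / area_t


def _candidate_overlaps(
    masks_t: np.ndarray,
    masks_t1: np.ndarray,
    dilation_iters: int,
) -> list[tuple[float, int, int]]:
    """All (overlap, label_t, label_t1) pairs with nonzero intersection."""
    out: list[tuple[float, int, int]] = []
    slices = ndimage.find_objects(masks_t)
    h, w = masks_t.shape
    pad = max(dilation_iters, 0)
    for label_t, sl in enumerate(slices, start=1):
        if sl is None:
            continue
        r0 = max(sl[0].start - pad, 0)
        r1 = min(sl[0].stop + pad, h)
        c0 = max(sl[1].start - pad, 0)
        c1 = min(sl[1].stop + pad, w)
        window = (slice(r0, r1), slice(c0, c1))
        blob = masks_t[window] == label_t
        if dilation_iters > 0:
            blob = ndimage.binary_dilation(
                blob, structure=_STRUCT3, iterations=dilation_iters
            )
        area = int(blob.sum())
        counts = np.bincount(masks_t1[window][blob])
        for label_t1 in np.nonzero(counts)[0]:
            if label_t1 == 0:
                continue
            out.append((counts[label_t1] / area, label_t, int(label_t1)))
    return out


def link_frames(
    masks_t: np.ndarray,
    masks_t1: np.ndarray,
    run: RunConfig,
) -> set[tuple[int, int]]:
    """Greedy overlap linking between two consecutive labelled frames.

    Returns ``{(label_t, label_t1), ...}``.  Each later marker receives
    at most one parent and each earlier marker at most two successors,
    assigned in order of descending overlap (ties broken by lower ids).
    """
    pairs = _candidate_overlaps(masks_t, masks_t1, run.dilation_iters)
    pairs = [p for p in pairs if p[0] >= run.overlap_threshold]
    pairs.sort(key=lambda p: (-p[0], p[1], p[2]))
    n_children: dict[int, int] = {}
    parent_of: dict[int, int] = {}
    edges: set[tuple[int, int]] = set()
    for ov, lt, lt1 in pairs:
        if lt1 in parent_of:
            continue
        if n_children.get(lt, 0) >= 2:
            continue
        parent_of[lt1] = lt
        n_children[lt] = n_children.get(lt, 0) + 1
        edges.add((lt, lt1))
    return edges


def build_tracks(masks: np.ndarray, run: RunConfig | None = None) -> TrackGraph:
    """Link every consecutive frame pair of a labelled sequence into a graph."""
    if run is None:
        run = RunConfig()
    masks = np.asarray(masks)
    graph = TrackGraph()
    for t in range(masks.shape[0]):
        counts = np.bincount(masks[t].ravel())
        for label in np.nonzero(counts)[0]:
            if label == 0:
                continue
            graph.add_node(t, int(label), int(counts[label]))
    graph._n_frames = masks.shape[0]
    for t in range(masks.shape[0] - 1):
        for lt, lt1 in sorted(link_frames(masks[t], masks[t + 1], run)):
            graph.add_edge((t, lt), (t + 1, lt1))
    return graph


def relabel_by_tracks(
    masks: np.ndarray, graph: TrackGraph
) -> tuple[np.ndarray, list[TrackRecord]]:
    """Rewrite mask labels so each marker carries its track id (CTC result layout)."""
    records, node_track = graph.compile_tracks()
    out = np.zeros_like(masks, dtype=np.uint16)
    for (frame, label), tid in node_track.items():
        out[frame][masks[frame] == label] = tid
    return out, records
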