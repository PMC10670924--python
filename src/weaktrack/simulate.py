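"""Synthetic paired brightfield/fluorescence time-lapse movies with ground truth.

The generator emulates the data regime the refinement method was designed
for: nucleus-sized elliptical cells drifting by a Gaussian random walk on a
textured background, occasional divisions into exactly two children
(multi-division and fusion never occur), short-lived impurity blobs that
appear in the brightfield channel only, and a fluorescence channel in which
only a *fraction* of lineages carry the reporter and the signal decays
radially from the frame centre under a point-light illumination profile —
the regime in which global thresholding of the fluorescence fails.

Brightfield cell contrast is deliberately low (default ≈ 14 % of the 8-bit
dynamic range) so that detection is a learning problem rather than a
thresholding exercise.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np
from scipy import ndimage
from skimage.draw import ellipse as draw_ellipse

from .tracker import TrackGraph


@dataclass
class SimConfig:
    width: int = 256
    height: int = 256
    n_frames: int = 40
    n_cells: int = 15
    radius_range: tuple[float, float] = (6.0, 10.0)
    step_sigma: float = 1.5
    division_prob: float = 0.01
    transfection_fraction: float = 0.5
    light_sigma: float = 90.0
    impurity_count: int = 8
    impurity_lifetime: int = 2
    background_texture_sigma: float = 8.0
    cell_contrast: float = 35.0
    seed: int = 0

    def __post_init__(self) -> None:
        if self.width < 64 or self.height < 64:
            raise ValueError("frames must be at least 64x64 pixels")
        if self.n_frames < 2:
            raise ValueError("a movie needs at least 2 frames")
        if not 0.0 <= self.transfection_fraction <= 1.0:
            raise ValueError("transfection_fraction must lie in [0, 1]")
        if self.radius_range[0] > self.radius_range[1]:
            raise ValueError("radius_range must be (min, max) with min <= max")
        if self.radius_range[0] <= 0:
            raise ValueError("radii must be positive")
        if self.impurity_lifetime >= self.n_frames:
            raise ValueError("impurity_lifetime must be < n_frames")
        expected_area = self.n_cells * math.pi * self.radius_range[1] ** 2
        if expected_area > 0.5 * self.width * self.height:
            raise ValueError(
                "expected cell area exceeds 50% of the frame; "
                "overcrowding breaks overlap-tracking assumptions"
            )


@dataclass
class GroundTruthMovie:
    """A simulated movie plus everything needed to score a method against it."""

    brightfield: np.ndarray  # (T, H, W) uint8
    fluorescence: np.ndarray  # (T, H, W) uint8
    masks: np.ndarray  # (T, H, W) uint16, label = track id
    tracks: TrackGraph
    transfected_ids: frozenset[int]  # lineage (founder track) ids
    lineage_of: dict[int, int] = field(default_factory=dict)

    @property
    def n_frames(self) -> int:
        return self.brightfield.shape[0]

    @property
    def shape(self) -> tuple[int, int]:
        return self.brightfield.shape[1:]


class _Cell:
    __slots__ = ("cid", "lineage", "x", "y", "rx", "ry", "theta")

    def __init__(self, cid, lineage, x, y, rx, ry, theta):
        self.cid = cid
        self.lineage = lineage
        self.x = x
        self.y = y
        self.rx = rx
        self.ry = ry
        self.theta = theta


def _disc_intersection(r1: float, r2: float, d: float) -> float:
    """Area of the intersection of two discs with radii r1, r2 at distance d."""
    if d >= r1 + r2:
        return 0.0
    if d <= abs(r1 - r2):
        return math.pi * min(r1, r2) ** 2
    a1 = r1 * r1 * math.acos((d * d + r1 * r1 - r2 * r2) / (2 * d * r1))
    a2 = r2 * r2 * math.acos((d * d + r2 * r2 - r1 * r1) / (2 * d * r2))
    a3 = 0.5 * math.sqrt(
        (-d + r1 + r2) * (d + r1 - r2) * (d - r1 + r2) * (d + r1 + r2)
    )
    return a1 + a2 - a3


def _division_trackable(parent: _Cell, child: _Cell, min_overlap: float = 0.12) -> bool:
    """Will overlap linking (threshold 0.1, 1 dilation) recover this edge?

    Conservative disc approximation: the dilated parent as a disc of its
    max radius + 1, the child as a disc of its min radius.
    """
    r_p = max(parent.rx, parent.ry) + 1.0
    r_c = min(child.rx, child.ry)
    d = math.hypot(child.x - parent.x, child.y - parent.y)
    return _disc_intersection(r_p, r_c, d) / (math.pi * r_p * r_p) >= min_overlap


def _resolve_collisions(cells: list[_Cell], w: int, h: int) -> None:
    """Push overlapping cells apart so GT markers stay disjoint."""
    for _ in range(8):
        moved = False
        for i in range(len(cells)):
            for j in range(i + 1, len(cells)):
                a, b = cells[i], cells[j]
                min_d = max(a.rx, a.ry) + max(b.rx, b.ry) + 1.0
                dx, dy = b.x - a.x, b.y - a.y
                d = math.hypot(dx, dy)
                if d >= min_d:
                    continue
                if d < 1e-6:
                    dx, dy, d = 1.0, 0.0, 1.0
                shift = (min_d - d) / 2 + 0.5
                ux, uy = dx / d, dy / d
                a.x -= ux * shift
                a.y -= uy * shift
                b.x += ux * shift
                b.y += uy * shift
                moved = True
        for c in cells:
            r = max(c.rx, c.ry)
            c.x = float(np.clip(c.x, r, w - 1 - r))
            c.y = float(np.clip(c.y, r, h - 1 - r))
        if not moved:
            break


def _render_masks(cells: list[_Cell], shape: tuple[int, int]) -> np.ndarray:
    frame = np.zeros(shape, np.uint16)
    for c in sorted(cells, key=lambda c: c.cid):
        rr, cc = draw_ellipse(c.y, c.x, c.ry, c.rx, shape=shape, rotation=c.theta)
        vals = frame[rr, cc]
        frame[rr, cc] = np.where(vals == 0, np.uint16(c.cid), vals)  # earlier ids win
    return frame


def _point_light(shape: tuple[int, int], sigma: float) -> np.ndarray:
    h, w = shape
    yy, xx = np.mgrid[0:h, 0:w]
    d2 = (yy - (h - 1) / 2.0) ** 2 + (xx - (w - 1) / 2.0) ** 2
    return np.exp(-d2 / (2.0 * sigma**2)).astype(np.float32)


def simulate_movie(config: SimConfig) -> GroundTruthMovie:
    """Generate a movie; bit-identical for a fixed ``config.seed``."""
    rng = np.random.default_rng(config.seed)
    w, h = config.width, config.height
    rmin, rmax = config.radius_range

    # --- initial population ------------------------------------------
    cells: list[_Cell] = []
    next_id = 1
    margin = rmax + 2
    for _ in range(config.n_cells):
        for _attempt in range(200):
            x = rng.uniform(margin, w - 1 - margin)
            y = rng.uniform(margin, h - 1 - margin)
            rx = rng.uniform(rmin, rmax)
            ry = rng.uniform(rmin, rmax)
            if all(
                math.hypot(c.x - x, c.y - y) > max(rx, ry) + max(c.rx, c.ry) + 2
                for c in cells
            ):
                break
        cells.append(_Cell(next_id, next_id, x, y, rx, ry, rng.uniform(0, math.pi)))
        next_id += 1

    transfected = frozenset(
        c.lineage for c in cells if rng.random() < config.transfection_fraction
    )
    lineage_of = {c.cid: c.lineage for c in cells}

    graph = TrackGraph()
    masks = np.zeros((config.n_frames, h, w), np.uint16)

    for t in range(config.n_frames):
        frame = _render_masks(cells, (h, w))
        masks[t] = frame
        counts = np.bincount(frame.ravel())
        for c in cells:
            area = int(counts[c.cid]) if c.cid < len(counts) else 0
            if not graph.has_node((t, c.cid)):  # division children pre-registered
                graph.add_node(t, c.cid, area)
            if t > 0:
                prev = (t - 1, c.cid)
                if graph.has_node(prev) and not graph.has_edge(prev, (t, c.cid)):
                    graph.add_edge(prev, (t, c.cid))
        if t == config.n_frames - 1:
            break

        # --- advance to t+1 ------------------------------------------
        new_cells: list[_Cell] = []
        pending: list[tuple[_Cell, list[_Cell]]] = []  # tentative divisions
        for c in cells:
            if rng.random() < config.division_prob:
                angle = rng.uniform(0, 2 * math.pi)
                sep = max(c.rx, c.ry) * 0.9
                children = []
                for sign in (1.0, -1.0):
                    children.append(
                        _Cell(
                            0,  # id assigned once the division validates
                            c.lineage,
                            c.x + sign * sep * math.cos(angle),
                            c.y + sign * sep * math.sin(angle),
                            max(rmin, c.rx * 0.8),
                            max(rmin, c.ry * 0.8),
                            rng.uniform(0, math.pi),
                        )
                    )
                pending.append((c, children))
                new_cells.extend(children)
            else:
                c.x += rng.normal(0.0, config.step_sigma)
                c.y += rng.normal(0.0, config.step_sigma)
                new_cells.append(c)
        _resolve_collisions(new_cells, w, h)
        # cancel divisions that overlap linking could not recover
        for parent, children in pending:
            if all(_division_trackable(parent, ch) for ch in children):
                for ch in children:
                    ch.cid = next_id
                    lineage_of[next_id] = parent.lineage
                    graph.add_node(t + 1, next_id, 0)  # area patched on render
                    graph.add_edge((t, parent.cid), (t + 1, next_id))
                    next_id += 1
            else:
                for ch in children:
                    new_cells.remove(ch)
                new_cells.append(parent)  # the cell simply persists
        cells = new_cells

    # patch areas of division children (nodes were added before rendering)
    for t in range(config.n_frames):
        counts = np.bincount(masks[t].ravel())
        for node in graph.nodes_in_frame(t):
            _, label = node
            area = int(counts[label]) if label < len(counts) else 0
            graph._area[node] = area

    # --- impurities (brightfield only, never intersecting GT masks) --
    impurities: list[tuple[int, int, float, float, float]] = []
    gt_any = masks > 0
    for _ in range(config.impurity_count):
        life = int(rng.integers(1, config.impurity_lifetime + 1))
        birth = int(rng.integers(0, config.n_frames - life + 1))
        for _attempt in range(100):
            x = rng.uniform(margin, w - 1 - margin)
            y = rng.uniform(margin, h - 1 - margin)
            r = rng.uniform(0.6 * rmin, 0.8 * rmax)
            rr, cc = draw_ellipse(y, x, r, r, shape=(h, w))
            if not gt_any[birth : birth + life, rr, cc].any():
                impurities.append((birth, life, x, y, r))
                break

    # --- brightfield rendering ---------------------------------------
    texture = ndimage.gaussian_filter(rng.normal(0, 1, (h, w)), 8.0)
    texture = texture / max(texture.std(), 1e-9) * config.background_texture_sigma
    bright = np.zeros((config.n_frames, h, w), np.float32)
    for t in range(config.n_frames):
        img = 110.0 + texture + rng.normal(0, 3.0, (h, w))
        cellmap = np.zeros((h, w), np.float32)
        cellmap[masks[t] > 0] = 1.0
        for birth, life, x, y, r in impurities:
            if birth <= t < birth + life:
                rr, cc = draw_ellipse(y, x, r, r, shape=(h, w))
                cellmap[rr, cc] = 1.0
        img += config.cell_contrast * ndimage.gaussian_filter(cellmap, 1.0)
        bright[t] = img
    brightfield = np.clip(bright, 0, 255).astype(np.uint8)

    # --- fluorescence rendering --------------------------------------
    light = _point_light((h, w), config.light_sigma)
    fluor = np.zeros((config.n_frames, h, w), np.float32)
    for t in range(config.n_frames):
        signal = np.zeros((h, w), np.float32)
        frame = masks[t]
        for node in graph.nodes_in_frame(t):
            _, label = node
            if lineage_of[label] in transfected:
                signal[frame == label] = 180.0
        signal = ndimage.gaussian_filter(signal, 1.0) * light
        fluor[t] = 8.0 + signal + rng.normal(0, 3.0, (h, w))
    fluorescence = np.clip(fluor, 0, 255).astype(np.uint8)

    return GroundTruthMovie(
        brightfield=brightfield,
        fluorescence=fluorescence,
        masks=masks,
        tracks=graph,
        transfected_ids=transfected,
        lineage_of=lineage_of,
    )


def count_fluorescent_markers(movie: GroundTruthMovie, frame_index: int) -> int:
    """Number of GT markers in a frame that belong to transfected lineages."""
    if not 0 <= frame_index < movie.n_frames:
        raise IndexError(f"frame {frame_index} out of range")
    labels = np.unique(movie.masks[frame_index])
    return int(
        sum(
            1
            for lab in labels
            if lab != 0 and movie.lineage_of[int(lab)] in movie.transfected_ids
        )
    )
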