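"""Detection and tracking accuracy measures based on acyclic oriented graph
matching (AOGM), as used by the Cell Tracking Challenge, plus plain
detection statistics.

A ground-truth marker is *matched* by a predicted marker iff the prediction
covers strictly more than half of the marker's pixels; because majority
coverage is exclusive, each GT marker has at most one matching prediction,
while one prediction may match several GT markers (each extra match is a
*split* event).  The editing costs are

    FN node 10, FP node 1, split node 5,
    redundant edge (delete) 1, missing edge (add) 1.5, wrong-semantics edge 1,

and the normalised scores are

    DET = 1 − min(AOGM_D, AOGM_D0) / AOGM_D0,   AOGM_D0 = 10 · |GT nodes|
    TRA = 1 − min(AOGM,   AOGM0)   / AOGM0,     AOGM0 = 10 · |GT nodes| + 1.5 · |GT edges|

where AOGM_D counts node errors only and AOGM adds the edge errors.  An
edge has wrong semantics when its link type (track continuation versus
parent→daughter division link) disagrees between the two graphs.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np

from .tracker import Node, TrackGraph

#: AOGM editing weights (CTC convention); exposed for configurability.
WEIGHTS = {
    "fn_node": 10.0,
    "fp_node": 1.0,
    "split_node": 5.0,
    "edge_delete": 1.0,
    "edge_add": 1.5,
    "edge_semantics": 1.0,
}


@dataclass
class ErrorCounts:
    fn_nodes: int = 0
    fp_nodes: int = 0
    split_nodes: int = 0
    edges_to_delete: int = 0
    edges_to_add: int = 0
    edges_wrong_semantics: int = 0

    def node_cost(self, weights=None) -> float:
        w = weights or WEIGHTS
        return (
            w["fn_node"] * self.fn_nodes
            + w["fp_node"] * self.fp_nodes
            + w["split_node"] * self.split_nodes
        )

    def total_cost(self, weights=None) -> float:
        w = weights or WEIGHTS
        return self.node_cost(w) + (
            w["edge_delete"] * self.edges_to_delete
            + w["edge_add"] * self.edges_to_add
            + w["edge_semantics"] * self.edges_wrong_semantics
        )


@dataclass
class FrameMatch:
    """Majority-coverage matching for one frame."""

    gt_to_pred: dict[int, int]  # gt label -> covering pred label
    fn: list[int]  # unmatched gt labels
    fp: list[int]  # pred labels covering no gt marker
    splits: int  # sum over preds of (matched gt count - 1)
    tp: int  # matched gt markers


@dataclass
class MetricsReport:
    det: float
    tra: float
    precision: float
    recall: float
    f_measure: float
    nfn_per_image: float
    nfp_per_image: float
    per_frame: list[FrameMatch] = field(default_factory=list)

    def as_dict(self) -> dict[str, float]:
        return {
            "DET": self.det,
            "TRA": self.tra,
            "precision": self.precision,
            "recall": self.recall,
            "f_measure": self.f_measure,
            "nfn_per_image": self.nfn_per_image,
            "nfp_per_image": self.nfp_per_image,
        }


def match_markers(gt_frame: np.ndarray, pred_frame: np.ndarray) -> FrameMatch:
    """Match one GT frame against one predicted frame.

    ``pred`` matches ``gt`` iff |pred ∩ gt| > 0.5·|gt|.  Majority coverage
    makes the match unique per GT marker; a prediction matching k > 1 GT
    markers contributes k − 1 split events.
    """
    gt_frame = np.asarray(gt_frame)
    pred_frame = np.asarray(pred_frame)
    if gt_frame.shape != pred_frame.shape:
        raise ValueError("frames must share geometry")
    gt_labels = np.unique(gt_frame)
    gt_labels = gt_labels[gt_labels != 0]
    pred_labels = np.unique(pred_frame)
    pred_labels = pred_labels[pred_labels != 0]

    # joint histogram of (gt, pred) label pairs
    k = int(pred_frame.max()) + 1
    joint = gt_frame.astype(np.int64) * k + pred_frame.astype(np.int64)
    counts = np.bincount(joint.ravel(), minlength=(int(gt_frame.max()) + 1) * k)
    gt_areas = np.bincount(gt_frame.ravel())

    gt_to_pred: dict[int, int] = {}
    for g in gt_labels:
        row = counts[g * k : (g + 1) * k]
        covering = np.nonzero(row > 0.5 * gt_areas[g])[0]
        covering = covering[covering != 0]
        if covering.size:
            gt_to_pred[int(g)] = int(covering[0])
    matched_preds: dict[int, int] = {}
    for p in gt_to_pred.values():
        matched_preds[p] = matched_preds.get(p, 0) + 1
    fn = [int(g) for g in gt_labels if int(g) not in gt_to_pred]
    fp = [int(p) for p in pred_labels if int(p) not in matched_preds]
    splits = sum(c - 1 for c in matched_preds.values())
    return FrameMatch(gt_to_pred, fn, fp, splits, tp=len(gt_to_pred))


def _match_sequences(gt_masks, pred_masks) -> list[FrameMatch]:
    gt_masks = np.asarray(gt_masks)
    pred_masks = np.asarray(pred_masks)
    if gt_masks.shape != pred_masks.shape:
        raise ValueError("sequences must share geometry")
    return [match_markers(gt_masks[t], pred_masks[t]) for t in range(gt_masks.shape[0])]


def _node_errors(matches: list[FrameMatch]) -> ErrorCounts:
    err = ErrorCounts()
    for m in matches:
        err.fn_nodes += len(m.fn)
        err.fp_nodes += len(m.fp)
        err.split_nodes += m.splits
    return err


def det_score(
    gt_masks: np.ndarray,
    pred_masks: np.ndarray,
    weights: dict | None = None,
) -> float:
    """Normalised node-matching score; 1 is perfect, 0 is an empty result."""
    matches = _match_sequences(gt_masks, pred_masks)
    n_gt = sum(len(m.fn) + m.tp for m in matches)
    if n_gt == 0:
        raise ValueError("DET undefined: ground truth contains no markers")
    w = weights or WEIGHTS
    aogm_d = _node_errors(matches).node_cost(w)
    aogm_d0 = w["fn_node"] * n_gt
    return 1.0 - min(aogm_d, aogm_d0) / aogm_d0


def _edge_errors(
    matches: list[FrameMatch],
    gt_graph: TrackGraph,
    pred_graph: TrackGraph,
) -> tuple[int, int, int]:
    """(edges_to_delete, edges_to_add, edges_wrong_semantics)."""

    def pred_node_for(gt_node: Node) -> Node | None:
        t, label = gt_node
        p = matches[t].gt_to_pred.get(label)
        return (t, p) if p is not None else None

    ea = 0
    ec = 0
    used_pred_edges: set[tuple[Node, Node]] = set()
    for gu, gv in gt_graph.edges():
        pu, pv = pred_node_for(gu), pred_node_for(gv)
        if pu is None or pv is None or not pred_graph.has_edge(pu, pv):
            ea += 1
            continue
        used_pred_edges.add((pu, pv))
        if gt_graph.edge_kind(gu, gv) != pred_graph.edge_kind(pu, pv):
            ec += 1
    ed = len(pred_graph.edges()) - len(used_pred_edges)
    return ed, ea, ec


def tra_score(
    gt_masks: np.ndarray,
    gt_graph: TrackGraph,
    pred_masks: np.ndarray,
    pred_graph: TrackGraph,
    weights: dict | None = None,
) -> float:
    """Normalised node+edge graph-matching score; 1 is perfect."""
    matches = _match_sequences(gt_masks, pred_masks)
    n_gt = sum(len(m.fn) + m.tp for m in matches)
    if n_gt == 0:
        raise ValueError("TRA undefined: ground-truth graph is empty")
    w = weights or WEIGHTS
    err = _node_errors(matches)
    err.edges_to_delete, err.edges_to_add, err.edges_wrong_semantics = _edge_errors(
        matches, gt_graph, pred_graph
    )
    aogm = err.total_cost(w)
    aogm0 = w["fn_node"] * n_gt + w["edge_add"] * len(gt_graph.edges())
    return 1.0 - min(aogm, aogm0) / aogm0


def detection_stats(
    gt_masks: np.ndarray, pred_masks: np.ndarray
) -> tuple[float, float, float, float, float]:
    """(precision, recall, F-measure, N_fn/image, N_fp/image).

    Zero denominators (e.g. an empty prediction) yield 0 with a warning.
    """
    matches = _match_sequences(gt_masks, pred_masks)
    tp = sum(m.tp for m in matches)
    fp = sum(len(m.fp) for m in matches)
    fn = sum(len(m.fn) for m in matches)
    n_frames = len(matches)

    def ratio(num, den, name):
        if den == 0:
            warnings.warn(f"{name} undefined (zero denominator); reporting 0")
            return 0.0
        return num / den

    precision = ratio(tp, tp + fp, "precision")
    recall = ratio(tp, tp + fn, "recall")
    f = ratio(2 * precision * recall, precision + recall, "f_measure")
    return precision, recall, f, fn / n_frames, fp / n_frames


def evaluate_sequences(
    gt_masks: np.ndarray,
    pred_masks: np.ndarray,
    gt_graph: TrackGraph | None = None,
    pred_graph: TrackGraph | None = None,
    weights: dict | None = None,
) -> MetricsReport:
    """Full report for one evaluation run; TRA is NaN when graphs are absent."""
    matches = _match_sequences(gt_masks, pred_masks)
    det = det_score(gt_masks, pred_masks, weights)
    if gt_graph is not None and pred_graph is not None:
        tra = tra_score(gt_masks, gt_graph, pred_masks, pred_graph, weights)
    else:
        tra = float("nan")
    precision, recall, f, nfn, nfp = detection_stats(gt_masks, pred_masks)
    return MetricsReport(det, tra, precision, recall, f, nfn, nfp, matches)
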