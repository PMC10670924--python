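# weaktrack

Weakly supervised cell detection and tracking for time-lapse brightfield
microscopy with **incomplete** annotations.

## The problem

In live-cell experiments with partially transfected populations (e.g.
fibroblasts during iPS reprogramming), only the cells carrying a
fluorescent reporter can be annotated automatically from the paired
fluorescence channel: each lit nucleus yields a marker, every dark cell
yields nothing.  Such labels have precision ≈ 1 but recall equal to the
transfection fraction — useless as ground truth, yet far cheaper than
manual annotation.  `weaktrack` treats them as *pseudo-ground truth* and
refines them while training the detector they supervise:

    for each of n iterations (default 10):
        train the U-Net on the current pseudo-GT        (≤ 100 Adam updates)
        predict each frame over 8 contrast variants      (×0.8 … ×1.5)
        fuse the 8 probability maps with weight 1/8, binarise
        union the prediction with the pseudo-GT          (never lose a marker)
        track the union by mask overlap                  (threshold 0.1)
        prune short non-associable trajectories          (α = 3, β = 5)

Tracking is the supervision signal that ordinary self-training lacks:
impurities and bubbles look like cells in a single frame but live only a
frame or two, so trajectory length separates them from real cells.  A
candidate track shorter than α frames is deleted unless a gap search
(3× dilation, overlap ≥ 0.1 against orphan markers in the next β frames)
re-associates it.

Detections and lineages are scored with the Cell Tracking Challenge's
graph-matching measures

    DET = 1 − min(AOGM_D, AOGM_D0) / AOGM_D0        (nodes only)
    TRA = 1 − min(AOGM,   AOGM0)   / AOGM0          (nodes + edges)

with editing weights FN 10, FP 1, split 5, edge-delete 1, edge-add 1.5,
wrong-semantics 1, plus precision/recall/F-measure and per-image FN/FP
counts.

Everything runs at desk scale on synthetic movies from the built-in
generator (paired brightfield/fluorescence channels, point-light
illumination falloff, partial transfection, divisions, impurity blobs,
exact ground-truth masks and lineage graphs).  The detector is a numpy
U-Net — no deep-learning framework required.

## Worked example

`examples/02_initial_labels.py` builds a 10-frame movie of 12 cells in
which only some lineages fluoresce, and runs the fluorescence labelling
pipeline (CLAHE → bilateral → threshold → small-object removal):

```
transfected markers: 40/120 = 0.333 (upper bound on recall)
precision 1.000  (markers we found are real cells)
recall    0.333  (dark, untransfected cells cannot be labelled)
DET       0.333
after thinning to 50%: recall 0.167
```

Every marker found is a real cell, but two thirds of the cells are
invisible — the starting point of the refinement loop.
`examples/04_refinement_loop.py` then runs the full loop from labels
thinned to 50 % of the ground truth and prints the per-iteration label
quality (seed 1):

```
iter  markers  added  removed   DET    recall
   0      161      0        0  0.559  0.559
   ...
   7      278    127        6  0.931  0.951
  10      278      7        7  0.983  1.000
inference on the movie with the trained model: DET 0.993 TRA 0.992
```

DET climbs from the thinned-label level (≈ 0.5) towards 1 as the union
recruits the missing cells and tracking prunes short-lived false
positives.
`examples/03_tracking_and_metrics.py` demonstrates the tracker and the
metrics on a movie with divisions:

```
tracked 10 lineage segments (generator truth: 10)
self-evaluation: DET 1.000 TRA 1.000
after deleting 30% of markers: DET 0.640 TRA 0.615 recall 0.640 N_fn/image 3.6
```

## Acceptance script

```bash
python scripts/acceptance.py --seed 1 --out results/acceptance.json
```

recomputes the package's end-to-end behaviour from scratch: it generates
a synthetic movie, derives initial labels from the fluorescence channel,
runs the full refinement benchmark (10 iterations, tracking assistance
on) and prints the initial and final pseudo-GT DET, then writes the
machine-readable target values to `--out`.

## Layout

| module | contents |
| --- | --- |
| `weaktrack.simulate` | synthetic movie generator with ground truth |
| `weaktrack.labels` | fluorescence → initial pseudo-GT pipeline, thinning |
| `weaktrack.augment` | contrast-ladder augmentation (lazy dataset) |
| `weaktrack.detector` / `nnet` | numpy U-Net, Adam/BCE training, prediction |
| `weaktrack.tracker` | overlap linking, lineage graphs, CTC track records |
| `weaktrack.correction` | short-track pruning with gap association |
| `weaktrack.loop` | the refinement loop and test-time inference |
| `weaktrack.metrics` | AOGM-based DET/TRA, detection statistics |
| `weaktrack.io_ctc` | CTC-layout TIFF/track-file I/O, config files |
| `weaktrack.benchmark` | the desk-scale end-to-end benchmark |

Methodological details, parameter defaults and known limitations are in
[docs/methods.md](docs/methods.md).
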