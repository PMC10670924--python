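# Methods

## Problem setting

Time-lapse brightfield microscopy of partially transfected cell
populations (e.g. fibroblasts undergoing iPS reprogramming) yields movies
in which only the lineages carrying a fluorescent reporter can be
annotated automatically — the paired fluorescence channel shows a
nucleus-sized spot for each transfected cell and nothing for the rest.
Labels derived from fluorescence are therefore *incomplete*: essentially
every marker is a real cell (precision ≈ 1), but a large fraction of
cells has no marker at all.  `weaktrack` implements a weakly supervised
procedure that starts from such incomplete pseudo-ground truth (pseudo-GT)
and refines it while training a cell detector, using cell *tracking* to
control the false positives that refinement introduces.

## The refinement loop

One run consists of `n_iterations` (default 10) rounds of:

1. **Train.**  A binary U-Net segmenter is trained on the current
   pseudo-GT over a contrast-augmented dataset (each frame × each factor
   of the ladder 0.8 … 1.5, step 0.1 — 8 variants).  Training within one
   round is capped at `max_updates_per_iteration` (default 100) Adam
   updates of binary cross-entropy; the deliberately small budget keeps
   the model from fitting the pseudo-GT's false negatives too closely.
2. **Predict + fuse.**  Every frame is predicted once per contrast
   variant and the eight probability maps are averaged with equal weight
   (1/8 each), then binarised at `fuse_threshold`.
3. **Union.**  The binarised prediction is OR-ed with the current
   pseudo-GT and re-labelled by connected components (8-connectivity).
   Union never discards an existing marker, so label recall is
   non-decreasing except where the correction step removes markers.
4. **Track + prune** (skippable for the ablation).  The union sequence is
   linked frame-to-frame by mask overlap and trajectories shorter than
   `alpha` frames that cannot be re-associated within the next `beta`
   frames are deleted from the pseudo-GT.

The result seeds the next round; iteration 0 denotes the initial labels.

## Initial labels from fluorescence

Point-light illumination concentrates intensity mid-frame, so no global
threshold separates dim peripheral nuclei from bright central background.
The pipeline is CLAHE (tile 32 px, clip 0.02 in scikit-image's fractional
convention) → bilateral filter (window 9, σ_color 0.1 on the [0, 1]
scale, σ_space 3 px) → fixed threshold (default 0.5 on the equalised
image; `suggest_threshold` sweeps candidates and picks the marker-count
plateau, mimicking how an operator chooses it manually) → removal of
components below `min_area` (20 px²).  Markers are frame-local connected
components; there is deliberately no tracking at this stage.

`subsample_labels` emulates "X% of markers" experiments by frame-wise
Bernoulli thinning; it never creates markers, and the recall of the
thinned labels against the originals concentrates tightly around the
keep fraction.

## Tracking by detection

Linking uses the asymmetric overlap of consecutive-frame masks,

    overlap(A_t, A_{t+1}) = |A_t ∩ A_{t+1}| / |A_t| ,

with the earlier mask dilated once (3×3 structuring element) before the
ratio is formed; after dilation the *dilated* area is the denominator.
Candidates with overlap ≥ 0.1 are assigned greedily by descending
overlap; each later marker takes at most one parent and each earlier
marker at most two successors (a division).  Ties break toward the lower
marker id, which makes linking fully deterministic.  CTC-style track
records are compiled from maximal single-child chains; both daughters of
a division start new tracks carrying the parent's id.

## Tracking-assisted correction

False-positive detections (impurities, bubbles) produce trajectories
much shorter than real cells.  A track is removed when all of the
following hold: it spans fewer than `alpha` = 3 frames; it neither starts
at frame 0 nor ends at the last frame; none of its masks intersects the
border band (width = `border_margin`, default 2 × the median equivalent
marker radius of the movie); it has no parent and no daughters (it is not
already part of a lineage); and a rescue search fails.  The rescue
dilates the track's last mask three times and scans the following
`beta` frames (5 by default, 8 in the strong-contrast preset) for a
parentless marker with overlap ≥ 0.1; the earliest qualifying frame wins
and the track is spliced to it across the gap, after which its length is
re-measured.  Removal is idempotent and never adds markers.

## Evaluation

Matching follows the majority-coverage rule: a prediction matches a GT
marker iff it covers strictly more than half of the marker's pixels,
which makes the match unique per GT marker.  Editing costs are FN 10,
FP 1, split 5, edge-delete 1, edge-add 1.5, wrong-edge-semantics 1
(an edge's semantics is its link type: track continuation versus
parent→daughter).  DET normalises node costs by the cost of building the
GT nodes from scratch (10 per node); TRA additionally counts edge costs
and normalises by 10·|nodes| + 1.5·|edges|.  Precision, recall, F-measure
and the per-image FN/FP counts come from the same matching.  Zero
denominators (empty predictions) are reported as 0 with a warning.

## Synthetic movies

The generator produces the statistical structure the method assumes and
nothing more: elliptical nucleus-sized cells (radius 5–10 px) on a
smoothed-noise background, Gaussian random-walk motion with pairwise
collision resolution so GT markers stay disjoint, divisions into exactly
two daughters (a division is cancelled, and the cell simply persists,
when a conservative disc-intersection bound shows overlap linking could
not recover the parent→daughter edge — the generator must not emit
lineages the method's own assumptions declare untrackable), short-lived
impurity blobs rendered into the brightfield channel only and never
intersecting GT masks, and a fluorescence channel in which only a
Bernoulli-sampled fraction of lineages is lit, modulated by a Gaussian
point-light profile centred mid-frame.  Brightfield cell contrast is low
(≈ 14 % of the 8-bit range over a textured background) so detection is a
learning problem.  All stochastic draws flow from one seeded generator;
movies are bit-identical for a fixed seed.

What the generator does **not** emulate: optics (PSF, defocus), photo-
bleaching, intensity variation between cells of one movie, cell shape
change, fusion, or multi-division.  A green test on synthetic data
therefore establishes the *logic* of the pipeline (label refinement,
linking, pruning, scoring), not performance on real microscopy.

## Desk-scale choices and numerical notes

* **Detector.**  The environment provides no deep-learning framework, so
  the U-Net (depth-4 encoder of two 3×3 convolutions + max-pool per
  block, symmetric deconvolution decoder with skip concatenation,
  sigmoid head) is implemented directly on numpy with im2col/GEMM
  convolutions and hand-derived backprop, verified against finite
  differences.  Channel widths are free parameters and the parameter
  count is explicitly not a contract; any object with `forward/backward/params` plugs in
  as an alternative detector.
* **Scale.**  The end-to-end benchmark runs 128×128 frames, 12 founder
  cells, 24 frames, a depth-3/8-channel U-Net on 64 px crops, and the
  full-scale 10 × ≤100-update schedule, with the learning rate raised
  from 1e-4 to 3e-3 to compensate for the much smaller model and pixel
  budget.  A higher rate (5e-3) converges so fast that the transient
  generalisation the bootstrap relies on disappears; 3e-3 is the
  documented compromise.
* **Fused-map binarisation.**  With identical-looking synthetic cells
  and a fraction *f* of markers kept, the converged foreground
  probability of an unlabelled cell is ≈ *f* (the detector cannot tell
  labelled from unlabelled cells apart), so binarising at 0.5 sits on a
  knife edge when *f* = 0.5.  The benchmark therefore fuses at a
  threshold below that asymptote; the library default stays at 0.5.
* **Degenerate-prediction guards.**  Predicted components smaller than
  `min_marker_area` (20 px², the same nucleus-noise cutoff the
  fluorescence pipeline uses) are discarded, and a predicted frame whose
  foreground exceeds `max_union_fraction` (0.5, the generator's own
  overcrowding bound) contributes nothing to the union.  Both guards
  neutralise half-trained-detector output that a full-scale setting
  never exhibits (speckle at the sigmoid midpoint; whole-frame
  floods during warm-up).
* **Determinism.**  Every stochastic component (simulation, thinning,
  weight init, shuffling, cropping) draws from seeded generators;
  repeated runs are bit-identical on one machine.

## Known limitations

* The synthetic world's cells share one appearance, which makes the
  recruitment dynamics of the loop *harder* than on real data (the
  detector cannot memorise individual labelled cells) and the
  tracking-assistance effect *smaller* (there is little short-lived
  structured noise for correction to remove).  In the benchmark both the
  with-tracking and the without-tracking arm end with label recall 1.0,
  and their final DET difference (±0.01, either sign depending on seed)
  is carried by split events — union components bridging adjacent
  cells — and by persistent texture-noise detections whose trajectories
  are long, which trajectory-length pruning cannot remove *by design*.
  The directional with-versus-without comparison is therefore a
  statistical tie at this scale rather than the clear win reported on
  real data, where incomplete labels carry dense short-lived noise.
* Correction can remove fragments of genuinely tracked cells when
  touching cells merge into one component in some frames, and removes a
  handful of frame-wise-thinned true markers whose gap rescue fails
  (probability 0.5^β per fragment at keep fraction 0.5); at desk scale
  this roughly balances the false positives it removes.
* `overlap` is asymmetric by definition; masks shrinking drastically
  between frames can evade the 0.1 threshold.
* TRA's wrong-semantics accounting distinguishes only track-continuation
  from division edges, the two kinds the data model admits.
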