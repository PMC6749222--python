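# Methods

This note documents the models, conventions and numerical choices behind
`handvein`: what the pipeline assumes, what the synthetic data emulate,
which parameters matter and why their defaults are what they are.

## 1. The verification model

The system is a *verification* (1:1) system: a probe capture is compared
with the claimed subject's enrollment template. Two independent
biometric characteristics are read from one dorsal hand image:

* **hand geometry** — 62 contour-derived measurements (5 finger lengths,
  5×10 finger widths at the fractions 5%, 15%, …, 95% of the tip→base
  segment, 3 fingertip gaps excluding the thumb–index pair, 3 adjacent
  finger-valley gaps, 1 palm width), all Euclidean pixel distances;
* **dorsal vein minutiae** — bifurcations (skeleton crossing number ≥ 3)
  and vessel exits (crossing number 1 at the border) of the vein network
  inside the dorsum region of interest (ROI).

Scores are dissimilarities. Each metric is min-max normalized over the
comparison batch (in batch evaluation: all genuine+impostor comparisons;
in single-probe verification: the probe against all enrolled templates),
the Hamming and modified-Hausdorff scores are averaged, and the claim is
accepted when the fused score is ≤ 0.5 (boundary inclusive). Fusing at
score level assumes the two modalities err independently; the synthetic
experiments bear this out (the fused EER undercuts both constituents).

## 2. Geometry conventions

All arrays are (row, col) with row 0 at top. Every neighbourhood
operation replicates the edge pixels beyond the border, so no artificial
dark frame can contaminate thresholding. Measurements are taken in the
original image frame along pose-aware rays: the hand's axis is estimated
(principal axis of the silhouette, sign fixed by the lower area density
of the finger side, then refined from the middle/ring finger axes once
the valleys are known) and lengths/widths are ray-marched with bilinear
silhouette sampling at 0.25 px steps. This makes translation invariance
exact and avoids the interpolation loss of resampling the image to a
canonical pose; in-plane rotations up to ±10° cost <1% feature error.

Landmark sub-pixel details that matter at the 2 px accuracy level:

* a circular fingertip cap has *constant* contour curvature, so the
  maximum-curvature criterion has a plateau; the tip is the centroid of
  the plateau's extremal points along the hand axis, with the apex row
  refined from the spans of the top two contour rows
  (`d₁ = s₁²/(s₂²−s₁²)` for a circle);
* a flat-bottomed finger web makes the deepest convexity defect ambiguous
  along the floor; the valley is the centroid of the floor points
  (within 1.5 px of the lowest point along the axis), pushed half a pixel
  outward because contour pixel centres lie inside the true boundary;
* the finger-base "reflection" rule (midpoint of a valley and its mirror
  across the finger axis) is implemented as what it is algebraically: the
  orthogonal projection of the valley onto the axis line through the tip.

## 3. Vein pipeline

ROI: top edge spanning valleys 2–4, width = that span, height = 1.4 ×
width toward the wrist, bilinearly derotated so vessels run vertically.
The rectangle is seated 4 px below the web line (`roi_seat`): valley
localisation is pixel-accurate and a crop through the web line samples
inter-finger background, which the inverted threshold would segment as a
false vessel.

Segmentation: median(11) → histogram equalization → adaptive threshold of
the inverted ROI with a *negative* offset (object ⇔ pixel exceeds its
15×15 local mean by 14 grey levels) → median(3) → closing (radius-1
digital disk in the Chebyshev metric, which bridges 2 px gaps) → fill
enclosed pockets < 40 px (a bifurcation wedge must not thin into a loop)
→ drop components < 60 px (noise blobs; a real vessel run is larger).
Thinning is the two-sub-iteration Zhang–Suen scheme, run on an
edge-replicated canvas (pad 8, cropped after) so border-crossing vessels
keep their centerline up to the frame edge; one pixel of any component
the parallel scheme would erase outright is retained, which preserves the
8-connected component count exactly. Spur pruning deletes crossing-number-1
paths shorter than `max_spur` = 10 px up to the first junction, except
ends lying in the border band (true vessel exits). Ending minutiae are
counted on the top/bottom edges by default (`ending_edges`): with a
vertically oriented ROI these are the anatomical vessel exits, whereas
side contacts are clipping artifacts of ROI placement jitter (`"top"` and
`"all"` are available).

Branch criterion: crossing number ≥ 3 (`branch_min_cn`), the standard
reading; adjacent branch pixels within 3 px merge to their centroid, as
thinning can emit several high-crossing pixels at one bifurcation. The
strict `= 4` reading is available but leaves branchings nearly extinct on
thinned skeletons.

Minutiae sets are translation-registered by centroid before
Hausdorff-type matching (`align_minutiae`): nothing fixes the hand pose,
so the ROI shifts a few pixels between captures. Matching ignores the
minutia kind by default; `kind_match` restricts branchings to branchings.

## 4. Key tunables

| parameter | default | unit | role |
|---|---|---|---|
| `hand_tg` | −40 | grey | global threshold = image mean + 40; sits between the background noise tail (~18±5) and the hand (~185) for any plausible hand size |
| `min_depth` | 20 | px | convexity-defect depth filter for valleys |
| `curvature_k` | 15 | contour px | fingertip curvature half-window |
| `cluster_gap` | 16 | px | hull-vertex cluster merge distance (> fingertip cap top-row span, < inter-finger hull gap ≈ 20) |
| `roi_factor` / `roi_seat` | 1.4 / 4 | — / px | ROI aspect and seating |
| `vein_median_large/small` | 11 / 3 | px | smoothing / fragment removal |
| `vein_surrounding`, `vein_tg` | 15, −14 | px, grey | adaptive threshold window and margin, calibrated from measured vein-centerline vs tissue excess distributions on the synthetic cohort (both noise regimes) |
| `max_spur`, `border_band` | 10, 3 | px | spur pruning and ending band |
| `sigma_floor` | 0.5 | px | lower bound on template RMS spreads (coinciding enrollment captures must not zero a σ) |
| `accept_threshold` | 0.5 | — | fused-score accept bound |
| `grid_step` | 0.005 | — | FMR/FNMR threshold grid |

Every field is validated at construction and can be set from a YAML file
(`PipelineConfig.load`).

## 5. The synthetic study

No public dataset matches the acquisition this pipeline assumes, so the
generator *is* the study population. It emulates: a bright hand on a dark
matte background at 640×480/8-bit; five separated fingers; a planar
branching vein network, darker than tissue, inside the dorsum ROI;
per-subject persistent anatomy with small intra-subject jitter between
captures; and per-capture nuisances (pose rotation ±8°, translation
±10 px, optics blur σ 0.7 px, sensor noise σ 5 grey, and a smooth
skin-shading field, σ 5 grey at 18 px correlation — real tissue is not
flat, and a broad ROI histogram is what keeps histogram equalization
gentle).

The phantom is deliberately analytic rather than photorealistic: palm =
axis-aligned rectangle with a flat top edge; fingers = parallel vertical
capsules on that edge (thumb shorter, rooted 20 px below the edge, with a
wider gap). This makes every measured feature *equal by construction* to
the generator parameter — the fingertip is the capsule apex, valleys lie
on the flat top edge, the valley-projection base coincides with the
capsule base — so "parameter recovery" is a meaningful end-to-end test of
segmentation+landmarks+measurement, not of a second geometry model. The
cohort's fingertip-height profile is kept strictly concave across the
hand (margins ≈ 4σ of the length draws plus jitter) so every fingertip is
a convex-hull vertex, which the landmark construction requires.

The vein tree is planned top-down: k = (branchings+1) vessels exit
through the ROI top edge at columns ≥ 17 px apart, and adjacent vessels
merge pairwise at random, well-separated rows until a single trunk leaves
through the bottom. Three renderer-driven constraints are built in, each
traceable to a pipeline property: band widths 6.0–7.2 px (an 11 px median
erases narrower vertical bands); ≥ 17 px between parallel runs (closer
pairs shade the tissue between them under the median filter, and
equalization can turn that shading into a bridge); and wide symmetric-V
bifurcations (~105–130° pairwise angles), because the medial-axis
junction of a Y displaces into the wedge between the outgoing branches by
≈ (w/2)/tan(φ/2) — a straight-through trunk with a shallow tributary
would put the skeleton junction ~6 px from the geometric node, wider V
geometry keeps it within ~2 px.

Ground truth per capture: the exact analytic silhouette, the 62-entry
feature vector implied by the jittered anatomy (cap-region widths use the
circle formula `w(d) = 2√(2rd−d²)`), and the minutiae (branch nodes, and
edge/ROI-border crossings as endings) in image coordinates after jitter
and pose.

What the generator does **not** model — and hence what passing tests do
not show about real data: perspective and out-of-plane pose, skin
wrinkles/hair/texture beyond smooth shading, vein depth-dependent
contrast loss, specular lighting, sensor fixed-pattern noise, and
anatomical correlations between dimensions (all draws are independent).
The reported EERs characterize the pipeline under the stated synthetic
conditions only.

## 6. Evaluation protocol and problem sizes

The default study is 20 subjects × 7 captures (a half-size version of a
40×7 protocol; 40×7 runs in roughly double the time and is a flag away).
Captures 0–1 enroll each subject (template means/spreads + the first
capture's minutiae as vein reference); captures 2–6 are probes scored
against *every* template, giving 100 genuine and 1900 impostor
comparisons. Curves use a 0→1 threshold grid with step 0.005 and linear
interpolation of the FMR/FNMR crossing; if the curves touch over an
interval, the midpoint threshold is reported. A capture whose landmark
detection fails (≲1% at default noise) is skipped with a warning, as on a
real device where acquisition would be repeated.

Representative numbers, recomputed from scratch by
`scripts/acceptance.py --seed 1`: Euclidean EER 2.1%, Hamming 5.5%,
Hausdorff 9.0%, MHV 9.0%, fused (Hamming+MHV) 4.9%; zero-noise anatomy
recovery 0.58 px median error; branch-minutiae recall = precision 0.94 at
a 3 px radius; silhouette IoU 0.989 at default noise. The qualitative
finding — score-level fusion of the two modalities beats each fused
constituent — is stable across seeds.

## 7. Known limitations

* The fused system is only guaranteed (and tested) to dominate its own
  constituents (Hamming, MHV); on this cohort plain Euclidean geometry
  happens to be the single best metric, which a Hamming+MHV fusion cannot
  dominate in general.
* Hamming spreads are estimated from 2 enrollment captures and are
  therefore noisy; `sigma_floor` guards the degenerate case but more
  enrollment captures would materially improve the geometry modality.
* Ending minutiae depend on the ROI convention (scale 1.4× a detected
  valley span), so their absolute positions are less stable than branch
  points; matching relies on centroid registration to absorb this.
* The two-sample evaluation normalizes scores over the whole batch
  (min-max), so a single extreme outlier compresses everyone else's
  scores; robust normalization is out of scope here.
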