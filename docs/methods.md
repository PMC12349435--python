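# Methods

## Problem setting and model

`treerow` addresses instance segmentation of individual trees in dense
planted rows, where canopies of neighboring trees intertwine. The method
assumes each tree is anchored by a near-vertical trunk visible in the lower
part of the image, and reduces the instance problem to geometry: locate the
trunks, extend each trunk's axis upward through the foliage, and place five
foreground prompt points per tree — trunk bottom B, summit T, center C and
two lateral points R/L in a diamond layout — that a prompt-conditioned
segmenter then turns into a mask. The package's contribution is everything
around the segmenter: trunk instancing, the prompt geometry, offline
reference backends, and the evaluation stack.

### Trunk instancing

Foreground pixels of a semantic trunk mask are clustered with DBSCAN on
their (x, y) coordinates (Euclidean metric). Defaults `eps_px = 5`,
`min_pts = 20`, `min_area_px = 200` reflect trunk geometry in row images:
trunks are dense ribbons a handful of pixels wide and tens-to-hundreds of
pixels apart, so the clustering outcome is insensitive to these values over
a wide range; all are exposed on the CLI. Surviving clusters are relabeled
1..k by increasing centroid column so ids are deterministic and match the
left-to-right neighbor search. `subsample_stride > 1` clusters a pixel
subgrid and propagates labels to full resolution by nearest labeled pixel;
this trades exactness at cluster boundaries for speed on large rasters
(pixel-set DBSCAN is quadratic in the worst case) and is off by default.

### Axis fit and angle constraint

The per-trunk regression is column-on-row (`x = a·y + b`, angle
`atan(a)` from the image vertical). The transposed fit would be
ill-conditioned for exactly the near-vertical trunks the method targets.
Per-trunk angles are combined by plain arithmetic mean into the shared row
tilt α — appropriate because tilts in a trellis row are small and
sign-consistent; circular statistics would add nothing at |α| < 10°. The
constraint can be disabled (`shared_angle=False` / `--free-angles`), in
which case each tree keeps its own fitted angle.

B is defined as the point of the constrained axis at the trunk's maximal
pixel row: the trunk mask's own extent is the only anchor available without
depth or ground-plane information.

### Summit estimation

*Supervised*: T = B displaced h pixels along the axis (Euclidean distance,
decreasing y). A summit above the image top is clamped to y = 0 along the
line, with a warning.

*Unsupervised*: the axis is rasterized one pixel per row from B up to the
image top and intersected with a vegetation mask F. The run defining the
tree starts at the first foreground hit at-or-above B — not strictly at B,
because the trunk base is bark, not vegetation, and a literal start-at-B
rule would fail on virtually every real image. The run tolerates off-mask
gaps up to `gap_tolerance_px` rows (default 10, roughly the scale of
branch gaps at typical row-image resolutions); T is the run's topmost
point. Gaps are counted in rows rather than along-line distance; at the
small angles involved the difference is below one pixel per ten rows.

F can be any user-supplied mask (the fidelity path for real data, where a
dedicated vegetation-segmentation tool should be used). The built-in
fallback thresholds the excess-green index ExG = 2g − r − b (channels
normalized to [0, 1]) with Otsu's method; a constant-ExG image is handled
by a fixed positive cut so that trivially green / trivially gray inputs
resolve to all-foreground / all-background.

### Lateral points and borders

R and L sit at C's height, 20% of the horizontal distance from C toward the
neighboring border: `R = (x_c + 0.2·(x_br − x_c), y_c)`,
`L = (x_c − 0.2·(x_c − x_bl), y_c)`. For interior trees the border is the
neighboring trunk's centroid column. For boundary trees two readings are
implemented behind `edge_policy`: `"edge"` (default) uses the image border
itself (0 / width−1); `"half"` uses the midpoint between the centroid and
the border. The neighbor reference is the neighbor's *centroid* column,
not its axis position at C's height; with the shared-angle constraint the
two differ by at most a few pixels at realistic tilts, and the centroid
reading keeps the neighbor span independent of each tree's own C.

Prompt coordinates are floats; rounding (half away from zero) happens only
where a consumer needs integer pixels.

### Segmentation backends and assembly

Backends implement a minimal contract — image plus foreground points in,
one binary mask out, checked for shape and binariness by a wrapper. Two
offline backends ship:

* **oracle** — returns the ground-truth instance receiving the majority of
  the five points (ties: the instance containing C; no hits: empty). It is
  a test instrument: with it, end-to-end error is exactly prompt error.
* **region growing** — from each point, iteratively admits neighboring
  pixels (4- or 8-connected) whose RGB distance to the running region mean
  is within `color_tol` (default 40 of 255·√3), optionally confined to the
  column corridor between the tree's neighbor borders; the five regions
  are unioned. The running mean is updated once per growth wave, which
  makes the operation deterministic and vectorizable. This is a classical
  baseline that makes the pipeline runnable offline — not a stand-in claim
  about any foundation model's behavior.

External promptable models plug in through a subprocess protocol
(image PNG + prompt JSON in, mask PNG out) without touching the library.

Per-tree masks are merged into one instance raster by assigning
multiply-claimed pixels to the tree whose prompt center C is nearest
(ties to the lower label) — deterministic, symmetric in the input order,
and agnostic to how the masks were produced. No mask post-processing is
applied by default; `--keep-largest-component` is available.

### Evaluation

Dice, signed mean error ME (positive = over-segmentation), pixel- and
instance-level precision/recall, and Average Precision are implemented as
stated in the README. Decisions the standard definitions leave open:

* both-empty Dice = 1.0 (the masks agree there is nothing), flagged;
* empty-denominator precision/recall = 1.0 (nothing claimed, nothing wrong);
* instance matching is greedy by descending pairwise Dice at threshold 0.1
  (strictly above), each id used once; the assignment rule is checked
  against an exhaustive optimal-assignment oracle in the tests;
* AP uses all-point interpolation (precision envelope monotonized from the
  right), score ties broken by input order; unscored detectors pass
  score 1 for a degenerate single-point PR curve;
* per-image Dice is the mean over matched trees with unmatched truths
  contributing 0 — reference protocols rarely state this, so it is recorded
  here and in the report header;
* the paired Student t-test uses sample sd (n−1); identical samples give
  (t=0, p=1), a constant nonzero difference gives (±∞, 0), flagged.

## Synthetic scenes: what they emulate, and what they do not

The generator emulates the geometry that makes row segmentation hard:
1–10 trunks per image at configurable spacing (default 90 px ± 6) and
width (6 px), per-scene row tilt drawn from ±10° with ±2° per-tree jitter
(trellis rows lean together; the per-tree spread is what the shared-angle
constraint exploits and is also why an arithmetic mean is the right
combiner), per-tree heights 150–215 px in a 360×260 frame, and canopies
built from tapered ellipses strung along the trunk axis, with left/right
asymmetry (±25%) and a controllable neighbor-overlap fraction. The
canopy's top coincides with the true summit by construction, so the
unsupervised foliage-top scan and the supervised displacement target the
same point. Where canopies overlap, truth ownership goes to the
horizontally nearest trunk axis (ties to the lower label); a tree always
owns its own trunk pixels. Colors make the unsupervised path work by
construction: vegetation is green-dominant over a desaturated
gradient-plus-clutter background, so ExG+Otsu recovers foliage almost
exactly.

Deliberately **not** modeled: photorealistic texture, illumination
variation, harvest state, trellis poles, second-row background trees,
annotation noise. Tests passing on these scenes therefore validate the
geometry and the evaluation machinery — trunk instancing, axis and summit
recovery, prompt layout, metric correctness — but say nothing about how any
particular segmentation model performs on real orchard imagery; that is
exactly why the oracle backend exists (isolating prompt quality) and why
the foreground mask and segmenter are both pluggable.

Default batch sizes used by the statistical checks (100 scenes for
geometry/cluster/summit properties, 8 for the region grower, which
dominates runtime at ~2 s/scene) keep the full suite under a minute while
leaving the measured fractions far from their thresholds.

## Numerical and degenerate-input choices

* Determinism everywhere: one `numpy` Generator per scene seeded from the
  config; batch seeds derived from a master seed; DBSCAN, region growth and
  assembly are deterministic; identical (config, seed) reproduces scenes
  bit-for-bit.
* A trunk whose pixels span a single row is rejected as degenerate
  ("degenerate trunk"); per-tree summit failures are recorded per tree in
  the prompt set rather than aborting the scene.
* Empty masks are legal throughout: clustering an empty mask gives k = 0;
  an empty prompt set warns; evaluation of an empty prediction set yields
  Dice 0 against nonempty truth.
* `n_trees` whose spacing cannot fit the image width is rejected at config
  construction.

## Known limitations

* The trunk-instancing defaults assume roughly nadir-free row views where
  trunks do not overlap in the image; heavily occluded trunks merge.
* The unsupervised summit inherits every defect of the vegetation mask: a
  gap larger than `gap_tolerance_px` truncates the tree; overhanging
  foreign vegetation extends it.
* The region-growing baseline leaks between touching same-color canopies
  unless corridor confinement is on; it is bounded in the tests only on
  non-overlapping scenes.
* Neighbor borders use trunk centroid columns; for strongly leaning rows
  at large C heights the axis-at-height reading could differ visibly. The
  alternative is a one-line change in `horizontal_neighbors` callers.
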