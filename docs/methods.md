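# Methods

## Camera geometry

The camera is an ideal nadir pinhole over flat terrain. The ground sample
distance is computed over the sensor diagonal,

    GSD = 2 H tan(FOV_diag / 2) / sqrt(W² + H_px²),

because consumer-drone spec sheets quote a single diagonal field-of-view
angle for the 4:3 sensor (78.8° for the reference platform). At H = 4 m with
a 4000 × 3000 sensor this gives 1.31 mm/px; any other FOV reading would be a
configuration change, not a different formula. Per-image lens distortion is
ignored — at plot scale each image is used alone, without ortho-rectification
or stitching.

The parallax correction treats the canopy as a single global height h
(default 0.10 m, the measured plot average at the second leaf collar stage).
An object at height h images onto the ground plane at radius |p|·H/(H−h)
from nadir, so the correction scales the apparent centroid by (H−h)/H. The
scale is applied at the canopy top; a `height_fraction` knob (default 1.0)
moves the reference level, e.g. 0.5 for mid-canopy, since the level at which
a leafy rosette's centroid effectively sits is not knowable from one image.
With h = 0 the correction is the identity, and `apparent_position` /
`correct_centroid` are exact inverses (used by the simulator's forward
model).

## Segmentation choices

* **Band normalization** for ExG divides by the bit-depth maximum (255 for
  8-bit) by default; "maximum value of each band" is ambiguous between bit
  depth and the per-image band maximum, and the bit-depth reading is
  deterministic across crops of one scene. The per-image alternative is a
  parameter.
* The 0.1 vegetation threshold is **strict** (`ExG > 0.1`); boundary pixels
  are background.
* **8-connectivity** by default: seedling leaf tips are thin, often diagonal
  structures that 4-connectivity would fragment.
* **Perimeter** is the count of member pixels with at least one 4-neighbour
  outside the object — a simple boundary-pixel count, adequate because only
  the *relative* P/A ratio is ever used.
* Both relative filters are evaluated against the **pre-filter means** in one
  pass, then the dilation merge runs on the surviving mask; merged objects
  recompute area/perimeter/centroid from the union of original (undilated)
  pixels.
* The direction of the published shape filter is ambiguous: read literally,
  removing P/A < 0.3 × mean removes *compact* objects, although the stated
  intent is removing small outliers. Both readings are implemented
  (`shape_filter_mode="literal_less_than"` (default) and `"thin_object"`,
  which removes P/A > mean/0.3); no intent is guessed beyond the switch.

## Row fitting

Each candidate row line performs **one** move-to-mean refinement (the
procedure describes a single move, not iteration to convergence);
`refine_iters` allows more. Membership is re-evaluated against the *moved*
line before assignment, which stops a seed plant sitting at the row edge
from capturing its neighbours' plants; the alternative (keep the initial
collection) is an equally honest reading, but re-evaluation is more stable.
The default seed policy is `lowest_id` for bitwise reproducibility;
`random` with a seed reproduces the randomized variant. The buffer half-width
is w/2 with a single w = 0.508 m everywhere, including across an optional
planter wheel gap. Rows are infinite lines; the plot boundary is handled
upstream by imaging single plots.

## Matching and spacing evaluation

Matching is greedy nearest-first among all detection–truth pairs within a
5 cm tolerance — about half the smallest interval observed in real stands
(9.4 cm), so a double cannot steal its neighbour's truth point. Greedy was
chosen over optimal assignment for transparency; a test verifies it equals
the brute-force optimum on a thousand small randomized instances drawn from
row-like layouts.

An estimated interval enters the agreement index d_e only when both endpoint
detections are true positives matched to *adjacent* plants in the truth
ordering of one row; intervals spanning a missed plant or touching a false
positive are flagged invalid and excluded. The relative error is reported
both in aggregate (r = d_e / mean measured distance) and per pair
(|d_ie − d_im|/d_im), since the aggregate alone cannot support
distribution statements such as "75% of relative errors below 10%".

## Plot statistics

Stand density divides the detected count by the agronomic plot area
length × n_rows × row_spacing (5 × 6 × 0.508 = 15.24 m²), not the nominal
3 m width — only the agronomic width is consistent with per-row spacing
accounting. Spacing SD is the sample (n−1) standard deviation. The ANOVA and
simple regression delegate to scipy (`f_oneway`, `linregress`); a constant
response is reported as R² = 0 by convention.

## Synthetic scenes

The generator emulates the reference field setup: 5 m plots of six rows at
50.8 cm (optional 60.96 cm wheel gap), target 9.8 plants/m², plants ~10 cm
tall, flights at 4–5 m. Within-row intervals are truncated-Normal with mean
1/(density × row spacing) ≈ 20.1 cm and floor 5 cm; defaults
`spacing_sd = 0.05 m`, `p_missing = 0.03`, `p_double = 0.01` (doubles offset
5–12 cm) were chosen once to reproduce the qualitative character of observed
stands — intervals from below 12 cm to above 40 cm, occasional gaps and
doubles; realized rates were not published, so these are stand-ins.
Confounder defaults are 0.5 weeds/m² and 1.0 residue streaks/m².

The default simulator camera is the study sensor **rotated to portrait**
(3000 × 4000): with the rows along the image vertical, the landscape
orientation cannot contain a 5 m plot at either flight height (3.94 m
vertical footprint at 4 m), so an operator would fly the long axis along the
rows. A `resolution_scale` parameter shrinks the pixel count at fixed FOV
(same footprint, coarser GSD) for fast studies.

Rendering details that matter for interpretation:

* Plants are rosettes of 2–6 elliptical leaves (major axis 3–6 cm) drawn in
  **point-symmetric pairs** about the seed point with 4× supersampled edges,
  at their parallax-displaced apparent positions. Symmetry makes the
  green-pixel centroid coincide with the seed point to a small fraction of a
  pixel — real seedlings are asymmetric, so real centroid noise (and hence
  real d_e, ~1–2 cm in the field) is much larger than the simulator's
  (~0.1 cm). Passing spacing tests therefore validate the *geometry chain*
  (segmentation → correction → projection), not field-level error magnitude.
* Leaf length scales as 1/sqrt(leaf count), so per-plant canopy area is
  narrowly distributed, as in a uniform-stage stand; this is what makes the
  relative area filter safe for true plants while still removing weeds.
* Soil is brown multiscale luminance noise with 2g − r − b < 0 by
  construction; residue streaks are near-grey with slight red excess (ExG
  ≈ −0.01), so the ExG threshold is meaningful by design. A `greenish_residue`
  option renders residue above the ExG threshold to stress the filters.
  An optional global illumination gradient emulates sun/cloud variation
  (off by default).
* Everything is drawn from two `numpy` Generator streams derived from
  `rng_seed` (layout and rendering), so a (plan, camera, seed) triple yields
  a bit-identical image and truth table.

Not modelled: perspective distortion within a plant, canopy overlap between
rows, growth-stage variation, shadows cast by plants, in-row weeds
touching plants, and sensor noise/vignetting. Detection on real imagery will
be harder than on these scenes in all of those respects.

## Problem sizes in the test suite

End-to-end accuracy tests and the acceptance script run the simulator at
`resolution_scale = 0.4` (1200 × 1600 px, GSD ≈ 3.3 mm at 4 m): plants are
then ~30 px across, comfortably above the scale where segmentation behaviour
changes, and a 50–100 scene study completes in about a minute on one core.
All pixel-denominated contracts (e.g. spacing within 2 × GSD on noise-free
scenes) are evaluated at the rendered GSD. The stochastic suite uses 50
seeded scenes under the default noise/confounder conditions; the noise-free
suite uses 100 seeds.

## Known limitations

* The iterative row finder assumes a known row angle and straight rows; it
  will mis-assign plants if the true angle is off by more than a few degrees
  over a 5 m plot, and curved rows are out of scope.
* A double closer than ~12 cm to its neighbour usually merges into one
  object (the plants physically overlap at 10 cm canopy width); the pipeline
  counts one plant and the evaluation discards the affected intervals, which
  matches the published exclusion rule but means very tight doubles are
  systematically undercounted.
* The uniform-height parallax correction biases centroids of plants whose
  true height deviates from the global value; the error grows with distance
  from nadir.
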