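# maizestand

Maize stand counting and plant-to-plant spacing estimation from plot-scale
UAV imagery.

Uneven maize stands — missing plants, doubles, irregular within-row spacing —
can cost grain yield, and detecting them early in the season informs
replanting and management decisions. `maizestand` implements an image-analysis
pipeline that takes a single nadir RGB image of a small plot (a consumer
quadcopter hovering at 4–5 m, ~1–3 mm ground sample distance, plants at the
second leaf collar stage) and returns per-plant positions, crop rows, stand
density and the distribution of within-row plant intervals, together with the
matching-based accuracy metrics used to validate such pipelines and a
synthetic scene generator that provides exact ground truth.

## Method

1. **Vegetation segmentation.** Per pixel, the excess green index
   ExG = (2g − r − b)/(r + g + b) on normalized bands; pixels with
   ExG > 0.1 are vegetation.
2. **Object extraction and refinement.** Connected components become candidate
   plants. Two relative filters remove residue/weed outliers: objects with
   area A < 0.3·Ā or with an outlying perimeter-to-area ratio P/A (thresholds
   are 0.3 × the image means) are dropped. Fragments of one plant are then
   merged when their dilations (10 px × 10 px square structuring element)
   overlap.
3. **Parallax correction.** A plant canopy of height h under a camera at
   height H appears displaced radially from nadir; each object centroid is
   pulled back by the factor (H − h)/H to its true planting position.
4. **Row fitting and spacing.** Rows are found iteratively: seed a line at the
   known row angle through an unassigned centroid, collect centroids within a
   perpendicular buffer of w/2 (w = 50.8 cm row spacing), move the line
   through their mean, and assign; repeat until all centroids have a row.
   Plant-to-plant distance is the gap between perpendicular projections of
   adjacent centroids onto the row line.
5. **Evaluation.** Detections match ground truth one-to-one (greedy
   nearest-first within 5 cm); precision = TP/(TP+FP), recall = TP/(TP+FN).
   Spacing accuracy is the agreement index d_e = Σᵢ|d_ie − d_im|/n over the n
   valid intervals (those not touching a false positive or missed plant), and
   the relative error r = d_e / mean measured distance.

The segmentation step is exposed as a scikit-learn style transformer
(`PlantDetector`) and row finding as a clustering estimator (`CropRowFitter`,
with `fit`/`labels_`), so both compose with sklearn tooling; plain functions
(`detect_plants`, `fit_rows`, …) wrap them.

## Worked example

```python
from maizestand import (ScenePlan, PlotGeometry, analyze_image,
                        default_camera, score_against_truth, simulate_scene,
                        summarize_plot)

cam = default_camera(flight_height=4.0, resolution_scale=0.4)
plan = ScenePlan(rng_seed=7)            # 5 m x 6-row plot, 9.8 plants/m2 target
image, truth = simulate_scene(plan, cam)

result = analyze_image(image, cam)      # segment -> correct -> rows -> spacing
score = score_against_truth(result, truth)
summary = summarize_plot(result.n_plants, result.spacings, PlotGeometry())
```

Printing the fields of `score` and `summary` gives:

```
GSD: 3.29 mm/px
true plants: 146, detected: 145, rows: 6
precision: 0.993, recall: 0.986
stand density: 9.51 plants/m^2
spacing mean: 20.7 cm, SD: 5.3 cm
spacing agreement d_e: 0.04 cm, relative error r: 0.18% over n=138 intervals
```

One plant of 146 was missed (a close pair merged into one object — the same
failure mode seen in real imagery); the 145 detected centroids fall into the
six planted rows, the stand density follows from count over the 15.24 m²
plot area, and the estimated intervals agree with the generator's truth to a
fraction of a pixel.

The same workflow is available from the shell:

```bash
maizestand simulate --config run.yaml --out scene.png --truth truth.csv
maizestand detect   --image scene.png --config run.yaml --out objects.csv
maizestand spacing  --objects objects.csv --config run.yaml --out spacing.csv
maizestand evaluate --image scene.png --truth truth.csv --out eval.json
maizestand report   --evals eval.json --zones zones.csv --out report.csv
```

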