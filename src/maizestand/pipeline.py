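"""End-to-end convenience: image -> detections -> rows -> spacings -> scores."""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .camera import CameraModel
from .evaluate import EvalResult, MatchResult, match_detections, precision, \
    recall, spacing_agreement
from .rows import RowLine, SpacingRecord, fit_rows, spacing_along_rows
from .segment import PlantDetector, PlantObject
from .simulate import TruthTable

__all__ = ["StandResult", "analyze_image", "score_against_truth"]


@dataclass
class StandResult:
    """Everything the pipeline derives from one plot image."""

    objects: list[PlantObject]
    rows: list[RowLine]
    spacings: list[SpacingRecord]

    @property
    def centroids(self) -> np.ndarray:
        return np.array([o.centroid_ground for o in self.objects], dtype=float
                        ).reshape(-1, 2)

    @property
    def n_plants(self) -> int:
        return len(self.objects)


def analyze_image(image: np.ndarray, camera: CameraModel, *,
                  row_angle: float = 90.0, row_spacing: float = 0.508,
                  detector: PlantDetector | None = None,
                  **segmentation_params) -> StandResult:
    """Detect plants, fit crop rows and measure within-row spacings."""
    if detector is None:
        detector = PlantDetector(camera, **segmentation_params)
    objects = detector.detect(image)
    if not objects:
        return StandResult(objects=[], rows=[], spacings=[])
    pts = np.array([o.centroid_ground for o in objects])
    rows = fit_rows(pts, row_angle=row_angle, row_spacing=row_spacing)
    return StandResult(objects=objects, rows=rows,
                       spacings=spacing_along_rows(rows))


@dataclass
class SceneScore:
    match: MatchResult
    precision: float
    recall: float
    spacing: EvalResult | None


def score_against_truth(result: StandResult, truth: TruthTable, *,
                        tolerance: float = 0.05,
                        row_angle: float = 90.0) -> SceneScore:
    """Match detections to a truth table and score counts and spacings."""
    match = match_detections(result.centroids, truth.positions,
                             tolerance=tolerance,
                             truth_ids=truth.frame["plant_id"].tolist())
    spacing = None
    if result.spacings:
        try:
            spacing = spacing_agreement(result.spacings, truth.frame, match,
                                        row_angle=row_angle)
        except ValueError:
            spacing = None
    return SceneScore(match=match, precision=precision(match),
                      recall=recall(match), spacing=spacing)
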