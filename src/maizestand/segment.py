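"""Plant segmentation: excess-green thresholding, object extraction and refinement.

The pipeline separates green vegetation from soil with the excess green index

    ExG = (2 g - r - b) / (r + g + b)

on normalized band values, binarizes at a fixed threshold (0.1 by default),
labels connected components, removes residue/weed outliers with two relative
filters (area and perimeter-to-area ratio, each thresholded at 0.3x the image
mean), and finally merges fragments of single plants whose dilated footprints
overlap (10x10 square structuring element by default).
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
from scipy import ndimage as ndi
from skimage import measure
from sklearn.base import BaseEstimator

from .camera import CameraModel

__all__ = [
    "PlantObject", "PlantDetector",
    "compute_exg", "binarize", "extract_objects", "filter_objects",
    "merge_fragments", "detect_plants", "objects_to_mask", "objects_to_frame",
]

_CROSS = ndi.generate_binary_structure(2, 1)  # 4-neighbourhood


@dataclass
class PlantObject:
    """One segmented connected component (a candidate plant).

    ``centroid_px`` is (col, row), the unweighted mean of member pixel
    coordinates. Ground centroids are filled in by :func:`detect_plants`.
    """

    label: int
    coords: np.ndarray          # (n, 2) array of (row, col) member pixels
    area: int
    perimeter: int
    centroid_px: tuple[float, float]
    centroid_ground_apparent: tuple[float, float] | None = None
    centroid_ground: tuple[float, float] | None = None

    @property
    def shape_ratio(self) -> float:
        """Perimeter-to-area ratio P/A (dimensionless, in pixel units)."""
        return self.perimeter / self.area


def _band_normalizers(image: np.ndarray, normalization: str) -> np.ndarray:
    if normalization == "bit_depth_max":
        if image.dtype == np.uint8:
            m = 255.0
        elif image.dtype == np.uint16:
            m = 65535.0
        else:
            # float imagery is assumed already scaled to [0, 1]
            m = 1.0
        return np.array([m, m, m])
    if normalization == "per_band_image_max":
        m = image.reshape(-1, 3).max(axis=0).astype(float)
        m[m == 0] = 1.0
        return m
    raise ValueError(f"unknown normalization {normalization!r}")


def compute_exg(image: np.ndarray, *, normalization: str = "bit_depth_max") -> np.ndarray:
    """Excess green index per pixel: (2g - r - b) / (r + g + b).

    Bands are normalized per ``normalization`` before the quotient; with equal
    normalizers the result equals the same expression on raw digital numbers.
    Pixels with r + g + b = 0 map to 0. Output lies in [-1, 2].
    """
    image = np.asarray(image)
    if image.ndim != 3 or image.shape[2] != 3:
        raise ValueError("expected an (H, W, 3) RGB image")
    norm = _band_normalizers(image, normalization)
    r = image[..., 0] / norm[0]
    g = image[..., 1] / norm[1]
    b = image[..., 2] / norm[2]
    s = r + g + b
    with np.errstate(divide="ignore", invalid="ignore"):
        exg = np.where(s > 0, (2.0 * g - r - b) / np.where(s > 0, s, 1.0), 0.0)
    return exg


def binarize(exg: np.ndarray, threshold: float = 0.1) -> np.ndarray:
    """Vegetation mask: strictly ``exg > threshold``."""
    return np.asarray(exg) > threshold


def _perimeter_by_label(labels: np.ndarray, n_labels: int) -> np.ndarray:
    """Per-label count of member pixels with a 4-neighbour outside the component.

    Components produced by labelling are never 4-adjacent to one another, so
    eroding the union mask with the cross kernel (background border) marks
    exactly the boundary pixels of every component.
    """
    mask = labels > 0
    interior = ndi.binary_erosion(mask, structure=_CROSS, border_value=0)
    boundary = mask & ~interior
    return np.bincount(labels[boundary], minlength=n_labels + 1)[1:]


def _objects_from_labels(labels: np.ndarray, n_labels: int) -> list[PlantObject]:
    perim = _perimeter_by_label(labels, n_labels)
    objs: list[PlantObject] = []
    for region in measure.regionprops(labels):
        i = region.label
        r_c, c_c = region.centroid
        objs.append(PlantObject(
            label=i,
            coords=region.coords,
            area=int(region.area),
            perimeter=int(perim[i - 1]),
            centroid_px=(float(c_c), float(r_c)),
        ))
    return objs


def extract_objects(mask: np.ndarray, *, connectivity: int = 8) -> list[PlantObject]:
    """Label connected components of a binary mask into PlantObjects."""
    if connectivity not in (4, 8):
        raise ValueError("connectivity must be 4 or 8")
    labels, n = measure.label(np.asarray(mask, dtype=bool),
                              connectivity=1 if connectivity == 4 else 2,
                              return_num=True)
    return _objects_from_labels(labels, n)


def filter_objects(objs: list[PlantObject], *, filter_factor: float = 0.3,
                   shape_filter_mode: str = "literal_less_than") -> list[PlantObject]:
    """Drop outlier objects by the two relative filters.

    Both criteria are evaluated against the means of the *input* list: objects
    with area < ``filter_factor`` x mean area are removed, and the shape
    criterion removes either shape_ratio < factor x mean ratio
    (``literal_less_than``) or shape_ratio > mean ratio / factor
    (``thin_object``).
    """
    if not objs:
        return []
    if shape_filter_mode not in ("literal_less_than", "thin_object"):
        raise ValueError(f"unknown shape_filter_mode {shape_filter_mode!r}")
    mean_area = float(np.mean([o.area for o in objs]))
    mean_ratio = float(np.mean([o.shape_ratio for o in objs]))
    kept = []
    for o in objs:
        if o.area < filter_factor * mean_area:
            continue
        if shape_filter_mode == "literal_less_than":
            if o.shape_ratio < filter_factor * mean_ratio:
                continue
        else:
            if o.shape_ratio > mean_ratio / filter_factor:
                continue
        kept.append(o)
    return kept


def objects_to_mask(objs: list[PlantObject], shape: tuple[int, int]) -> np.ndarray:
    """Rasterize object member pixels back into a binary mask."""
    mask = np.zeros(shape, dtype=bool)
    for o in objs:
        mask[o.coords[:, 0], o.coords[:, 1]] = True
    return mask


def merge_fragments(mask: np.ndarray, *, dilation_size: int = 10,
                    connectivity: int = 8) -> list[PlantObject]:
    """Merge fragments of single plants via a dilation overlap test.

    The mask is dilated with a ``dilation_size`` x ``dilation_size`` square;
    original components whose dilated footprints touch are merged into one
    object.  Areas, perimeters and centroids are recomputed from the union of
    the *original* (undilated) pixels.
    """
    mask = np.asarray(mask, dtype=bool)
    if dilation_size < 1:
        raise ValueError("dilation_size must be >= 1")
    footprint = np.ones((dilation_size, dilation_size), dtype=bool)
    dilated = ndi.binary_dilation(mask, structure=footprint)
    lab_dil, n = measure.label(dilated, connectivity=1 if connectivity == 4 else 2,
                               return_num=True)
    labels = np.where(mask, lab_dil, 0)
    # relabel consecutively in case a dilated component holds no original pixel
    return [o for o in _objects_from_labels(labels, n) if o.area > 0]


@dataclass
class _SegmentationParams:
    exg_threshold: float = 0.1
    filter_factor: float = 0.3
    dilation_size: int = 10
    normalization: str = "bit_depth_max"
    connectivity: int = 8
    shape_filter_mode: str = "literal_less_than"


class PlantDetector(BaseEstimator):
    """End-to-end plant detector for one nadir plot image.

    A stateless scikit-learn style transformer: ``fit`` only validates
    parameters; :meth:`detect` (or ``transform``) maps an RGB image to a list
    of :class:`PlantObject` with parallax-corrected ground centroids.

    Parameters
    ----------
    camera : CameraModel
        Geometry used to convert pixel centroids to metric ground positions
        and to apply the plant-height parallax correction.
    exg_threshold : float, default 0.1
        Vegetation threshold on the excess green index (strict ``>``).
    filter_factor : float, default 0.3
        Relative factor for the area and shape filters.
    dilation_size : int, default 10
        Side of the square structuring element used for fragment merging.
    normalization : {"bit_depth_max", "per_band_image_max"}
        Band normalization applied before the ExG quotient.
    connectivity : {4, 8}, default 8
        Pixel connectivity for component labelling.
    shape_filter_mode : {"literal_less_than", "thin_object"}
        Direction of the perimeter/area filter.
    """

    def __init__(self, camera: CameraModel | None = None, *,
                 exg_threshold: float = 0.1, filter_factor: float = 0.3,
                 dilation_size: int = 10, normalization: str = "bit_depth_max",
                 connectivity: int = 8,
                 shape_filter_mode: str = "literal_less_than"):
        self.camera = camera
        self.exg_threshold = exg_threshold
        self.filter_factor = filter_factor
        self.dilation_size = dilation_size
        self.normalization = normalization
        self.connectivity = connectivity
        self.shape_filter_mode = shape_filter_mode

    def _validate(self):
        if self.filter_factor <= 0:
            raise ValueError("filter_factor must be > 0")
        if self.dilation_size < 1:
            raise ValueError("dilation_size must be >= 1")
        if self.connectivity not in (4, 8):
            raise ValueError("connectivity must be 4 or 8")
        _band_normalizers(np.zeros((1, 1, 3), dtype=np.uint8), self.normalization)
        if self.shape_filter_mode not in ("literal_less_than", "thin_object"):
            raise ValueError(f"unknown shape_filter_mode {self.shape_filter_mode!r}")

    def fit(self, X=None, y=None):
        self._validate()
        self.is_fitted_ = True
        return self

    def detect(self, image: np.ndarray) -> list[PlantObject]:
        """Run the full segmentation chain on one RGB image."""
        self._validate()
        exg = compute_exg(image, normalization=self.normalization)
        mask = binarize(exg, self.exg_threshold)
        objs = extract_objects(mask, connectivity=self.connectivity)
        if not objs:
            return []
        objs = filter_objects(objs, filter_factor=self.filter_factor,
                              shape_filter_mode=self.shape_filter_mode)
        kept_mask = objects_to_mask(objs, mask.shape)
        merged = merge_fragments(kept_mask, dilation_size=self.dilation_size,
                                 connectivity=self.connectivity)
        if self.camera is not None:
            for o in merged:
                col, row = o.centroid_px
                xa, ya = self.camera.pixel_to_ground(col, row, strict=False)
                o.centroid_ground_apparent = (xa, ya)
                o.centroid_ground = self.camera.correct_centroid(xa, ya)
        return merged

    def transform(self, X: np.ndarray) -> list[PlantObject]:
        return self.detect(X)


def detect_plants(image: np.ndarray, camera: CameraModel,
                  **params) -> list[PlantObject]:
    """Functional wrapper over :class:`PlantDetector`."""
    return PlantDetector(camera, **params).detect(image)


def objects_to_frame(objs: list[PlantObject]):
    """Tabulate detections as a DataFrame (one row per object)."""
    import pandas as pd

    rows = []
    for o in objs:
        x, y = o.centroid_ground if o.centroid_ground is not None else (np.nan, np.nan)
        rows.append({
            "label": o.label, "area_px": o.area, "perimeter_px": o.perimeter,
            "centroid_col": o.centroid_px[0], "centroid_row": o.centroid_px[1],
            "x_m": x, "y_m": y,
        })
    return pd.DataFrame(rows, columns=["label", "area_px", "perimeter_px",
                                       "centroid_col", "centroid_row", "x_m", "y_m"])
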