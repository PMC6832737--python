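"""Nadir pinhole-camera geometry for low-altitude plot imagery.

A consumer quadcopter hovering a few metres above a plot approximates a
pinhole camera looking straight down.  Three geometric services are needed
by the rest of the pipeline:

* the ground sample distance (GSD) — ground size of one pixel — from flight
  height, diagonal field of view and sensor pixel counts;
* an affine map between pixel indices and metric ground coordinates with the
  origin at the nadir point (the image centre);
* the parallax correction: a plant canopy sits above the ground plane, so its
  image is displaced radially *away* from nadir.  For a canopy of uniform
  height ``h`` under a camera at height ``H`` the apparent ground position is
  the true position magnified by ``H / (H - h)``; the correction divides it
  back out.

The ground frame: ``x`` increases along image columns (east), ``y`` increases
with *decreasing* row index (north).  Pixel centres sit at integer indices,
0-based, so the nadir pixel is ``((w-1)/2, (h-1)/2)``.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np

__all__ = ["CameraModel", "ground_sample_distance", "pixel_to_ground",
           "ground_to_pixel", "correct_centroid", "apparent_position"]


@dataclass(frozen=True)
class CameraModel:
    """Flight and sensor geometry of one nadir image.

    Parameters
    ----------
    flight_height : float
        Camera height above the ground plane, metres. Must exceed ``plant_height``.
    fov_diagonal : float
        Diagonal field-of-view angle, degrees, in (0, 180).
    image_width, image_height : int
        Sensor size in pixels.
    plant_height : float
        Uniform canopy height used by the parallax correction, metres.
    height_fraction : float
        Fraction of ``plant_height`` at which the correction is evaluated.
        1.0 corrects at the canopy top; 0.5 would correct at mid-canopy.
    """

    flight_height: float
    fov_diagonal: float = 78.8
    image_width: int = 4000
    image_height: int = 3000
    plant_height: float = 0.10
    height_fraction: float = 1.0

    def __post_init__(self) -> None:
        if not (0.0 < self.fov_diagonal < 180.0):
            raise ValueError(f"fov_diagonal must be in (0, 180), got {self.fov_diagonal}")
        if self.image_width <= 0 or self.image_height <= 0:
            raise ValueError("image dimensions must be positive")
        if self.plant_height < 0:
            raise ValueError("plant_height must be >= 0")
        if not (0.0 <= self.height_fraction <= 1.0):
            raise ValueError("height_fraction must be in [0, 1]")
        if self.flight_height <= self.effective_plant_height:
            raise ValueError(
                f"flight_height ({self.flight_height} m) must exceed the effective "
                f"plant height ({self.effective_plant_height} m)")

    # -- basic geometry -----------------------------------------------------

    @property
    def effective_plant_height(self) -> float:
        return self.height_fraction * self.plant_height

    @property
    def diagonal_pixels(self) -> float:
        return math.hypot(self.image_width, self.image_height)

    @property
    def gsd(self) -> float:
        """Ground sample distance, metres per pixel.

        Half the diagonal ground footprint is ``H * tan(fov/2)``; dividing by
        half the pixel diagonal gives metres per pixel.
        """
        half = math.radians(self.fov_diagonal) / 2.0
        return 2.0 * self.flight_height * math.tan(half) / self.diagonal_pixels

    @property
    def footprint(self) -> tuple[float, float]:
        """Ground footprint (width_m, height_m) of the full image."""
        return self.image_width * self.gsd, self.image_height * self.gsd

    @property
    def center_px(self) -> tuple[float, float]:
        """(col, row) of the nadir point."""
        return (self.image_width - 1) / 2.0, (self.image_height - 1) / 2.0

    # -- pixel <-> ground ---------------------------------------------------

    def pixel_to_ground(self, col, row, *, strict: bool = True):
        """Map pixel indices to metric ground coordinates relative to nadir.

        Accepts scalars or arrays. With ``strict`` (default) indices must lie
        inside ``[0, width) x [0, height)``.
        """
        col = np.asarray(col, dtype=float)
        row = np.asarray(row, dtype=float)
        if strict:
            if np.any(col < 0) or np.any(col >= self.image_width) or \
               np.any(row < 0) or np.any(row >= self.image_height):
                raise ValueError("pixel coordinates outside image bounds")
        c0, r0 = self.center_px
        g = self.gsd
        x = (col - c0) * g
        y = -(row - r0) * g
        if x.ndim == 0:
            return float(x), float(y)
        return x, y

    def ground_to_pixel(self, x, y, *, strict: bool = True):
        """Inverse of :meth:`pixel_to_ground`."""
        x = np.asarray(x, dtype=float)
        y = np.asarray(y, dtype=float)
        c0, r0 = self.center_px
        g = self.gsd
        col = x / g + c0
        row = -y / g + r0
        if strict:
            if np.any(col < 0) or np.any(col >= self.image_width) or \
               np.any(row < 0) or np.any(row >= self.image_height):
                raise ValueError("ground point maps outside image bounds")
        if col.ndim == 0:
            return float(col), float(row)
        return col, row

    # -- parallax -----------------------------------------------------------

    @property
    def parallax_factor(self) -> float:
        """(H - h_eff) / H: multiply an apparent position by this to correct it."""
        H = self.flight_height
        return (H - self.effective_plant_height) / H

    def correct_centroid(self, x, y):
        """Shift an apparent ground position radially toward nadir.

        An object at canopy height projects onto the ground plane farther from
        nadir than it really is; scaling by ``(H - h)/H`` recovers the true
        planting position.  The bearing from nadir is preserved.
        """
        f = self.parallax_factor
        x = np.asarray(x, dtype=float) * f
        y = np.asarray(y, dtype=float) * f
        if x.ndim == 0:
            return float(x), float(y)
        return x, y

    def apparent_position(self, x, y):
        """Forward model: where a true ground position appears in the image frame."""
        f = self.parallax_factor
        x = np.asarray(x, dtype=float) / f
        y = np.asarray(y, dtype=float) / f
        if x.ndim == 0:
            return float(x), float(y)
        return x, y

    # -- serialization ------------------------------------------------------

    def to_dict(self) -> dict:
        return {
            "flight_height_m": self.flight_height,
            "fov_diagonal_deg": self.fov_diagonal,
            "image_width_px": self.image_width,
            "image_height_px": self.image_height,
            "plant_height_m": self.plant_height,
            "height_fraction": self.height_fraction,
        }

    @classmethod
    def from_dict(cls, d: dict) -> "CameraModel":
        return cls(
            flight_height=float(d["flight_height_m"]),
            fov_diagonal=float(d.get("fov_diagonal_deg", 78.8)),
            image_width=int(d.get("image_width_px", 4000)),
            image_height=int(d.get("image_height_px", 3000)),
            plant_height=float(d.get("plant_height_m", 0.10)),
            height_fraction=float(d.get("height_fraction", 1.0)),
        )


# Thin functional wrappers ----------------------------------------------------

def ground_sample_distance(cam: CameraModel) -> float:
    """Metres per pixel for `cam` (see :attr:`CameraModel.gsd`)."""
    return cam.gsd


def pixel_to_ground(col, row, cam: CameraModel, *, strict: bool = True):
    return cam.pixel_to_ground(col, row, strict=strict)


def ground_to_pixel(x, y, cam: CameraModel, *, strict: bool = True):
    return cam.ground_to_pixel(x, y, strict=strict)


def correct_centroid(x, y, cam: CameraModel):
    return cam.correct_centroid(x, y)


def apparent_position(x, y, cam: CameraModel):
    return cam.apparent_position(x, y)
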