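"""Synthetic nadir plot scenes with exactly known plant positions.

The generator emulates the field setup the pipeline targets: 5 m plots of six
maize rows at 50.8 cm spacing (optionally a 60.96 cm planter-wheel gap),
planted toward 9.8 plants per square metre, imaged from 4-5 m with a 78.8
degree diagonal-FOV 4:3 sensor while plants are ~10 cm tall at the second
leaf collar stage.  Plants are drawn as rosettes of elliptical leaves at
their *apparent* (parallax-displaced) positions, so the centroid correction
is genuinely exercised; soil is brown multiscale noise, crop residue appears
as pale streaks and weeds as small green blobs.  Every scene is bit-exact
reproducible from its plan seed, and the returned truth table carries the
true seed positions and per-row spacings against which detections can be
scored.

Two rendering choices matter for interpreting end-to-end tests.  Leaves are
drawn in point-symmetric pairs about the seed point with 4x supersampled
edges, so the green-pixel centroid of an isolated plant coincides with its
seed position to a small fraction of a pixel; real seedlings are not
symmetric, so real-image centroid noise is larger.  Residue is near-grey
with a slight red excess, keeping its excess-green index non-positive by
construction (a greener, filter-stressing residue is available as an option).
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import ndimage as ndi
from scipy import stats
from skimage.draw import polygon as draw_polygon

from .camera import CameraModel

__all__ = ["ScenePlan", "TruthTable", "plan_scene", "render_scene",
           "simulate_scene", "default_camera"]

_LEAF_REACH_M = 0.05          # max radial extent of a rosette from its seed
_MIN_INTERVAL_M = 0.05        # truncation point of the spacing distribution


@dataclass(frozen=True)
class ScenePlan:
    """Layout and stochasticity of one synthetic plot.

    Defaults reproduce the reference field conditions; probabilities and the
    spacing noise are stand-ins chosen to produce the observed character of
    real stands (intervals from below 12 cm to above 40 cm, occasional extra
    and missing plants).
    """

    plot_length: float = 5.0          # m, along the row direction
    n_rows: int = 6
    row_spacing: float = 0.508        # m
    wheel_gap: float | None = None    # m, replaces the middle inter-row gap
    target_density: float = 9.8       # plants per m^2
    spacing_sd: float = 0.05          # m, within-row interval noise
    p_missing: float = 0.03           # probability a seed drop never emerges
    p_double: float = 0.01            # probability of an extra plant nearby
    weed_density: float = 0.5         # weeds per m^2
    residue_density: float = 1.0      # residue streaks per m^2
    plant_height: float = 0.10        # m, canopy height written to the truth
    greenish_residue: bool = False    # residue bright enough to pass the ExG cut
    illumination_gradient: bool = False
    rng_seed: int = 0

    def __post_init__(self) -> None:
        for name in ("p_missing", "p_double"):
            v = getattr(self, name)
            if not (0.0 <= v <= 1.0):
                raise ValueError(f"{name} must be in [0, 1]")
        for name in ("plot_length", "row_spacing", "target_density",
                     "spacing_sd", "weed_density", "residue_density"):
            if getattr(self, name) < 0:
                raise ValueError(f"{name} must be >= 0")
        if self.n_rows < 1:
            raise ValueError("n_rows must be >= 1")
        if self.plot_length == 0:
            raise ValueError("plot_length must be > 0")

    @property
    def mean_interval(self) -> float:
        """Planned seed interval: 1 / (target_density x row_spacing)."""
        return 1.0 / (self.target_density * self.row_spacing)

    @property
    def row_x_positions(self) -> np.ndarray:
        """Across-row coordinates of the rows, centred on the plot."""
        gaps = [self.row_spacing] * (self.n_rows - 1)
        if self.wheel_gap is not None and self.n_rows > 1:
            gaps[(self.n_rows - 1) // 2] = self.wheel_gap
        xs = np.concatenate([[0.0], np.cumsum(gaps)])
        return xs - xs[-1] / 2.0

    @property
    def plot_half_width(self) -> float:
        xs = self.row_x_positions
        return float(np.max(np.abs(xs)))


@dataclass
class TruthTable:
    """Ground truth of a planned scene.

    ``frame`` columns: plant_id, row_index, x_m, y_m, height_m, is_double
    (plus col_px/row_px once rendered).  True per-row spacings are the
    differences of consecutive along-row (y) coordinates.
    """

    frame: pd.DataFrame

    @property
    def n_plants(self) -> int:
        return len(self.frame)

    @property
    def positions(self) -> np.ndarray:
        return self.frame[["x_m", "y_m"]].to_numpy(dtype=float)

    def spacings(self) -> pd.DataFrame:
        """Adjacent true intervals per row (row_index, plant_a, plant_b, distance_m)."""
        from .evaluate import true_spacings
        return true_spacings(self.frame, row_angle=90.0)


def _draw_intervals(rng: np.random.Generator, plan: ScenePlan, n: int) -> np.ndarray:
    mu, sd = plan.mean_interval, plan.spacing_sd
    if sd == 0:
        return np.full(n, mu)
    a = (_MIN_INTERVAL_M - mu) / sd
    return stats.truncnorm.rvs(a, np.inf, loc=mu, scale=sd, size=n, random_state=rng)


def plan_scene(plan: ScenePlan) -> TruthTable:
    """Place plants row by row; deterministic given ``plan.rng_seed``.

    Seed points advance along each row by truncated-Normal intervals
    (mean 1/(density x row spacing), floor 5 cm); each is dropped with
    ``p_missing`` and duplicated with ``p_double`` at a 5-12 cm offset.
    """
    rng = np.random.default_rng([int(plan.rng_seed), 0])
    half_len = plan.plot_length / 2.0
    rows = []
    pid = 0
    for row_index, x in enumerate(plan.row_x_positions):
        y = -half_len + rng.uniform(_MIN_INTERVAL_M, plan.mean_interval)
        seeds = []
        while y <= half_len:
            seeds.append(y)
            y += _draw_intervals(rng, plan, 1)[0]
        for y_seed in seeds:
            if rng.random() < plan.p_missing:
                continue
            plants_here = [(y_seed, False)]
            if rng.random() < plan.p_double:
                off = rng.uniform(_MIN_INTERVAL_M, 0.12) * rng.choice([-1.0, 1.0])
                y_extra = y_seed + off
                if -half_len <= y_extra <= half_len:
                    plants_here.append((y_extra, True))
            for y_p, is_double in plants_here:
                rows.append({"plant_id": pid, "row_index": row_index,
                             "x_m": float(x), "y_m": float(y_p),
                             "height_m": plan.plant_height,
                             "is_double": is_double})
                pid += 1
    frame = pd.DataFrame(rows, columns=["plant_id", "row_index", "x_m", "y_m",
                                        "height_m", "is_double"])
    return TruthTable(frame=frame)


def default_camera(flight_height: float = 4.0, *, plant_height: float = 0.10,
                   resolution_scale: float = 1.0) -> CameraModel:
    """The study camera flown in portrait orientation.

    The sensor is rotated so its long (4000 px) axis runs along the crop
    rows; only then does a 5 m plot fit the footprint at 4-5 m flight height.
    ``resolution_scale`` shrinks the pixel count (coarser GSD, same FOV and
    footprint) for fast simulation studies.
    """
    return CameraModel(
        flight_height=flight_height,
        fov_diagonal=78.8,
        image_width=max(2, int(round(3000 * resolution_scale))),
        image_height=max(2, int(round(4000 * resolution_scale))),
        plant_height=plant_height,
    )


# -- rendering ----------------------------------------------------------------

_SOIL_RGB = np.array([128.0, 100.0, 82.0])        # ExG = -0.032
_LEAF_RGB = np.array([72.0, 158.0, 62.0])         # ExG =  0.623
_WEED_RGB = np.array([95.0, 150.0, 70.0])         # ExG =  0.429
_RESIDUE_RGB = np.array([190.0, 172.0, 160.0])    # ExG = -0.011
_GREEN_RESIDUE_RGB = np.array([160.0, 185.0, 140.0])  # ExG = 0.144 (> 0.1)

_SUPERSAMPLE = 4


def _soil_background(shape: tuple[int, int], rng: np.random.Generator) -> np.ndarray:
    h, w = shape
    lum = np.ones((h, w))
    for cell, amp in ((32, 0.10), (8, 0.06)):
        gh, gw = max(2, h // cell + 2), max(2, w // cell + 2)
        coarse = rng.standard_normal((gh, gw))
        lum += amp * ndi.zoom(coarse, (h / gh, w / gw), order=1, grid_mode=True,
                              mode="nearest")
    lum += 0.03 * rng.standard_normal((h, w))
    np.clip(lum, 0.5, 1.5, out=lum)
    return lum[..., None] * _SOIL_RGB[None, None, :]


def _paste_alpha(img: np.ndarray, alpha: np.ndarray, r0: int, c0: int,
                 color: np.ndarray) -> None:
    """Alpha-blend a patch onto the image, clipped to the frame."""
    h, w = img.shape[:2]
    ph, pw = alpha.shape
    rs, cs = max(r0, 0), max(c0, 0)
    re, ce = min(r0 + ph, h), min(c0 + pw, w)
    if rs >= re or cs >= ce:
        return
    a = alpha[rs - r0:re - r0, cs - c0:ce - c0, None]
    img[rs:re, cs:ce] = a * color[None, None, :] + (1.0 - a) * img[rs:re, cs:ce]


def _rosette_alpha(center_rc: tuple[float, float], leaves: list[tuple],
                   gsd: float) -> tuple[np.ndarray, int, int]:
    """Supersampled coverage of a set of ground-frame ellipses.

    ``leaves``: (angle, center_offset_m, semi_major_m, semi_minor_m); each
    entry is drawn together with its point reflection about the plant centre,
    so the coverage is symmetric and the blob centroid sits on the centre.
    """
    reach_px = max(lf[1] + lf[2] for lf in leaves) / gsd
    rad = int(math.ceil(reach_px)) + 2
    r_c, c_c = center_rc
    r0, c0 = int(math.floor(r_c)) - rad, int(math.floor(c_c)) - rad
    n = 2 * rad + 1
    ss = _SUPERSAMPLE
    # subpixel sample coordinates relative to the plant centre, in pixels
    u = (np.arange(n * ss) + 0.5) / ss - 0.5
    rr = r0 + u[:, None] - r_c
    cc = c0 + u[None, :] - c_c
    inside = np.zeros((n * ss, n * ss), dtype=bool)
    for ang, off_m, sa_m, sb_m in leaves:
        off, sa, sb = off_m / gsd, sa_m / gsd, sb_m / gsd
        # image rows grow downward; ground angle is CCW, so row component is -sin
        dc, dr = math.cos(ang), -math.sin(ang)
        for s in (1.0, -1.0):
            ec, er = s * off * dc, s * off * dr
            # coordinates in the leaf frame
            lc = (cc - ec) * dc + (rr - er) * dr
            ln = -(cc - ec) * dr + (rr - er) * dc
            inside |= (lc / sa) ** 2 + (ln / sb) ** 2 <= 1.0
    alpha = inside.reshape(n, ss, n, ss).mean(axis=(1, 3))
    return alpha, r0, c0


def _draw_plant(img: np.ndarray, cam: CameraModel, rng: np.random.Generator,
                col: float, row: float, *, scale: float = 1.0,
                color: np.ndarray = _LEAF_RGB) -> None:
    n_pairs = int(rng.integers(1, 4))           # 2, 4 or 6 leaves
    base = rng.uniform(0.0, math.pi)
    # plants at one growth stage share similar total leaf area: leaf length
    # shrinks as leaf count grows, so the relative area filter stays meaningful
    sa0 = rng.uniform(0.026, 0.030) / math.sqrt(n_pairs)
    leaves = []
    for k in range(n_pairs):
        ang = base + k * math.pi / n_pairs + rng.normal(0.0, 0.15)
        sa = min(sa0 * rng.uniform(0.92, 1.08), 0.030) * scale  # semi-major, m
        sb = sa * rng.uniform(0.22, 0.34)
        off = 0.6 * sa
        leaves.append((ang, off, sa, sb))
    lum = rng.uniform(0.85, 1.1)
    alpha, r0, c0 = _rosette_alpha((row, col), leaves, cam.gsd)
    _paste_alpha(img, alpha, r0, c0, np.clip(color * lum, 0, 255))


def _draw_residue(img: np.ndarray, cam: CameraModel, rng: np.random.Generator,
                  x: float, y: float, color: np.ndarray) -> None:
    length = rng.uniform(0.05, 0.25)
    width = rng.uniform(0.006, 0.02)
    ang = rng.uniform(0.0, math.pi)
    lum = rng.uniform(0.8, 1.15)
    dx, dy = math.cos(ang), math.sin(ang)
    nx, ny = -dy, dx
    corners = []
    for su, sv in ((1, 1), (1, -1), (-1, -1), (-1, 1)):
        cx = x + su * dx * length / 2 + sv * nx * width / 2
        cy = y + su * dy * length / 2 + sv * ny * width / 2
        corners.append(cam.ground_to_pixel(cx, cy, strict=False))
    cols = np.array([c for c, _ in corners])
    rows_ = np.array([r for _, r in corners])
    rr, cc = draw_polygon(rows_, cols, shape=img.shape[:2])
    img[rr, cc] = np.clip(color * lum, 0, 255)


def render_scene(truth: TruthTable, cam: CameraModel,
                 plan: ScenePlan) -> tuple[np.ndarray, TruthTable]:
    """Render a planned scene to an 8-bit RGB image.

    Plants are drawn at their apparent (parallax-displaced) positions; the
    returned truth table gains ``col_px``/``row_px`` columns with those
    apparent pixel locations.  Raises if the plot (plus leaf margin) does not
    fit the camera footprint.
    """
    rng = np.random.default_rng([int(plan.rng_seed), 1])
    half_w_m, half_h_m = cam.footprint[0] / 2.0, cam.footprint[1] / 2.0
    margin = _LEAF_REACH_M
    f = cam.parallax_factor
    need_x = (plan.plot_half_width + margin) / f
    need_y = (plan.plot_length / 2.0 + margin) / f
    if need_x > half_w_m or need_y > half_h_m:
        raise ValueError(
            f"plot ({2 * need_x:.2f} x {2 * need_y:.2f} m apparent) exceeds the "
            f"camera footprint ({2 * half_w_m:.2f} x {2 * half_h_m:.2f} m)")

    img = _soil_background((cam.image_height, cam.image_width), rng)

    plot_area = plan.plot_length * plan.n_rows * plan.row_spacing
    res_color = _GREEN_RESIDUE_RGB if plan.greenish_residue else _RESIDUE_RGB
    for _ in range(rng.poisson(plan.residue_density * plot_area)):
        x = rng.uniform(-plan.plot_half_width, plan.plot_half_width)
        y = rng.uniform(-plan.plot_length / 2, plan.plot_length / 2)
        _draw_residue(img, cam, rng, x, y, res_color)

    for _ in range(rng.poisson(plan.weed_density * plot_area)):
        x = rng.uniform(-plan.plot_half_width, plan.plot_half_width)
        y = rng.uniform(-plan.plot_length / 2, plan.plot_length / 2)
        col, row = cam.ground_to_pixel(x, y, strict=False)  # weeds hug the ground
        _draw_plant(img, cam, rng, col, row, scale=0.28, color=_WEED_RGB)

    cols, rows_px = [], []
    for rec in truth.frame.itertuples():
        xa, ya = cam.apparent_position(rec.x_m, rec.y_m)
        col, row = cam.ground_to_pixel(xa, ya, strict=False)
        _draw_plant(img, cam, rng, col, row)
        cols.append(col)
        rows_px.append(row)

    if plan.illumination_gradient:
        ramp = np.linspace(0.85, 1.15, cam.image_width)[None, :, None]
        img *= ramp

    frame = truth.frame.copy()
    frame["col_px"] = cols
    frame["row_px"] = rows_px
    return np.clip(img, 0, 255).astype(np.uint8), TruthTable(frame=frame)


def simulate_scene(plan: ScenePlan, cam: CameraModel | None = None
                   ) -> tuple[np.ndarray, TruthTable]:
    """Plan and render in one call; the camera defaults to the portrait study
    camera at 4 m."""
    if cam is None:
        cam = default_camera()
    truth = plan_scene(plan)
    return render_scene(truth, cam, plan)
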