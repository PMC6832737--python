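"""Plot-level stand statistics and light comparison statistics.

Stand density is detected plant count over agronomic plot area
(length x n_rows x row_spacing); spacing mean and standard deviation are
taken over the valid within-row intervals.  For comparing plots across
zones the module exposes a one-way ANOVA and ordinary least-squares simple
regression, both delegated to scipy.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import stats

from .rows import SpacingRecord

__all__ = ["PlotGeometry", "PlotSummary", "plot_area", "summarize_plot",
           "one_way_anova", "simple_regression"]


@dataclass(frozen=True)
class PlotGeometry:
    """Agronomic plot layout: length (m), number of rows, row spacing (m)."""

    plot_length: float = 5.0
    n_rows: int = 6
    row_spacing: float = 0.508

    @property
    def area(self) -> float:
        return self.plot_length * self.n_rows * self.row_spacing


@dataclass
class PlotSummary:
    plot_id: str
    zone_label: str
    plant_count: int
    plot_area: float
    density: float                 # plants per m^2
    spacing_mean: float            # metres; NaN when < 1 interval
    spacing_sd: float              # sample SD (n-1); NaN when < 2 intervals
    n_spacings: int


def plot_area(geometry: PlotGeometry) -> float:
    return geometry.area


def summarize_plot(plant_count: int, spacing_records: list[SpacingRecord],
                   geometry: PlotGeometry, *, plot_id: str = "",
                   zone_label: str = "") -> PlotSummary:
    """Stand density and spacing statistics for one plot.

    Only records flagged valid enter the spacing statistics.
    """
    dists = np.array([r.distance for r in spacing_records if r.valid], dtype=float)
    area = geometry.area
    if area <= 0:
        raise ValueError("plot area must be positive")
    return PlotSummary(
        plot_id=plot_id,
        zone_label=zone_label,
        plant_count=int(plant_count),
        plot_area=area,
        density=plant_count / area,
        spacing_mean=float(dists.mean()) if dists.size >= 1 else float("nan"),
        spacing_sd=float(dists.std(ddof=1)) if dists.size >= 2 else float("nan"),
        n_spacings=int(dists.size),
    )


def one_way_anova(*groups) -> tuple[float, float]:
    """Classical one-way ANOVA F test of equal group means.

    Returns (F, p) with df (k-1, N-k). Requires at least two groups of at
    least two values each.
    """
    if len(groups) < 2:
        raise ValueError("need at least two groups")
    if any(len(g) < 2 for g in groups):
        raise ValueError("each group needs at least two values")
    f, p = stats.f_oneway(*[np.asarray(g, dtype=float) for g in groups])
    return float(f), float(p)


def simple_regression(x, y) -> tuple[float, float, float]:
    """Ordinary least squares y ~ x; returns (slope, intercept, R^2)."""
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.size < 3:
        raise ValueError("need at least three points")
    if np.var(x) == 0:
        raise ValueError("x must vary")
    res = stats.linregress(x, y)
    # constant response: zero total variance, fit explains nothing
    r2 = 0.0 if np.var(y) == 0 else float(res.rvalue ** 2)
    return float(res.slope), float(res.intercept), r2
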