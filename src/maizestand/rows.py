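"""Crop-row detection by iterative buffer averaging, and within-row spacing.

Rows are found one at a time: pick an unassigned centroid, drop a line
through it at the known row angle, collect all unassigned centroids within a
perpendicular buffer of half the row spacing (w/2), move the line to pass
through their mean position, and take that as the final row.  Membership is
re-evaluated against the moved line before plants are marked assigned; the
loop repeats until every centroid belongs to a row.

Plant-to-plant distance within a row is the gap between the perpendicular
projections of adjacent member centroids onto the row line.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np
from sklearn.base import BaseEstimator, ClusterMixin

__all__ = ["RowLine", "SpacingRecord", "CropRowFitter", "fit_rows",
           "spacing_along_rows"]


@dataclass
class RowLine:
    """A fitted crop-row line with its ordered member plants."""

    row_id: int
    anchor: tuple[float, float]       # a point the line passes through
    angle_deg: float                  # CCW from ground +x axis
    member_ids: list[int]             # sorted by along-line coordinate
    member_along: list[float] = field(default_factory=list)

    @property
    def direction(self) -> tuple[float, float]:
        a = math.radians(self.angle_deg)
        return math.cos(a), math.sin(a)

    @property
    def n_members(self) -> int:
        return len(self.member_ids)


@dataclass
class SpacingRecord:
    """One adjacent-plant interval along a row."""

    row_id: int
    plant_a: int
    plant_b: int
    distance: float                   # metres between projected centroids
    valid: bool = True


class CropRowFitter(ClusterMixin, BaseEstimator):
    """Assign plant centroids to crop rows (a clustering estimator).

    Parameters
    ----------
    row_angle : float, default 90.0
        Known row direction, degrees CCW from the ground +x axis; 90 means
        rows parallel to the image vertical.
    row_spacing : float, default 0.508
        Planter row spacing w in metres; the membership buffer is w/2.
    seed_policy : {"lowest_id", "random"}
        How the next unassigned seed centroid is chosen. ``lowest_id`` is
        deterministic; ``random`` reproduces the randomized variant.
    refine_iters : int, default 1
        Number of move-to-mean refinements of each candidate line.
    random_state : int or None
        Seed for ``seed_policy="random"``.

    Attributes
    ----------
    rows_ : list of RowLine
    labels_ : ndarray of shape (n,)
        Row id of each input centroid.
    n_rows_ : int
    """

    def __init__(self, row_angle: float = 90.0, row_spacing: float = 0.508,
                 seed_policy: str = "lowest_id", refine_iters: int = 1,
                 random_state: int | None = None):
        self.row_angle = row_angle
        self.row_spacing = row_spacing
        self.seed_policy = seed_policy
        self.refine_iters = refine_iters
        self.random_state = random_state

    def fit(self, X, y=None):
        X = np.asarray(X, dtype=float)
        if X.ndim != 2 or X.shape[1] != 2:
            raise ValueError("X must be an (n, 2) array of ground coordinates")
        n = X.shape[0]
        if n == 0:
            raise ValueError("cannot fit rows to an empty centroid list")
        if self.row_spacing <= 0:
            raise ValueError("row_spacing must be > 0")
        if not (0.0 <= self.row_angle % 360.0 < 360.0):  # always true; guard NaN
            raise ValueError("row_angle must be finite")
        if self.seed_policy not in ("lowest_id", "random"):
            raise ValueError(f"unknown seed_policy {self.seed_policy!r}")

        a = math.radians(self.row_angle)
        d = np.array([math.cos(a), math.sin(a)])      # along-row direction
        nrm = np.array([-math.sin(a), math.cos(a)])   # row-normal direction
        half_w = self.row_spacing / 2.0
        # work in (along, across) coordinates; a line is "across = const"
        along = X @ d
        across = X @ nrm

        rng = np.random.default_rng(self.random_state)
        unassigned = np.ones(n, dtype=bool)
        labels = np.full(n, -1, dtype=int)
        rows: list[RowLine] = []

        while unassigned.any():
            idx = np.flatnonzero(unassigned)
            if self.seed_policy == "lowest_id":
                seed = idx[0]
            else:
                seed = rng.choice(idx)
            line_across = across[seed]
            for _ in range(max(1, int(self.refine_iters))):
                members = idx[np.abs(across[idx] - line_across) <= half_w]
                if members.size == 0:
                    break
                line_across = across[members].mean()
            members = idx[np.abs(across[idx] - line_across) <= half_w]
            if members.size == 0:       # degenerate; keep at least the seed
                members = np.array([seed])
                line_across = across[seed]
            order = members[np.argsort(along[members], kind="stable")]
            row_id = len(rows)
            anchor = line_across * nrm  # closest point of the line to the origin
            rows.append(RowLine(
                row_id=row_id,
                anchor=(float(anchor[0]), float(anchor[1])),
                angle_deg=self.row_angle,
                member_ids=[int(i) for i in order],
                member_along=[float(along[i]) for i in order],
            ))
            labels[members] = row_id
            unassigned[members] = False

        self.rows_ = rows
        self.labels_ = labels
        self.n_rows_ = len(rows)
        return self


def fit_rows(centroids, *, row_angle: float = 90.0, row_spacing: float = 0.508,
             seed_policy: str = "lowest_id", refine_iters: int = 1,
             random_state: int | None = None) -> list[RowLine]:
    """Cluster ground centroids into crop rows (wrapper over CropRowFitter)."""
    fitter = CropRowFitter(row_angle=row_angle, row_spacing=row_spacing,
                           seed_policy=seed_policy, refine_iters=refine_iters,
                           random_state=random_state)
    return fitter.fit(centroids).rows_


def spacing_along_rows(rows: list[RowLine]) -> list[SpacingRecord]:
    """Adjacent-plant distances per row from projected along-line coordinates.

    Rows with fewer than two members yield no records; in total there are
    sum(members - 1) records.
    """
    records: list[SpacingRecord] = []
    for row in rows:
        t = row.member_along
        for a, b, ta, tb in zip(row.member_ids[:-1], row.member_ids[1:],
                                t[:-1], t[1:]):
            records.append(SpacingRecord(row_id=row.row_id, plant_a=a,
                                         plant_b=b, distance=float(tb - ta)))
    return records
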