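"""Detection and spacing accuracy against ground truth.

Detections are matched one-to-one to true plant positions by greedy
nearest-first pairing within a distance tolerance; leftovers are false
positives (spurious detections) and false negatives (missed plants).
Precision = TP/(TP+FP), recall = TP/(TP+FN).

Spacing accuracy is the agreement index d_e — the mean absolute difference
between estimated and measured adjacent-plant distances — and the relative
error r = d_e / mean measured distance.  Intervals touching a false positive
or a missed plant are excluded: an estimated interval only counts when both
endpoints are true positives whose matched plants are adjacent in the truth
ordering of the same row.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.spatial.distance import cdist

from .rows import SpacingRecord

__all__ = ["MatchResult", "EvalResult", "match_detections", "precision",
           "recall", "spacing_agreement", "round_half_up_percent"]


@dataclass
class MatchResult:
    """One-to-one pairing of detections with true plants."""

    pairs: list[tuple[int, int, float]]   # (detected_id, truth_id, distance)
    tp: int
    fp: int
    fn: int
    match_tolerance: float
    fp_ids: list[int] = field(default_factory=list)
    fn_ids: list[int] = field(default_factory=list)

    @property
    def det_to_truth(self) -> dict[int, int]:
        return {d: t for d, t, _ in self.pairs}


@dataclass
class EvalResult:
    """Spacing agreement over the valid adjacent-plant intervals."""

    d_e: float                      # mean |d_est - d_meas|, metres
    r: float                        # d_e / mean(d_meas)
    per_pair_rel_errors: list[float]
    n: int                          # number of valid intervals
    records: list[SpacingRecord] = field(default_factory=list)
    measured: list[float] = field(default_factory=list)
    estimated: list[float] = field(default_factory=list)


def match_detections(detected: np.ndarray, truth: np.ndarray,
                     tolerance: float = 0.05,
                     detected_ids=None, truth_ids=None) -> MatchResult:
    """Greedy one-to-one matching by ascending pair distance.

    Parameters
    ----------
    detected, truth : (n, 2) arrays of ground coordinates (metres).
    tolerance : float
        Maximum centre distance for a detection to count as a true positive.
    detected_ids, truth_ids : sequences, optional
        Identifiers reported in the pairing; positional indices by default.
    """
    if tolerance <= 0:
        raise ValueError("tolerance must be > 0")
    detected = np.asarray(detected, dtype=float).reshape(-1, 2)
    truth = np.asarray(truth, dtype=float).reshape(-1, 2)
    det_ids = list(range(len(detected))) if detected_ids is None else list(detected_ids)
    tr_ids = list(range(len(truth))) if truth_ids is None else list(truth_ids)

    pairs: list[tuple[int, int, float]] = []
    used_d = np.zeros(len(detected), dtype=bool)
    used_t = np.zeros(len(truth), dtype=bool)
    if len(detected) and len(truth):
        dist = cdist(detected, truth)
        cand = np.argwhere(dist <= tolerance)
        order = np.argsort(dist[cand[:, 0], cand[:, 1]], kind="stable")
        for i, j in cand[order]:
            if not used_d[i] and not used_t[j]:
                used_d[i] = used_t[j] = True
                pairs.append((det_ids[i], tr_ids[j], float(dist[i, j])))
    tp = len(pairs)
    return MatchResult(
        pairs=pairs, tp=tp, fp=len(detected) - tp, fn=len(truth) - tp,
        match_tolerance=tolerance,
        fp_ids=[det_ids[i] for i in np.flatnonzero(~used_d)],
        fn_ids=[tr_ids[j] for j in np.flatnonzero(~used_t)],
    )


def precision(m: MatchResult) -> float:
    """TP / (TP + FP); NaN (with a warning) when there are no detections."""
    if m.tp + m.fp == 0:
        warnings.warn("precision undefined: no detections", stacklevel=2)
        return float("nan")
    return m.tp / (m.tp + m.fp)


def recall(m: MatchResult) -> float:
    """TP / (TP + FN); NaN (with a warning) when there are no true plants."""
    if m.tp + m.fn == 0:
        warnings.warn("recall undefined: no true plants", stacklevel=2)
        return float("nan")
    return m.tp / (m.tp + m.fn)


def round_half_up_percent(fraction: float) -> int:
    """Display rounding to integer percent, halves up (0.965 -> 97)."""
    return int(math.floor(fraction * 100.0 + 0.5))


def _truth_order(truth: pd.DataFrame, row_angle: float) -> dict[int, tuple[int, int]]:
    """Map truth plant_id -> (row_index, rank along the row direction)."""
    a = math.radians(row_angle)
    along = truth["x_m"].to_numpy() * math.cos(a) + truth["y_m"].to_numpy() * math.sin(a)
    t = truth.assign(_along=along)
    order: dict[int, tuple[int, int]] = {}
    for row_idx, grp in t.groupby("row_index"):
        g = grp.sort_values("_along")
        for rank, pid in enumerate(g["plant_id"].to_numpy()):
            order[int(pid)] = (int(row_idx), rank)
    return order


def true_spacings(truth: pd.DataFrame, row_angle: float = 90.0) -> pd.DataFrame:
    """Adjacent true spacings per row: differences of consecutive along-row
    coordinates.  Returns columns row_index, plant_a, plant_b, distance_m."""
    a = math.radians(row_angle)
    along = truth["x_m"].to_numpy() * math.cos(a) + truth["y_m"].to_numpy() * math.sin(a)
    t = truth.assign(_along=along)
    out = []
    for row_idx, grp in t.groupby("row_index"):
        g = grp.sort_values("_along")
        ids = g["plant_id"].to_numpy()
        al = g["_along"].to_numpy()
        for i in range(len(g) - 1):
            out.append({"row_index": int(row_idx), "plant_a": int(ids[i]),
                        "plant_b": int(ids[i + 1]),
                        "distance_m": float(al[i + 1] - al[i])})
    return pd.DataFrame(out, columns=["row_index", "plant_a", "plant_b", "distance_m"])


def spacing_agreement(records: list[SpacingRecord], truth: pd.DataFrame,
                      match: MatchResult, *, row_angle: float = 90.0) -> EvalResult:
    """Agreement index d_e and relative error r over valid intervals.

    ``truth`` must carry columns plant_id, row_index, x_m, y_m.  An estimated
    interval is valid when both endpoint detections are matched and their
    matched true plants are consecutive within one truth row (so no missed
    plant lies between them); all other intervals are flagged invalid and
    excluded, mirroring the FP/FN exclusion rule.
    """
    d2t = match.det_to_truth
    order = _truth_order(truth, row_angle)
    ts = true_spacings(truth, row_angle)
    meas_lookup = {(int(r.plant_a), int(r.plant_b)): float(r.distance_m)
                   for r in ts.itertuples()}

    measured, estimated = [], []
    for rec in records:
        rec.valid = False
        ta, tb = d2t.get(rec.plant_a), d2t.get(rec.plant_b)
        if ta is None or tb is None:
            continue
        (row_a, rank_a), (row_b, rank_b) = order[ta], order[tb]
        if row_a != row_b or abs(rank_a - rank_b) != 1:
            continue
        key = (ta, tb) if rank_a < rank_b else (tb, ta)
        rec.valid = True
        measured.append(meas_lookup[key])
        estimated.append(rec.distance)

    if not measured:
        raise ValueError("no valid spacing intervals to evaluate")
    est = np.asarray(estimated)
    mea = np.asarray(measured)
    abs_err = np.abs(est - mea)
    d_e = float(abs_err.mean())
    return EvalResult(
        d_e=d_e,
        r=float(d_e / mea.mean()),
        per_pair_rel_errors=list(abs_err / mea),
        n=len(measured),
        records=list(records),
        measured=list(mea),
        estimated=list(est),
    )
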