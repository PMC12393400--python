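"""Secondary behavioral assay metrics: thrashing, roaming and lawn aversion.

Thrashing (swimming vigor): one thrash is one reversal of the direction of
the midbody bend.  The manual count registers every time the body flexes to
one side; the computational analogue counts hysteresis-gated direction
reversals of the bend-angle series so that sensor noise below the gate does
not inflate the count.

Roaming (exploration on food): the number of distinct 3 x 3 mm grid squares
a worm's track traverses over a long incubation, the overlay-count analogue
of scoring ink trails on the lawn.

Aversion: the fraction of worms outside the bacterial lawn per frame of a
20 h, 1 frame/min recording, summarized by its time average.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .simulate import BendSeries

__all__ = [
    "GridSpec",
    "ThrashResult",
    "count_thrashes",
    "roaming_squares",
    "aversion_ratio",
]

DEFAULT_HYSTERESIS_RAD = math.radians(10.0)


@dataclass(frozen=True)
class GridSpec:
    """Square grid overlay for the roaming count (3 mm squares anchored at
    the plate center by default; the origin offset covers arbitrary overlay
    placement)."""

    square_size_mm: float = 3.0
    origin_xy_mm: tuple[float, float] = (0.0, 0.0)

    def __post_init__(self) -> None:
        if not self.square_size_mm > 0:
            raise ValueError("square_size_mm must be strictly positive")

    def cell(self, x: float, y: float) -> tuple[int, int]:
        ox, oy = self.origin_xy_mm
        s = self.square_size_mm
        return (math.floor((x - ox) / s), math.floor((y - oy) / s))


@dataclass(frozen=True)
class ThrashResult:
    count: int
    duration_s: float

    @property
    def rate_per_min(self) -> float:
        return self.count * 60.0 / self.duration_s if self.duration_s > 0 else float("nan")


def count_thrashes(
    series: BendSeries, hysteresis_rad: float = DEFAULT_HYSTERESIS_RAD
) -> ThrashResult:
    """Count direction reversals of the bend angle with a hysteresis gate.

    A reversal is registered each time the angle, having moved at least
    ``hysteresis_rad`` in one direction since the last registered extremum,
    turns around.  On a clean sinusoid this counts every extremum: two
    thrashes per cycle, so a 1 Hz swimmer scores 120/min.
    """
    if hysteresis_rad < 0:
        raise ValueError("hysteresis_rad must be non-negative")
    angle = np.asarray(series.angle_rad, dtype=float)
    if angle.size == 0:
        raise ValueError("bend series is empty")
    if not np.all(np.isfinite(angle)):
        raise ValueError("bend series contains non-finite values")

    count = 0
    ref = angle[0]  # running extremum candidate
    direction = 0  # +1 rising, -1 falling, 0 undetermined
    for a in angle[1:]:
        if direction == 0:
            # anchor stays at the start until the angle commits one way
            if a - ref >= hysteresis_rad:
                direction = 1
                ref = a
            elif ref - a >= hysteresis_rad:
                direction = -1
                ref = a
        elif direction == 1:
            if a > ref:
                ref = a
            elif ref - a >= hysteresis_rad:
                count += 1
                direction = -1
                ref = a
        else:
            if a < ref:
                ref = a
            elif a - ref >= hysteresis_rad:
                count += 1
                direction = 1
                ref = a
    duration = float(series.time_s[-1] - series.time_s[0]) if len(series.time_s) > 1 else 0.0
    return ThrashResult(count=count, duration_s=duration)


def _segment_cells(p0, p1, grid: GridSpec):
    """All grid cells a straight segment passes through (supercover by
    splitting the segment at every grid-line crossing and binning the
    midpoint of each piece)."""
    cells = {grid.cell(*p0), grid.cell(*p1)}
    (x0, y0), (x1, y1) = p0, p1
    ox, oy = grid.origin_xy_mm
    s = grid.square_size_mm
    ts = [0.0, 1.0]
    for (a0, a1, o) in ((x0, x1, ox), (y0, y1, oy)):
        if a1 != a0:
            k_lo = math.ceil((min(a0, a1) - o) / s)
            k_hi = math.floor((max(a0, a1) - o) / s)
            for k in range(k_lo, k_hi + 1):
                t = (o + k * s - a0) / (a1 - a0)
                if 0.0 < t < 1.0:
                    ts.append(t)
    ts.sort()
    for ta, tb in zip(ts[:-1], ts[1:]):
        tm = 0.5 * (ta + tb)
        cells.add(grid.cell(x0 + tm * (x1 - x0), y0 + tm * (y1 - y0)))
    return cells


def roaming_squares(
    track: pd.DataFrame, grid: GridSpec = GridSpec(), method: str = "distinct"
) -> int:
    """Grid squares traversed by a single-worm track.

    ``method='distinct'`` (default) counts distinct cells touched, with
    linear interpolation between consecutive detected points so boundary
    crossings between frames are not missed.  ``method='crossings'`` counts
    cell-boundary crossings instead (the alternative reading of a
    squares-traversed score).
    """
    if method not in ("distinct", "crossings"):
        raise ValueError("method must be 'distinct' or 'crossings'")
    det = track.loc[track["detected"]] if "detected" in track.columns else track
    pts = det[["x_mm", "y_mm"]].to_numpy(float)
    pts = pts[np.all(np.isfinite(pts), axis=1)]
    if len(pts) == 0:
        raise ValueError("track has no detected points")

    if method == "crossings":
        crossings = 0
        ox, oy = grid.origin_xy_mm
        s = grid.square_size_mm
        for (x0, y0), (x1, y1) in zip(pts[:-1], pts[1:]):
            for (a0, a1, o) in ((x0, x1, ox), (y0, y1, oy)):
                if a1 != a0:
                    lo = (min(a0, a1) - o) / s
                    hi = (max(a0, a1) - o) / s
                    crossings += max(math.floor(hi) - math.ceil(lo) + 1, 0)
                    if lo == math.ceil(lo):  # started exactly on a line
                        crossings -= 1
        return crossings

    visited = {grid.cell(*pts[0])}
    for p0, p1 in zip(pts[:-1], pts[1:]):
        visited |= _segment_cells(tuple(p0), tuple(p1), grid)
    return len(visited)


def aversion_ratio(occupancy: np.ndarray) -> tuple[np.ndarray, float]:
    """Per-frame aversion ratio and its time-average summary.

    ``occupancy`` is a boolean (n_frames, n_worms) matrix, True meaning the
    worm is outside the lawn at that frame.  The per-frame ratio is the
    outside count over the total worm count; the scalar summary averages the
    ratio over all frames (an endpoint reading is available as
    ``ratios[-1]``).
    """
    occ = np.asarray(occupancy, dtype=bool)
    if occ.ndim != 2:
        raise ValueError("occupancy must be a 2-D (frames x worms) matrix")
    if occ.shape[1] == 0:
        raise ValueError("occupancy has zero worms")
    ratios = occ.mean(axis=1)
    return ratios, float(ratios.mean())
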