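"""The four scalar whole-path metrics of a DAR.

* net displacement — straight-line distance between the averaged start and
  end points ("openness");
* maximum displacement — largest distance of any trajectory point from the
  start point;
* maximum diameter — largest pairwise distance among trajectory points, the
  segment achieving it being the diameter line;
* maximum width — sum of the largest perpendicular offsets of trajectory
  points on either side of the (infinite) diameter line.

Internal unit is meters; reported unit is kilometers. These metrics are
whole-path scalars, deliberately insensitive to relocation frequency.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.spatial import ConvexHull, QhullError
from scipy.spatial.distance import pdist

from .dar_extraction import DAR
from .errors import DataError

#: above this many points the diameter search is restricted to hull vertices
HULL_CUTOFF = 500


@dataclass
class DarMetrics:
    dar_id: str
    net_displacement: float      # km, NaN when an endpoint is missing
    max_displacement: float      # km, NaN when the start point is missing
    max_diameter: float          # km
    max_width: float             # km
    diameter_pair: tuple[int, int]
    complete: bool


def net_displacement(start, end) -> float:
    """Bee-line start-to-end distance in km; NaN if either endpoint missing."""
    if start is None or end is None:
        return float("nan")
    return float(np.hypot(end[0] - start[0], end[1] - start[1]) / 1000.0)


def max_displacement(points: np.ndarray, start) -> float:
    """Largest distance from the start point over all points, in km."""
    if start is None:
        return float("nan")
    points = np.asarray(points, dtype=float)
    if len(points) == 0:
        raise DataError("max_displacement needs at least one point")
    d = np.hypot(points[:, 0] - start[0], points[:, 1] - start[1])
    return float(d.max() / 1000.0)


def _brute_diameter(points: np.ndarray) -> tuple[float, tuple[int, int]]:
    n = len(points)
    d = pdist(points)
    flat = int(np.argmax(d))          # first occurrence = lexicographic pair
    # invert condensed index
    i = int(n - 2 - np.floor(np.sqrt(-8 * flat + 4 * n * (n - 1) - 7) / 2.0 - 0.5))
    j = int(flat + i + 1 - n * (n - 1) // 2 + (n - i) * ((n - i) - 1) // 2)
    return float(d[flat]), (i, j)


def max_diameter(points: np.ndarray, method: str | None = None
                 ) -> tuple[float, tuple[int, int]]:
    """Maximum pairwise distance (km) and the index pair achieving it.

    Exhaustive O(n^2) below :data:`HULL_CUTOFF`; above it the search is
    restricted to convex-hull vertices, which contain every diameter
    endpoint. Ties break to the lexicographically smallest index pair.
    ``method`` forces "brute" or "hull" (used by oracle tests).
    """
    points = np.asarray(points, dtype=float)
    if points.ndim != 2 or points.shape[1] != 2:
        raise DataError("points must be an (n, 2) array")
    n = len(points)
    if n == 0:
        raise DataError("max_diameter needs at least one point")
    if n == 1:
        return 0.0, (0, 0)
    if method is None:
        method = "hull" if n > HULL_CUTOFF else "brute"
    if method == "brute" or n < 3:
        dist_m, pair = _brute_diameter(points)
        return dist_m / 1000.0, pair
    try:
        hull = ConvexHull(points)
        verts = np.sort(hull.vertices)
    except QhullError:                 # degenerate (collinear) point sets
        dist_m, pair = _brute_diameter(points)
        return dist_m / 1000.0, pair
    sub = points[verts]
    dist_m, (a, b) = _brute_diameter(sub)
    # map back and re-scan for ties to keep the lexicographic contract
    dd = pdist(sub)
    ties = np.flatnonzero(dd == dist_m)
    best = None
    m = len(sub)
    for flat in ties:
        i = int(m - 2 - np.floor(np.sqrt(-8 * flat + 4 * m * (m - 1) - 7) / 2.0 - 0.5))
        j = int(flat + i + 1 - m * (m - 1) // 2 + (m - i) * ((m - i) - 1) // 2)
        pair = tuple(sorted((int(verts[i]), int(verts[j]))))
        if best is None or pair < best:
            best = pair
    return dist_m / 1000.0, best


def max_width(points: np.ndarray, diameter_pair: tuple[int, int]) -> float:
    """Sum of the largest perpendicular offsets on either side of the
    infinite line through the diameter pair, in km.

    Offsets are signed by the left/right of the directed diameter; a side
    with no points contributes zero. Degenerate (coincident) pairs give 0.
    """
    points = np.asarray(points, dtype=float)
    i, j = diameter_pair
    p, q = points[i], points[j]
    d = q - p
    norm = np.hypot(*d)
    if norm == 0.0:
        return 0.0
    rel = points - p
    offsets = (d[0] * rel[:, 1] - d[1] * rel[:, 0]) / norm
    return float((max(offsets.max(), 0.0) + max(-offsets.min(), 0.0)) / 1000.0)


def compute_metrics(dar: DAR) -> DarMetrics:
    """All four whole-path metrics for one DAR.

    The averaged start and end points (when present) are included in the
    point set, so the invariant chain net displacement <= max displacement
    <= max diameter and max width <= max diameter holds unconditionally.
    """
    pts = dar.points[["x", "y"]].to_numpy(dtype=float)
    if len(pts) == 0:
        raise DataError(f"{dar.dar_id}: DAR has no points")
    extra = [np.asarray(p, dtype=float) for p in (dar.start_point, dar.end_point)
             if p is not None]
    allpts = np.vstack([np.array(extra), pts]) if extra else pts

    net = net_displacement(dar.start_point, dar.end_point)
    maxd = max_displacement(allpts, dar.start_point)
    diam, pair = max_diameter(allpts)
    width = max_width(allpts, pair)
    complete = bool(np.isfinite(net) and np.isfinite(maxd))
    return DarMetrics(dar.dar_id, net, maxd, diam, width, pair, complete)


METRIC_COLUMNS = ["net_displacement", "max_displacement", "max_diameter", "max_width"]


def metrics_table(dars: list[DAR]) -> pd.DataFrame:
    """One row per DAR: dar_id, individual_id, night_date, the four metrics
    (km), diameter indices, and the completeness flag."""
    rows = []
    for d in dars:
        m = compute_metrics(d)
        rows.append({
            "dar_id": m.dar_id,
            "individual_id": d.individual_id,
            "night_date": d.night_date,
            "net_displacement": m.net_displacement,
            "max_displacement": m.max_displacement,
            "max_diameter": m.max_diameter,
            "max_width": m.max_width,
            "diameter_i": m.diameter_pair[0],
            "diameter_j": m.diameter_pair[1],
            "complete": m.complete,
            "no_flight": bool(d.quality.get("no_flight", False)),
        })
    return pd.DataFrame(rows)
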