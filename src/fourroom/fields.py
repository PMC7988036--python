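"""Place-field detection, properties, door overrepresentation, the bridge
index, and tracking of fields across sessions.

A place field is a connected region (8-connectivity by default) of the
foraging rate map above 20% of the map maximum, with at least 9 bins and a
peak above 1 Hz.  The *bridge index* of a field near a door is

    1 - |a - b| / (a + b)

where a and b are the field's bin counts on either side of the door line:
0 when the field sits entirely on one side, 1 at an even split.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import ndimage
from shapely.geometry import MultiPoint

from .maze import DoorSegment, MazeGeometry, SessionProtocol
from .ratemaps import RateMap
from .stats import chi2_expected_proportions, holm_bonferroni

STRUCT_8 = np.ones((3, 3), dtype=bool)
STRUCT_4 = ndimage.generate_binary_structure(2, 1)


@dataclass
class PlaceField:
    """A detected field region and its summary properties."""

    bins: np.ndarray  # (n, 2) array of (row, col) indices
    area: int  # bin count
    centroid: tuple[float, float]  # rate-weighted, world cm
    hull: np.ndarray  # (m, 2) convex hull vertices, world cm
    mean_rate: float  # Hz
    peak_rate: float  # Hz
    origin: tuple[float, float]
    bin_size: float
    session: str | None = None
    cell: int | None = None


def _bin_centers(rows, cols, origin, bin_size):
    xs = origin[0] + (np.asarray(cols) + 0.5) * bin_size
    ys = origin[1] + (np.asarray(rows) + 0.5) * bin_size
    return xs, ys


def detect_fields(
    rate_map: RateMap,
    *,
    threshold_frac: float = 0.2,
    min_area: int = 9,
    min_peak: float = 1.0,
    connectivity: int = 8,
    session: str | None = None,
    cell: int | None = None,
) -> list[PlaceField]:
    """Detect place fields in a (foraging) rate map.

    The threshold is relative (20% of the map maximum) so detection is
    invariant to scaling the map; the absolute 1 Hz peak rule is re-checked
    per region.
    """
    rate = np.where(rate_map.visited, rate_map.rate, np.nan)
    if not np.isfinite(rate).any():
        return []
    peak = np.nanmax(rate)
    if peak <= 0:
        return []
    above = np.where(np.isfinite(rate), rate, -np.inf) >= threshold_frac * peak
    struct = STRUCT_8 if connectivity == 8 else STRUCT_4
    labels, n = ndimage.label(above, structure=struct)
    out = []
    for k in range(1, n + 1):
        region = labels == k
        area = int(region.sum())
        if area < min_area:
            continue
        region_peak = float(np.nanmax(rate[region]))
        if not region_peak > min_peak:
            continue
        rows, cols = np.nonzero(region)
        w = rate[rows, cols]
        xs, ys = _bin_centers(rows, cols, rate_map.origin, rate_map.bin_size)
        cx = float(np.sum(w * xs) / w.sum())
        cy = float(np.sum(w * ys) / w.sum())
        hull = MultiPoint(list(zip(xs, ys))).convex_hull
        hull_xy = np.asarray(hull.exterior.coords) if hull.geom_type == "Polygon" else (
            np.asarray(hull.coords)
        )
        out.append(
            PlaceField(
                np.column_stack([rows, cols]), area, (cx, cy), hull_xy,
                float(np.nanmean(w)), region_peak, rate_map.origin,
                rate_map.bin_size, session, cell,
            )
        )
    return out


@dataclass(frozen=True)
class BridgeResult:
    index: float  # in [0, 1]
    a: float  # bins on the first adjacent box's side
    b: float
    projection_limits: tuple[float, float]  # hull extent along the door-perpendicular axis
    projection_centroid: float


def bridge_index(field: PlaceField, door: DoorSegment) -> BridgeResult:
    """Field extent across a door: 1 - |a-b|/(a+b) over the door side split.

    The splitting line runs through the door centre along the door axis;
    bins whose centre lies exactly on the line count half to each side.
    Also returns the convex-hull projection onto the perpendicular axis.
    """
    rows = field.bins[:, 0]
    cols = field.bins[:, 1]
    xs, ys = _bin_centers(rows, cols, field.origin, field.bin_size)
    # perpendicular coordinate: signed offset from the door line
    if door.axis == "y":  # door line vertical, passage along x
        offs = xs - door.center[0]
        c_perp = field.centroid[0] - door.center[0]
        hull_perp = field.hull[:, 0] - door.center[0]
    else:
        offs = ys - door.center[1]
        c_perp = field.centroid[1] - door.center[1]
        hull_perp = field.hull[:, 1] - door.center[1]
    a = float(np.sum(offs < 0) + 0.5 * np.sum(offs == 0))
    b = float(np.sum(offs > 0) + 0.5 * np.sum(offs == 0))
    if a + b == 0:
        raise ValueError("field has no bins to split")
    idx = 1.0 - abs(a - b) / (a + b)
    return BridgeResult(idx, a, b, (float(hull_perp.min()), float(hull_perp.max())), float(c_perp))


def nearest_door(field: PlaceField, geometry: MazeGeometry) -> tuple[str, float]:
    doors = geometry.door_segments
    best = min(
        doors,
        key=lambda d: (field.centroid[0] - doors[d].center[0]) ** 2
        + (field.centroid[1] - doors[d].center[1]) ** 2,
    )
    c = doors[best].center
    return best, float(np.hypot(field.centroid[0] - c[0], field.centroid[1] - c[1]))


@dataclass
class OverrepresentationResult:
    locked_vs_open: dict[str, object]  # per-session chi-square of the 50/50 door split
    area_test: dict[str, object]  # doors vs dummy doors vs box centres
    corrected_p_locked: np.ndarray
    corrected_p_area: np.ndarray


def _within(px, py, centers, radius):
    d2 = np.min([(px - cx) ** 2 + (py - cy) ** 2 for cx, cy in centers], axis=0)
    return d2 <= radius**2


def overrepresentation_tests(
    fields_by_session: dict[str, list[PlaceField]],
    geometry: MazeGeometry,
    dwell_maps: dict[str, np.ndarray],
    protocol: SessionProtocol,
    *,
    radius: float = 25.0,
    dwell_median_floor: float = 0.01,
    bin_size: float = 2.0,
) -> OverrepresentationResult:
    """Field-count tests around doors.

    (i) per session, fields with centroid within 25 cm of the locked door(s)
    versus the open doors, against a 50/50 split of that total;
    (ii) fields within 25 cm of doors / dummy doors / box centres against
    expectations proportional to the surviving dwell surface of each test
    area (median dwell across sessions, bins below 0.01 s discarded).
    p values are Holm-Bonferroni corrected across sessions.
    """
    if not any(fields_by_session.values()):
        raise ValueError("no fields to test")
    doors = geometry.door_segments
    locked = protocol.locked_doors
    open_doors = [d for d in doors if d not in locked]

    locked_res, locked_p = {}, []
    for label, fields in fields_by_session.items():
        if not fields:
            continue
        cx = np.array([f.centroid[0] for f in fields])
        cy = np.array([f.centroid[1] for f in fields])
        n_locked = int(_within(cx, cy, [doors[d].center for d in locked], radius).sum())
        per_open = _within(cx, cy, [doors[d].center for d in open_doors], radius)
        mean_open = per_open.sum() / max(len(open_doors), 1) * max(len(locked), 1)
        total = n_locked + mean_open
        if total > 0:
            res = chi2_expected_proportions([n_locked, mean_open], [total / 2, total / 2])
            locked_res[label] = res
            locked_p.append(res.p_value)

    # median dwell surface across sessions
    stack = np.stack(list(dwell_maps.values()))
    med = np.median(stack, axis=0)
    surviving = med >= dwell_median_floor
    ny, nx = med.shape
    xs = (np.arange(nx) + 0.5) * bin_size
    ys = (np.arange(ny) + 0.5) * bin_size
    gx, gy = np.meshgrid(xs, ys)
    areas = {
        "doors": [d.center for d in doors.values()],
        "dummy_doors": [d.center for d in geometry.dummy_door_segments.values()],
        "box_centers": list(geometry.box_centers.values()),
    }
    surface = {
        k: int((surviving & _within(gx, gy, centers, radius).reshape(gx.shape)).sum())
        for k, centers in areas.items()
    }
    area_res, area_p = {}, []
    for label, fields in fields_by_session.items():
        if not fields:
            continue
        cx = np.array([f.centroid[0] for f in fields])
        cy = np.array([f.centroid[1] for f in fields])
        obs = np.array([
            _within(cx, cy, centers, radius).sum() for centers in areas.values()
        ], dtype=float)
        n_tot = obs.sum()
        if n_tot == 0:
            continue
        s_tot = sum(surface.values())
        exp = np.array([surface[k] / s_tot for k in areas]) * n_tot
        res = chi2_expected_proportions(obs, exp)
        area_res[label] = res
        area_p.append(res.p_value)

    return OverrepresentationResult(
        locked_res, area_res,
        holm_bonferroni(np.array(locked_p)),
        holm_bonferroni(np.array(area_p)),
    )


def _gap_statistic_k(
    points: np.ndarray, k_max: int, rng: np.random.Generator, n_refs: int = 100,
    n_init: int = 50,
) -> int:
    """Tibshirani gap statistic over k = 1..k_max (uniform reference draws)."""
    from sklearn.cluster import KMeans

    def log_wk(pts, k, seed):
        if k == 1:
            c = pts.mean(axis=0)
            w = np.sum((pts - c) ** 2)
        else:
            km = KMeans(n_clusters=k, n_init=n_init, random_state=seed).fit(pts)
            w = km.inertia_
        return np.log(max(w, 1e-12))

    lo = points.min(axis=0)
    hi = points.max(axis=0)
    gaps, sks = [], []
    for k in range(1, k_max + 1):
        obs = log_wk(points, k, int(rng.integers(2**31)))
        refs = []
        for _ in range(n_refs):
            ref = rng.uniform(lo, hi, size=points.shape)
            refs.append(log_wk(ref, k, int(rng.integers(2**31))))
        refs = np.asarray(refs)
        gaps.append(refs.mean() - obs)
        sks.append(refs.std(ddof=0) * np.sqrt(1 + 1 / n_refs))
    # smallest k whose gap is within one SE of the global maximum gap
    gaps = np.asarray(gaps)
    sks = np.asarray(sks)
    best = int(np.argmax(gaps))
    for k in range(1, k_max + 1):
        if gaps[k - 1] >= gaps[best] - sks[best]:
            return k
    return k_max


@dataclass
class FieldTrackingResult:
    n_clusters: int
    cluster_labels: np.ndarray  # per field
    shifts: np.ndarray  # between-session centroid shifts (cm), <= 60 cm
    excluded_shifts: int
    door_distance_stats: dict[str, tuple[float, float]]  # door/key -> (mean, sd)


def track_fields(
    fields_by_session: dict[str, list[PlaceField]],
    geometry: MazeGeometry,
    protocol: SessionProtocol,
    *,
    rng: np.random.Generator | None = None,
    max_shift: float = 60.0,
    n_refs: int = 100,
) -> FieldTrackingResult:
    """Track fields across sessions by k-means on their weighted centroids.

    The cluster count is chosen by gap evaluation over 1..N (N = maximum
    number of fields in any single session); between-session shifts above
    60 cm (one box side) are excluded.  Door-distance statistics use the
    closest 16 fields per door (Closed-Door) or closest 8 per door side
    (One-Way).
    """
    from sklearn.cluster import KMeans

    rng = rng if rng is not None else np.random.default_rng()
    sessions = [s for s in fields_by_session if fields_by_session[s]]
    if len(sessions) < 2 or sum(len(v) for v in fields_by_session.values()) < 2:
        raise ValueError("need fields from at least two sessions")
    pts, sess_idx = [], []
    for si, s in enumerate(sessions):
        for f in fields_by_session[s]:
            pts.append(f.centroid)
            sess_idx.append(si)
    pts = np.asarray(pts)
    sess_idx = np.asarray(sess_idx)
    k_max = max(len(fields_by_session[s]) for s in sessions)
    k = _gap_statistic_k(pts, max(k_max, 1), rng, n_refs=n_refs)
    if k == 1:
        labels = np.zeros(len(pts), dtype=int)
    else:
        labels = KMeans(n_clusters=k, n_init=50, random_state=int(rng.integers(2**31))).fit_predict(pts)

    shifts, excluded = [], 0
    for c in range(k):
        for si in range(len(sessions) - 1):
            a = pts[(labels == c) & (sess_idx == si)]
            b = pts[(labels == c) & (sess_idx == si + 1)]
            if len(a) and len(b):
                d = float(np.hypot(*(a.mean(axis=0) - b.mean(axis=0))))
                if d > max_shift:
                    excluded += 1
                else:
                    shifts.append(d)

    doors = geometry.door_segments
    stats: dict[str, tuple[float, float]] = {}
    if protocol.sequence_type == "Closed-Door":
        for name, d in doors.items():
            dist = np.sort(np.hypot(pts[:, 0] - d.center[0], pts[:, 1] - d.center[1]))[:16]
            stats[name] = (float(dist.mean()), float(dist.std(ddof=0)))
    else:
        side_groups = _one_way_sides(protocol)
        for name, d in doors.items():
            for side in d.boxes:
                mask = _side_mask(pts, d)
                sel = mask if side in _negative_side_boxes(d) else ~mask
                dd = np.hypot(pts[sel, 0] - d.center[0], pts[sel, 1] - d.center[1])
                dd = np.sort(dd)[:8]
                key = f"{name}:{side}:{side_groups.get((name, side), '?')}"
                stats[key] = (float(dd.mean()) if dd.size else np.nan,
                              float(dd.std(ddof=0)) if dd.size else np.nan)
    return FieldTrackingResult(k, labels, np.asarray(shifts), excluded, stats)


def _negative_side_boxes(door: DoorSegment) -> set[str]:
    # boxes on the negative-offset side of the door line (left / below)
    return {b for b in door.boxes if b in ("A", "D")} if door.axis == "y" else {
        b for b in door.boxes if b in ("C", "D")
    }


def _side_mask(pts: np.ndarray, door: DoorSegment) -> np.ndarray:
    if door.axis == "y":
        return pts[:, 0] < door.center[0]
    return pts[:, 1] < door.center[1]


def _one_way_sides(protocol: SessionProtocol) -> dict[tuple[str, str], str]:
    from .behavior import door_side_groups

    return {k: ("locked" if v == "locked-plan" else "open")
            for k, v in door_side_groups(protocol).items()}
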