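"""Occupancy, spike and firing-rate maps, spatial information and the
place-cell classifier.

Maps are bivariate histograms on a 2 cm square grid anchored to the maze
geometry (not to the data extent), so maps from different sessions are
directly comparable bin-for-bin.  Spike and dwell maps are smoothed with a
Gaussian kernel (sigma 2.5 bins, 9x9 support) *before* division; the kernel
is renormalized over visited bins so that mass is not smeared into the
unvisited void.  Bins occupied for less than 0.05 s are considered empty.

Spatial information is the Skaggs statistic in bits/s,

    SI = sum_i p_i * lam_i * log2(lam_i / lam),

with p_i the occupancy probability of bin i, lam_i its firing rate and lam
the occupancy-weighted overall mean rate.  Its significance is assessed
against 100 circular spike-train time shifts (uniform in [20 s, T - 20 s]).
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Sequence

import numpy as np
from scipy import ndimage

from .maze import MazeGeometry

BIN_SIZE_CM = 2.0
SMOOTH_SIGMA_BINS = 2.5
KERNEL_BINS = 9
DWELL_FLOOR_S = 0.05
SPEED_FLOOR_CMS = 5.0


def gaussian_kernel(sigma: float = SMOOTH_SIGMA_BINS, size: int = KERNEL_BINS) -> np.ndarray:
    half = size // 2
    ax = np.arange(-half, half + 1, dtype=float)
    xx, yy = np.meshgrid(ax, ax)
    k = np.exp(-(xx**2 + yy**2) / (2.0 * sigma**2))
    return k / k.sum()


def masked_smooth(values: np.ndarray, valid: np.ndarray, kernel: np.ndarray) -> np.ndarray:
    """Convolve over valid bins only, renormalizing the kernel at mask edges.

    Invalid bins come back NaN.
    """
    v = np.where(valid, values, 0.0)
    num = ndimage.convolve(v, kernel, mode="constant", cval=0.0)
    den = ndimage.convolve(valid.astype(float), kernel, mode="constant", cval=0.0)
    out = np.full_like(num, np.nan)
    np.divide(num, den, out=out, where=valid & (den > 0))
    return out


@dataclass
class RateMap:
    """A smoothed firing-rate map with its raw dwell/spike histograms.

    Arrays are indexed [row, col] = [y bin, x bin]; ``origin`` is the world
    coordinate of the grid's lower-left corner.
    """

    rate: np.ndarray  # Hz, NaN on empty bins
    dwell: np.ndarray  # raw seconds per bin
    spikes: np.ndarray  # raw spike counts per bin
    dwell_smoothed: np.ndarray
    spikes_smoothed: np.ndarray
    visited: np.ndarray  # dwell >= floor
    origin: tuple[float, float]
    bin_size: float = BIN_SIZE_CM
    behavior_filter: str = "all"  # 'all' | 'foraging' | 'goal-directed'

    @property
    def peak_rate(self) -> float:
        if not self.visited.any():
            return 0.0
        return float(np.nanmax(self.rate))

    @property
    def shape(self) -> tuple[int, int]:
        return self.rate.shape

    def bin_centers(self) -> tuple[np.ndarray, np.ndarray]:
        """(x, y) world coordinates of every bin centre, shaped like rate."""
        ny, nx = self.rate.shape
        xs = self.origin[0] + (np.arange(nx) + 0.5) * self.bin_size
        ys = self.origin[1] + (np.arange(ny) + 0.5) * self.bin_size
        return np.meshgrid(xs, ys)

    def subview(self, mask: np.ndarray) -> "MapView":
        return MapView(self.rate, self.visited & mask)


@dataclass
class MapView:
    """A masked view of a rate map (e.g. a 25 cm doorway region)."""

    rate: np.ndarray
    visited: np.ndarray

    @property
    def peak_rate(self) -> float:
        if not self.visited.any():
            return 0.0
        return float(np.nanmax(np.where(self.visited, self.rate, np.nan)))


@dataclass(frozen=True)
class SpatialInfoResult:
    observed: float  # bits/s
    shuffle: np.ndarray  # shuffle SI values
    significant: bool  # observed > 95th percentile of shuffle
    percentile_bound: float


def _filter_samples(
    t: np.ndarray,
    speed: np.ndarray,
    mode_labels: np.ndarray | None,
    mode: str,
    speed_floor: float,
) -> np.ndarray:
    keep = speed >= speed_floor
    if mode != "all":
        if mode_labels is None:
            raise ValueError("mode filter requested but no mode labels supplied")
        keep &= mode_labels == mode
    return keep


def build_maps(
    trajectory,
    spike_times: Sequence[float],
    *,
    origin: tuple[float, float] = (0.0, 0.0),
    extent: float | tuple[float, float] | None = None,
    geometry: MazeGeometry | None = None,
    mode_labels: np.ndarray | None = None,
    mode: str = "all",
    speed_floor: float = SPEED_FLOOR_CMS,
    bin_size: float = BIN_SIZE_CM,
    sigma_bins: float = SMOOTH_SIGMA_BINS,
    kernel_bins: int = KERNEL_BINS,
    dwell_floor: float = DWELL_FLOOR_S,
) -> RateMap:
    """Speed- and mode-filtered dwell/spike/rate maps.

    ``trajectory`` provides arrays ``t, x, y`` (attributes or a 3-tuple).
    ``extent`` is the side length (or (width, height)) of the mapped area;
    it defaults to the maze footprint when ``geometry`` is given.
    """
    from .behavior import compute_speed  # local import to avoid a cycle

    if hasattr(trajectory, "t"):
        t, x, y = np.asarray(trajectory.t), np.asarray(trajectory.x), np.asarray(trajectory.y)
    else:
        t, x, y = (np.asarray(a, dtype=float) for a in trajectory)
    if extent is None:
        if geometry is None:
            raise ValueError("need extent or geometry")
        extent = geometry.footprint
    wx, wy = (extent, extent) if np.isscalar(extent) else extent
    nx = int(round(wx / bin_size))
    ny = int(round(wy / bin_size))

    speed = compute_speed((t, x, y))
    keep = _filter_samples(t, speed, mode_labels, mode, speed_floor)
    dt = float(np.median(np.diff(t))) if t.size > 1 else 0.0

    xk, yk = x[keep], y[keep]
    in_grid = (
        (xk >= origin[0]) & (xk < origin[0] + nx * bin_size)
        & (yk >= origin[1]) & (yk < origin[1] + ny * bin_size)
    )
    xk, yk = xk[in_grid], yk[in_grid]
    ix = np.floor((xk - origin[0]) / bin_size).astype(int)
    iy = np.floor((yk - origin[1]) / bin_size).astype(int)
    dwell = np.zeros((ny, nx))
    np.add.at(dwell, (iy, ix), dt)

    # spikes inherit the filter of the tracking sample they fall into
    st = np.asarray(spike_times, dtype=float)
    st = st[(st >= t[0]) & (st <= t[-1])] if t.size else st[:0]
    spikes = np.zeros((ny, nx))
    if st.size:
        idx = np.clip(np.searchsorted(t, st, side="right") - 1, 0, t.size - 1)
        ok = keep[idx]
        sx = np.interp(st[ok], t, x)
        sy = np.interp(st[ok], t, y)
        ing = (
            (sx >= origin[0]) & (sx < origin[0] + nx * bin_size)
            & (sy >= origin[1]) & (sy < origin[1] + ny * bin_size)
        )
        jx = np.floor((sx[ing] - origin[0]) / bin_size).astype(int)
        jy = np.floor((sy[ing] - origin[1]) / bin_size).astype(int)
        np.add.at(spikes, (jy, jx), 1.0)

    visited = dwell >= dwell_floor
    kernel = gaussian_kernel(sigma_bins, kernel_bins)
    dwell_s = masked_smooth(dwell, visited, kernel)
    spikes_s = masked_smooth(spikes, visited, kernel)
    rate = np.full_like(dwell, np.nan)
    np.divide(spikes_s, dwell_s, out=rate, where=visited & (dwell_s > 0))
    return RateMap(rate, dwell, spikes, dwell_s, spikes_s, visited, origin, bin_size, mode)


def box_maps(
    trajectory,
    spike_times: Sequence[float],
    geometry: MazeGeometry,
    **kwargs,
) -> dict[str, RateMap]:
    """Per-box rate maps, each cut to its box rectangle and smoothed alone."""
    out = {}
    for box in geometry.box_origins:
        x0, y0, x1, y1 = geometry.box_rect(box)
        out[box] = build_maps(
            trajectory, spike_times, origin=(x0, y0), extent=(x1 - x0, y1 - y0), **kwargs
        )
    return out


def doorway_maps(
    box_rate_maps: dict[str, RateMap],
    geometry: MazeGeometry,
    radius: float = 25.0,
) -> dict[tuple[str, str], MapView]:
    """25 cm doorway regions, one per (door, box side), cut from box maps."""
    out = {}
    for door in geometry.door_segments.values():
        cx, cy = door.center
        for box in door.boxes:
            m = box_rate_maps[box]
            xs, ys = m.bin_centers()
            mask = (xs - cx) ** 2 + (ys - cy) ** 2 <= radius**2
            out[(door.name, box)] = m.subview(mask)
    return out


def spatial_information(rate_map: RateMap | MapView, dwell: np.ndarray | None = None) -> float:
    """Skaggs information rate in bits/s over visited bins."""
    visited = rate_map.visited
    if not visited.any():
        return 0.0
    lam = np.where(visited, rate_map.rate, 0.0)[visited]
    if dwell is None:
        if not isinstance(rate_map, RateMap):
            raise ValueError("a dwell map is required for MapView inputs")
        dwell = rate_map.dwell_smoothed
    occ = np.where(visited, dwell, 0.0)[visited]
    total = occ.sum()
    if total <= 0:
        return 0.0
    p = occ / total
    overall = float(np.sum(p * lam))
    if overall <= 0:
        return 0.0
    ratio = lam / overall
    terms = np.where(lam > 0, p * lam * np.log2(np.where(ratio > 0, ratio, 1.0)), 0.0)
    return float(terms.sum())


def circular_shift_spikes(
    spike_times: np.ndarray, duration: float, shift: float, t0: float = 0.0
) -> np.ndarray:
    """Shift spike times by ``shift`` seconds, wrapping around the session."""
    st = np.asarray(spike_times, dtype=float)
    return np.sort(t0 + np.mod(st - t0 + shift, duration))


def spike_shift_shuffle(
    trajectory,
    spike_times: Sequence[float],
    duration: float,
    *,
    n_shuffles: int = 100,
    rng: np.random.Generator | None = None,
    min_margin: float = 20.0,
    **map_kwargs,
) -> SpatialInfoResult:
    """Shuffle significance of spatial information via circular time shifts.

    Each shuffle shifts the whole spike train by a uniform random interval in
    [20 s, duration - 20 s] (wrapping), preserving spike count and inter-spike
    structure, then rebuilds the map and recomputes SI.
    """
    if duration <= 2 * min_margin:
        raise ValueError("session too short for the 20 s shift margin")
    rng = rng if rng is not None else np.random.default_rng()
    t0 = float(np.asarray(trajectory.t if hasattr(trajectory, "t") else trajectory[0])[0])
    observed_map = build_maps(trajectory, spike_times, **map_kwargs)
    observed = spatial_information(observed_map)
    shuffled = np.empty(n_shuffles)
    st = np.asarray(spike_times, dtype=float)
    for k in range(n_shuffles):
        shift = rng.uniform(min_margin, duration - min_margin)
        shifted = circular_shift_spikes(st, duration, shift, t0=t0)
        shuffled[k] = spatial_information(build_maps(trajectory, shifted, **map_kwargs))
    bound = float(np.percentile(shuffled, 95))
    return SpatialInfoResult(observed, shuffled, bool(observed > bound), bound)


@dataclass(frozen=True)
class CellSessionStats:
    """Per-session summary used by the place-cell classifier."""

    session_label: str
    mean_rate: float  # Hz, spikes / session duration
    spatial_info: float  # bits/s
    si_significant: bool


@dataclass(frozen=True)
class PlaceCellResult:
    is_place_cell: bool
    reasons: tuple[str, ...] = ()
    best_session: str | None = None


def classify_place_cell(
    session_stats: Sequence[CellSessionStats],
    waveform_width_us: float,
    *,
    min_rate: float = 0.1,
    max_rate: float = 5.0,
    min_si: float = 0.5,
    min_width_us: float = 300.0,
    min_active_sessions: int = 2,
) -> PlaceCellResult:
    """Putative place-cell classification.

    The cell must fire above 0.1 Hz in at least two sessions and, in its
    highest-rate session: mean rate in (0.1, 5) Hz, SI > 0.5 bits/s, SI above
    the 95th shuffle percentile, and waveform width > 300 us.
    """
    if not session_stats:
        raise ValueError("need at least one session of statistics")
    reasons = []
    active = sum(s.mean_rate > min_rate for s in session_stats)
    if active < min_active_sessions:
        reasons.append("active-sessions")
    best = max(session_stats, key=lambda s: s.mean_rate)
    if not (best.mean_rate > min_rate):
        reasons.append("rate-floor")
    if not (best.mean_rate < max_rate):
        reasons.append("rate-ceiling")
    if not (best.spatial_info > min_si):
        reasons.append("spatial-information")
    if not best.si_significant:
        reasons.append("si-shuffle")
    if not (waveform_width_us > min_width_us):
        reasons.append("waveform-width")
    return PlaceCellResult(not reasons, tuple(reasons), best.session_label)
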