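"""Memoryless Bayesian decoding of position (and box quadrants) from
population spike counts.

Spiking is modelled as Poisson and independent across neurons within
tau = 300 ms windows.  With a uniform prior over position bins x, the
posterior is

    P(x | s) prop. prod_i Poisson(s_i | lam_xi * tau),

evaluated in the log domain with a small rate floor (0.01 Hz) on the
training rates to keep zero-rate bins finite.  Training rate maps always
come from a different session than the decoded data; windows where the
animal moved slower than 5 cm/s are dropped.  Decoded and true positions
are summarized in a 16x16 confusion matrix over box quadrants, rows
normalized to probabilities; chance performance is 1/16.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .behavior import compute_speed
from .data import Trajectory
from .maze import MazeGeometry, quadrant_of
from .ratemaps import RateMap

TAU_S = 0.3
RATE_FLOOR_HZ = 0.01
MIN_CELLS = 15
SPEED_FLOOR_CMS = 5.0


@dataclass
class DecoderModel:
    """Per-cell expected rates over position bins, from training-session maps."""

    cell_ids: tuple[int, ...]
    rates: np.ndarray  # (n_cells, n_bins), floored, Hz
    bin_xy: np.ndarray  # (n_bins, 2) world coordinates of bin centres
    tau: float
    train_session: str | None = None

    @property
    def n_cells(self) -> int:
        return len(self.cell_ids)

    @property
    def n_bins(self) -> int:
        return self.rates.shape[1]


def fit_decoder(
    training_maps: dict[int, RateMap],
    *,
    tau: float = TAU_S,
    rate_floor: float = RATE_FLOOR_HZ,
    min_cells: int = MIN_CELLS,
    train_session: str | None = None,
) -> DecoderModel:
    """Build the decoding model from one session's rate maps.

    Position bins are the bins visited in the training session (the dwell
    grid is shared across simultaneously recorded cells).
    """
    if len(training_maps) < min_cells:
        raise ValueError(
            f"need at least {min_cells} simultaneously recorded place cells, "
            f"got {len(training_maps)}"
        )
    cids = tuple(sorted(training_maps))
    first = training_maps[cids[0]]
    visited = first.visited.copy()
    for m in training_maps.values():
        if m.rate.shape != first.rate.shape:
            raise ValueError("training maps must share a grid")
    rows, cols = np.nonzero(visited)
    xs, ys = first.bin_centers()
    bin_xy = np.column_stack([xs[rows, cols], ys[rows, cols]])
    rates = np.empty((len(cids), rows.size))
    for i, c in enumerate(cids):
        r = training_maps[c].rate[rows, cols]
        r = np.where(np.isfinite(r), r, 0.0)
        rates[i] = np.maximum(r, rate_floor)
    return DecoderModel(cids, rates, bin_xy, tau, train_session)


def decode_window(
    counts: np.ndarray,
    model: DecoderModel,
    *,
    rng: np.random.Generator | None = None,
) -> tuple[np.ndarray, int]:
    """Posterior over bins and the arg-max bin for one spike-count vector.

    Ties break to the lowest bin index unless an ``rng`` is supplied.
    """
    counts = np.asarray(counts, dtype=float)
    if counts.shape != (model.n_cells,):
        raise ValueError("count vector length must equal the cell count")
    log_post = _log_likelihoods(counts[None, :], model)[0]
    log_post -= log_post.max()
    post = np.exp(log_post)
    post /= post.sum()
    best = np.flatnonzero(log_post == log_post.max())
    pick = int(best[0]) if rng is None else int(rng.choice(best))
    return post, pick


def _log_likelihoods(counts: np.ndarray, model: DecoderModel) -> np.ndarray:
    """(n_windows, n_bins) Poisson log likelihood (constant terms dropped)."""
    lam = model.rates * model.tau  # (cells, bins)
    return counts @ np.log(lam) - lam.sum(axis=0)[None, :]


@dataclass
class ConfusionMatrix:
    counts: np.ndarray  # 16x16, rows = true quadrant, cols = decoded
    zero_rows: np.ndarray  # rows with no windows

    @property
    def probabilities(self) -> np.ndarray:
        sums = self.counts.sum(axis=1, keepdims=True)
        with np.errstate(invalid="ignore", divide="ignore"):
            p = self.counts / sums
        p[self.zero_rows] = np.nan
        return p

    def category_summary(self) -> dict[str, float]:
        """Mean probability by category: correct quadrant (diagonal), same
        quadrant in the wrong box, wrong quadrant in the same box, rest."""
        p = self.probabilities
        n = 16
        cats = {"diagonal": [], "same_quadrant_wrong_box": [],
                "same_box_wrong_quadrant": [], "rest": []}
        for i in range(n):
            if self.zero_rows[i]:
                continue
            for j in range(n):
                if i == j:
                    cats["diagonal"].append(p[i, j])
                elif i % 4 == j % 4:
                    cats["same_quadrant_wrong_box"].append(p[i, j])
                elif i // 4 == j // 4:
                    cats["same_box_wrong_quadrant"].append(p[i, j])
                else:
                    cats["rest"].append(p[i, j])
        out = {k: float(np.mean(v)) if v else float("nan") for k, v in cats.items()}
        out["chance"] = 1.0 / 16.0
        return out


@dataclass
class DecodingResult:
    confusion: ConfusionMatrix
    summary: dict[str, float]
    n_windows: int
    decoded_quadrants: np.ndarray
    true_quadrants: np.ndarray


def decode_session(
    model: DecoderModel,
    trajectory: Trajectory,
    spike_times: dict[int, np.ndarray],
    geometry: MazeGeometry,
    *,
    test_session: str | None = None,
    speed_floor: float = SPEED_FLOOR_CMS,
) -> DecodingResult:
    """Decode a test session window-by-window and summarize as a confusion
    matrix of actual vs predicted quadrants.

    Windows are non-overlapping ``tau`` intervals anchored at the session
    start; a window's speed is the mean sample speed within it and windows
    below 5 cm/s are dropped.  The true quadrant uses the window's mean
    position.
    """
    if test_session is not None and model.train_session == test_session:
        raise ValueError("training and test data must come from different sessions")
    t = trajectory.t
    t0, t1 = float(t[0]), float(t[-1])
    n_win = int((t1 - t0) / model.tau)
    if n_win == 0:
        raise ValueError("session shorter than one decoding window")
    speed = compute_speed(trajectory)
    win_idx = np.clip(((t - t0) / model.tau).astype(int), 0, n_win - 1)

    # window means of speed and position
    sums = np.bincount(win_idx, minlength=n_win)
    mean_speed = np.bincount(win_idx, weights=speed, minlength=n_win) / np.maximum(sums, 1)
    mean_x = np.bincount(win_idx, weights=trajectory.x, minlength=n_win) / np.maximum(sums, 1)
    mean_y = np.bincount(win_idx, weights=trajectory.y, minlength=n_win) / np.maximum(sums, 1)
    keep = (sums > 0) & (mean_speed >= speed_floor)
    if not keep.any():
        raise ValueError("no decoding windows survive the speed filter")

    counts = np.zeros((n_win, model.n_cells))
    for i, cid in enumerate(model.cell_ids):
        st = np.asarray(spike_times.get(cid, ()), dtype=float)
        st = st[(st >= t0) & (st < t0 + n_win * model.tau)]
        if st.size:
            counts[:, i] = np.bincount(((st - t0) / model.tau).astype(int), minlength=n_win)

    log_l = _log_likelihoods(counts[keep], model)
    best = np.argmax(log_l, axis=1)  # lowest index wins ties (np.argmax)
    decoded_xy = model.bin_xy[best]
    decoded_q = np.array([quadrant_of(p, geometry) for p in decoded_xy])
    true_q = np.array([
        quadrant_of((mx, my), geometry)
        for mx, my in zip(mean_x[keep], mean_y[keep])
    ])

    conf = np.zeros((16, 16))
    np.add.at(conf, (true_q - 1, decoded_q - 1), 1.0)
    zero_rows = conf.sum(axis=1) == 0
    cm = ConfusionMatrix(conf, zero_rows)
    return DecodingResult(cm, cm.category_summary(), int(keep.sum()), decoded_q, true_q)
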