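"""Synthetic four-room sessions with known ground truth.

The generator emulates the study conditions end to end: five-session
sequences (O1, O2, C1, C2, O3) with per-direction door locking, 12
bell-cued trials per session following the protocol's goal list, behavior
alternating between fast, direct goal-directed travel and slow, circuitous
foraging in the rewarded box, door pushes that adapt to the lock state with
a tunable learning rate, and place cells firing as inhomogeneous Poisson
processes driven by ground-truth maps built from sums of planar Gaussians.

Ground-truth maps support per-box field repetition (the same field template
recurring in 2, 3 or 4 boxes), connectivity-triggered remapping at the
O2 -> C1 transition, and slow across-session drift (small centroid jitter
plus multiplicative rate noise).  Every generated quantity is recorded so
each analysis stage has a parameter-recovery oracle.

Spike generation uses thinning against the cell's peak rate with continuous
event times (sub-millisecond resolution); position is interpolated linearly
between 50 Hz tracking samples.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .data import BellEvent, EventLog, PushEvent, SpikeData, Trajectory
from .maze import (
    BOXES,
    ConnectivityState,
    MazeGeometry,
    SESSION_LABELS,
    SessionProtocol,
    shortest_door_path,
)

TRANSITIONS = (("O1", "O2"), ("O2", "C1"), ("C1", "C2"), ("C2", "O3"))


@dataclass
class SimulationConfig:
    """Knobs of the synthetic world; defaults emulate the study conditions."""

    n_cells: int = 30
    tracking_rate_hz: float = 50.0
    session_minutes: float = 23.0
    foraging_speed: tuple[float, float] = (8.0, 25.0)  # cm/s
    goal_speed: tuple[float, float] = (35.0, 60.0)  # cm/s
    fields_per_cell_probs: tuple[float, ...] = (0.35, 0.30, 0.20, 0.15)  # P(1..4 fields)
    field_sigma_cm: float = 8.0
    peak_rate_range: tuple[float, float] = (2.0, 8.0)  # Hz
    fraction_repeating: float = 0.15
    repeat_k: int = 2  # boxes sharing the repeated template
    fraction_connectivity_remapping: float = 0.0
    drift_centroid_cm: float = 1.0  # per-session centroid jitter SD
    drift_rate_sd: float = 0.05  # per-session multiplicative log-rate SD
    push_avoidance_learning: float = 0.8  # decay per locked-door push
    naive_push_prob: float = 0.9  # initial P(trying a locked door on the old route)
    protocol: SessionProtocol = field(default_factory=SessionProtocol.closed_door)
    geometry: MazeGeometry = field(default_factory=MazeGeometry)

    def __post_init__(self):
        if not 0 <= self.fraction_repeating <= 1:
            raise ValueError("fraction_repeating must be in [0,1]")
        if not 0 <= self.fraction_connectivity_remapping <= 1:
            raise ValueError("fraction_connectivity_remapping must be in [0,1]")
        if self.session_minutes <= 0:
            raise ValueError("session duration must be positive")
        if self.repeat_k not in (2, 3, 4):
            raise ValueError("repeat_k must be 2, 3 or 4")
        if min(self.peak_rate_range) < 0:
            raise ValueError("rates must be >= 0")


@dataclass
class GroundTruthCell:
    """True rate function per session: a sum of planar Gaussians."""

    cell_id: int
    centers: dict[str, np.ndarray]  # session -> (n_fields, 2) cm
    sigmas: dict[str, np.ndarray]  # session -> (n_fields,) cm
    peaks: dict[str, np.ndarray]  # session -> (n_fields,) Hz
    repetition_k: int = 1  # 1 = no repetition
    remap_flags: tuple[bool, bool, bool, bool] = (False, False, False, False)
    waveform_width_us: float = 400.0

    def rate(self, x, y, session: str) -> np.ndarray:
        x = np.asarray(x, dtype=float)
        y = np.asarray(y, dtype=float)
        out = np.zeros(np.broadcast(x, y).shape)
        for (cx, cy), s, p in zip(
            self.centers[session], self.sigmas[session], self.peaks[session]
        ):
            out += p * np.exp(-((x - cx) ** 2 + (y - cy) ** 2) / (2 * s**2))
        return out

    def peak_total(self, session: str) -> float:
        return float(self.peaks[session].sum()) if self.peaks[session].size else 0.0

    def truth_map(self, session: str, geometry: MazeGeometry, bin_size: float = 2.0) -> np.ndarray:
        n = int(round(geometry.footprint / bin_size))
        c = (np.arange(n) + 0.5) * bin_size
        xs, ys = np.meshgrid(c, c)
        return self.rate(xs, ys, session)


def _random_field_offset(rng, geometry: MazeGeometry, margin: float = 8.0) -> np.ndarray:
    s = geometry.box_side
    return rng.uniform(margin, s - margin, size=2)


def make_ground_truth(
    config: SimulationConfig,
    rng: np.random.Generator,
    *,
    independent_sessions: bool = False,
) -> list[GroundTruthCell]:
    """Draw the ground-truth cell population.

    A ``fraction_repeating`` of cells place one field template at the same
    within-box offset in ``repeat_k`` boxes; a ``fraction_connectivity_remapping``
    of cells redraw their fields between O2 and C1; the rest keep their O1
    fields up to drift.  With ``independent_sessions=True`` every session's
    map is an independent draw (the chance-similarity regime used to
    calibrate shuffle-based classifiers).
    """
    geom = config.geometry
    origins = geom.box_origins
    cells = []
    for cid in range(config.n_cells):
        def draw_fields():
            if rng.random() < config.fraction_repeating:
                k = config.repeat_k
                offset = _random_field_offset(rng, geom)
                boxes = list(rng.choice(list(BOXES), size=k, replace=False))
                centers = np.array([np.add(origins[b], offset) for b in boxes])
                peak = rng.uniform(*config.peak_rate_range)
                peaks = np.full(k, peak)
                return centers, peaks, k
            n_fields = 1 + rng.choice(len(config.fields_per_cell_probs),
                                      p=config.fields_per_cell_probs)
            boxes = rng.choice(list(BOXES), size=n_fields, replace=True)
            centers = np.array([
                np.add(origins[b], _random_field_offset(rng, geom)) for b in boxes
            ])
            peaks = rng.uniform(*config.peak_rate_range, size=n_fields)
            return centers, peaks, 1

        centers0, peaks0, rep_k = draw_fields()
        sigma = config.field_sigma_cm
        centers: dict[str, np.ndarray] = {}
        peaks: dict[str, np.ndarray] = {}
        sigmas: dict[str, np.ndarray] = {}
        remap = [False, False, False, False]
        if independent_sessions:
            for s in SESSION_LABELS:
                c, p, _ = draw_fields()
                centers[s], peaks[s] = c, p
                sigmas[s] = np.full(len(c), sigma)
            remap = [True, True, True, True]
            rep_k = 1
        else:
            remaps_at_c1 = rng.random() < config.fraction_connectivity_remapping
            cur_c, cur_p = centers0, peaks0
            for s in SESSION_LABELS:
                if s == "C1" and remaps_at_c1:
                    cur_c, cur_p, _ = draw_fields()
                    remap[1] = True
                if s != "O1":
                    cur_c = cur_c + rng.normal(0, config.drift_centroid_cm, cur_c.shape)
                    cur_p = cur_p * np.exp(rng.normal(0, config.drift_rate_sd, cur_p.shape))
                centers[s], peaks[s] = cur_c.copy(), cur_p.copy()
                sigmas[s] = np.full(len(cur_c), sigma)
        width = rng.uniform(320, 520)  # putative pyramidal waveform widths, us
        cells.append(GroundTruthCell(cid, centers, sigmas, peaks, rep_k, tuple(remap), width))
    return cells


def make_repetition_truth(
    config: SimulationConfig,
    rng: np.random.Generator,
    k: int = 1,
) -> list[GroundTruthCell]:
    """Cells with exactly one field per box; ``k`` boxes share the template.

    This balanced design (every box occupied) is the natural population for
    cross-box repetition analyses: with ``k = 1`` all four within-box field
    offsets are independent, with ``k > 1`` a random subset of ``k`` boxes
    carries the same within-box offset.  Drift and remapping settings of the
    config apply as in :func:`make_ground_truth`.
    """
    if k not in (1, 2, 3, 4):
        raise ValueError("k must be 1..4")
    geom = config.geometry
    origins = geom.box_origins
    sigma = config.field_sigma_cm
    cells = []
    for cid in range(config.n_cells):
        offsets = {b: _random_field_offset(rng, geom) for b in BOXES}
        if k > 1:
            shared = _random_field_offset(rng, geom)
            for b in rng.choice(list(BOXES), size=k, replace=False):
                offsets[b] = shared
        peak = rng.uniform(*config.peak_rate_range)
        base = np.array([np.add(origins[b], offsets[b]) for b in BOXES])
        peaks0 = np.full(4, peak)
        centers, peaks, sigmas = {}, {}, {}
        cur_c, cur_p = base, peaks0
        for s in SESSION_LABELS:
            if s != "O1":
                cur_c = cur_c + rng.normal(0, config.drift_centroid_cm, cur_c.shape)
                cur_p = cur_p * np.exp(rng.normal(0, config.drift_rate_sd, cur_p.shape))
            centers[s], peaks[s] = cur_c.copy(), cur_p.copy()
            sigmas[s] = np.full(4, sigma)
        cells.append(GroundTruthCell(cid, centers, sigmas, peaks, k))
    return cells


# ---------------------------------------------------------------------------
# behavioral simulation

def _door_approach_points(door, geometry: MazeGeometry) -> dict[str, np.ndarray]:
    """A point just inside each adjacent box, facing the door centre."""
    cx, cy = door.center
    off = geometry.door_size / 2.0 + 4.0
    pts = {}
    for b in door.boxes:
        bx, by = geometry.box_centers[b]
        if door.axis == "y":  # passage along x
            pts[b] = np.array([cx - off if bx < cx else cx + off, cy])
        else:
            pts[b] = np.array([cx, cy - off if by < cy else cy + off])
    return pts


class _Walker:
    """Accumulates 50 Hz samples; keeps time, position and mode labels."""

    def __init__(self, start: np.ndarray, rate_hz: float, rng: np.random.Generator):
        self.dt = 1.0 / rate_hz
        self.rng = rng
        self.t = [0.0]
        self.xy = [np.asarray(start, dtype=float)]
        self.mode = ["foraging"]

    @property
    def now(self) -> float:
        return self.t[-1]

    @property
    def pos(self) -> np.ndarray:
        return self.xy[-1]

    def walk_to(self, target: np.ndarray, speed: float, mode: str, jitter: float = 1.0):
        p = self.pos.copy()
        target = np.asarray(target, dtype=float)
        step = speed * self.dt
        while np.linalg.norm(target - p) > step:
            d = target - p
            p = p + d / np.linalg.norm(d) * step
            if jitter > 0:
                p = p + self.rng.normal(0, jitter * self.dt, 2)
            self._push(p, mode)
        self._push(target.copy(), mode)

    def dwell(self, seconds: float, mode: str):
        n = max(int(round(seconds / self.dt)), 1)
        for _ in range(n):
            p = self.pos + self.rng.normal(0, 0.3, 2)
            self._push(p, mode)

    def _push(self, p: np.ndarray, mode: str):
        self.t.append(self.now + self.dt)
        self.xy.append(p)
        self.mode.append(mode)


def simulate_session(
    config: SimulationConfig,
    state: ConnectivityState,
    rng: np.random.Generator,
    *,
    start_box: str | None = None,
    locked_pushes_so_far: int = 0,
) -> tuple[Trajectory, EventLog, np.ndarray, int]:
    """One session of behavior: 12 bell-cued trials from the goal list.

    Returns the trajectory, the event log, the per-sample ground-truth mode
    labels, and the updated locked-push counter (the agent's connectivity
    knowledge carries across sessions of a sequence).

    The agent navigates near-shortest paths respecting its *beliefs*: a
    naive agent tries locked doors on the previously open route with a
    probability that decays by ``exp(-push_avoidance_learning)`` per locked
    push; locked doors are never crossed.
    """
    geom = config.geometry
    protocol = config.protocol
    goals = protocol.goal_list
    if start_box is None:
        start_box = next(b for b in BOXES if b != goals[0])
    start = np.asarray(geom.box_centers[start_box]) + rng.uniform(-8, 8, 2)
    walker = _Walker(start, config.tracking_rate_hz, rng)
    bells: list[BellEvent] = []
    pushes: list[PushEvent] = []
    n_locked = locked_pushes_so_far

    trial_budget = config.session_minutes * 60.0 / len(goals)
    doors = geom.door_segments
    current = start_box
    # brief exploration-like settling before the first bell
    walker.dwell(2.0, "foraging")

    for goal in goals:
        bells.append(BellEvent(walker.now, goal))
        t_bell = walker.now
        # --- goal-directed travel -------------------------------------
        here = current
        guard = 0
        while here != goal and guard < 12:
            guard += 1
            open_path = shortest_door_path(ConnectivityState.all_open(state.session_label),
                                           here, goal)
            true_path = shortest_door_path(state, here, goal)
            if not true_path.reachable:
                raise ValueError(f"goal {goal} unreachable from {here}")
            # does the memorized (all-open) route use a door now locked?
            tempted = None
            if open_path.first_doors:
                first = str(rng.choice(sorted(open_path.first_doors)))
                if state.is_locked(here, _other_box(first, here)):
                    tempted = first
            p_try = config.naive_push_prob * np.exp(
                -config.push_avoidance_learning * n_locked
            )
            if tempted is not None and rng.random() < p_try:
                # push the locked door, fail, reconsider
                ap = _door_approach_points(doors[tempted], geom)[here]
                speed = rng.uniform(*config.goal_speed)
                walker.walk_to(ap, speed, "goal-directed")
                pushes.append(PushEvent(walker.now, tempted, here, False))
                n_locked += 1
                walker.dwell(0.6, "goal-directed")
                continue
            door = str(rng.choice(sorted(true_path.first_doors)))
            nxt = _other_box(door, here)
            ap = _door_approach_points(doors[door], geom)
            speed = rng.uniform(*config.goal_speed)
            walker.walk_to(ap[here], speed, "goal-directed")
            pushes.append(PushEvent(walker.now, door, here, True))
            walker.walk_to(np.asarray(doors[door].center), speed, "goal-directed")
            walker.walk_to(ap[nxt], speed, "goal-directed")
            here = nxt
        current = here
        # --- foraging in the goal box ---------------------------------
        travel = walker.now - t_bell
        forage_s = max(trial_budget - travel, 20.0)
        x0, y0, x1, y1 = geom.box_rect(goal)
        t_end = walker.now + forage_s
        while walker.now < t_end:
            target = rng.uniform([x0 + 4, y0 + 4], [x1 - 4, y1 - 4])
            walker.walk_to(target, rng.uniform(*config.foraging_speed), "foraging")
    traj = Trajectory(np.asarray(walker.t), *np.asarray(walker.xy).T)
    np.clip(traj.x, 0.5, geom.footprint - 0.5, out=traj.x)
    np.clip(traj.y, 0.5, geom.footprint - 0.5, out=traj.y)
    return traj, EventLog(bells, pushes), np.asarray(walker.mode, dtype=object), n_locked


def _other_box(door: str, box: str) -> str:
    a, b = door[0], door[1]
    return b if box == a else a


def simulate_spikes(
    trajectory: Trajectory,
    cell: GroundTruthCell,
    session: str,
    rng: np.random.Generator,
) -> np.ndarray:
    """Inhomogeneous Poisson spike times by thinning.

    Candidate events are drawn homogeneously at the cell's summed peak rate
    and accepted with probability rate(position)/peak; positions are
    interpolated between tracking samples, so effective resolution is the
    candidate spacing (well under 1 ms at typical rates).
    """
    lam_max = cell.peak_total(session)
    if lam_max <= 0:
        return np.array([])
    T = trajectory.duration
    n = rng.poisson(lam_max * T)
    times = np.sort(rng.uniform(trajectory.t[0], trajectory.t[-1], size=n))
    x, y = trajectory.position_at(times)
    lam = cell.rate(x, y, session)
    accept = rng.uniform(0, lam_max, size=n) < lam
    return times[accept]


@dataclass
class SimulatedSession:
    label: str
    state: ConnectivityState
    trajectory: Trajectory
    events: EventLog
    mode_truth: np.ndarray  # per-sample 'foraging' / 'goal-directed'
    spikes: SpikeData


@dataclass
class SimulatedSequence:
    config: SimulationConfig
    cells: list[GroundTruthCell]
    sessions: list[SimulatedSession]

    def session(self, label: str) -> SimulatedSession:
        for s in self.sessions:
            if s.label == label:
                return s
        raise KeyError(label)


def synth_waveform(width_us: float, amp: float = 120.0, rate_hz: float = 48000.0,
                   n_samples: int = 64) -> np.ndarray:
    """Two-parameter biphasic template on 4 channels with decaying amplitude."""
    t = np.arange(n_samples) / rate_hz * 1e6  # us
    t_peak = 200.0
    t_trough = t_peak + width_us
    sigma = max(width_us / 4.0, 40.0)
    w = np.exp(-((t - t_peak) ** 2) / (2 * (sigma / 2) ** 2)) - 0.9 * np.exp(
        -((t - t_trough) ** 2) / (2 * sigma**2)
    )
    scales = amp * np.array([1.0, 0.7, 0.45, 0.3])
    return scales[:, None] * w[None, :]


def simulate_sequence(
    config: SimulationConfig,
    seed: int | np.random.Generator,
    *,
    independent_sessions: bool = False,
) -> SimulatedSequence:
    """Simulate a full five-session sequence with spikes for every cell."""
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    cells = make_ground_truth(config, rng, independent_sessions=independent_sessions)
    sessions = []
    n_locked = 0
    current_box = None
    for st in config.protocol.session_states:
        traj, events, modes, n_locked = simulate_session(
            config, st, rng, start_box=current_box, locked_pushes_so_far=n_locked
        )
        if not st.session_label.startswith("C"):
            n_locked = max(n_locked - 1, 0)  # mild forgetting between lock regimes
        spk = {c.cell_id: simulate_spikes(traj, c, st.session_label, rng) for c in cells}
        wf = {c.cell_id: synth_waveform(c.waveform_width_us) for c in cells}
        sessions.append(
            SimulatedSession(st.session_label, st, traj, events, modes,
                             SpikeData(spk, wf))
        )
        # next session starts where the animal finished (same box)
        from .maze import assign_region, nearest_box

        last = (traj.x[-1], traj.y[-1])
        region = assign_region(last, config.geometry)
        current_box = region if region in BOXES else nearest_box(last, config.geometry)
    return SimulatedSequence(config, cells, sessions)
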