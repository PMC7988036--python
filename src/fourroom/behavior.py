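"""Behavior segmentation and connectivity-knowledge metrics.

Sessions alternate between two locomotor modes: slow, circuitous *foraging*
within a box and fast, direct *goal-directed* travel between boxes.  A box
visit counts as foraging when the animal covered more than 120 cm of path
and more than 20% of the box area (10x10 unsmoothed grid, bins with more
than one tracking sample).  Samples around door crossings (1 s before to
1 s after) and door pushes (2 s before to 1 s after) are goal-directed
regardless of the visit they fall in, as are all samples of non-foraging
visits.

The module also owns the offline correction of manually flagged events, the
normalized door-push rates that index connectivity knowledge, bell-response
metrics, and the optimal-first-door / correct-first-foraging scores.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .data import EventLog, PushEvent, Trajectory
from .maze import (
    BOXES,
    ConnectivityState,
    MazeGeometry,
    SessionProtocol,
    are_adjacent,
    assign_region,
    door_between,
    nearest_box,
    shortest_door_path,
)

FORAGING_MIN_PATH_CM = 120.0
FORAGING_MIN_COVERAGE = 0.20
COVERAGE_GRID = 10  # per box side, unsmoothed
CROSS_WINDOW = (1.0, 1.0)  # s before, after a door crossing
PUSH_WINDOW = (2.0, 1.0)  # s before, after a door push


def compute_speed(trajectory) -> np.ndarray:
    """Per-sample running speed (cm/s): forward-difference distance / time.

    The last sample copies the previous value.
    """
    if hasattr(trajectory, "t"):
        t, x, y = trajectory.t, trajectory.x, trajectory.y
    else:
        t, x, y = (np.asarray(a, dtype=float) for a in trajectory)
    if t.size < 2:
        raise ValueError("need at least 2 samples")
    dt = np.diff(t)
    if np.any(dt <= 0):
        raise ValueError("timestamps must be strictly increasing")
    v = np.hypot(np.diff(x), np.diff(y)) / dt
    return np.concatenate([v, v[-1:]])


def sample_boxes(trajectory: Trajectory, geometry: MazeGeometry) -> np.ndarray:
    """Box label per sample; door-gap samples attach to the preceding box."""
    labels = np.empty(trajectory.t.size, dtype=object)
    prev = None
    for i in range(trajectory.t.size):
        region = assign_region((trajectory.x[i], trajectory.y[i]), geometry)
        if region in BOXES:
            prev = region
        elif prev is None:
            prev = nearest_box((trajectory.x[i], trajectory.y[i]), geometry)
        labels[i] = prev
    return labels


@dataclass(frozen=True)
class VisitSegment:
    box: str
    start: float
    end: float
    path_length: float  # cm, summed over non-overlapping 1 s windows
    coverage: float  # fraction of the 10x10 box grid with > 1 sample
    mode: str  # 'foraging' | 'goal-directed'
    start_index: int = 0
    end_index: int = 0  # inclusive


def _windowed_path_length(t, x, y, window: float = 1.0) -> float:
    """Path length summed within non-overlapping 1 s windows anchored at the
    visit start; steps straddling a window boundary are not counted."""
    if t.size < 2:
        return 0.0
    win = np.floor((t - t[0]) / window).astype(int)
    steps = np.hypot(np.diff(x), np.diff(y))
    same = win[:-1] == win[1:]
    return float(steps[same].sum())


def _coverage(x, y, box: str, geometry: MazeGeometry) -> float:
    x0, y0, x1, y1 = geometry.box_rect(box)
    cell = (x1 - x0) / COVERAGE_GRID
    inside = (x >= x0) & (x < x1) & (y >= y0) & (y < y1)
    if not inside.any():
        return 0.0
    ix = np.floor((x[inside] - x0) / cell).astype(int)
    iy = np.floor((y[inside] - y0) / cell).astype(int)
    counts = np.zeros((COVERAGE_GRID, COVERAGE_GRID))
    np.add.at(counts, (iy, ix), 1)
    return float((counts > 1).sum() / counts.size)


def segment_and_classify(
    trajectory: Trajectory,
    events: EventLog,
    geometry: MazeGeometry,
) -> tuple[list[VisitSegment], np.ndarray]:
    """Split a session into box visits and label every sample's mode.

    Returns the visit list and a per-sample array of 'foraging' /
    'goal-directed' labels.  Door-crossing and push windows override the
    visit-level label at the sample level.
    """
    boxes = sample_boxes(trajectory, geometry)
    t = trajectory.t
    change = np.flatnonzero(boxes[1:] != boxes[:-1]) + 1
    starts = np.concatenate([[0], change])
    ends = np.concatenate([change - 1, [boxes.size - 1]])

    visits: list[VisitSegment] = []
    for s, e in zip(starts, ends):
        seg_t, seg_x, seg_y = t[s : e + 1], trajectory.x[s : e + 1], trajectory.y[s : e + 1]
        path = _windowed_path_length(seg_t, seg_x, seg_y)
        cov = _coverage(seg_x, seg_y, boxes[s], geometry)
        foraging = path > FORAGING_MIN_PATH_CM and cov > FORAGING_MIN_COVERAGE
        visits.append(
            VisitSegment(
                boxes[s], float(seg_t[0]), float(seg_t[-1]), path, cov,
                "foraging" if foraging else "goal-directed", int(s), int(e),
            )
        )

    labels = np.empty(t.size, dtype=object)
    for v in visits:
        labels[v.start_index : v.end_index + 1] = v.mode
    # goal-directed overrides around door crossings ...
    for idx in change:
        lo, hi = t[idx] - CROSS_WINDOW[0], t[idx] + CROSS_WINDOW[1]
        labels[(t >= lo) & (t <= hi)] = "goal-directed"
    # ... and around pushes
    for push in events.pushes:
        lo, hi = push.time - PUSH_WINDOW[0], push.time + PUSH_WINDOW[1]
        labels[(t >= lo) & (t <= hi)] = "goal-directed"
    return visits, labels


def door_crossings(trajectory: Trajectory, geometry: MazeGeometry) -> list[tuple[float, str, str]]:
    """(time, door, origin box) of every box-to-box transition."""
    boxes = sample_boxes(trajectory, geometry)
    out = []
    for i in np.flatnonzero(boxes[1:] != boxes[:-1]) + 1:
        a, b = boxes[i - 1], boxes[i]
        if are_adjacent(a, b):
            out.append((float(trajectory.t[i]), door_between(a, b), a))
    return out


@dataclass
class CleanedEvents:
    events: EventLog
    rejected_trials: list[int]  # bell indices where the rat was already at goal
    replaced_pushes: int = 0
    filled_pushes: int = 0


def clean_event_flags(
    events: EventLog,
    trajectory: Trajectory,
    geometry: MazeGeometry,
) -> CleanedEvents:
    """Correct manually flagged events against the tracked position.

    Trials where the animal was already in the goal box at the bell are
    rejected; pushes impossible given the animal's box are replaced by the
    first door crossed after the bell; trials missing a first push are
    filled with the first crossing.  Bell events are never altered.
    """
    events = events.sorted()
    boxes = sample_boxes(trajectory, geometry)
    crossings = door_crossings(trajectory, geometry)

    def box_at(time: float) -> str:
        i = int(np.clip(np.searchsorted(trajectory.t, time, side="right") - 1, 0, boxes.size - 1))
        return boxes[i]

    bell_times = [b.time for b in events.bells]
    rejected = [i for i, b in enumerate(events.bells) if box_at(b.time) == b.goal_box]

    new_pushes: list[PushEvent] = []
    replaced = filled = 0
    for i, bell in enumerate(events.bells):
        t_end = bell_times[i + 1] if i + 1 < len(bell_times) else np.inf
        trial_pushes = [p for p in events.pushes if bell.time <= p.time < t_end]
        after = [c for c in crossings if c[0] > bell.time and c[0] < t_end]
        if i in rejected:
            new_pushes.extend(trial_pushes)
            continue
        fixed = []
        for p in trial_pushes:
            here = box_at(p.time)
            if here in p.door:  # plausible: animal adjacent to the door it pushed
                fixed.append(p)
            elif after:
                fixed.append(PushEvent(after[0][0], after[0][1], after[0][2], True))
                replaced += 1
        if not fixed and after:
            fixed.append(PushEvent(after[0][0], after[0][1], after[0][2], True))
            filled += 1
        new_pushes.extend(fixed)
    # keep pushes before the first bell (exploration) untouched
    if bell_times:
        new_pushes.extend(p for p in events.pushes if p.time < bell_times[0])
    else:
        new_pushes = list(events.pushes)
    cleaned = EventLog(list(events.bells), sorted(new_pushes, key=lambda p: p.time))
    return CleanedEvents(cleaned, rejected, replaced, filled)


def door_side_groups(protocol: SessionProtocol) -> dict[tuple[str, str], str]:
    """Map each (door, side) to 'locked-plan' or 'open'.

    'locked-plan' sides are the door directions locked during C1/C2: in
    control (O) sessions these form the 'control' group, in C sessions the
    'locked' group.
    """
    from .maze import _DOOR_BOXES

    c1 = protocol.state("C1")
    groups = {}
    for door, (a, b) in _DOOR_BOXES.items():
        for side, other in ((a, b), (b, a)):
            groups[(door, side)] = "locked-plan" if c1.is_locked(side, other) else "open"
    return groups


def push_rate_analysis(
    session_events: dict[str, EventLog],
    protocol: SessionProtocol,
    session_durations: dict[str, float],
    n_quarters: int = 1,
) -> pd.DataFrame:
    """Pushes per door side per minute, grouped by lock plan.

    Returns tidy rows (session, quarter, group, rate) where group is
    'control' (will-be/was-locked sides in O sessions), 'locked' (those
    sides in C sessions) or 'open'.  ``n_quarters`` > 1 splits each session
    into equal time quarters.
    """
    side_groups = door_side_groups(protocol)
    rows = []
    for label, ev in session_events.items():
        dur = session_durations[label]
        if dur <= 0:
            raise ValueError(f"session {label} has non-positive duration")
        in_test = label.startswith("C")
        t0 = min((b.time for b in ev.bells), default=0.0)
        qlen = dur / n_quarters
        for q in range(n_quarters):
            lo, hi = t0 + q * qlen, t0 + (q + 1) * qlen
            counts = {"locked-plan": 0, "open": 0}
            for p in ev.pushes:
                if lo <= p.time < hi:
                    counts[side_groups[(p.door, p.side)]] += 1
            n_plan = sum(1 for g in side_groups.values() if g == "locked-plan")
            n_open = len(side_groups) - n_plan
            minutes = qlen / 60.0
            rows.append(
                dict(
                    session=label, quarter=q + 1,
                    group="locked" if in_test else "control",
                    rate=counts["locked-plan"] / max(n_plan, 1) / minutes,
                )
            )
            rows.append(dict(session=label, quarter=q + 1, group="open",
                             rate=counts["open"] / max(n_open, 1) / minutes))
    return pd.DataFrame(rows)


@dataclass
class BellResponse:
    pre_speed: np.ndarray  # mean speed 1 s before each bell (cm/s)
    post_speed: np.ndarray  # mean speed 1 s after
    latencies: np.ndarray  # bell -> next push (s), NaN when none
    shuffle_latencies: np.ndarray  # pooled over shuffles


def bell_response_metrics(
    trajectory: Trajectory,
    events: EventLog,
    *,
    n_shuffles: int = 1000,
    rng: np.random.Generator | None = None,
) -> BellResponse:
    """Speed change and push latency around bell sounds, with a uniform-time
    shuffle for the latencies (N random times per shuffle, N = real pushes)."""
    rng = rng if rng is not None else np.random.default_rng()
    speed = compute_speed(trajectory)
    t = trajectory.t
    pre, post = [], []
    for b in events.bells:
        if b.time + 1.0 > t[-1] or b.time - 1.0 < t[0]:
            continue  # bell too close to the session edge for the speed metric
        pre.append(float(speed[(t >= b.time - 1.0) & (t < b.time)].mean()))
        post.append(float(speed[(t > b.time) & (t <= b.time + 1.0)].mean()))

    push_times = np.array(sorted(p.time for p in events.pushes))
    lat = []
    for b in events.bells:
        nxt = push_times[push_times > b.time]
        lat.append(float(nxt[0] - b.time) if nxt.size else np.nan)

    shuffle = []
    bell_times = np.array([b.time for b in events.bells])
    n = push_times.size
    for _ in range(n_shuffles):
        pts = np.sort(rng.uniform(t[0], t[-1], size=n))
        idx = np.searchsorted(pts, bell_times, side="right")
        ok = idx < n
        shuffle.extend((pts[idx[ok]] - bell_times[ok]).tolist())
    return BellResponse(np.array(pre), np.array(post), np.array(lat), np.array(shuffle))


@dataclass
class FirstChoiceResult:
    trials: pd.DataFrame  # one row per scored trial
    door_accuracy_by_distance: dict[int, float]
    foraging_accuracy: float
    door_chance: float = 0.5
    foraging_chance: float = 1.0 / 3.0
    dropped: list[int] = field(default_factory=list)


def first_choice_accuracy(
    events: EventLog,
    visits: list[VisitSegment],
    state: ConnectivityState,
    *,
    start_boxes: list[str] | None = None,
    rejected_trials: list[int] | None = None,
) -> FirstChoiceResult:
    """Optimal first door pushes and correct first foraging after each bell.

    A first push is optimal when its door lies on some shortest door path
    from the start box to the goal; open-session trials at distance 2 are
    discarded (both doors are equally optimal).  First foraging is correct
    when the first foraging visit after the bell (in a box other than the
    start box) is the goal box.  Chance levels are 1/2 and 1/3.
    """
    rejected = set(rejected_trials or [])
    open_session = state.session_label.startswith("O")
    bell_times = [b.time for b in events.bells]
    pushes_sorted = sorted(events.pushes, key=lambda p: p.time)
    push_times = np.array([p.time for p in pushes_sorted])
    visit_starts = np.array([v.start for v in visits])
    rows, dropped = [], []
    path_cache: dict[tuple[str, str], object] = {}
    for i, bell in enumerate(events.bells):
        if i in rejected:
            continue
        t_end = bell_times[i + 1] if i + 1 < len(bell_times) else np.inf
        if start_boxes is not None:
            start = start_boxes[i]
        else:
            j = int(np.searchsorted(visit_starts, bell.time, side="right")) - 1
            start = visits[j].box if 0 <= j < len(visits) and visits[j].end >= bell.time else None
        if start is None or start == bell.goal_box:
            dropped.append(i)
            continue
        key = (start, bell.goal_box)
        if key not in path_cache:
            path_cache[key] = shortest_door_path(state, start, bell.goal_box)
        path = path_cache[key]
        jp = int(np.searchsorted(push_times, bell.time, side="left"))
        first_push = pushes_sorted[jp] if jp < len(pushes_sorted) and push_times[jp] < t_end else None
        first_forage = None
        jv = int(np.searchsorted(visit_starts, bell.time, side="right"))
        while jv < len(visits) and visits[jv].start < t_end:
            v = visits[jv]
            if v.mode == "foraging" and v.box != start:
                first_forage = v
                break
            jv += 1
        if first_push is None and first_forage is None:
            dropped.append(i)
            continue
        door_ok = first_push.door in path.first_doors if first_push else None
        score_door = door_ok is not None and not (open_session and path.hops == 2)
        forage_ok = first_forage.box == bell.goal_box if first_forage else None
        rows.append(
            dict(
                trial=i, start=start, goal=bell.goal_box, distance=path.hops,
                first_door=first_push.door if first_push else None,
                door_optimal=door_ok, door_scored=score_door,
                first_foraging=first_forage.box if first_forage else None,
                foraging_correct=forage_ok,
            )
        )
    df = pd.DataFrame(rows)
    by_dist: dict[int, float] = {}
    forage_acc = float("nan")
    if not df.empty:
        scored = df[df.door_scored & df.door_optimal.notna()]
        for d, grp in scored.groupby("distance"):
            by_dist[int(d)] = float(grp.door_optimal.mean())
        fz = df[df.foraging_correct.notna()]
        if len(fz):
            forage_acc = float(fz.foraging_correct.mean())
    return FirstChoiceResult(df, by_dist, forage_acc, dropped=dropped)
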