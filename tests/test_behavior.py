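"""Behavior segmentation, event cleaning and connectivity-knowledge metrics."""

import numpy as np
import pytest

from fourroom import behavior
from fourroom.behavior import (
    VisitSegment,
    bell_response_metrics,
    clean_event_flags,
    compute_speed,
    first_choice_accuracy,
    push_rate_analysis,
    segment_and_classify,
)
from fourroom.data import BellEvent, EventLog, PushEvent, Trajectory
from fourroom.maze import ConnectivityState


class TestSpeed:
    def test_stationary(self):
        t = np.arange(0, 5, 0.02)
        v = compute_speed((t, np.full_like(t, 1.0), np.full_like(t, 2.0)))
        assert np.all(v == 0)

    def test_uniform_motion(self):
        t = np.arange(0, 5, 0.02)
        v = compute_speed((t, 10.0 * t, np.zeros_like(t)))
        assert np.allclose(v, 10.0)

    def test_matches_pairwise_oracle(self, rng):
        t = np.arange(0, 3, 0.02)
        x = np.cumsum(rng.normal(0, 0.3, t.size))
        y = np.cumsum(rng.normal(0, 0.3, t.size))
        v = compute_speed((t, x, y))
        for i in range(t.size - 1):
            d = np.hypot(x[i + 1] - x[i], y[i + 1] - y[i]) / (t[i + 1] - t[i])
            assert v[i] == pytest.approx(d)
        assert v[-1] == v[-2]

    def test_nonmonotone_rejected(self):
        with pytest.raises(ValueError):
            compute_speed((np.array([0.0, 1.0, 0.5]), np.zeros(3), np.zeros(3)))


def _box_walk(geometry, box, duration, rate=50.0, speed=15.0, seed=0):
    """A circuitous walk within one box (high coverage)."""
    rng = np.random.default_rng(seed)
    x0, y0, x1, y1 = geometry.box_rect(box)
    n = int(duration * rate)
    t = np.arange(n) / rate
    pts = [np.array([(x0 + x1) / 2, (y0 + y1) / 2])]
    target = rng.uniform([x0 + 3, y0 + 3], [x1 - 3, y1 - 3])
    for _ in range(n - 1):
        d = target - pts[-1]
        dist = np.linalg.norm(d)
        if dist < 1:
            target = rng.uniform([x0 + 3, y0 + 3], [x1 - 3, y1 - 3])
            d = target - pts[-1]
            dist = np.linalg.norm(d)
        pts.append(pts[-1] + d / dist * speed / rate)
    xy = np.array(pts)
    return t, xy[:, 0], xy[:, 1]


class TestSegmentation:
    def test_foraging_visit_detected(self, geometry):
        t, x, y = _box_walk(geometry, "D", 30.0)
        traj = Trajectory(t, x, y)
        visits, labels = segment_and_classify(traj, EventLog(), geometry)
        assert len(visits) == 1
        v = visits[0]
        assert v.box == "D"
        assert v.path_length > 120 and v.coverage > 0.2
        assert v.mode == "foraging"

    def test_short_visit_is_goal_directed(self, geometry):
        # ~3 s straight dash through a box: < 120 cm
        t = np.arange(0, 3, 0.02)
        x = 5 + 15 * t
        y = np.full_like(t, 30.0)
        visits, labels = segment_and_classify(Trajectory(t, x, y), EventLog(), geometry)
        assert all(v.mode == "goal-directed" for v in visits)

    def test_push_window_overrides_foraging(self, geometry):
        t, x, y = _box_walk(geometry, "D", 30.0)
        traj = Trajectory(t, x, y)
        ev = EventLog(pushes=[PushEvent(15.0, "AD", "D", False)])
        _, labels = segment_and_classify(traj, ev, geometry)
        win = (t >= 13.0) & (t <= 16.0)
        assert np.all(labels[win] == "goal-directed")
        before = (t >= 5.0) & (t <= 12.0)
        assert np.all(labels[before] == "foraging")

    def test_modes_partition_samples(self, geometry, small_sequence):
        s = small_sequence.sessions[0]
        _, labels = segment_and_classify(s.trajectory, s.events, geometry)
        assert set(np.unique(labels)) <= {"foraging", "goal-directed"}

    def test_translation_invariance_of_classification(self, geometry):
        # shifting the whole frame with the maze moves boxes with it; the
        # classification depends only on relative geometry
        t, x, y = _box_walk(geometry, "A", 25.0)
        visits1, _ = segment_and_classify(Trajectory(t, x, y), EventLog(), geometry)
        visits2, _ = segment_and_classify(Trajectory(t, x.copy(), y.copy()), EventLog(), geometry)
        assert [v.mode for v in visits1] == [v.mode for v in visits2]

    def test_recovers_planted_modes(self, geometry, small_sequence):
        s = small_sequence.sessions[0]
        _, labels = segment_and_classify(s.trajectory, s.events, geometry)
        agree = (labels == s.mode_truth).mean()
        assert agree > 0.9


class TestEventCleaning:
    def test_clean_log_unchanged(self, geometry, small_sequence):
        s = small_sequence.sessions[0]
        res = clean_event_flags(s.events, s.trajectory, geometry)
        assert res.replaced_pushes == 0
        assert [b.time for b in res.events.bells] == [b.time for b in s.events.bells]

    def test_bell_in_goal_box_rejected(self, geometry):
        t, x, y = _box_walk(geometry, "D", 20.0)
        traj = Trajectory(t, x, y)
        ev = EventLog(bells=[BellEvent(5.0, "D")])
        res = clean_event_flags(ev, traj, geometry)
        assert res.rejected_trials == [0]

    def test_impossible_push_replaced(self, geometry, small_sequence):
        s = small_sequence.sessions[0]
        ev = s.events.sorted()
        bell = ev.bells[0]
        # fabricate a push on a door not adjacent to the animal's position
        boxes = behavior.sample_boxes(s.trajectory, geometry)
        i = np.searchsorted(s.trajectory.t, bell.time + 0.2)
        here = boxes[i]
        far_door = {"A": "BC", "B": "AD", "C": "AB", "D": "AB"}[here]
        bad = EventLog(list(ev.bells), [PushEvent(bell.time + 0.2, far_door, here, False)])
        res = clean_event_flags(bad, s.trajectory, geometry)
        assert res.replaced_pushes + res.filled_pushes >= 1
        fixed = [p for p in res.events.pushes if p.time > bell.time]
        assert fixed and fixed[0].door != far_door


class TestPushRates:
    def make_events(self, n_ab, n_cd, t_max=600.0):
        pushes = [PushEvent(t_max * (i + 1) / (n_ab + 1), "AB", "A", True) for i in range(n_ab)]
        pushes += [PushEvent(t_max * (i + 1) / (n_cd + 1), "CD", "C", True) for i in range(n_cd)]
        return EventLog(bells=[BellEvent(0.0, "B")], pushes=pushes)

    def test_no_pushes_zero_rates(self, closed_door_protocol):
        ev = {s: EventLog() for s in ("O1", "O2", "C1", "C2", "O3")}
        df = push_rate_analysis(ev, closed_door_protocol, {s: 600.0 for s in ev})
        assert (df.rate == 0).all()

    def test_rate_invariant_to_proportional_scaling(self, closed_door_protocol):
        ev1 = {"O1": self.make_events(6, 12, 600.0)}
        ev2 = {"O1": self.make_events(12, 24, 1200.0)}
        df1 = push_rate_analysis(ev1, closed_door_protocol, {"O1": 600.0})
        df2 = push_rate_analysis(ev2, closed_door_protocol, {"O1": 1200.0})
        assert np.allclose(df1.rate.to_numpy(), df2.rate.to_numpy())

    def test_learned_agent_pushes_locked_door_less(self, closed_door_protocol, small_sequence):
        ev = {s.label: s.events for s in small_sequence.sessions}
        dur = {s.label: s.trajectory.duration for s in small_sequence.sessions}
        df = push_rate_analysis(ev, closed_door_protocol, dur)
        c1 = df[df.session == "C1"].set_index("group").rate
        assert c1["locked"] < c1["open"]

    def test_zero_duration_rejected(self, closed_door_protocol):
        with pytest.raises(ValueError):
            push_rate_analysis({"O1": EventLog()}, closed_door_protocol, {"O1": 0.0})


class TestBellResponse:
    def test_stationary_agent_pre_equals_post(self, rng):
        t = np.arange(0, 100, 0.02)
        traj = Trajectory(t, np.full_like(t, 30.0), np.full_like(t, 30.0))
        ev = EventLog(bells=[BellEvent(50.0, "A")], pushes=[PushEvent(60.0, "AD", "A", True)])
        res = bell_response_metrics(traj, ev, rng=rng, n_shuffles=10)
        assert res.pre_speed[0] == res.post_speed[0] == 0.0

    def test_sprinting_agent_post_exceeds_pre(self, geometry, small_sequence):
        s = small_sequence.sessions[0]
        res = bell_response_metrics(s.trajectory, s.events, n_shuffles=10,
                                    rng=np.random.default_rng(0))
        assert np.mean(res.post_speed) > np.mean(res.pre_speed)

    def test_shuffle_latency_matches_order_statistics(self, rng):
        # with N uniform points the expected gap past a fixed time ~ T/(N+1)
        T, N = 1000.0, 24
        t = np.arange(0, T, 0.02)
        traj = Trajectory(t, np.full_like(t, 30.0), np.full_like(t, 30.0))
        bells = [BellEvent(1.0, "A")]
        pushes = [PushEvent(rng.uniform(0, T), "AD", "A", True) for _ in range(N)]
        res = bell_response_metrics(traj, EventLog(bells, pushes), rng=rng, n_shuffles=2000)
        assert np.mean(res.shuffle_latencies) == pytest.approx(T / (N + 1), rel=0.1)

    def test_bell_in_final_second_omitted(self, rng):
        t = np.arange(0, 10, 0.02)
        traj = Trajectory(t, np.full_like(t, 30.0), np.full_like(t, 30.0))
        ev = EventLog(bells=[BellEvent(9.8, "A")])
        res = bell_response_metrics(traj, ev, rng=rng, n_shuffles=5)
        assert res.pre_speed.size == 0


class TestFirstChoice:
    def make_visits(self, boxes, t0=1.0):
        return [
            VisitSegment(b, t0 + 10 * i, t0 + 10 * i + 8, 200.0, 0.4, "foraging")
            for i, b in enumerate(boxes)
        ]

    def test_always_optimal_agent_scores_one(self):
        st = ConnectivityState.all_open("O1")
        bells = [BellEvent(10 * i, g) for i, g in enumerate("BCDA")]
        pushes = [PushEvent(10 * i + 1, d, s, True)
                  for i, (d, s) in enumerate([("AB", "A"), ("BC", "B"), ("CD", "C"), ("AD", "D")])]
        visits = [VisitSegment(g, 10 * i + 2, 10 * i + 9, 200.0, 0.4, "foraging")
                  for i, g in enumerate("BCDA")]
        res = first_choice_accuracy(EventLog(bells, pushes), visits, st,
                                    start_boxes=list("ABCD"))
        assert all(v == 1.0 for v in res.door_accuracy_by_distance.values())
        assert res.foraging_accuracy == 1.0

    def test_distance_two_open_trials_not_scored_for_doors(self):
        st = ConnectivityState.all_open("O1")
        bells = [BellEvent(0.0, "C")]  # A -> C is diagonal, distance 2
        pushes = [PushEvent(1.0, "AB", "A", True)]
        res = first_choice_accuracy(EventLog(bells, pushes), [], st, start_boxes=["A"])
        assert res.door_accuracy_by_distance == {}
        row = res.trials.iloc[0]
        assert row.distance == 2 and not row.door_scored

    def test_uniform_random_chooser_near_chance(self, rng):
        st = ConnectivityState.all_open("O1")
        n = 4000
        bells, visits, starts = [], [], []
        others = {b: [o for o in "ABCD" if o != b] for b in "ABCD"}
        for i in range(n):
            start = "ABCD"[rng.integers(4)]
            goal = others[start][rng.integers(3)]
            choice = others[start][rng.integers(3)]
            bells.append(BellEvent(10.0 * i, goal))
            visits.append(VisitSegment(choice, 10.0 * i + 1, 10.0 * i + 8,
                                       200.0, 0.4, "foraging"))
            starts.append(start)
        res = first_choice_accuracy(EventLog(bells, []), visits, st, start_boxes=starts)
        assert res.foraging_accuracy == pytest.approx(1 / 3, abs=0.03)
        assert res.foraging_chance == pytest.approx(1 / 3)
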