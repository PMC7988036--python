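"""Synthetic-data generator: invariants, determinism and parameter recovery."""

import numpy as np
import pytest

from fourroom import behavior, ratemaps
from fourroom.fields import detect_fields
from fourroom.maze import ConnectivityState
from fourroom.simulate import (
    GroundTruthCell,
    SimulationConfig,
    make_ground_truth,
    simulate_sequence,
    simulate_session,
    simulate_spikes,
    synth_waveform,
)
from fourroom.stats import width_of_waveform


class TestGroundTruth:
    def test_no_repetition_when_fraction_zero(self, rng, closed_door_protocol):
        cfg = SimulationConfig(n_cells=20, fraction_repeating=0.0,
                               protocol=closed_door_protocol)
        cells = make_ground_truth(cfg, rng)
        assert all(c.repetition_k == 1 for c in cells)

    def test_k4_repetition_identical_across_boxes(self, rng, closed_door_protocol):
        cfg = SimulationConfig(n_cells=10, fraction_repeating=1.0, repeat_k=4,
                               protocol=closed_door_protocol)
        cells = make_ground_truth(cfg, rng)
        geom = cfg.geometry
        for c in cells:
            assert c.repetition_k == 4
            # the per-box offsets of the field centres are all equal
            offs = {tuple(np.round(np.mod(ctr, 76.0), 6)) for ctr in c.centers["O1"]}
            assert len(offs) == 1

    def test_drift_free_truth_identical_across_sessions(self, rng, closed_door_protocol):
        cfg = SimulationConfig(n_cells=5, drift_centroid_cm=0.0, drift_rate_sd=0.0,
                               fraction_connectivity_remapping=0.0,
                               protocol=closed_door_protocol)
        cells = make_ground_truth(cfg, rng)
        for c in cells:
            for s in ("O2", "C1", "C2", "O3"):
                assert np.allclose(c.centers[s], c.centers["O1"])
                assert np.allclose(c.peaks[s], c.peaks["O1"])
            assert not any(c.remap_flags)

    def test_connectivity_remap_flag_set(self, rng, closed_door_protocol):
        cfg = SimulationConfig(n_cells=30, fraction_connectivity_remapping=1.0,
                               protocol=closed_door_protocol)
        cells = make_ground_truth(cfg, rng)
        assert all(c.remap_flags[1] for c in cells)

    def test_invalid_config_rejected(self, closed_door_protocol):
        with pytest.raises(ValueError):
            SimulationConfig(fraction_repeating=1.5, protocol=closed_door_protocol)
        with pytest.raises(ValueError):
            SimulationConfig(session_minutes=0, protocol=closed_door_protocol)


class TestBehaviorSimulation:
    def test_session_invariants(self, geometry, small_sequence):
        for s in small_sequence.sessions:
            assert len(s.events.bells) == 12
            s.trajectory.validate(geometry)
            goals = [b.goal_box for b in s.events.bells]
            assert goals == list(small_sequence.config.protocol.goal_list)
            # locked doors are never crossed
            boxes = behavior.sample_boxes(s.trajectory, geometry)
            for i in np.flatnonzero(boxes[1:] != boxes[:-1]) + 1:
                a, b = boxes[i - 1], boxes[i]
                assert not s.state.is_locked(a, b), f"crossed locked {a}->{b}"
            # crossed=True pushes only on unlocked directions
            for p in s.events.pushes:
                if p.crossed:
                    assert not s.state.is_locked(p.side, _other(p))

    def test_foraging_segments_meet_criteria(self, geometry, small_sequence):
        s = small_sequence.sessions[0]
        visits, _ = behavior.segment_and_classify(s.trajectory, s.events, geometry)
        foraging = [v for v in visits if v.mode == "foraging"]
        assert len(foraging) >= 10
        for v in foraging:
            assert v.path_length > 120.0
            assert v.coverage > 0.2

    def test_same_seed_bit_identical(self, closed_door_protocol):
        cfg = SimulationConfig(n_cells=2, session_minutes=3, protocol=closed_door_protocol)
        a = simulate_sequence(cfg, 42)
        b = simulate_sequence(cfg, 42)
        for sa, sb in zip(a.sessions, b.sessions):
            assert np.array_equal(sa.trajectory.x, sb.trajectory.x)
            assert np.array_equal(sa.spikes.spike_times[0], sb.spikes.spike_times[0])
            assert [p.time for p in sa.events.pushes] == [p.time for p in sb.events.pushes]

    def test_naive_agent_pushes_locked_door_then_learns(self, closed_door_protocol):
        cfg = SimulationConfig(n_cells=1, session_minutes=8,
                               push_avoidance_learning=0.5, naive_push_prob=0.95,
                               protocol=closed_door_protocol)
        rng = np.random.default_rng(3)
        traj, ev, _, n_locked = simulate_session(
            cfg, closed_door_protocol.state("C1"), rng)
        locked_pushes = [p for p in ev.pushes if not p.crossed]
        assert len(locked_pushes) >= 1
        mid = traj.duration / 2 + traj.t[0]
        early = sum(1 for p in locked_pushes if p.time < mid)
        late = len(locked_pushes) - early
        assert early >= late

    def test_locked_push_rate_monotone_in_learning(self, closed_door_protocol):
        counts = []
        for lr in (0.05, 2.0):
            cfg = SimulationConfig(n_cells=1, session_minutes=8,
                                   push_avoidance_learning=lr,
                                   protocol=closed_door_protocol)
            total = 0
            for seed in range(3):
                _, ev, _, _ = simulate_session(
                    cfg, closed_door_protocol.state("C1"),
                    np.random.default_rng(seed))
                total += sum(1 for p in ev.pushes if not p.crossed)
            counts.append(total)
        assert counts[1] < counts[0]

    def test_unreachable_goal_rejected(self, closed_door_protocol):
        cfg = SimulationConfig(n_cells=1, session_minutes=3, protocol=closed_door_protocol)
        # a fully locked maze is not constructible via the public states, so
        # fake one by locking every door both ways
        state = ConnectivityState(
            "C1", {d: frozenset({d[0], d[1]}) for d in ("AB", "AD", "BC", "CD")})
        with pytest.raises(ValueError):
            simulate_session(cfg, state, np.random.default_rng(0))


def _other(p):
    return p.door.replace(p.side, "", 1)


class TestSpikes:
    def test_zero_rate_cell_silent(self, small_sequence, rng):
        cell = GroundTruthCell(99, {"O1": np.empty((0, 2))}, {"O1": np.empty(0)},
                               {"O1": np.empty(0)})
        st = simulate_spikes(small_sequence.sessions[0].trajectory, cell, "O1", rng)
        assert st.size == 0

    def test_constant_rate_poisson_count(self, rng):
        from fourroom.data import Trajectory

        t = np.arange(0, 100.0, 0.02)
        traj = Trajectory(t, np.full_like(t, 68.0), np.full_like(t, 68.0))
        # an effectively flat 5 Hz field (huge sigma)
        cell = GroundTruthCell(0, {"O1": np.array([[68.0, 68.0]])},
                               {"O1": np.array([1e6])}, {"O1": np.array([5.0])})
        n = simulate_spikes(traj, cell, "O1", rng).size
        assert abs(n - 500) < 3 * np.sqrt(500)

    def test_peak_rate_recovered_in_field(self, geometry, rng):
        cfg = SimulationConfig(n_cells=1, session_minutes=10)
        traj, ev, _, _ = simulate_session(cfg, ConnectivityState.all_open("O1"), rng)
        center = np.add(geometry.box_origins["A"], (30.0, 30.0))
        cell = GroundTruthCell(0, {"O1": center[None, :]}, {"O1": np.array([8.0])},
                               {"O1": np.array([6.0])})
        st = simulate_spikes(traj, cell, "O1", rng)
        m = ratemaps.build_maps(traj, st, geometry=geometry, speed_floor=0.0)
        xs, ys = m.bin_centers()
        i = np.unravel_index(
            np.argmin((xs - center[0]) ** 2 + (ys - center[1]) ** 2), xs.shape)
        assert m.rate[i] == pytest.approx(6.0, rel=0.35)

    def test_spikes_sorted_within_session(self, small_sequence):
        for s in small_sequence.sessions:
            for st in s.spikes.spike_times.values():
                assert np.all(np.diff(st) >= 0)


class TestEndToEndRecovery:
    def test_place_cell_classifier_accepts_planted_cells(self, geometry, closed_door_protocol):
        """Cells planted with >= 3 Hz peaks pass the classifier."""
        cfg = SimulationConfig(n_cells=10, session_minutes=6,
                               peak_rate_range=(3.0, 8.0), fraction_repeating=0.0,
                               protocol=closed_door_protocol)
        seq = simulate_sequence(cfg, 17)
        rng = np.random.default_rng(17)
        accepted = 0
        for c in seq.cells:
            stats = []
            for s in seq.sessions:
                st = s.spikes.spike_times[c.cell_id]
                dur = s.trajectory.duration
                if s.label == max(
                    (x.label for x in seq.sessions),
                    key=lambda l: len(seq.session(l).spikes.spike_times[c.cell_id]),
                ):
                    res = ratemaps.spike_shift_shuffle(
                        s.trajectory, st, dur, n_shuffles=30, rng=rng,
                        geometry=geometry)
                    si, sig = res.observed, res.significant
                else:
                    m = ratemaps.build_maps(s.trajectory, st, geometry=geometry)
                    si, sig = ratemaps.spatial_information(m), True
                stats.append(ratemaps.CellSessionStats(s.label, len(st) / dur, si, sig))
            width = width_of_waveform(seq.sessions[0].spikes.waveforms[c.cell_id], 48000.0)
            if ratemaps.classify_place_cell(stats, width).is_place_cell:
                accepted += 1
        assert accepted >= 9  # >= 90% of planted cells

    def test_isolated_field_centroids_recovered(self, geometry):
        cfg = SimulationConfig(n_cells=1, session_minutes=10)
        rng = np.random.default_rng(23)
        traj, ev, _, _ = simulate_session(cfg, ConnectivityState.all_open("O1"), rng)
        visits, labels = behavior.segment_and_classify(traj, ev, geometry)
        errs = []
        for k in range(8):
            box = list(geometry.box_origins)[k % 4]
            center = np.add(geometry.box_origins[box], rng.uniform(16, 44, 2))
            cell = GroundTruthCell(0, {"O1": center[None, :]}, {"O1": np.array([8.0])},
                                   {"O1": np.array([6.0])})
            st = simulate_spikes(traj, cell, "O1", rng)
            m = ratemaps.build_maps(traj, st, geometry=geometry,
                                    mode_labels=labels, mode="foraging")
            fl = detect_fields(m)
            assert fl, "planted field not detected"
            f = max(fl, key=lambda f: f.peak_rate)
            errs.append(np.hypot(f.centroid[0] - center[0], f.centroid[1] - center[1]))
        assert np.mean(errs) <= 4.0


def test_waveform_width_parameter_respected():
    for width in (250.0, 350.0, 450.0):
        w = synth_waveform(width)
        got = width_of_waveform(w, 48000.0)
        assert got == pytest.approx(width, abs=25.0)
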