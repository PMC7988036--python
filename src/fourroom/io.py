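"""Plain-text dataset layout for simulated (or converted) sequences.

A dataset directory holds ``protocol.json``, ``truth.json`` and one
subdirectory per session (``O1`` ... ``O3``) containing ``tracking.csv``
(t,x,y), ``spikes.csv`` (cell_id,t), ``events.csv`` (t,type,door,side,
crossed,goal_box) and ``modes.csv`` (the generator's ground-truth behavior
labels, absent for real data).
"""

from __future__ import annotations

import json
from pathlib import Path

import numpy as np
import pandas as pd

from .data import BellEvent, EventLog, PushEvent, SpikeData, Trajectory
from .maze import SessionProtocol
from .simulate import (
    GroundTruthCell,
    SimulatedSequence,
    SimulatedSession,
    SimulationConfig,
    synth_waveform,
)


def save_dataset(seq: SimulatedSequence, out_dir: str | Path) -> Path:
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    with open(out / "protocol.json", "w") as fh:
        json.dump(seq.config.protocol.to_json(), fh, indent=1)
    truth = {
        "cells": [
            {
                "cell_id": c.cell_id,
                "repetition_k": c.repetition_k,
                "remap_flags": list(c.remap_flags),
                "waveform_width_us": c.waveform_width_us,
                "sessions": {
                    s: {
                        "centers": np.asarray(c.centers[s]).tolist(),
                        "sigmas": np.asarray(c.sigmas[s]).tolist(),
                        "peaks": np.asarray(c.peaks[s]).tolist(),
                    }
                    for s in c.centers
                },
            }
            for c in seq.cells
        ]
    }
    with open(out / "truth.json", "w") as fh:
        json.dump(truth, fh)
    for sess in seq.sessions:
        d = out / sess.label
        d.mkdir(exist_ok=True)
        pd.DataFrame({"t": sess.trajectory.t, "x": sess.trajectory.x,
                      "y": sess.trajectory.y}).to_csv(d / "tracking.csv", index=False)
        rows = [(cid, t) for cid, st in sess.spikes.spike_times.items() for t in st]
        pd.DataFrame(rows, columns=["cell_id", "t"]).to_csv(d / "spikes.csv", index=False)
        ev = [
            dict(t=b.time, type="bell", door="", side="", crossed="", goal_box=b.goal_box)
            for b in sess.events.bells
        ] + [
            dict(t=p.time, type="push", door=p.door, side=p.side,
                 crossed=int(p.crossed), goal_box="")
            for p in sess.events.pushes
        ]
        pd.DataFrame(ev).sort_values("t").to_csv(d / "events.csv", index=False)
        pd.DataFrame({"mode": sess.mode_truth}).to_csv(d / "modes.csv", index=False)
    return out


def load_dataset(path: str | Path) -> SimulatedSequence:
    path = Path(path)
    protocol = SessionProtocol.from_json(json.load(open(path / "protocol.json")))
    with open(path / "truth.json") as fh:
        truth = json.load(fh)
    cells = [
        GroundTruthCell(
            c["cell_id"],
            {s: np.asarray(v["centers"], dtype=float) for s, v in c["sessions"].items()},
            {s: np.asarray(v["sigmas"], dtype=float) for s, v in c["sessions"].items()},
            {s: np.asarray(v["peaks"], dtype=float) for s, v in c["sessions"].items()},
            c["repetition_k"],
            tuple(bool(b) for b in c["remap_flags"]),
            c["waveform_width_us"],
        )
        for c in truth["cells"]
    ]
    config = SimulationConfig(n_cells=len(cells), protocol=protocol)
    sessions = []
    for state in protocol.session_states:
        d = path / state.session_label
        tr = pd.read_csv(d / "tracking.csv")
        traj = Trajectory(tr.t.to_numpy(), tr.x.to_numpy(), tr.y.to_numpy())
        sp = pd.read_csv(d / "spikes.csv")
        spikes = {
            c.cell_id: np.sort(sp[sp.cell_id == c.cell_id].t.to_numpy()) for c in cells
        }
        wf = {c.cell_id: synth_waveform(c.waveform_width_us) for c in cells}
        ev = pd.read_csv(d / "events.csv")
        bells = [BellEvent(r.t, r.goal_box) for r in ev[ev.type == "bell"].itertuples()]
        pushes = [
            PushEvent(r.t, r.door, r.side, bool(int(r.crossed)))
            for r in ev[ev.type == "push"].itertuples()
        ]
        modes_file = d / "modes.csv"
        modes = (
            pd.read_csv(modes_file)["mode"].to_numpy(dtype=object)
            if modes_file.exists()
            else np.array([], dtype=object)
        )
        sessions.append(
            SimulatedSession(state.session_label, state, traj, EventLog(bells, pushes),
                             modes, SpikeData(spikes, wf))
        )
    return SimulatedSequence(config, cells, sessions)
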