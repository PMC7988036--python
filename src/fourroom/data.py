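"""Per-session raw data containers shared by the simulator and the analyses."""

from __future__ import annotations

from dataclasses import dataclass, field


import numpy as np

from .maze import MazeGeometry


@dataclass
class Trajectory:
    """Head position tracked at a fixed rate (default 50 Hz)."""

    t: np.ndarray  # s, uniformly sampled
    x: np.ndarray  # cm
    y: np.ndarray  # cm

    def __post_init__(self):
        self.t = np.asarray(self.t, dtype=float)
        self.x = np.asarray(self.x, dtype=float)
        self.y = np.asarray(self.y, dtype=float)
        if not (self.t.shape == self.x.shape == self.y.shape):
            raise ValueError("t, x, y must have equal length")

    @property
    def duration(self) -> float:
        return float(self.t[-1] - self.t[0]) if self.t.size > 1 else 0.0

    def validate(self, geometry: MazeGeometry, max_speed: float = 200.0) -> None:
        f = geometry.footprint
        if np.any((self.x < 0) | (self.x > f) | (self.y < 0) | (self.y > f)):
            raise ValueError("positions outside maze footprint")
        if self.t.size > 1:
            d = np.hypot(np.diff(self.x), np.diff(self.y)) / np.diff(self.t)
            if np.any(d >= max_speed):
                raise ValueError("per-sample speed exceeds plausibility limit")

    def position_at(self, times) -> tuple[np.ndarray, np.ndarray]:
        times = np.asarray(times, dtype=float)
        return np.interp(times, self.t, self.x), np.interp(times, self.t, self.y)


@dataclass(frozen=True)
class BellEvent:
    time: float
    goal_box: str


@dataclass(frozen=True)
class PushEvent:
    time: float
    door: str  # door name, e.g. 'AB'
    side: str  # box the animal pushed from
    crossed: bool


@dataclass
class EventLog:
    bells: list[BellEvent] = field(default_factory=list)
    pushes: list[PushEvent] = field(default_factory=list)

    def sorted(self) -> "EventLog":
        return EventLog(
            sorted(self.bells, key=lambda e: e.time),
            sorted(self.pushes, key=lambda e: e.time),
        )


@dataclass
class SpikeData:
    """Sorted spike times per cell, with optional mean waveforms for QC."""

    spike_times: dict[int, np.ndarray]
    waveforms: dict[int, np.ndarray] = field(default_factory=dict)  # (ch, samples)
    waveform_rate_hz: float = 48000.0

    def validate(self, session_end: float) -> None:
        for cid, st in self.spike_times.items():
            st = np.asarray(st)
            if st.size and (np.any(np.diff(st) < 0) or st[0] < 0 or st[-1] > session_end + 1e-9):
                raise ValueError(f"cell {cid}: spike times unsorted or out of session")
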