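"""Shared fixtures: geometry, protocols, and a small simulated sequence."""

from __future__ import annotations

import numpy as np
import pytest

from fourroom.maze import MazeGeometry, SessionProtocol
from fourroom.simulate import SimulationConfig, simulate_sequence


@pytest.fixture(scope="session")
def geometry() -> MazeGeometry:
    return MazeGeometry()


@pytest.fixture(scope="session")
def closed_door_protocol() -> SessionProtocol:
    return SessionProtocol.closed_door("AB", goal_list="ABDCBACDCBAD")


@pytest.fixture(scope="session")
def one_way_protocol() -> SessionProtocol:
    return SessionProtocol.one_way(goal_list="ABDCBACDCBAD")


@pytest.fixture(scope="session")
def small_sequence(closed_door_protocol):
    """A short Closed-Door sequence with a handful of cells (shared, read-only)."""
    cfg = SimulationConfig(
        n_cells=6, session_minutes=6, protocol=closed_door_protocol,
        fraction_repeating=0.0,
    )
    return simulate_sequence(cfg, seed=11)


@pytest.fixture()
def rng() -> np.random.Generator:
    return np.random.default_rng(12345)
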