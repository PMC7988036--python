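"""Four-room maze geometry, door connectivity and region queries.

The apparatus is a 2x2 arrangement of square boxes joined by door units set
in the gaps between adjacent boxes.  Saloon-type doors can be locked per
direction, turning the maze into a directed graph over the four boxes.  All
spatial quantities are in centimetres; the coordinate frame has its origin at
the outer lower-left corner of the maze footprint with y pointing up.

Box labels follow a fixed declared convention: A upper-left, B upper-right,
C lower-right, D lower-left.  Quadrant ids 1-16 are ``box_index * 4 +
sub_quadrant + 1`` with boxes ordered A,B,C,D and sub-quadrants numbered
row-major from the lower-left of each box (half-open boundaries: a point
exactly on a centroid axis belongs to the upper/right side).
"""

from __future__ import annotations

import itertools
import json
from dataclasses import dataclass, field
from typing import Iterable, Mapping, Sequence

import networkx as nx
import numpy as np

BOXES = ("A", "B", "C", "D")
#: internal doors, named by the two boxes they join (alphabetical order)
DOORS = ("AB", "AD", "BC", "CD")
SESSION_LABELS = ("O1", "O2", "C1", "C2", "O3")

# adjacency in the 2x2 layout: door name -> (box, box)
_DOOR_BOXES = {"AB": ("A", "B"), "AD": ("A", "D"), "BC": ("B", "C"), "CD": ("C", "D")}
_ADJACENT_PAIRS = frozenset(frozenset(p) for p in _DOOR_BOXES.values())


@dataclass(frozen=True)
class DoorSegment:
    """An internal door: its centre point and the axis its panels lie along.

    ``axis`` is the direction of the door line ('x' horizontal, 'y'
    vertical); the passage direction is perpendicular to it.
    """

    name: str
    center: tuple[float, float]
    axis: str  # 'x' or 'y'
    boxes: tuple[str, str]


@dataclass(frozen=True)
class MazeGeometry:
    """Physical layout of the four-room maze.

    With the defaults the footprint is 136 x 136 cm: two 60 cm boxes per
    side separated by the 16 cm depth of a door unit.
    """

    box_side: float = 60.0
    door_size: float = 16.0
    wall_height: float = 20.0  # metadata only

    @property
    def footprint(self) -> float:
        return 2 * self.box_side + self.door_size

    @property
    def box_origins(self) -> dict[str, tuple[float, float]]:
        """Lower-left corner of each box."""
        s, g = self.box_side, self.door_size
        return {
            "A": (0.0, s + g),
            "B": (s + g, s + g),
            "C": (s + g, 0.0),
            "D": (0.0, 0.0),
        }

    @property
    def box_centers(self) -> dict[str, tuple[float, float]]:
        h = self.box_side / 2.0
        return {b: (x0 + h, y0 + h) for b, (x0, y0) in self.box_origins.items()}

    @property
    def door_segments(self) -> dict[str, DoorSegment]:
        s, g = self.box_side, self.door_size
        mid_gap = s + g / 2.0  # centre of the corridor between two boxes
        lo = s / 2.0  # centre of the lower/left box row
        hi = s + g + s / 2.0  # centre of the upper/right box row
        return {
            "AB": DoorSegment("AB", (mid_gap, hi), "y", ("A", "B")),
            "AD": DoorSegment("AD", (lo, mid_gap), "x", ("A", "D")),
            "BC": DoorSegment("BC", (hi, mid_gap), "x", ("B", "C")),
            "CD": DoorSegment("CD", (mid_gap, lo), "y", ("C", "D")),
        }

    @property
    def dummy_door_segments(self) -> dict[str, DoorSegment]:
        """Eight door-sized panels on the external walls (two per box)."""
        f = self.footprint
        lo = self.box_side / 2.0
        hi = f - self.box_side / 2.0
        out = {
            "A_left": ((0.0, hi), "y", ("A", "A")),
            "A_top": ((lo, f), "x", ("A", "A")),
            "B_top": ((hi, f), "x", ("B", "B")),
            "B_right": ((f, hi), "y", ("B", "B")),
            "C_right": ((f, lo), "y", ("C", "C")),
            "C_bottom": ((hi, 0.0), "x", ("C", "C")),
            "D_bottom": ((lo, 0.0), "x", ("D", "D")),
            "D_left": ((0.0, lo), "y", ("D", "D")),
        }
        return {k: DoorSegment(k, c, ax, bx) for k, (c, ax, bx) in out.items()}

    def box_rect(self, box: str) -> tuple[float, float, float, float]:
        """(x0, y0, x1, y1) minimum enclosing rectangle of a box."""
        x0, y0 = self.box_origins[box]
        return (x0, y0, x0 + self.box_side, y0 + self.box_side)

    def contains(self, x: float, y: float) -> bool:
        f = self.footprint
        return 0.0 <= x <= f and 0.0 <= y <= f

    def to_json(self) -> dict:
        return {
            "box_side": self.box_side,
            "door_size": self.door_size,
            "wall_height": self.wall_height,
            "box_origins": self.box_origins,
            "doors": {
                d.name: {"center": d.center, "axis": d.axis, "boxes": d.boxes}
                for d in self.door_segments.values()
            },
        }


def are_adjacent(a: str, b: str) -> bool:
    return frozenset((a, b)) in _ADJACENT_PAIRS


def door_between(a: str, b: str) -> str:
    if not are_adjacent(a, b):
        raise ValueError(f"boxes {a},{b} share no door")
    return "".join(sorted((a, b)))


@dataclass(frozen=True)
class ConnectivityState:
    """Per-direction lock state of the four doors in one session.

    ``locks`` maps door name -> set of *origin* boxes from which the door
    cannot be pushed (i.e. the direction origin->other is locked).
    """

    session_label: str
    locks: Mapping[str, frozenset[str]] = field(default_factory=dict)

    def __post_init__(self):
        if self.session_label not in SESSION_LABELS:
            raise ValueError(f"unknown session label {self.session_label!r}")
        for door, origins in self.locks.items():
            if door not in DOORS:
                raise ValueError(f"unknown door {door!r}")
            if not frozenset(origins) <= frozenset(_DOOR_BOXES[door]):
                raise ValueError(f"lock origins {origins} not adjacent to door {door}")

    def is_locked(self, origin: str, dest: str) -> bool:
        door = door_between(origin, dest)
        return origin in self.locks.get(door, frozenset())

    @classmethod
    def all_open(cls, label: str) -> "ConnectivityState":
        return cls(label, {})

    @classmethod
    def closed_door(cls, label: str, door: str) -> "ConnectivityState":
        """One door locked in both directions."""
        return cls(label, {door: frozenset(_DOOR_BOXES[door])})

    @classmethod
    def one_way(cls, label: str, locked_origins: Mapping[str, str]) -> "ConnectivityState":
        """All four doors locked in one direction each.

        ``locked_origins`` maps each door to the box from which it cannot be
        pushed.  The open directions must form a single directed cycle over
        the four boxes (the physical constraint of the task).
        """
        if set(locked_origins) != set(DOORS):
            raise ValueError("one-way state must lock every door in one direction")
        state = cls(label, {d: frozenset({o}) for d, o in locked_origins.items()})
        g = connectivity_graph(state)
        if sorted(d for _, d in g.out_degree()) != [1, 1, 1, 1] or not nx.is_strongly_connected(g):
            raise ValueError("one-way locks must leave a single directed cycle")
        return state

    @classmethod
    def one_way_cycle(cls, label: str, clockwise: bool = True) -> "ConnectivityState":
        """Convenience one-way state: traffic flows around A-B-C-D (or reverse)."""
        cycle = ("A", "B", "C", "D") if clockwise else ("D", "C", "B", "A")
        locked = {}
        for i, origin in enumerate(cycle):
            dest = cycle[(i + 1) % 4]
            # flow origin->dest allowed, so the door is locked from dest
            locked[door_between(origin, dest)] = dest
        return cls.one_way(label, locked)

    def to_json(self) -> dict:
        return {
            "session_label": self.session_label,
            "locks": {d: sorted(o) for d, o in self.locks.items()},
        }

    @classmethod
    def from_json(cls, obj: dict) -> "ConnectivityState":
        return cls(obj["session_label"], {d: frozenset(o) for d, o in obj["locks"].items()})


def connectivity_graph(state: ConnectivityState) -> nx.DiGraph:
    """Directed graph over the four boxes; edge (u,v) iff u->v is unlocked.

    Edges carry the door name in the ``door`` attribute.
    """
    g = nx.DiGraph()
    g.add_nodes_from(BOXES)
    for door, (a, b) in _DOOR_BOXES.items():
        if not state.is_locked(a, b):
            g.add_edge(a, b, door=door)
        if not state.is_locked(b, a):
            g.add_edge(b, a, door=door)
    return g


@dataclass(frozen=True)
class DoorPath:
    """Shortest-route answer: hop count, one realizing door sequence, and
    the set of first doors lying on *any* optimal path."""

    hops: int | None
    doors: tuple[str, ...]
    first_doors: frozenset[str]

    @property
    def reachable(self) -> bool:
        return self.hops is not None


def shortest_door_path(state: ConnectivityState, origin: str, goal: str) -> DoorPath:
    """Minimum number of door crossings from ``origin`` to ``goal``.

    Locked directions are absent from the graph, so a detour around a locked
    door is counted door-by-door (adjacent boxes with their shared door
    locked both ways are 3 crossings apart).
    """
    for b in (origin, goal):
        if b not in BOXES:
            raise ValueError(f"unknown box {b!r}")
    if origin == goal:
        return DoorPath(0, (), frozenset())
    g = connectivity_graph(state)
    try:
        paths = list(nx.all_shortest_paths(g, origin, goal))
    except nx.NetworkXNoPath:
        return DoorPath(None, (), frozenset())
    doors = tuple(door_between(u, v) for u, v in itertools.pairwise(paths[0]))
    first = frozenset(door_between(p[0], p[1]) for p in paths)
    return DoorPath(len(paths[0]) - 1, doors, first)


def assign_region(point: Sequence[float], geometry: MazeGeometry) -> str:
    """Box label ('A'..'D') or door-gap label ('gap:AB', 'gap:center', ...).

    Box membership uses half-open boundaries (left/bottom edges inclusive);
    anything inside the footprint but outside all boxes is a gap.
    """
    x, y = float(point[0]), float(point[1])
    if not geometry.contains(x, y):
        raise ValueError(f"point ({x},{y}) outside maze footprint")
    s = geometry.box_side
    for b, (x0, y0) in geometry.box_origins.items():
        if x0 <= x < x0 + s and y0 <= y < y0 + s:
            return b
        # points on the outer footprint edge belong to the adjacent box
        if x0 <= x <= x0 + s and y0 <= y <= y0 + s:
            f = geometry.footprint
            on_outer = np.isclose(x, 0) or np.isclose(x, f) or np.isclose(y, 0) or np.isclose(y, f)
            if on_outer:
                return b
    in_col = 0.0 <= x < s or s + geometry.door_size <= x <= geometry.footprint
    in_row = 0.0 <= y < s or s + geometry.door_size <= y <= geometry.footprint
    if in_row and not in_col:
        # vertical corridor: between A-B (top row) or C-D (bottom row)
        return "gap:AB" if y >= s + geometry.door_size else "gap:CD"
    if in_col and not in_row:
        return "gap:AD" if x < s else "gap:BC"
    return "gap:center"


def nearest_box(point: Sequence[float], geometry: MazeGeometry) -> str:
    """Box with the nearest centroid (used for quadrant truth on gap points)."""
    x, y = float(point[0]), float(point[1])
    centers = geometry.box_centers
    return min(BOXES, key=lambda b: (x - centers[b][0]) ** 2 + (y - centers[b][1]) ** 2)


def quadrant_of(point: Sequence[float], geometry: MazeGeometry) -> int:
    """Quadrant id 1-16.  Door-gap points go to the nearest box centroid."""
    label = assign_region(point, geometry)
    box = label if label in BOXES else nearest_box(point, geometry)
    cx, cy = geometry.box_centers[box]
    x, y = float(point[0]), float(point[1])
    col = 1 if x >= cx else 0
    row = 1 if y >= cy else 0
    sub = row * 2 + col  # row-major from the lower-left sub-quadrant
    return BOXES.index(box) * 4 + sub + 1


def door_region_predicate(door: DoorSegment, radius: float, side: str | None = None):
    """Point predicate: within Euclidean ``radius`` of the door centre.

    ``side`` restricts to the half-plane of one adjacent box ('A'..'D'),
    giving the per-side half-disks used by One-Way analyses.
    """
    if radius < 0:
        raise ValueError("radius must be >= 0")
    cx, cy = door.center

    def pred(x, y):
        x = np.asarray(x, dtype=float)
        y = np.asarray(y, dtype=float)
        ok = (x - cx) ** 2 + (y - cy) ** 2 <= radius**2
        if side is not None:
            if side not in door.boxes:
                raise ValueError(f"box {side} is not adjacent to door {door.name}")
            # the side half-plane is along the passage axis
            if door.axis == "y":  # passage along x: left box vs right box
                ok = ok & ((x < cx) if side in ("A", "D") else (x >= cx))
            else:  # passage along y: upper box vs lower box
                ok = ok & ((y >= cy) if side in ("A", "B") else (y < cy))
        return ok

    return pred


def door_region_mask(
    door: DoorSegment,
    radius: float,
    geometry: MazeGeometry,
    bin_size: float = 2.0,
    side: str | None = None,
) -> np.ndarray:
    """Boolean mask over the whole-maze bin grid (row = y index, col = x)."""
    n = int(round(geometry.footprint / bin_size))
    centers = (np.arange(n) + 0.5) * bin_size
    xs, ys = np.meshgrid(centers, centers)
    return door_region_predicate(door, radius, side=side)(xs, ys)


def default_goal_list(rng: np.random.Generator) -> list[str]:
    """Pseudo-random 12-goal list: three permutations of the four boxes,
    no box repeated back-to-back across block boundaries."""
    while True:
        blocks = [list(rng.permutation(list(BOXES))) for _ in range(3)]
        goals = [b for blk in blocks for b in blk]
        if all(goals[i] != goals[i + 1] for i in range(len(goals) - 1)):
            return goals


@dataclass(frozen=True)
class SessionProtocol:
    """A five-session recording sequence and its goal list."""

    sequence_type: str  # 'Closed-Door' or 'One-Way'
    session_states: tuple[ConnectivityState, ...]
    goal_list: tuple[str, ...]

    def __post_init__(self):
        if self.sequence_type not in ("Closed-Door", "One-Way"):
            raise ValueError(f"unknown sequence type {self.sequence_type!r}")
        if tuple(s.session_label for s in self.session_states) != SESSION_LABELS:
            raise ValueError("session states must be labelled O1,O2,C1,C2,O3")
        if len(self.goal_list) != 12:
            raise ValueError("goal list must have 12 entries")
        for b in BOXES:
            if self.goal_list.count(b) != 3:
                raise ValueError("each box must appear exactly 3 times as goal")
        for i in range(0, 12, 4):
            if set(self.goal_list[i : i + 4]) != set(BOXES):
                raise ValueError("all four boxes must be used before repeating one")

    @property
    def locked_doors(self) -> frozenset[str]:
        """Doors carrying any lock in the test sessions (C1/C2)."""
        out = set()
        for s in self.session_states:
            if s.session_label.startswith("C"):
                out |= {d for d, o in s.locks.items() if o}
        return frozenset(out)

    def state(self, label: str) -> ConnectivityState:
        for s in self.session_states:
            if s.session_label == label:
                return s
        raise KeyError(label)

    def to_json(self) -> dict:
        return {
            "sequence_type": self.sequence_type,
            "session_states": [s.to_json() for s in self.session_states],
            "goal_list": list(self.goal_list),
        }

    @classmethod
    def from_json(cls, obj: dict) -> "SessionProtocol":
        return cls(
            obj["sequence_type"],
            tuple(ConnectivityState.from_json(s) for s in obj["session_states"]),
            tuple(obj["goal_list"]),
        )

    @classmethod
    def closed_door(
        cls, locked_door: str = "AB", goal_list: Iterable[str] | None = None,
        rng: np.random.Generator | None = None,
    ) -> "SessionProtocol":
        goals = tuple(goal_list) if goal_list is not None else tuple(
            default_goal_list(rng if rng is not None else np.random.default_rng(0))
        )
        states = (
            ConnectivityState.all_open("O1"),
            ConnectivityState.all_open("O2"),
            ConnectivityState.closed_door("C1", locked_door),
            ConnectivityState.closed_door("C2", locked_door),
            ConnectivityState.all_open("O3"),
        )
        return cls("Closed-Door", states, goals)

    @classmethod
    def one_way(
        cls, clockwise: bool = True, goal_list: Iterable[str] | None = None,
        rng: np.random.Generator | None = None,
    ) -> "SessionProtocol":
        goals = tuple(goal_list) if goal_list is not None else tuple(
            default_goal_list(rng if rng is not None else np.random.default_rng(0))
        )
        states = (
            ConnectivityState.all_open("O1"),
            ConnectivityState.all_open("O2"),
            ConnectivityState.one_way_cycle("C1", clockwise),
            ConnectivityState.one_way_cycle("C2", clockwise),
            ConnectivityState.all_open("O3"),
        )
        return cls("One-Way", states, goals)


def save_protocol(protocol: SessionProtocol, path) -> None:
    with open(path, "w") as fh:
        json.dump(protocol.to_json(), fh, indent=1)


def load_protocol(path) -> SessionProtocol:
    with open(path) as fh:
        return SessionProtocol.from_json(json.load(fh))
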