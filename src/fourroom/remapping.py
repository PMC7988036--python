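"""Correlation-based remapping analyses.

All comparisons are pairwise Pearson correlations between firing-rate maps
over the bins visited (dwell >= 0.05 s) in *both* maps; a pair is only
correlated when at least one map has a peak above 1 Hz and there are at
least 10 common bins.

Individual remapping at a session transition is judged against a shuffle of
random-cell cross-pairings within the same recording sequence (1000 draws,
pooled over sequences with more than 10 simultaneous place cells).  The
published threshold wording is ambiguous; by default a cell "remaps" when
its correlation falls below the shuffle's 5th percentile (significantly less
similar than random cell pairs), with the literal below-the-95th-percentile
reading available via ``bound='below95'``.  Stability is flagged above the
95th percentile.

Rate remapping uses the Fuhs difference metric on zero-meaned maps,

    F = sum|f1 - f2| / sum(|f1| + |f2|),

which is 0 for identical fields and approaches 1 for fully different ones.
"""

from __future__ import annotations

import itertools
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats as sps

from .maze import SESSION_LABELS, SessionProtocol
from .ratemaps import MapView, RateMap
from .stats import holm_bonferroni

TRANSITIONS = (("O1", "O2"), ("O2", "C1"), ("C1", "C2"), ("C2", "O3"))
ADJACENT_PAIRS = (("A", "B"), ("B", "C"), ("C", "D"), ("A", "D"))
DIAGONAL_PAIRS = (("A", "C"), ("B", "D"))


def map_correlation(
    map_a: RateMap | MapView,
    map_b: RateMap | MapView,
    *,
    min_common_bins: int = 10,
    min_peak: float = 1.0,
) -> float | None:
    """Pearson r over bins visited in both maps; None when not assessable."""
    if map_a.rate.shape != map_b.rate.shape:
        raise ValueError("maps must share a grid")
    if max(map_a.peak_rate, map_b.peak_rate) <= min_peak:
        return None
    common = map_a.visited & map_b.visited
    if common.sum() < min_common_bins:
        return None
    a = map_a.rate[common]
    b = map_b.rate[common]
    if np.std(a) == 0 or np.std(b) == 0:
        return None
    return float(np.corrcoef(a, b)[0, 1])


def fuhs_metric(map_a, map_b, *, min_common_bins: int = 10) -> float | None:
    """Rate-remapping index in [0, 1] on zero-normalized maps."""
    if map_a.rate.shape != map_b.rate.shape:
        raise ValueError("maps must share a grid")
    common = map_a.visited & map_b.visited
    if common.sum() < min_common_bins:
        return None
    f1 = map_a.rate[common]
    f2 = map_b.rate[common]
    f1 = f1 - f1.mean()
    f2 = f2 - f2.mean()
    denom = np.sum(np.abs(f1) + np.abs(f2))
    if denom == 0:
        return None  # both maps constant
    return float(np.sum(np.abs(f1 - f2)) / denom)


# ---------------------------------------------------------------------------
# session-level correlations

def session_correlation_matrix(cell_maps: dict[str, RateMap]) -> np.ndarray:
    """5x5 matrix of pairwise session correlations for one cell (NaN where
    unassessable)."""
    n = len(SESSION_LABELS)
    out = np.full((n, n), np.nan)
    for i, a in enumerate(SESSION_LABELS):
        for j, b in enumerate(SESSION_LABELS):
            if i == j:
                out[i, j] = 1.0
                continue
            if a in cell_maps and b in cell_maps:
                r = map_correlation(cell_maps[a], cell_maps[b])
                if r is not None:
                    out[i, j] = r
    return out


@dataclass
class SessionCorrelationResult:
    mean_matrix: np.ndarray  # cell-averaged 5x5
    per_cell: pd.DataFrame  # cell, session_a, session_b, r, separation
    contrast: pd.DataFrame  # per-cell O1-O2 vs O2-C1 values
    separation_curve: pd.Series  # mean r by separation 0..3


def session_correlation_analysis(
    cells: dict[int, dict[str, RateMap]],
) -> SessionCorrelationResult:
    rows = []
    mats = []
    for cid, maps in cells.items():
        m = session_correlation_matrix(maps)
        mats.append(m)
        for i, j in itertools.combinations(range(len(SESSION_LABELS)), 2):
            if np.isfinite(m[i, j]):
                rows.append(
                    dict(cell=cid, session_a=SESSION_LABELS[i], session_b=SESSION_LABELS[j],
                         r=m[i, j], separation=j - i - 1)
                )
    df = pd.DataFrame(rows)
    if df.empty:
        raise ValueError("no assessable cells")
    pairs = df.set_index(["cell", "session_a", "session_b"]).r
    contrast_rows = []
    for cid in cells:
        r_base = pairs.get((cid, "O1", "O2"), np.nan)
        r_change = pairs.get((cid, "O2", "C1"), np.nan)
        contrast_rows.append(dict(cell=cid, r_O1O2=r_base, r_O2C1=r_change))
    curve = df.groupby("separation").r.mean()
    return SessionCorrelationResult(
        np.nanmean(np.stack(mats), axis=0), df, pd.DataFrame(contrast_rows), curve
    )


def doorway_correlation_analysis(
    cells: dict[int, dict[str, dict[tuple[str, str], MapView]]],
    protocol: SessionProtocol,
) -> pd.DataFrame:
    """Per-cell doorway correlations grouped closed/control vs open.

    ``cells[cid][session][(door, side)]`` are 25 cm doorway map views.  For
    each cell and each comparison (O1-O2 baseline, O2-C1) the door-side
    correlations are averaged within group so every cell contributes exactly
    one value per group.
    """
    from .behavior import door_side_groups

    groups = door_side_groups(protocol)
    rows = []
    for cid, sess in cells.items():
        for pair in (("O1", "O2"), ("O2", "C1")):
            if pair[0] not in sess or pair[1] not in sess:
                continue
            vals = {"closed/control": [], "open": []}
            for key, view_a in sess[pair[0]].items():
                view_b = sess[pair[1]].get(key)
                if view_b is None:
                    continue
                r = map_correlation(view_a, view_b)
                if r is None:
                    continue
                g = "closed/control" if groups[key] == "locked-plan" else "open"
                vals[g].append(r)
            for g, v in vals.items():
                if v:
                    rows.append(dict(cell=cid, comparison="-".join(pair), group=g,
                                     r=float(np.mean(v))))
    return pd.DataFrame(rows)


# ---------------------------------------------------------------------------
# individual remapping classification

@dataclass(frozen=True)
class RemappingProfile:
    cell: int
    remap: tuple[bool, bool, bool, bool]  # O1-O2, O2-C1, C1-C2, C2-O3
    stable: tuple[bool, bool, bool, bool]

    @property
    def pattern_id(self) -> int:
        """Binary encoding, O1-O2 as the most significant bit: (F,T,F,F) -> 4."""
        return int("".join("1" if b else "0" for b in self.remap), 2)


@dataclass
class IndividualRemappingResult:
    profiles: list[RemappingProfile]
    pattern_histogram: np.ndarray  # length 16
    shuffle: dict[tuple[str, str], np.ndarray]
    bounds: dict[tuple[str, str], float]
    stability_bounds: dict[tuple[str, str], float]


def classify_individual_remapping(
    sequences: list[dict[int, dict[str, RateMap]]],
    *,
    n_shuffles: int = 1000,
    rng: np.random.Generator | None = None,
    bound: str = "low5",  # 'low5' | 'below95'
    min_cells: int = 10,
) -> IndividualRemappingResult:
    """Shuffle-classified per-cell remapping across the four transitions.

    Shuffles pair the session-s map of one cell with the session-(s+1) map
    of a *different* random cell from the same sequence; only sequences with
    more than ``min_cells`` place cells contribute, and their shuffle
    distributions are pooled per transition.
    """
    rng = rng if rng is not None else np.random.default_rng()
    qualifying = [seq for seq in sequences if len(seq) > min_cells]
    if not qualifying:
        raise ValueError(f"no sequence has more than {min_cells} place cells")

    shuffle: dict[tuple[str, str], list[float]] = {t: [] for t in TRANSITIONS}
    for seq in qualifying:
        cids = list(seq)
        for t in TRANSITIONS:
            have_a = [c for c in cids if t[0] in seq[c]]
            have_b = [c for c in cids if t[1] in seq[c]]
            if len(have_a) < 2 or len(have_b) < 2:
                continue
            count = 0
            attempts = 0
            while count < n_shuffles and attempts < 20 * n_shuffles:
                attempts += 1
                i = have_a[rng.integers(len(have_a))]
                j = have_b[rng.integers(len(have_b))]
                if i == j:
                    continue
                r = map_correlation(seq[i][t[0]], seq[j][t[1]])
                if r is not None:
                    shuffle[t].append(r)
                    count += 1
    shuffle_arr = {t: np.asarray(v) for t, v in shuffle.items()}
    pct = 5 if bound == "low5" else 95
    bounds = {t: float(np.percentile(v, pct)) if v.size else np.nan
              for t, v in shuffle_arr.items()}
    stab = {t: float(np.percentile(v, 95)) if v.size else np.nan
            for t, v in shuffle_arr.items()}

    profiles = []
    for seq in qualifying:
        for cid, maps in seq.items():
            remap, stable = [], []
            for t in TRANSITIONS:
                if t[0] in maps and t[1] in maps:
                    r = map_correlation(maps[t[0]], maps[t[1]])
                else:
                    r = None
                if r is None or not np.isfinite(bounds[t]):
                    remap.append(False)
                    stable.append(False)
                else:
                    remap.append(bool(r < bounds[t]))
                    stable.append(bool(r > stab[t]))
            profiles.append(RemappingProfile(cid, tuple(remap), tuple(stable)))
    hist = np.bincount([p.pattern_id for p in profiles], minlength=16)
    return IndividualRemappingResult(profiles, hist, shuffle_arr, bounds, stab)


# ---------------------------------------------------------------------------
# cross-box repetition analyses

def cross_box_correlations(box_maps: dict[str, RateMap]) -> dict[tuple[str, str], float | None]:
    """The six pairwise box correlations of one cell in one session."""
    out = {}
    for a, b in itertools.combinations(sorted(box_maps), 2):
        out[(a, b)] = map_correlation(box_maps[a], box_maps[b])
    return out


@dataclass
class CrossBoxResult:
    per_cell: pd.DataFrame  # cell, pair, r, adjacency
    mean_per_cell: pd.Series  # mean pairwise r by cell
    adjacent_vs_diagonal: tuple[float, float]  # mean r (adjacent), mean r (diagonal)


def cross_box_analysis(
    cells: dict[int, dict[str, RateMap]],
) -> CrossBoxResult:
    """Per-cell mean pairwise box correlations in one session.

    ``cells[cid][box]`` are per-box maps (smoothed separately, compared in
    maze coordinates without rotation).
    """
    rows = []
    for cid, maps in cells.items():
        for (a, b), r in cross_box_correlations(maps).items():
            if r is None:
                continue
            adj = "adjacent" if (a, b) in ADJACENT_PAIRS or (b, a) in ADJACENT_PAIRS else "diagonal"
            rows.append(dict(cell=cid, pair=f"{a}{b}", r=r, adjacency=adj))
    df = pd.DataFrame(rows)
    if df.empty:
        raise ValueError("no assessable box pairs")
    mean_per_cell = df.groupby("cell").r.mean()
    adj = df[df.adjacency == "adjacent"].r.mean()
    diag = df[df.adjacency == "diagonal"].r.mean()
    return CrossBoxResult(df, mean_per_cell, (float(adj), float(diag)))


def repetition_shuffle(
    cells: dict[int, dict[str, dict[str, RateMap]]],
    k: int,
    *,
    n_draws: int = 1000,
    rng: np.random.Generator | None = None,
) -> np.ndarray:
    """Shuffle distribution of cross-box correlations under k-fold repetition.

    ``cells[cid][session][box]`` are per-box maps.  Each draw takes a random
    cell's four O1 box maps, picks a random compartment and duplicates it
    across ``k`` slots, the duplicates taken from the *same* compartment in
    different sessions (the same compartment sampled at different times
    approximates sampling a repeated field in different boxes); the mean
    pairwise correlation of the resulting 4 maps is recorded.
    """
    if k not in (2, 3, 4):
        raise ValueError("k must be 2, 3 or 4")
    rng = rng if rng is not None else np.random.default_rng()
    cids = [c for c, s in cells.items() if "O1" in s and len(s) >= 2]
    if not cids:
        raise ValueError("need cells with O1 plus at least one other session")
    out = []
    boxes = ("A", "B", "C", "D")
    for _ in range(n_draws):
        cid = cids[rng.integers(len(cids))]
        sess = cells[cid]
        other_sessions = [s for s in sess if s != "O1"]
        src = boxes[rng.integers(4)]
        slots = {b: sess["O1"][b] for b in boxes}
        dup_slots = [b for b in boxes if b != src]
        rng.shuffle(dup_slots)
        dup_sessions = list(rng.choice(other_sessions, size=k - 1,
                                       replace=len(other_sessions) < k - 1))
        for slot, s in zip(dup_slots[: k - 1], dup_sessions):
            slots[slot] = sess[s][src]
        rs = [r for r in cross_box_correlations(slots).values() if r is not None]
        if rs:
            out.append(float(np.mean(rs)))
    return np.asarray(out)


def compare_to_repetition_shuffles(
    observed: np.ndarray,
    shuffles: dict[int | str, np.ndarray],
    alpha: float = 0.05,
) -> pd.DataFrame:
    """Two-sample KS tests of the observed cross-box distribution against
    each repetition shuffle, Holm-Bonferroni corrected."""
    rows = []
    for name, sh in shuffles.items():
        stat, p = sps.ks_2samp(observed, sh)
        rows.append(dict(shuffle=name, ks=float(stat), p=float(p)))
    df = pd.DataFrame(rows)
    df["p_corrected"] = holm_bonferroni(df.p.to_numpy(), alpha=alpha)
    return df


# ---------------------------------------------------------------------------
# foraging vs goal-directed stability

@dataclass
class ModeStabilityResult:
    per_session: pd.DataFrame  # session, median_r, shuffle_95, stable
    observed: dict[str, np.ndarray]
    shuffle: dict[str, np.ndarray]


def foraging_vs_goal_remapping(
    cells: dict[int, dict[str, dict[str, RateMap]]],
    *,
    n_shuffles: int = 1000,
    rng: np.random.Generator | None = None,
) -> ModeStabilityResult:
    """Within-session foraging-vs-goal-directed map stability.

    ``cells[cid][session]`` maps 'foraging' / 'goal-directed' to rate maps.
    The shuffle pairs the foraging map of one cell with the goal-directed
    map of a different random cell *within the same session*; cells are
    called stable in a session when the median observed correlation exceeds
    the shuffle's 95th percentile.
    """
    rng = rng if rng is not None else np.random.default_rng()
    rows = []
    observed_all, shuffle_all = {}, {}
    for label in SESSION_LABELS:
        have = [c for c in cells
                if label in cells[c]
                and "foraging" in cells[c][label] and "goal-directed" in cells[c][label]]
        if len(have) < 2:
            continue
        obs = []
        for c in have:
            r = map_correlation(cells[c][label]["foraging"], cells[c][label]["goal-directed"])
            if r is not None:
                obs.append(r)
        sh = []
        attempts = 0
        while len(sh) < n_shuffles and attempts < 20 * n_shuffles:
            attempts += 1
            i = have[rng.integers(len(have))]
            j = have[rng.integers(len(have))]
            if i == j:
                continue
            r = map_correlation(cells[i][label]["foraging"], cells[j][label]["goal-directed"])
            if r is not None:
                sh.append(r)
        if not obs or not sh:
            continue
        obs = np.asarray(obs)
        sh = np.asarray(sh)
        bound = float(np.percentile(sh, 95))
        rows.append(dict(session=label, median_r=float(np.median(obs)),
                         shuffle_95=bound, stable=bool(np.median(obs) > bound)))
        observed_all[label] = obs
        shuffle_all[label] = sh
    return ModeStabilityResult(pd.DataFrame(rows), observed_all, shuffle_all)
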