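"""Pipeline orchestration: simulate -> analyze -> report.

``RunConfig`` gathers every analysis parameter with its standard default
(2 cm bins, 2.5-bin/9x9 Gaussian smoothing, 0.05 s dwell floor, 5 cm/s
speed filter, 20% field threshold, 9-bin minimum field area, 1 Hz peak,
25 cm door radius, tau = 300 ms decoding windows, 100/1000 shuffles at the
95th-percentile bound, 15-cell decoder minimum, 10-cell shuffle minimum,
60 cm shift exclusion).  A single seed drives every stochastic stage.
"""

from __future__ import annotations

import json
from dataclasses import asdict, dataclass
from pathlib import Path

import numpy as np
import pandas as pd

from . import behavior, decoding, fields, ratemaps, remapping
from .io import load_dataset, save_dataset
from .maze import SESSION_LABELS
from .simulate import SimulatedSequence, SimulationConfig, simulate_sequence


@dataclass
class RunConfig:
    seed: int = 0
    bin_size_cm: float = 2.0
    smooth_sigma_bins: float = 2.5
    smooth_kernel_bins: int = 9
    dwell_floor_s: float = 0.05
    speed_floor_cms: float = 5.0
    field_threshold_frac: float = 0.2
    field_min_area_bins: int = 9
    field_min_peak_hz: float = 1.0
    door_radius_cm: float = 25.0
    decoder_tau_s: float = 0.3
    decoder_min_cells: int = 15
    si_shuffles: int = 100
    pair_shuffles: int = 1000
    shuffle_min_cells: int = 10
    max_field_shift_cm: float = 60.0
    stages: tuple[str, ...] = (
        "behavior", "ratemaps", "fields", "remapping", "decoding",
    )

    def rng(self) -> np.random.Generator:
        return np.random.default_rng(self.seed)


def cmd_simulate(sim_config: SimulationConfig, seed: int, out_dir: str | Path) -> Path:
    seq = simulate_sequence(sim_config, seed)
    return save_dataset(seq, out_dir)


def _session_maps(seq: SimulatedSequence, run: RunConfig):
    """Whole-maze foraging maps + per-box maps + per-mode maps per cell/session."""
    geom = seq.config.geometry
    out = {"whole": {}, "box": {}, "mode": {}, "dwell": {}, "labels": {}, "visits": {}}
    for sess in seq.sessions:
        visits, labels = behavior.segment_and_classify(sess.trajectory, sess.events, geom)
        out["labels"][sess.label] = labels
        out["visits"][sess.label] = visits
        common = dict(geometry=geom, mode_labels=labels,
                      speed_floor=run.speed_floor_cms, bin_size=run.bin_size_cm,
                      sigma_bins=run.smooth_sigma_bins, kernel_bins=run.smooth_kernel_bins,
                      dwell_floor=run.dwell_floor_s)
        whole, box, mode = {}, {}, {}
        for c in seq.cells:
            st = sess.spikes.spike_times[c.cell_id]
            whole[c.cell_id] = ratemaps.build_maps(
                sess.trajectory, st, mode="foraging", **common)
            box[c.cell_id] = ratemaps.box_maps(
                sess.trajectory, st, mode="foraging", **{k: v for k, v in common.items()
                                                         if k != "geometry"},
                geometry=geom)
            mode[c.cell_id] = {
                m: ratemaps.build_maps(sess.trajectory, st, mode=m, **common)
                for m in ("foraging", "goal-directed")
            }
        out["whole"][sess.label] = whole
        out["box"][sess.label] = box
        out["mode"][sess.label] = mode
        any_cell = next(iter(whole))
        out["dwell"][sess.label] = whole[any_cell].dwell
    return out


def cmd_analyze(
    dataset_dir: str | Path,
    out_dir: str | Path,
    run: RunConfig | None = None,
) -> Path:
    """Run the analysis stages on a dataset directory and write result tables."""
    run = run if run is not None else RunConfig()
    rng = run.rng()
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    seq = load_dataset(dataset_dir)
    geom = seq.config.geometry
    protocol = seq.config.protocol

    maps = _session_maps(seq, run)

    if "behavior" in run.stages:
        rows = []
        for sess in seq.sessions:
            for v in maps["visits"][sess.label]:
                rows.append(dict(session=sess.label, box=v.box, start=v.start, end=v.end,
                                 path_cm=v.path_length, coverage=v.coverage, mode=v.mode))
        pd.DataFrame(rows).to_csv(out / "visits.csv", index=False)

        events = {s.label: behavior.clean_event_flags(s.events, s.trajectory, geom)
                  for s in seq.sessions}
        durations = {s.label: s.trajectory.duration for s in seq.sessions}
        behavior.push_rate_analysis(
            {k: v.events for k, v in events.items()}, protocol, durations, n_quarters=4
        ).to_csv(out / "push_rates_quarters.csv", index=False)
        behavior.push_rate_analysis(
            {k: v.events for k, v in events.items()}, protocol, durations
        ).to_csv(out / "push_rates.csv", index=False)

        bell_rows, fc_rows = [], []
        for sess in seq.sessions:
            ce = events[sess.label]
            br = behavior.bell_response_metrics(sess.trajectory, ce.events, rng=rng)
            for pre, post in zip(br.pre_speed, br.post_speed):
                bell_rows.append(dict(session=sess.label, pre=pre, post=post))
            fc = behavior.first_choice_accuracy(
                ce.events, maps["visits"][sess.label], sess.state,
                rejected_trials=ce.rejected_trials)
            if not fc.trials.empty:
                t = fc.trials.copy()
                t.insert(0, "session", sess.label)
                fc_rows.append(t)
        pd.DataFrame(bell_rows).to_csv(out / "bell_speeds.csv", index=False)
        if fc_rows:
            pd.concat(fc_rows).to_csv(out / "first_choice.csv", index=False)

    if "ratemaps" in run.stages:
        rows = []
        for sess in seq.sessions:
            dur = sess.trajectory.duration
            for c in seq.cells:
                st = sess.spikes.spike_times[c.cell_id]
                sm = maps["whole"][sess.label][c.cell_id]
                rows.append(dict(
                    session=sess.label, cell=c.cell_id,
                    mean_rate=len(st) / dur,
                    peak_rate=sm.peak_rate,
                    spatial_info=ratemaps.spatial_information(sm),
                ))
        pd.DataFrame(rows).to_csv(out / "cell_session_stats.csv", index=False)

    if "fields" in run.stages:
        rows = []
        all_fields = {s: [] for s in SESSION_LABELS}
        for sess in seq.sessions:
            for c in seq.cells:
                fl = fields.detect_fields(
                    maps["whole"][sess.label][c.cell_id],
                    threshold_frac=run.field_threshold_frac,
                    min_area=run.field_min_area_bins,
                    min_peak=run.field_min_peak_hz,
                    session=sess.label, cell=c.cell_id)
                all_fields[sess.label].extend(fl)
                for f in fl:
                    dname, ddist = fields.nearest_door(f, geom)
                    row = dict(session=sess.label, cell=c.cell_id, area=f.area,
                               cx=f.centroid[0], cy=f.centroid[1],
                               mean_rate=f.mean_rate, peak_rate=f.peak_rate,
                               nearest_door=dname, door_distance=ddist)
                    if ddist <= run.door_radius_cm:
                        row["bridge_index"] = fields.bridge_index(
                            f, geom.door_segments[dname]).index
                    rows.append(row)
        pd.DataFrame(rows).to_csv(out / "fields.csv", index=False)
        try:
            over = fields.overrepresentation_tests(
                all_fields, geom, maps["dwell"], protocol, radius=run.door_radius_cm)
            with open(out / "overrepresentation.json", "w") as fh:
                json.dump({
                    "locked_vs_open": {k: vars(v) for k, v in over.locked_vs_open.items()},
                    "area_test": {k: vars(v) for k, v in over.area_test.items()},
                    "corrected_p_locked": over.corrected_p_locked.tolist(),
                    "corrected_p_area": over.corrected_p_area.tolist(),
                }, fh, indent=1)
        except ValueError:
            pass

    if "remapping" in run.stages:
        cells_whole = {c.cell_id: {s.label: maps["whole"][s.label][c.cell_id]
                                   for s in seq.sessions} for c in seq.cells}
        sc = remapping.session_correlation_analysis(cells_whole)
        sc.per_cell.to_csv(out / "session_correlations.csv", index=False)
        np.savetxt(out / "session_correlation_matrix.csv", sc.mean_matrix, delimiter=",")
        if len(cells_whole) > run.shuffle_min_cells:
            res = remapping.classify_individual_remapping(
                [cells_whole], n_shuffles=run.pair_shuffles, rng=rng,
                min_cells=run.shuffle_min_cells)
            pd.DataFrame([
                dict(cell=p.cell, pattern=p.pattern_id,
                     **{f"remap_{a}_{b}": r for (a, b), r in zip(
                         remapping.TRANSITIONS, p.remap)})
                for p in res.profiles
            ]).to_csv(out / "remapping_profiles.csv", index=False)
        fuhs_rows = []
        for cid, m in cells_whole.items():
            for a, b in remapping.TRANSITIONS:
                v = remapping.fuhs_metric(m[a], m[b])
                if v is not None:
                    fuhs_rows.append(dict(cell=cid, pair=f"{a}-{b}", fuhs=v))
        pd.DataFrame(fuhs_rows).to_csv(out / "fuhs.csv", index=False)
        cb_rows = []
        for sess in seq.sessions:
            cells_box = {c.cell_id: maps["box"][sess.label][c.cell_id] for c in seq.cells}
            try:
                cb = remapping.cross_box_analysis(cells_box)
                t = cb.per_cell.copy()
                t.insert(0, "session", sess.label)
                cb_rows.append(t)
            except ValueError:
                pass
        if cb_rows:
            pd.concat(cb_rows).to_csv(out / "cross_box.csv", index=False)
        mode_cells = {c.cell_id: {s.label: maps["mode"][s.label][c.cell_id]
                                  for s in seq.sessions} for c in seq.cells}
        fg = remapping.foraging_vs_goal_remapping(mode_cells, rng=rng,
                                                  n_shuffles=run.pair_shuffles)
        fg.per_session.to_csv(out / "mode_stability.csv", index=False)

    if "decoding" in run.stages:
        summaries = {}
        for train, test in (("O1", "O2"), ("O2", "C1")):
            train_maps = {c.cell_id: maps["whole"][train][c.cell_id] for c in seq.cells}
            try:
                model = decoding.fit_decoder(
                    train_maps, tau=run.decoder_tau_s,
                    min_cells=run.decoder_min_cells, train_session=train)
            except ValueError as e:
                summaries[f"{train}->{test}"] = {"skipped": str(e)}
                continue
            sess = seq.session(test)
            res = decoding.decode_session(
                model, sess.trajectory, sess.spikes.spike_times, geom,
                test_session=test, speed_floor=run.speed_floor_cms)
            summaries[f"{train}->{test}"] = dict(res.summary, n_windows=res.n_windows)
            np.savetxt(out / f"confusion_{train}_{test}.csv", res.confusion.counts,
                       delimiter=",")
        with open(out / "decoding.json", "w") as fh:
            json.dump(summaries, fh, indent=1)

    with open(out / "run_config.json", "w") as fh:
        json.dump(asdict(run), fh, indent=1, default=str)
    return out


def cmd_report(results_dir: str | Path, out_path: str | Path | None = None) -> Path:
    """Render a human-readable summary (markdown + a few figures)."""
    import matplotlib

    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    results = Path(results_dir)
    out_path = Path(out_path) if out_path else results / "report.md"
    lines = ["# Four-room analysis report", ""]

    fc = results / "first_choice.csv"
    if fc.exists():
        df = pd.read_csv(fc)
        scored = df[df.door_scored & df.door_optimal.notna()]
        if len(scored):
            lines.append(f"- Optimal first door pushes: {scored.door_optimal.mean():.1%} "
                         "(chance 50%)")
        fz = df[df.foraging_correct.notna()]
        if len(fz):
            lines.append(f"- Correct first foraging: {fz.foraging_correct.mean():.1%} "
                         "(chance 33%, excluding the initial box)")
    pr = results / "push_rates.csv"
    if pr.exists():
        df = pd.read_csv(pr)
        piv = df.pivot_table(index="session", columns="group", values="rate")
        lines.append("")
        lines.append("## Door pushes per side per minute")
        lines.append(piv.to_markdown())
    dec = results / "decoding.json"
    if dec.exists():
        with open(dec) as fh:
            summaries = json.load(fh)
        lines.append("")
        lines.append("## Quadrant decoding (chance = 1/16)")
        for pair, s in summaries.items():
            if "diagonal" in s:
                lines.append(f"- {pair}: diagonal {s['diagonal']:.3f}, "
                             f"windows {s['n_windows']}")
            else:
                lines.append(f"- {pair}: skipped ({s.get('skipped', '')})")
    sc = results / "session_correlation_matrix.csv"
    if sc.exists():
        m = np.loadtxt(sc, delimiter=",")
        fig, ax = plt.subplots(figsize=(4, 3.5))
        im = ax.imshow(m, vmin=-1, vmax=1, cmap="RdBu_r")
        ax.set_xticks(range(5), SESSION_LABELS)
        ax.set_yticks(range(5), SESSION_LABELS)
        fig.colorbar(im, ax=ax, label="mean map correlation")
        fig.tight_layout()
        fig.savefig(results / "session_correlations.png", dpi=120)
        plt.close(fig)
        lines.append("")
        lines.append("![session correlations](session_correlations.png)")
    out_path.write_text("\n".join(lines) + "\n")
    return out_path
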