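"""Delimited-text readers and writers for spikes, kinematics, logs and configs.

All formats are tab-separated text with a one-line header; numeric fields
round-trip at full float precision.  Spike files are ``time_s  unit_id``
sorted by time; kinematics files are one row per bin with position and
velocity; session logs are written as a trial table plus a trace file and
a YAML metadata block.  A YAML configuration file (seed included) fully
determines a simulated run.
"""

from __future__ import annotations

from dataclasses import asdict
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from .assist import AssistSchedule
from .point_process import SpikeEvents, bin_spikes
from .task import SessionLog, SimulatorConfig, TaskConfig, TrialRecord

__all__ = [
    "write_spike_file",
    "read_spike_file",
    "write_kinematics",
    "read_kinematics",
    "write_param_trace",
    "write_session_log",
    "read_session_log",
    "write_params",
    "read_params",
    "write_config",
    "read_config",
]

FORMAT_VERSION = 1

KINEMATICS_COLUMNS = ["time_s", "pos_x_cm", "pos_y_cm", "vel_x_cm_s", "vel_y_cm_s"]


class ParseError(ValueError):
    """Malformed input file; carries the offending line number when known."""

    def __init__(self, message: str, line: int | None = None):
        if line is not None:
            message = f"line {line}: {message}"
        super().__init__(message)
        self.line = line


def write_spike_file(events: SpikeEvents, path) -> None:
    """Write binary spike events as a sorted ``time_s  unit_id`` table.

    Spike times are placed at the center of their bins.
    """
    rows = []
    for c in range(events.n_units):
        bins = np.nonzero(events.events[c])[0]
        uid = events.unit_ids[c]
        for k in bins:
            rows.append((float((k + 0.5) * events.bin_width), uid))
    rows.sort()
    with open(path, "w") as f:
        f.write(f"# delta_s={events.bin_width!r} format_version={FORMAT_VERSION}\n")
        f.write("time_s\tunit_id\n")
        for t, uid in rows:
            f.write(f"{t!r}\t{uid}\n")


def read_spike_file(path, delta: float | None = None, duration: float | None = None) -> SpikeEvents:
    """Read a spike file back into binned events (re-binning at ``delta``)."""
    header_delta = None
    times, units = [], []
    with open(path) as f:
        for lineno, line in enumerate(f, start=1):
            line = line.strip()
            if not line:
                continue
            if line.startswith("#"):
                for tok in line[1:].split():
                    if tok.startswith("delta_s="):
                        header_delta = float(tok.split("=", 1)[1])
                continue
            if line.startswith("time_s"):
                continue
            parts = line.split("\t")
            if len(parts) != 2:
                raise ParseError("expected two tab-separated fields", lineno)
            try:
                t = float(parts[0])
            except ValueError:
                raise ParseError(f"bad time value {parts[0]!r}", lineno) from None
            if times and t < times[-1]:
                raise ParseError("spike times are not sorted", lineno)
            times.append(t)
            units.append(parts[1])
    delta = delta if delta is not None else header_delta
    if delta is None:
        raise ParseError("no bin width in header and none supplied")
    unit_ids = sorted(set(units), key=lambda u: (len(u), u))
    if duration is None:
        duration = (max(times) if times else 0.0) + delta
    per_unit = [
        np.array([t for t, u in zip(times, units) if u == uid]) for uid in unit_ids
    ]
    return bin_spikes(per_unit, delta, duration, unit_ids=unit_ids)


def write_kinematics(path, times, positions, velocities) -> None:
    df = pd.DataFrame(
        np.column_stack([np.asarray(times), np.asarray(positions), np.asarray(velocities)]),
        columns=KINEMATICS_COLUMNS,
    )
    df.to_csv(path, sep="\t", index=False, float_format="%.17g")


def read_kinematics(path) -> pd.DataFrame:
    df = pd.read_csv(path, sep="\t", float_precision="round_trip")
    missing = [c for c in KINEMATICS_COLUMNS if c not in df.columns]
    if missing:
        raise ParseError(f"kinematics file missing columns {missing}")
    if np.any(np.diff(df["time_s"].to_numpy()) <= 0):
        bad = int(np.argmax(np.diff(df["time_s"].to_numpy()) <= 0)) + 3
        raise ParseError("non-monotone times", bad)
    return df


def write_param_trace(path, times, snapshots, unit_ids=None) -> None:
    """Per-unit parameter trajectories: ``time_s unit_id beta alpha_x alpha_y``."""
    snapshots = np.asarray(snapshots)
    n_units = snapshots.shape[1]
    if unit_ids is None:
        unit_ids = list(range(n_units))
    with open(path, "w") as f:
        f.write("time_s\tunit_id\tbeta\talpha_x\talpha_y\n")
        for t, snap in zip(times, snapshots):
            for c in range(n_units):
                f.write(
                    f"{float(t)!r}\t{unit_ids[c]}\t{float(snap[c, 0])!r}\t{float(snap[c, 1])!r}\t{float(snap[c, 2])!r}\n"
                )


def write_params(path, phis: np.ndarray, unit_ids=None) -> None:
    """Write a parameter ensemble as ``unit_id beta alpha_x alpha_y``."""
    phis = np.atleast_2d(np.asarray(phis, dtype=float))
    if unit_ids is None:
        unit_ids = list(range(phis.shape[0]))
    with open(path, "w") as f:
        f.write("unit_id\tbeta\talpha_x\talpha_y\n")
        for uid, row in zip(unit_ids, phis):
            f.write(f"{uid}\t{float(row[0])!r}\t{float(row[1])!r}\t{float(row[2])!r}\n")


def read_params(path) -> tuple[np.ndarray, list]:
    df = pd.read_csv(path, sep="\t", float_precision="round_trip")
    needed = ["unit_id", "beta", "alpha_x", "alpha_y"]
    missing = [c for c in needed if c not in df.columns]
    if missing:
        raise ParseError(f"parameter file missing columns {missing}")
    return df[["beta", "alpha_x", "alpha_y"]].to_numpy(), df["unit_id"].tolist()


def write_session_log(log: SessionLog, directory) -> None:
    """Write trials, trace, parameter snapshots and metadata to a directory."""
    d = Path(directory)
    d.mkdir(parents=True, exist_ok=True)
    rows = []
    for tr in log.trials:
        rows.append(
            {
                "index": tr.index,
                "target_index": tr.target_index,
                "target_x_cm": tr.target_position[0],
                "target_y_cm": tr.target_position[1],
                "start_x_cm": tr.start_position[0],
                "start_y_cm": tr.start_position[1],
                "t_start_s": tr.t_start,
                "t_end_s": tr.t_end,
                "outcome": tr.outcome,
                "reach_time_s": tr.reach_time if tr.reach_time is not None else np.nan,
                "jumped": int(tr.jumped),
                "t_jump_s": tr.t_jump if tr.t_jump is not None else np.nan,
                "start_bin": tr.start_bin,
                "leave_bin": tr.leave_bin if tr.leave_bin is not None else -1,
                "arrive_bin": tr.arrive_bin if tr.arrive_bin is not None else -1,
                "end_bin": tr.end_bin,
            }
        )
    pd.DataFrame(rows).to_csv(d / "trials.tsv", sep="\t", index=False, float_format="%.17g")
    write_kinematics(d / "trace.tsv", log.trace_times(), log.trace_pos, log.trace_vel)
    write_param_trace(d / "params.tsv", log.snapshot_times, log.param_snapshots)
    meta = {
        "format_version": FORMAT_VERSION,
        "delta_s": float(log.delta),
        "duration_s": float(log.duration),
        "seed": log.seed,
        "assist_off_time_s": log.assist_off_time,
        "assist_events": [
            [float(t), phase, (float(tau) if tau is not None else None)]
            for t, phase, tau in log.assist_events
        ],
        "final_params": np.asarray(log.final_params).tolist(),
        "encoder_truth": (
            np.asarray(log.encoder_truth).tolist() if log.encoder_truth is not None else None
        ),
    }
    (d / "meta.yaml").write_text(yaml.safe_dump(meta, sort_keys=False))


def read_session_log(directory) -> SessionLog:
    d = Path(directory)
    meta = yaml.safe_load((d / "meta.yaml").read_text())
    if meta.get("format_version") != FORMAT_VERSION:
        raise ParseError(f"unsupported session log version {meta.get('format_version')}")
    trials_df = pd.read_csv(d / "trials.tsv", sep="\t", float_precision="round_trip")
    trace = read_kinematics(d / "trace.tsv")
    params = pd.read_csv(d / "params.tsv", sep="\t", float_precision="round_trip")
    snap_times = np.sort(params["time_s"].unique())
    n_units = params["unit_id"].nunique()
    snaps = (
        params.sort_values(["time_s", "unit_id"])[["beta", "alpha_x", "alpha_y"]]
        .to_numpy()
        .reshape(len(snap_times), n_units, 3)
    )
    trials = []
    for _, r in trials_df.iterrows():
        trials.append(
            TrialRecord(
                index=int(r["index"]),
                target_index=int(r["target_index"]),
                target_position=np.array([r["target_x_cm"], r["target_y_cm"]]),
                start_position=np.array([r["start_x_cm"], r["start_y_cm"]]),
                t_start=float(r["t_start_s"]),
                t_end=float(r["t_end_s"]),
                outcome=str(r["outcome"]),
                reach_time=None if np.isnan(r["reach_time_s"]) else float(r["reach_time_s"]),
                jumped=bool(r["jumped"]),
                t_jump=None if np.isnan(r["t_jump_s"]) else float(r["t_jump_s"]),
                start_bin=int(r["start_bin"]),
                leave_bin=None if r["leave_bin"] < 0 else int(r["leave_bin"]),
                arrive_bin=None if r["arrive_bin"] < 0 else int(r["arrive_bin"]),
                end_bin=int(r["end_bin"]),
            )
        )
    return SessionLog(
        delta=float(meta["delta_s"]),
        duration=float(meta["duration_s"]),
        trials=trials,
        trace_pos=trace[["pos_x_cm", "pos_y_cm"]].to_numpy(),
        trace_vel=trace[["vel_x_cm_s", "vel_y_cm_s"]].to_numpy(),
        assist_events=[(t, p, tau) for t, p, tau in meta.get("assist_events", [])],
        snapshot_times=snap_times,
        param_snapshots=snaps,
        final_params=np.asarray(meta["final_params"], dtype=float),
        encoder_truth=(
            np.asarray(meta["encoder_truth"], dtype=float)
            if meta.get("encoder_truth") is not None
            else None
        ),
        seed=meta.get("seed"),
        assist_off_time=meta.get("assist_off_time_s"),
    )


def write_config(cfg: SimulatorConfig, path, seed: int | None = None) -> None:
    """Serialize a run configuration (plus seed) to YAML."""
    doc = {"format_version": FORMAT_VERSION, "seed": seed, "config": asdict(cfg)}
    Path(path).write_text(yaml.safe_dump(doc, sort_keys=False))


def read_config(path) -> tuple[SimulatorConfig, int | None]:
    doc = yaml.safe_load(Path(path).read_text())
    if doc.get("format_version") != FORMAT_VERSION:
        raise ParseError(f"unsupported config version {doc.get('format_version')}")
    raw = dict(doc["config"])
    task = raw.pop("task", None)
    assist = raw.pop("assist", None)
    for key in ("baseline_range", "depth_range"):
        if key in raw and raw[key] is not None:
            raw[key] = tuple(raw[key])
    cfg = SimulatorConfig(
        **raw,
        task=TaskConfig(
            **{
                **task,
                "jump_types": tuple(map(tuple, task["jump_types"])) if task.get("jump_types") else None,
                "target_positions": (
                    tuple(map(tuple, task["target_positions"]))
                    if task.get("target_positions")
                    else None
                ),
            }
        )
        if task
        else TaskConfig(),
        assist=AssistSchedule(**{**assist, "tau_levels": tuple(assist["tau_levels"])})
        if assist
        else None,
    )
    return cfg, doc.get("seed")
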