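"""Behavioral metrics: success rate, percent correct, movement error, summaries.

Success rate is the number of successful trials per minute, evaluated in
2-minute windows (non-overlapping or sliding).  Steady-state values are
taken over the best ten minutes of a session (success rate) and the best
contiguous 100 trials (percent correct, reach time, movement error) so
that transient lapses do not dominate the summary.  Convergence time is
the first time the windowed success rate reaches 90% of its session
maximum.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .task import SessionLog

__all__ = [
    "PerformanceSummary",
    "success_rate",
    "percent_correct",
    "movement_error",
    "trial_movement_error",
    "steady_state_metrics",
    "convergence_time",
    "parameter_distance",
]


@dataclass
class PerformanceSummary:
    """Session-level behavioral summary."""

    window_times: np.ndarray  # s, right edge of each 2-min window
    success_rate_series: np.ndarray  # trials/min
    percent_correct: float  # %
    mean_movement_error: float  # cm
    mean_reach_time: float  # s
    steady_state_success_rate: float  # trials/min, best 10 min
    convergence_time_minutes: float  # time to 90% of max windowed rate
    partial: bool = False  # session shorter than the summary windows


def success_rate(
    log: SessionLog,
    window_minutes: float = 2.0,
    mode: str = "nonoverlapping",
    step_seconds: float = 1.0,
) -> tuple[np.ndarray, np.ndarray]:
    """Successes per minute in 2-min windows; returns (window end times, rates)."""
    if log.duration <= 0:
        raise ValueError("empty session log")
    win = window_minutes * 60.0
    t_succ = log.success_times()
    if mode == "nonoverlapping":
        ends = np.arange(win, log.duration + 1e-9, win)
    elif mode == "sliding":
        ends = np.arange(win, log.duration + 1e-9, step_seconds)
    else:
        raise ValueError(f"unknown mode {mode!r}")
    rates = np.array(
        [np.sum((t_succ > e - win) & (t_succ <= e)) / window_minutes for e in ends]
    )
    return ends, rates


def percent_correct(trials) -> float:
    """Percentage of initiated trials that ended in success."""
    if not trials:
        return float("nan")
    n_succ = sum(1 for t in trials if t.outcome == "success")
    return 100.0 * n_succ / len(trials)


def movement_error(trajectory: np.ndarray, start: np.ndarray, end: np.ndarray) -> float:
    """Mean absolute perpendicular deviation (cm) from the straight start-end line."""
    start = np.asarray(start, dtype=float)
    end = np.asarray(end, dtype=float)
    seg = end - start
    norm = np.linalg.norm(seg)
    if norm == 0:
        raise ValueError("degenerate reach: start equals end")
    pts = np.atleast_2d(np.asarray(trajectory, dtype=float)) - start
    cross = pts[:, 0] * seg[1] - pts[:, 1] * seg[0]
    return float(np.mean(np.abs(cross)) / norm)


def trial_movement_error(log: SessionLog, trial) -> float | None:
    """Movement error of one trial over its leave-start -> arrive-target span."""
    if trial.leave_bin is None or trial.arrive_bin is None or trial.arrive_bin <= trial.leave_bin:
        return None
    traj = log.trace_pos[trial.leave_bin : trial.arrive_bin + 1]
    return movement_error(traj, trial.start_position, trial.target_position)


def convergence_time(log: SessionLog, fraction: float = 0.9) -> float:
    """Minutes until the sliding 2-min success rate first reaches
    ``fraction`` of its session maximum."""
    ends, rates = success_rate(log, mode="sliding")
    if rates.size == 0 or rates.max() == 0:
        return float("nan")
    idx = np.argmax(rates >= fraction * rates.max())
    return float(ends[idx] / 60.0)


def steady_state_metrics(log: SessionLog) -> PerformanceSummary:
    """Full behavioral summary of one session."""
    ends, series = success_rate(log, mode="nonoverlapping")
    partial = False

    # best contiguous 10 minutes (sliding, 1 s grid)
    win = 600.0
    t_succ = log.success_times()
    if log.duration < win:
        partial = True
        ss_rate = len(t_succ) / (log.duration / 60.0)
    else:
        grid = np.arange(win, log.duration + 1e-9, 1.0)
        counts = np.array([np.sum((t_succ > e - win) & (t_succ <= e)) for e in grid])
        ss_rate = counts.max() / 10.0

    # best contiguous 100 trials
    n_run = 100
    trials = log.trials
    if len(trials) < n_run:
        partial = True
        best = trials
    else:
        outcomes = np.array([t.outcome == "success" for t in trials], dtype=float)
        csum = np.concatenate([[0.0], np.cumsum(outcomes)])
        wins = csum[n_run:] - csum[:-n_run]
        i0 = int(np.argmax(wins))
        best = trials[i0 : i0 + n_run]
    pc = percent_correct(best)
    reach_times = [t.reach_time for t in best if t.outcome == "success" and t.reach_time]
    errors = [
        e
        for t in best
        if t.outcome == "success" and (e := trial_movement_error(log, t)) is not None
    ]
    return PerformanceSummary(
        window_times=ends,
        success_rate_series=series,
        percent_correct=pc,
        mean_movement_error=float(np.mean(errors)) if errors else float("nan"),
        mean_reach_time=float(np.mean(reach_times)) if reach_times else float("nan"),
        steady_state_success_rate=float(ss_rate),
        convergence_time_minutes=convergence_time(log),
        partial=partial,
    )


def parameter_distance(estimates_a: np.ndarray, estimates_b: np.ndarray) -> tuple[float, float]:
    """Mean per-unit distance between two parameter ensembles.

    Returns ``(baseline_distance, alpha_distance)``: the mean over units
    of ``|beta_a - beta_b|`` and of ``||alpha_a - alpha_b||``.  Units must
    correspond row by row.
    """
    a = np.atleast_2d(np.asarray(estimates_a, dtype=float))
    b = np.atleast_2d(np.asarray(estimates_b, dtype=float))
    if a.shape != b.shape:
        raise ValueError("ensembles must have matching unit sets")
    beta_d = float(np.mean(np.abs(a[:, 0] - b[:, 0])))
    alpha_d = float(np.mean(np.linalg.norm(a[:, 1:] - b[:, 1:], axis=1)))
    return beta_d, alpha_d
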