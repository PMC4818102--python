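"""Dynamic assisted training: assist levels, test periods, stopping rule, chance level.

Assistance walks a discrete ladder of time constants tau (most assistive,
i.e. smallest tau, first).  After the last level a *test* period runs with
no assistance (random-walk prior); if the non-assisted success rate meets
the threshold, assistance stops permanently ("off" is absorbing),
otherwise a new assist period restarts at the level given by the restart
rule.  Parameter adaptation is independent of the assist phase and keeps
running after assistance stops.

The chance level of an assist level is the success-rate distribution of
the full closed loop with a *disengaged* subject (monitor off: zero
intention, baseline-only firing); performance above its upper percentile
indicates genuine engagement.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

__all__ = ["AssistSchedule", "AssistState", "advance", "chance_level"]


@dataclass(frozen=True)
class AssistSchedule:
    """Assistance ladder; ``tau_levels`` ordered most assistive first."""

    tau_levels: tuple = (0.4, 0.6, 0.9)
    level_duration: float = 120.0  # s per assist level
    test_duration: float = 120.0  # s of non-assisted test
    success_threshold: float = 5.0  # trials/min to stop assistance
    restart_level: int = 1  # level index an unsuccessful test restarts at

    def __post_init__(self):
        if len(self.tau_levels) == 0:
            raise ValueError("assist schedule needs at least one tau level")
        if any(b <= a for a, b in zip(self.tau_levels, self.tau_levels[1:])):
            raise ValueError("tau levels must strictly increase (assistance weakens)")
        if self.level_duration <= 0 or self.test_duration <= 0:
            raise ValueError("durations must be positive")
        if not (0 <= self.restart_level < len(self.tau_levels)):
            raise ValueError("restart level out of range")


@dataclass
class AssistState:
    """Where the ladder currently stands."""

    phase: str = "assist"  # assist | test | off
    level_index: int = 0
    elapsed_in_phase: float = 0.0
    test_history: list = field(default_factory=list)  # success rates of past tests


def advance(
    state: AssistState,
    schedule: AssistSchedule,
    elapsed: float,
    test_success_rate: float | None = None,
) -> tuple[AssistState, float | None]:
    """Advance the ladder by ``elapsed`` seconds; returns (state, active tau).

    ``test_success_rate`` (trials/min over the test window) must be
    supplied by the caller once the test period has run its course; until
    it is, the state waits at the end of the test.  The active tau is the
    current level's during assist and ``None`` (random-walk prior) during
    test and off.
    """
    if elapsed < 0:
        raise ValueError("time must be monotone")
    s = AssistState(state.phase, state.level_index, state.elapsed_in_phase, list(state.test_history))
    if s.phase == "off":
        return s, None
    s.elapsed_in_phase += elapsed
    if s.phase == "assist":
        while s.elapsed_in_phase >= schedule.level_duration:
            s.elapsed_in_phase -= schedule.level_duration
            if s.level_index + 1 < len(schedule.tau_levels):
                s.level_index += 1
            else:
                s.phase = "test"
                break
    if s.phase == "test" and s.elapsed_in_phase >= schedule.test_duration:
        if test_success_rate is not None:
            s.test_history.append(float(test_success_rate))
            if test_success_rate >= schedule.success_threshold:
                s.phase = "off"
                s.elapsed_in_phase = 0.0
            else:
                s.phase = "assist"
                s.level_index = schedule.restart_level
                s.elapsed_in_phase = 0.0
    tau = schedule.tau_levels[s.level_index] if s.phase == "assist" else None
    return s, tau


def chance_level(
    sim_config,
    tau: float | None,
    n_runs: int = 20,
    rng_seed: int = 0,
    run_minutes: float = 2.0,
) -> dict:
    """Success-rate distribution of the assisted loop with a disengaged subject.

    Runs ``n_runs`` independent closed-loop sessions in which the
    subject's monitor is off (zero intention, baseline-only spiking) at a
    fixed assist level ``tau`` (``None`` = random-walk prior, no assist),
    and summarizes the per-run success rate (trials/min).
    """
    from .task import SimulatorConfig, run_chance_session

    if n_runs < 1:
        raise ValueError("need at least one run")
    cfg: SimulatorConfig = sim_config
    rates = np.array(
        [
            run_chance_session(cfg, tau=tau, duration_s=run_minutes * 60.0, seed=rng_seed + i)
            for i in range(n_runs)
        ]
    )
    return {
        "rates": rates,
        "mean": float(rates.mean()),
        "p99": float(np.percentile(rates, 99)),
    }
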