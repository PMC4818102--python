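"""Behavioral tasks and the closed-loop simulator with a synthetic spiking brain.

The simulator closes the loop that a real BMI closes through a subject: a
synthetic "brain" observes the displayed (decoded) cursor,
forms an intended velocity through its own instant-OFC policy plus motor
noise, and an ensemble of ground-truth log-linear units spikes from that
intention.  The architecture under test sees only the spike events and the
task goals: it decodes the cursor with the kinematic PPF (assisted or
random-walk prior), infers the subject's intention with its own OFC model,
and adapts each unit's parameters with every spike event (or in
SmoothBatch batches).  Tasks are self-paced: the subject returns the
cursor to the start target to initiate each trial, and target holds are
strict — exiting the target before the hold period completes fails the
trial immediately.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np

from .assist import AssistSchedule, AssistState, advance
from .dynamics import CursorDynamics, Workspace, make_cursor_dynamics
from .ofc import (
    DEFAULT_INTENTION_WR,
    FeedbackGain,
    TargetState,
    assist_weights,
    cursorgoal_intention,
    intention_weights,
    solve_steady_state_gain,
)
from .param_filter import (
    DEFAULT_INIT_VAR,
    DEFAULT_Q_DIAG,
    EnsemblePosterior,
    SmoothBatchAdapter,
)
from .point_process import P_MAX

__all__ = [
    "TaskConfig",
    "make_task",
    "SyntheticBrain",
    "make_encoder",
    "visual_feedback_seed",
    "permuted_seed",
    "SimulatorConfig",
    "TrialRecord",
    "SessionLog",
    "Simulator",
    "run_trial",
    "run_session",
    "run_chance_session",
]


@dataclass(frozen=True)
class TaskConfig:
    """Task geometry and timing (center-out family defaults)."""

    task_kind: str = "center_out"
    n_targets: int = 8
    ring_diameter_cm: float = 13.0
    target_radius_cm: float = 1.2
    hold_seconds: float = 0.25
    reach_timeout_seconds: float = 10.0
    iti_seconds: float = 0.2
    jump_probability: float = 0.0
    jump_delay_seconds: float = 0.5
    jump_types: tuple | None = None  # optional (from_idx, to_idx) pairs
    target_positions: tuple | None = None  # explicit list for target_to_target

    def positions(self) -> np.ndarray:
        """Peripheral target centers (n_targets x 2, cm)."""
        if self.target_positions is not None:
            return np.asarray(self.target_positions, dtype=float)
        angles = 2 * np.pi * np.arange(self.n_targets) / self.n_targets
        r = self.ring_diameter_cm / 2.0
        return np.column_stack([r * np.cos(angles), r * np.sin(angles)])


def make_task(kind: str = "center_out", **overrides) -> TaskConfig:
    """Build a task configuration with the standard geometry per kind."""
    kinds = {"center_out", "target_jump", "target_to_target"}
    if kind not in kinds:
        raise ValueError(f"unknown task kind {kind!r}; expected one of {sorted(kinds)}")
    defaults: dict = {"task_kind": kind}
    if kind == "target_jump":
        defaults["jump_probability"] = 0.25
    cfg = TaskConfig(**{**defaults, **overrides})
    if cfg.jump_probability and kind != "target_jump":
        raise ValueError("jump parameters apply only to the target_jump task")
    return cfg


def make_encoder(
    n_units: int,
    rng,
    baseline_range=(5.0, 25.0),
    depth_range=(0.05, 0.15),
) -> np.ndarray:
    """Ground-truth tuning parameters phi* (n_units x 3).

    Preferred directions uniform on the circle, baseline rates (spikes/s)
    and modulation depths (per cm/s) uniform in the given ranges.
    """
    rng = np.random.default_rng(rng)
    theta = rng.uniform(-np.pi, np.pi, n_units)
    depth = rng.uniform(*depth_range, n_units)
    base = rng.uniform(*baseline_range, n_units)
    return np.column_stack([np.log(base), depth * np.cos(theta), depth * np.sin(theta)])


def visual_feedback_seed(
    encoder: np.ndarray,
    rng,
    pd_jitter_deg: float = 20.0,
    depth_log_sd: float = 0.3,
    baseline_sd: float = 0.2,
) -> np.ndarray:
    """A plausible initial estimate: the truth, imperfectly measured.

    Emulates seeding from passive viewing of cursor movement — tuning is
    roughly right but noisy (jittered preferred directions, log-normally
    perturbed depths, perturbed baselines).
    """
    rng = np.random.default_rng(rng)
    phi = np.asarray(encoder, dtype=float)
    n = phi.shape[0]
    theta = np.arctan2(phi[:, 2], phi[:, 1]) + np.deg2rad(rng.normal(0, pd_jitter_deg, n))
    depth = np.linalg.norm(phi[:, 1:], axis=1) * np.exp(rng.normal(0, depth_log_sd, n))
    beta = phi[:, 0] + rng.normal(0, baseline_sd, n)
    return np.column_stack([beta, depth * np.cos(theta), depth * np.sin(theta)])


def permuted_seed(seed_phis: np.ndarray, rng) -> np.ndarray:
    """An arbitrary initialization: the seed permuted across units."""
    rng = np.random.default_rng(rng)
    phi = np.asarray(seed_phis, dtype=float)
    perm = rng.permutation(phi.shape[0])
    while phi.shape[0] > 1 and np.all(perm == np.arange(phi.shape[0])):
        perm = rng.permutation(phi.shape[0])
    return phi[perm]


@dataclass
class SyntheticBrain:
    """OFC-policy subject model with a ground-truth spiking encoder."""

    policy_gain: FeedbackGain
    policy_dynamics: CursorDynamics
    encoder: np.ndarray  # C x 3 ground-truth phi*
    motor_noise_sd: float = 1.5  # cm/s, white noise on the intended velocity
    engaged: bool = True

    def intended_velocity(self, displayed_state: np.ndarray, target: np.ndarray | None, rng) -> np.ndarray:
        """The subject's private intended velocity for this bin."""
        if not self.engaged or target is None:
            return np.zeros(2)
        A = self.policy_dynamics.transition
        BL = self.policy_dynamics.control @ self.policy_gain.gain
        xstar = np.array([target[0], target[1], 0.0, 0.0])
        intended = (A - BL) @ displayed_state + BL @ xstar
        v = intended[2:]
        if self.motor_noise_sd > 0:
            v = v + rng.normal(0.0, self.motor_noise_sd, 2)
        return v


@dataclass(frozen=True)
class SimulatorConfig:
    """Everything that determines a closed-loop run except the seed."""

    n_units: int = 20
    delta: float = 0.005
    # decoder prior dynamics (the simulator analogue of fitting a, w to
    # the subject's natural cursor kinematics)
    decoder_a: float = 0.97
    decoder_w: float = 1.0  # (cm/s)^2 per bin
    workspace_halfwidth: float = 12.0
    # intention estimation (instant-OFC default)
    intention_wr: float = DEFAULT_INTENTION_WR
    intention_mode: str = "ofc"  # "ofc" | "cursorgoal"
    # synthetic brain
    brain_wr: float = DEFAULT_INTENTION_WR
    motor_noise_sd: float = 1.5
    baseline_range: tuple = (5.0, 25.0)
    depth_range: tuple = (0.05, 0.15)
    engaged: bool = True
    # adaptation
    adapt_mode: str = "spike"  # "spike" | "smoothbatch" | "none"
    q_diag: float = DEFAULT_Q_DIAG
    init_var: float = DEFAULT_INIT_VAR
    adapt_seconds: float | None = None  # None = adapt for the whole session
    seed_mode: str = "vf"  # "vf" | "permuted" | "true"
    # assist
    assist: AssistSchedule | None = field(default_factory=AssistSchedule)
    fixed_assist_tau: float | None = None  # overrides the schedule when set
    # task
    task: TaskConfig = field(default_factory=TaskConfig)
    # logging
    snapshot_interval_s: float = 5.0


@dataclass
class TrialRecord:
    """One initiated trial's outcome and timing."""

    index: int
    target_index: int
    target_position: np.ndarray
    start_position: np.ndarray
    t_start: float  # go cue (trial initiation)
    t_end: float = np.nan
    outcome: str = ""  # success | hold_error | timeout
    reach_time: float | None = None  # s from leaving start to arriving at target
    jumped: bool = False
    t_jump: float | None = None
    start_bin: int = 0
    leave_bin: int | None = None
    arrive_bin: int | None = None
    end_bin: int = 0


@dataclass
class SessionLog:
    """Time-stamped closed-loop trace plus the per-trial table."""

    delta: float
    duration: float
    trials: list
    trace_pos: np.ndarray  # T x 2
    trace_vel: np.ndarray  # T x 2
    assist_events: list  # (time_s, phase, tau)
    snapshot_times: np.ndarray
    param_snapshots: np.ndarray  # S x C x 3
    final_params: np.ndarray  # C x 3
    encoder_truth: np.ndarray | None
    seed: int | None
    assist_off_time: float | None = None

    @property
    def n_bins(self) -> int:
        return self.trace_pos.shape[0]

    def trace_times(self) -> np.ndarray:
        return (np.arange(self.n_bins) + 1) * self.delta

    def success_times(self) -> np.ndarray:
        return np.array([tr.t_end for tr in self.trials if tr.outcome == "success"])


class Simulator:
    """The closed loop: synthetic brain, spike encoder, decoder, adaptation, task."""

    def __init__(self, cfg: SimulatorConfig, seed: int, encoder: np.ndarray | None = None,
                 seed_phis: np.ndarray | None = None):
        self.cfg = cfg
        self.seed = seed
        root = np.random.default_rng(seed)
        self.rng_task, self.rng_brain, self.rng_spikes, rng_init = root.spawn(4)

        ws = Workspace(-cfg.workspace_halfwidth, cfg.workspace_halfwidth,
                       -cfg.workspace_halfwidth, cfg.workspace_halfwidth)
        self.dyn = make_cursor_dynamics(cfg.decoder_a, cfg.decoder_w, cfg.delta, workspace=ws)
        self.instant_dyn = make_cursor_dynamics(0.0, 0.0, cfg.delta, workspace=ws)

        # gains: intention estimation (fixed), brain policy, assist ladder
        self.intent_gain = solve_steady_state_gain(self.instant_dyn, intention_weights(cfg.intention_wr))
        brain_gain = solve_steady_state_gain(self.instant_dyn, intention_weights(cfg.brain_wr))
        if encoder is None:
            encoder = make_encoder(cfg.n_units, rng_init, cfg.baseline_range, cfg.depth_range)
        self.brain = SyntheticBrain(
            policy_gain=brain_gain,
            policy_dynamics=self.instant_dyn,
            encoder=np.asarray(encoder, dtype=float),
            motor_noise_sd=cfg.motor_noise_sd,
            engaged=cfg.engaged,
        )
        taus = []
        if cfg.fixed_assist_tau is not None:
            taus.append(cfg.fixed_assist_tau)
        elif cfg.assist is not None:
            taus.extend(cfg.assist.tau_levels)
        self._assist_mats = {}
        for tau in taus:
            g = solve_steady_state_gain(self.dyn, assist_weights(tau))
            BL = self.dyn.control @ g.gain
            self._assist_mats[tau] = (self.dyn.transition - BL, BL)

        # decoder parameter estimates
        if seed_phis is None:
            if cfg.seed_mode == "true":
                seed_phis = self.brain.encoder.copy()
            else:
                seed_phis = visual_feedback_seed(self.brain.encoder, rng_init)
                if cfg.seed_mode == "permuted":
                    seed_phis = permuted_seed(seed_phis, rng_init)
        if cfg.adapt_mode == "spike":
            self.params = EnsemblePosterior.from_seed(seed_phis, cfg.init_var, cfg.q_diag)
        elif cfg.adapt_mode == "smoothbatch":
            self.params = SmoothBatchAdapter(phis=seed_phis, delta=cfg.delta)
        elif cfg.adapt_mode == "none":
            self.params = None
            self._frozen_phis = np.atleast_2d(np.asarray(seed_phis, dtype=float)).copy()
        else:
            raise ValueError(f"unknown adapt_mode {cfg.adapt_mode!r}")

        # kinematic posterior: start at workspace center, zero velocity
        self.x = np.zeros(4)
        self.vel_cov = cfg.init_var * np.eye(2)

        # assist controller
        self.assist_state = AssistState() if (cfg.assist is not None and cfg.fixed_assist_tau is None) else None
        self.assist_off_time: float | None = None
        self._test_start_time: float | None = None
        self._test_start_successes = 0

        # task state
        self.task = cfg.task
        self._targets = self.task.positions()
        self._center = np.zeros(2)
        self._phase = "acquire_start"
        self._start_pos = self._center.copy() if self.task.task_kind != "target_to_target" else self._targets[0].copy()
        self._hold_timer = 0.0
        self._iti_timer = 0.0
        self._reach_timer = 0.0
        self._block: list = []
        self._trial: TrialRecord | None = None
        self._left_start = False
        self._leave_time: float | None = None
        self._jump_pending = False
        self._jump_target: int | None = None
        self._cur_target_idx: int | None = None
        self._cur_target: np.ndarray | None = None

        self.trials: list[TrialRecord] = []
        self._n_success = 0
        self.t = 0.0
        self.k = 0

    # ------------------------------------------------------------------ helpers
    @property
    def param_means(self) -> np.ndarray:
        if self.params is None:
            return self._frozen_phis
        return self.params.means

    def _next_target_index(self) -> int:
        if not self._block:
            self._block = list(self.rng_task.permutation(len(self._targets)))
        return int(self._block.pop())

    def _instructed_target(self) -> np.ndarray | None:
        """The position the subject is currently instructed to acquire."""
        if self._phase in ("acquire_start", "start_hold"):
            return self._start_pos
        if self._phase in ("reach", "target_hold"):
            return self._cur_target
        return None  # iti

    def _adapting(self) -> bool:
        if self.params is None:
            return False
        if self.cfg.adapt_seconds is not None and self.t >= self.cfg.adapt_seconds:
            return False
        return True

    # ------------------------------------------------------------------ task logic
    def _task_step(self) -> None:
        pos = self.x[:2]
        task = self.task
        if self._phase == "iti":
            self._iti_timer += self.cfg.delta
            if self._iti_timer >= task.iti_seconds:
                self._phase = "acquire_start"
                self._hold_timer = 0.0
            return
        if self._phase in ("acquire_start", "start_hold"):
            inside = np.linalg.norm(pos - self._start_pos) <= task.target_radius_cm
            if inside:
                self._phase = "start_hold"
                self._hold_timer += self.cfg.delta
                if self._hold_timer >= task.hold_seconds:
                    self._initiate_trial()
            else:
                self._phase = "acquire_start"
                self._hold_timer = 0.0
            return
        if self._phase == "reach":
            self._reach_timer += self.cfg.delta
            if not self._left_start and np.linalg.norm(pos - self._start_pos) > task.target_radius_cm:
                self._left_start = True
                self._leave_time = self.t
                self._trial.leave_bin = self.k
            if (
                self._jump_pending
                and self._left_start
                and self.t >= self._leave_time + task.jump_delay_seconds
            ):
                self._execute_jump()
            if np.linalg.norm(pos - self._cur_target) <= task.target_radius_cm:
                self._phase = "target_hold"
                self._hold_timer = 0.0
                self._trial.arrive_bin = self.k
                if self._left_start:
                    self._trial.reach_time = self.t - self._leave_time
            elif self._reach_timer >= task.reach_timeout_seconds:
                self._end_trial("timeout")
            return
        if self._phase == "target_hold":
            if np.linalg.norm(pos - self._cur_target) > task.target_radius_cm:
                # strict hold: no opportunity to re-enter
                self._end_trial("hold_error")
                return
            self._hold_timer += self.cfg.delta
            if self._hold_timer >= task.hold_seconds:
                self._end_trial("success")

    def _initiate_trial(self) -> None:
        task = self.task
        idx = self._next_target_index()
        if task.task_kind == "target_to_target":
            # draw an end target different from the start location
            while np.allclose(self._targets[idx], self._start_pos):
                idx = self._next_target_index()
        self._cur_target_idx = idx
        self._cur_target = self._targets[idx].copy()
        self._jump_pending = False
        self._jump_target = None
        if task.task_kind == "target_jump" and self.rng_task.random() < task.jump_probability:
            self._jump_pending = True
            if task.jump_types is not None:
                options = [b for a, b in task.jump_types if a == idx]
                if options:
                    self._jump_target = int(options[self.rng_task.integers(len(options))])
            if self._jump_target is None:
                others = [j for j in range(len(self._targets)) if j != idx]
                self._jump_target = int(others[self.rng_task.integers(len(others))])
        self._trial = TrialRecord(
            index=len(self.trials),
            target_index=idx,
            target_position=self._cur_target.copy(),
            start_position=self._start_pos.copy(),
            t_start=self.t,
            start_bin=self.k,
        )
        self._phase = "reach"
        self._reach_timer = 0.0
        self._left_start = False
        self._leave_time = None

    def _execute_jump(self) -> None:
        self._jump_pending = False
        self._trial.jumped = True
        self._trial.t_jump = self.t
        self._cur_target_idx = self._jump_target
        self._cur_target = self._targets[self._jump_target].copy()
        self._trial.target_index = self._jump_target
        self._trial.target_position = self._cur_target.copy()

    def _end_trial(self, outcome: str) -> None:
        self._trial.outcome = outcome
        self._trial.t_end = self.t
        self._trial.end_bin = self.k
        self.trials.append(self._trial)
        if outcome == "success":
            self._n_success += 1
        if self.task.task_kind == "target_to_target":
            self._start_pos = self._cur_target.copy()
        self._trial = None
        self._phase = "iti"
        self._iti_timer = 0.0

    # ------------------------------------------------------------------ assist
    def _assist_tau(self) -> float | None:
        cfg = self.cfg
        if cfg.fixed_assist_tau is not None:
            return cfg.fixed_assist_tau
        if self.assist_state is None:
            return None
        sched = cfg.assist
        rate = None
        if self.assist_state.phase == "test":
            if self._test_start_time is None:
                self._test_start_time = self.t
                self._test_start_successes = self._n_success
            elapsed = self.assist_state.elapsed_in_phase + cfg.delta
            if elapsed >= sched.test_duration:
                window_min = max(self.t - self._test_start_time, cfg.delta) / 60.0
                rate = (self._n_success - self._test_start_successes) / window_min
        prev_phase = self.assist_state.phase
        self.assist_state, tau = advance(self.assist_state, sched, cfg.delta, rate)
        if self.assist_state.phase != "test":
            self._test_start_time = None
        if prev_phase != "off" and self.assist_state.phase == "off" and self.assist_off_time is None:
            self.assist_off_time = self.t
        return tau

    # ------------------------------------------------------------------ main loop
    def step(self) -> tuple[np.ndarray, np.ndarray]:
        """Advance the closed loop one bin; returns (spikes, intended velocity)."""
        cfg = self.cfg
        delta = cfg.delta
        x_prev = self.x
        target = self._instructed_target()

        # subject: intention + spikes
        v_int = self.brain.intended_velocity(x_prev, target, self.rng_brain)
        exponent = self.brain.encoder[:, 0] + self.brain.encoder[:, 1:] @ v_int
        p = np.minimum(np.exp(exponent) * delta, P_MAX)
        spikes = (self.rng_spikes.random(p.size) < p).astype(np.float64)

        # assist level for this bin
        tau = self._assist_tau()

        # kinematic PPF: predict
        phi = self.param_means
        if tau is not None and target is not None:
            Acl, BL = self._assist_mats[tau]
            xstar = np.array([target[0], target[1], 0.0, 0.0])
            x_pred = Acl @ x_prev + BL @ xstar
            Mv = Acl[2:, 2:]
            Cp = Acl[2:, :2]
            # position is deterministic (zero covariance), so only the
            # velocity-velocity block of the closed-loop matrix propagates
            S_pred = Mv @ self.vel_cov @ Mv.T
            S_pred[0, 0] += cfg.decoder_w
            S_pred[1, 1] += cfg.decoder_w
            _ = Cp  # position columns carry no uncertainty
        else:
            a = cfg.decoder_a
            x_pred = np.array(
                [x_prev[0] + delta * x_prev[2], x_prev[1] + delta * x_prev[3],
                 a * x_prev[2], a * x_prev[3]]
            )
            S_pred = (a * a) * self.vel_cov
            S_pred = S_pred.copy()
            S_pred[0, 0] += cfg.decoder_w
            S_pred[1, 1] += cfg.decoder_w

        # kinematic PPF: velocity update from this bin's spike events
        alpha = phi[:, 1:]
        lam_d = np.minimum(np.exp(phi[:, 0] + alpha @ x_pred[2:]) * delta, P_MAX)
        info = (alpha * lam_d[:, None]).T @ alpha
        S_new = np.linalg.inv(np.linalg.inv(S_pred) + info)
        S_new = 0.5 * (S_new + S_new.T)
        x_new = x_pred.copy()
        x_new[2:] = x_pred[2:] + S_new @ (alpha.T @ (spikes - lam_d))
        x_new = self.dyn.workspace.clamp(x_new)
        self.x = x_new
        self.vel_cov = S_new

        # intention estimation + parameter adaptation
        v_tilde = np.zeros(2)
        if target is not None and self._adapting():
            xstar = np.array([target[0], target[1], 0.0, 0.0])
            if cfg.intention_mode == "ofc":
                A0 = self.instant_dyn.transition
                BL0 = self.instant_dyn.control @ self.intent_gain.gain
                v_tilde = ((A0 - BL0) @ x_new + BL0 @ xstar)[2:]
            else:
                v_tilde = cursorgoal_intention(
                    x_new, TargetState(xstar[:2]), self.task.target_radius_cm
                )
            self.params.step(v_tilde, spikes, delta)

        self.t += delta
        self.k += 1
        self._task_step()
        return spikes, v_int

    def run(self, duration_s: float) -> SessionLog:
        """Run the closed loop for ``duration_s`` and return the session log."""
        cfg = self.cfg
        n_bins = int(round(duration_s / cfg.delta))
        trace_pos = np.empty((n_bins, 2))
        trace_vel = np.empty((n_bins, 2))
        snap_every = max(int(round(cfg.snapshot_interval_s / cfg.delta)), 1)
        snaps = [self.param_means.copy()]
        snap_times = [self.t]
        assist_events = []
        last_phase_tau = (None, None)
        for i in range(n_bins):
            self.step()
            trace_pos[i] = self.x[:2]
            trace_vel[i] = self.x[2:]
            if self.assist_state is not None:
                key = (self.assist_state.phase, self.assist_state.level_index)
                if key != last_phase_tau:
                    tau_now = (
                        cfg.assist.tau_levels[self.assist_state.level_index]
                        if self.assist_state.phase == "assist"
                        else None
                    )
                    assist_events.append((self.t, self.assist_state.phase, tau_now))
                    last_phase_tau = key
            if (i + 1) % snap_every == 0:
                snaps.append(self.param_means.copy())
                snap_times.append(self.t)
        return SessionLog(
            delta=cfg.delta,
            duration=n_bins * cfg.delta,
            trials=list(self.trials),
            trace_pos=trace_pos,
            trace_vel=trace_vel,
            assist_events=assist_events,
            snapshot_times=np.asarray(snap_times),
            param_snapshots=np.stack(snaps),
            final_params=self.param_means.copy(),
            encoder_truth=self.brain.encoder.copy(),
            seed=self.seed,
            assist_off_time=self.assist_off_time,
        )


def run_trial(cfg: SimulatorConfig, seed: int, max_seconds: float = 60.0,
              encoder: np.ndarray | None = None,
              seed_phis: np.ndarray | None = None) -> TrialRecord:
    """Run the closed loop until the first initiated trial ends."""
    sim = Simulator(cfg, seed, encoder=encoder, seed_phis=seed_phis)
    n_max = int(round(max_seconds / cfg.delta))
    for _ in range(n_max):
        sim.step()
        if sim.trials:
            return sim.trials[0]
    # never initiated or never ended: report a timeout-like record
    return TrialRecord(
        index=0,
        target_index=-1,
        target_position=np.full(2, np.nan),
        start_position=np.full(2, np.nan),
        t_start=np.nan,
        t_end=sim.t,
        outcome="timeout",
    )


def run_session(cfg: SimulatorConfig, seed: int, duration_minutes: float,
                encoder: np.ndarray | None = None,
                seed_phis: np.ndarray | None = None) -> SessionLog:
    """Build the closed loop from a config and run a full session."""
    sim = Simulator(cfg, seed, encoder=encoder, seed_phis=seed_phis)
    return sim.run(duration_minutes * 60.0)


def run_chance_session(cfg: SimulatorConfig, tau: float | None, duration_s: float,
                       seed: int) -> float:
    """Success rate (trials/min) of one disengaged, fixed-assist run."""
    chance_cfg = replace(cfg, engaged=False, fixed_assist_tau=tau, assist=None)
    sim = Simulator(chance_cfg, seed)
    log = sim.run(duration_s)
    return len(log.success_times()) / (duration_s / 60.0)
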