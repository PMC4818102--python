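"""Tasks and the closed-loop simulator: geometry, trial machine, end-to-end runs."""

from dataclasses import replace

import numpy as np
import pytest

from ofcppf import (
    KinematicPosterior,
    Simulator,
    SimulatorConfig,
    decode_step,
    make_task,
    percent_correct,
    run_trial,
)
from ofcppf.ofc import TargetState

DELTA = 0.005


class TestMakeTask:
    def test_center_out_geometry(self):
        t = make_task("center_out")
        pos = t.positions()
        assert pos.shape == (8, 2)
        np.testing.assert_allclose(np.linalg.norm(pos, axis=1), 6.5)
        assert t.target_radius_cm == 1.2
        assert t.hold_seconds == 0.25

    def test_target_jump_defaults(self):
        t = make_task("target_jump")
        assert t.jump_probability == 0.25
        assert t.jump_delay_seconds == 0.5

    def test_unknown_kind_rejected(self):
        with pytest.raises(ValueError):
            make_task("spiral")

    def test_jump_params_only_for_jump_task(self):
        with pytest.raises(ValueError):
            make_task("center_out", jump_probability=0.5)

    def test_jump_draw_fraction(self):
        """The per-trial jump decision is Bernoulli(p): over many
        initiations the jump fraction lands within 3 sigma of p."""
        cfg = replace(
            SimulatorConfig(adapt_mode="none", seed_mode="true", assist=None),
            task=make_task("target_jump"),
        )
        sim = Simulator(cfg, seed=0)
        n = 10_000
        draws = 0
        for _ in range(n):
            sim._phase = "start_hold"
            sim._initiate_trial()
            draws += sim._jump_pending
            sim._trial = None
        p = 0.25
        assert abs(draws / n - p) < 3 * np.sqrt(p * (1 - p) / n)


class TestTrialMachine:
    def _driven_sim(self):
        cfg = SimulatorConfig(adapt_mode="none", seed_mode="true", assist=None)
        return Simulator(cfg, seed=0)

    def _drive(self, sim, positions):
        """Feed a constructed position path through the task machine."""
        for p in positions:
            sim.x = np.array([p[0], p[1], 0.0, 0.0])
            sim.t += DELTA
            sim.k += 1
            sim._task_step()

    def test_strict_hold_exit_fails_immediately(self):
        sim = self._driven_sim()
        hold_bins = int(0.25 / DELTA)
        # initiate: sit at center through the center hold
        self._drive(sim, [(0.0, 0.0)] * (hold_bins + 2))
        assert sim._phase == "reach"
        target = sim._cur_target
        # fly to the target, hold briefly, then exit before the hold is up
        self._drive(sim, [target] * (hold_bins // 2))
        assert sim._phase == "target_hold"
        self._drive(sim, [target + 5.0])
        assert sim.trials[-1].outcome == "hold_error"

    def test_full_hold_succeeds(self):
        sim = self._driven_sim()
        hold_bins = int(0.25 / DELTA)
        self._drive(sim, [(0.0, 0.0)] * (hold_bins + 2))
        target = sim._cur_target
        self._drive(sim, [target] * (hold_bins + 1))
        assert sim.trials[-1].outcome == "success"

    def test_timeout_when_target_never_reached(self):
        sim = self._driven_sim()
        hold_bins = int(0.25 / DELTA)
        self._drive(sim, [(0.0, 0.0)] * (hold_bins + 2))
        n_timeout = int(sim.task.reach_timeout_seconds / DELTA) + 1
        self._drive(sim, [(0.0, 0.0)] * n_timeout)
        assert sim.trials[-1].outcome == "timeout"

    def test_jump_occurs_at_configured_delay_after_leaving_center(self):
        cfg = replace(
            SimulatorConfig(adapt_mode="none", seed_mode="true", assist=None),
            task=make_task("target_jump", jump_probability=1.0),
        )
        sim = Simulator(cfg, seed=0)
        hold_bins = int(0.25 / DELTA)
        self._drive(sim, [(0.0, 0.0)] * (hold_bins + 2))
        assert sim._jump_pending
        # leave the center, then idle outside it until the jump fires
        self._drive(sim, [(2.0, 0.0)])
        t_leave = sim._leave_time
        self._drive(sim, [(2.0, 0.0)] * int(0.6 / DELTA))
        assert sim.trials == []  # still mid-trial
        tr = sim._trial
        assert tr.jumped
        assert tr.t_jump == pytest.approx(t_leave + 0.5, abs=2 * DELTA)


class TestClosedLoop:
    def test_true_seed_frozen_decoder_mostly_succeeds(self):
        """An engaged subject with a decoder built from the true encoder
        completes at least 80% of its first 50 trials."""
        cfg = SimulatorConfig(adapt_mode="none", seed_mode="true", assist=None)
        log = Simulator(cfg, seed=11).run(360.0)
        first50 = log.trials[:50]
        assert len(first50) == 50
        assert percent_correct(first50) >= 80.0

    def test_disengaged_subject_fails_without_assist(self):
        cfg = SimulatorConfig(adapt_mode="none", seed_mode="true", assist=None, engaged=False)
        rec = run_trial(cfg, seed=5, max_seconds=30.0)
        assert rec.outcome != "success"

    def test_seeded_run_is_reproducible(self):
        cfg = SimulatorConfig()
        a = Simulator(cfg, seed=9).run(30.0)
        b = Simulator(cfg, seed=9).run(30.0)
        np.testing.assert_array_equal(a.trace_pos, b.trace_pos)
        assert [t.outcome for t in a.trials] == [t.outcome for t in b.trials]
        np.testing.assert_array_equal(a.final_params, b.final_params)

    def test_trial_timestamps_strictly_increase(self):
        log = Simulator(SimulatorConfig(), seed=4).run(120.0)
        ends = [t.t_end for t in log.trials]
        assert all(b > a for a, b in zip(ends, ends[1:]))

    def test_self_pacing_trials_start_inside_start_target(self):
        log = Simulator(SimulatorConfig(adapt_mode="none", seed_mode="true", assist=None), seed=2).run(120.0)
        assert len(log.trials) > 5
        for tr in log.trials:
            # at the go cue the cursor has just completed the start hold
            d = np.linalg.norm(log.trace_pos[tr.start_bin - 1] - tr.start_position)
            assert d <= 1.2 + 1e-9

    def test_fast_path_matches_module_decoder(self):
        """The simulator's inlined PPF step must agree with the module-level
        predict/update composition, bin for bin."""
        for tau in (None, 0.4):
            cfg = SimulatorConfig(
                adapt_mode="none", seed_mode="true", assist=None, fixed_assist_tau=tau
            )
            sim = Simulator(cfg, seed=21)
            post = KinematicPosterior(
                mean=sim.x.copy(),
                covariance=np.diag([0, 0, *np.diag(sim.vel_cov)]),
            )
            gain = None
            if tau is not None:
                from ofcppf import assist_weights, solve_steady_state_gain

                gain = solve_steady_state_gain(sim.dyn, assist_weights(tau))
            for _ in range(400):
                target = sim._instructed_target()
                phi = sim.param_means.copy()
                spikes, _ = sim.step()
                tgt = TargetState(np.asarray(target)) if target is not None else None
                use_gain = gain if (tau is not None and tgt is not None) else None
                post = decode_step(post, sim.dyn, use_gain, tgt, spikes, phi, DELTA)
                np.testing.assert_allclose(post.mean, sim.x, atol=1e-10)
                np.testing.assert_allclose(post.covariance[2:, 2:], sim.vel_cov, atol=1e-12)

    def test_target_to_target_chains_targets(self):
        cfg = replace(
            SimulatorConfig(adapt_mode="none", seed_mode="true", assist=None),
            task=make_task("target_to_target"),
        )
        log = Simulator(cfg, seed=3).run(180.0)
        assert len(log.trials) > 3
        for prev, nxt in zip(log.trials, log.trials[1:]):
            np.testing.assert_allclose(nxt.start_position, prev.target_position)
            assert not np.allclose(nxt.start_position, nxt.target_position)
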