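"""Parameter PPF: prediction/update recursions, ensemble vectorization,
GLM batch fitting and the SmoothBatch blend."""

import numpy as np
import pytest

from ofcppf import (
    EnsemblePosterior,
    NeuronParams,
    ParamPosterior,
    adapt_ensemble,
    glm_fit_batch,
    predict_params,
    sample_spikes,
    smoothbatch_update,
    update_params,
)
from ofcppf.point_process import conditional_intensity

DELTA = 0.005


def _posterior(mean=None, var=0.01, q=1e-6):
    mean = np.array([np.log(20.0), 0.0, 0.0]) if mean is None else np.asarray(mean, float)
    return ParamPosterior(mean=mean, covariance=var * np.eye(3), process_noise=q * np.eye(3))


class TestPredict:
    def test_zero_process_noise_is_identity(self):
        p = _posterior(q=0.0)
        out = predict_params(p)
        np.testing.assert_array_equal(out.mean, p.mean)
        np.testing.assert_array_equal(out.covariance, p.covariance)

    def test_diagonal_growth(self):
        p = _posterior(q=1e-6)
        out = predict_params(p)
        np.testing.assert_allclose(np.diag(out.covariance - p.covariance), 1e-6)

    def test_trace_nondecreasing(self, rng):
        p = _posterior(q=1e-6)
        for _ in range(10):
            out = predict_params(p)
            assert np.trace(out.covariance) >= np.trace(p.covariance)
            p = out


class TestUpdate:
    def test_baseline_only_update_matches_matrix_arithmetic(self):
        """With zero intended velocity the regressor is [1,0,0]: only the
        baseline row is informed, by exactly lambda*Delta = 0.1."""
        pred = _posterior(var=0.01, q=0.0)
        out = update_params(pred, np.array([1.0, 0.0, 0.0]), 1, DELTA)
        np.testing.assert_allclose(
            np.diag(out.covariance), [1 / 100.1, 0.01, 0.01], rtol=1e-12
        )
        assert out.mean[0] == pytest.approx(np.log(20.0) + (1 / 100.1) * 0.9)
        np.testing.assert_array_equal(out.mean[1:], 0.0)

    def test_innovation_sign_flips_with_spike(self):
        pred = _posterior()
        s = np.array([1.0, 5.0, -3.0])
        up1 = update_params(pred, s, 1, DELTA)
        up0 = update_params(pred, s, 0, DELTA)
        d1 = up1.mean - pred.mean
        d0 = up0.mean - pred.mean
        # both move along cov @ s, in opposite directions
        assert d1 @ d0 < 0

    def test_information_never_decreases(self, rng):
        pred = _posterior(var=0.05)
        for _ in range(20):
            s = np.array([1.0, *rng.normal(0, 5, 2)])
            out = update_params(pred, s, int(rng.random() < 0.3), DELTA)
            gain = np.linalg.inv(out.covariance) - np.linalg.inv(pred.covariance)
            assert np.min(np.linalg.eigvalsh(gain)) > -1e-8
            pred = ParamPosterior(out.mean, out.covariance, pred.process_noise)

    def test_bad_regressor_rejected(self):
        with pytest.raises(ValueError):
            update_params(_posterior(), np.array([0.0, 1.0, 1.0]), 1, DELTA)


class TestEnsemble:
    def test_single_unit_reduces_to_composition(self):
        post = [_posterior()]
        v = np.array([3.0, -2.0])
        out = adapt_ensemble(post, v, np.array([1]), DELTA)
        ref = update_params(predict_params(post[0]), np.array([1.0, 3.0, -2.0]), 1, DELTA)
        np.testing.assert_allclose(out[0].mean, ref.mean)
        np.testing.assert_allclose(out[0].covariance, ref.covariance)

    def test_unit_order_permutes_outputs(self, rng):
        posts = [_posterior(mean=[np.log(r), 0.05, -0.02]) for r in (5.0, 20.0, 40.0)]
        v = np.array([4.0, 1.0])
        spikes = np.array([1, 0, 1])
        perm = [2, 0, 1]
        out = adapt_ensemble(posts, v, spikes, DELTA)
        out_p = adapt_ensemble([posts[i] for i in perm], v, spikes[perm], DELTA)
        for i, j in enumerate(perm):
            np.testing.assert_allclose(out_p[i].mean, out[j].mean)

    def test_vectorized_matches_per_unit_filters(self, rng):
        phis = np.column_stack(
            [np.log(rng.uniform(5, 30, 6)), rng.normal(0, 0.1, (6, 2))]
        )
        ens = EnsemblePosterior.from_seed(phis, init_var=0.02, q_diag=1e-6)
        singles = [ens.unit(c) for c in range(6)]
        for t in range(50):
            v = rng.normal(0, 5, 2)
            spikes = (rng.random(6) < 0.2).astype(int)
            ens.step(v, spikes, DELTA)
            singles = adapt_ensemble(singles, v, spikes, DELTA)
        for c in range(6):
            np.testing.assert_allclose(ens.means[c], singles[c].mean, rtol=1e-10)
            np.testing.assert_allclose(ens.covariances[c], singles[c].covariance, rtol=1e-9)

    def test_shape_mismatch_rejected(self):
        with pytest.raises(ValueError):
            adapt_ensemble([_posterior()], np.zeros(2), np.array([1, 0]), DELTA)

    def test_stationary_recovery_open_loop(self, rng):
        """Filtering 10 simulated minutes of varied intention recovers the
        generating baseline within 0.1 log-rate and the preferred
        direction within 15 degrees."""
        truth = np.array(
            [
                [np.log(18.0), 0.09, 0.05],
                [np.log(7.0), -0.06, 0.10],
                [np.log(30.0), 0.02, -0.11],
            ]
        )
        n = 120_000
        # smooth, varied intention stream (AR(1) velocities, ~6 cm/s)
        v = np.zeros((n, 2))
        eps = rng.normal(0, 1.2, (n, 2))
        for t in range(1, n):
            v[t] = 0.97 * v[t - 1] + eps[t]
        units = [NeuronParams(r[0], r[1:]) for r in truth]
        ev = sample_spikes(units, v, DELTA, rng=rng)
        start = truth + rng.normal(0, [0.3, 0.05, 0.05], truth.shape)
        ens = EnsemblePosterior.from_seed(start)
        for t in range(n):
            ens.step(v[t], ev.events[:, t], DELTA)
        beta_err = np.abs(ens.means[:, 0] - truth[:, 0])
        pd_est = np.arctan2(ens.means[:, 2], ens.means[:, 1])
        pd_true = np.arctan2(truth[:, 2], truth[:, 1])
        pd_err = np.abs(np.angle(np.exp(1j * (pd_est - pd_true))))
        assert np.all(beta_err < 0.1)
        assert np.all(np.degrees(pd_err) < 15.0)


class TestGLM:
    def _simulate(self, rng, truth, seconds=90.0):
        n = int(seconds / DELTA)
        v = np.zeros((n, 2))
        eps = rng.normal(0, 1.2, (n, 2))
        for t in range(1, n):
            v[t] = 0.97 * v[t - 1] + eps[t]
        unit = NeuronParams(truth[0], truth[1:])
        ev = sample_spikes([unit], v, DELTA, rng=rng)
        return ev.events[0], v

    def test_recovery_within_three_standard_errors(self, rng):
        truth = np.array([np.log(15.0), 0.08, -0.06])
        y, v = self._simulate(rng, truth)
        phi, fb = glm_fit_batch(y, v, DELTA)
        assert not fb
        # asymptotic standard errors from the Fisher information
        X = np.column_stack([np.ones(len(v)), v])
        lam_d = np.exp(X @ phi) * DELTA
        se = np.sqrt(np.diag(np.linalg.inv(X.T @ (X * lam_d[:, None]))))
        np.testing.assert_array_less(np.abs(phi - truth), 3 * se)

    def test_no_spikes_falls_back(self):
        prev = np.array([1.0, 0.1, 0.2])
        phi, fb = glm_fit_batch(np.zeros(1000), np.zeros((1000, 2)), DELTA, previous=prev)
        assert fb
        np.testing.assert_array_equal(phi, prev)

    def test_doubling_data_roughly_halves_variance(self, rng):
        truth = np.array([np.log(15.0), 0.08, -0.06])
        short, long_ = [], []
        for _ in range(24):
            y, v = self._simulate(rng, truth, seconds=45.0)
            short.append(glm_fit_batch(y, v, DELTA)[0])
            y, v = self._simulate(rng, truth, seconds=90.0)
            long_.append(glm_fit_batch(y, v, DELTA)[0])
        # pool the three components' variances to damp estimator noise
        var_s = np.sum(np.var(short, axis=0))
        var_l = np.sum(np.var(long_, axis=0))
        assert var_l < var_s
        assert var_l / var_s == pytest.approx(0.5, abs=0.35)


class TestSmoothBatch:
    def test_equal_estimates_unchanged(self):
        phi = np.array([1.0, 0.2, -0.1])
        np.testing.assert_allclose(smoothbatch_update(phi, phi, 90.0, 180.0), phi)

    def test_half_life_weight(self):
        prev = np.zeros(3)
        new = np.ones(3)
        out = smoothbatch_update(prev, new, 90.0, 180.0)
        rho = 0.5 ** 0.5
        np.testing.assert_allclose(out, (1 - rho) * np.ones(3))

    def test_two_batches_halve_the_original_weight(self):
        prev = np.ones(3)
        out = smoothbatch_update(prev, np.zeros(3), 90.0, 180.0)
        out = smoothbatch_update(out, np.zeros(3), 90.0, 180.0)
        np.testing.assert_allclose(out, 0.5 * np.ones(3))

    def test_bad_durations_rejected(self):
        with pytest.raises(ValueError):
            smoothbatch_update(np.zeros(3), np.ones(3), -90.0, 180.0)
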