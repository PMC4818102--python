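"""Spike-event-based adaptation of tuning parameters, and the SmoothBatch baseline.

Each unit's parameters ``phi = [beta, alpha_x, alpha_y]`` are tracked by
their own point-process filter under a random-walk prior
``phi_t = phi_{t-1} + q_t`` with ``q ~ N(0, Q)``.  The observation is the
unit's binary spike event; the regressor is ``s_t = [1, v~_t]`` built from
the intended velocity inferred by the OFC model.  The Gaussian posterior
recursion is

    predict:  mean unchanged,  cov += Q
    update:   cov^-1 += s s' lambda*Delta
              mean  += cov_new s (N - lambda*Delta)

with the rate evaluated at the predicted mean.  Q sets the learning rate:
larger Q tracks faster but with noisier estimates.  Units are updated
independently (they share only the regressor), so the ensemble update is
vectorized across units.

The SmoothBatch baseline instead refits ``phi`` by Poisson GLM maximum
likelihood on fixed-length batches (90 s) and blends consecutive batch
estimates with an exponential half-life (180 s).
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .point_process import P_MAX

__all__ = [
    "ParamPosterior",
    "EnsemblePosterior",
    "predict_params",
    "update_params",
    "adapt_ensemble",
    "glm_fit_batch",
    "smoothbatch_update",
    "SmoothBatchAdapter",
]

#: Default random-walk noise per bin on each parameter component.
DEFAULT_Q_DIAG = 1e-7
#: Default initial posterior variance per component (broad relative to
#: plausible tuning magnitudes).
DEFAULT_INIT_VAR = 1e-2

SMOOTHBATCH_BATCH_SECONDS = 90.0
SMOOTHBATCH_HALF_LIFE_SECONDS = 180.0


@dataclass
class ParamPosterior:
    """Gaussian posterior over one unit's ``phi`` with its learning rate Q."""

    mean: np.ndarray  # 3-vector
    covariance: np.ndarray  # 3x3 SPD
    process_noise: np.ndarray  # Q, 3x3 PSD

    def __post_init__(self):
        self.mean = np.asarray(self.mean, dtype=float)
        self.covariance = np.asarray(self.covariance, dtype=float)
        self.process_noise = np.asarray(self.process_noise, dtype=float)
        np.linalg.cholesky(self.covariance)  # raises if not SPD

    @classmethod
    def from_seed(cls, phi, init_var: float = DEFAULT_INIT_VAR, q_diag: float = DEFAULT_Q_DIAG):
        return cls(
            mean=np.asarray(phi, dtype=float),
            covariance=init_var * np.eye(3),
            process_noise=q_diag * np.eye(3),
        )


def predict_params(post: ParamPosterior) -> ParamPosterior:
    """Random-walk prediction: mean unchanged, covariance grows by Q."""
    return ParamPosterior(
        mean=post.mean.copy(),
        covariance=post.covariance + post.process_noise,
        process_noise=post.process_noise,
    )


def update_params(
    pred: ParamPosterior,
    regressor: np.ndarray,
    spike_event: int,
    delta: float,
) -> ParamPosterior:
    """One spike-event update of the parameter posterior.

    ``regressor`` is ``s = [1, v~_x, v~_y]``; ``spike_event`` is 0 or 1.
    Implemented in covariance form via the rank-one (Sherman-Morrison)
    identity, equivalent to the information-form update
    ``cov^-1 += s s' lambda*Delta``.
    """
    s = np.asarray(regressor, dtype=float)
    if s.shape != (3,) or s[0] != 1.0:
        raise ValueError("regressor must be [1, v_x, v_y]")
    lam_d = min(float(np.exp(s @ pred.mean)) * delta, P_MAX)
    cs = pred.covariance @ s
    denom = 1.0 + lam_d * float(s @ cs)
    cov = pred.covariance - np.outer(cs, cs) * (lam_d / denom)
    cov = 0.5 * (cov + cov.T)
    mean = pred.mean + cov @ s * (float(spike_event) - lam_d)
    return ParamPosterior(mean=mean, covariance=cov, process_noise=pred.process_noise)


@dataclass
class EnsemblePosterior:
    """Vectorized per-unit Gaussian posteriors sharing a common Q.

    ``means`` is C x 3 and ``covariances`` C x 3 x 3; the per-unit filters
    are independent, so all C rank-one updates are applied in one shot.
    """

    means: np.ndarray
    covariances: np.ndarray
    process_noise: np.ndarray  # 3x3, shared

    def __post_init__(self):
        self.means = np.atleast_2d(np.asarray(self.means, dtype=float))
        self.covariances = np.asarray(self.covariances, dtype=float)
        if self.covariances.ndim == 2:
            self.covariances = np.repeat(self.covariances[None], self.means.shape[0], axis=0)
        self.process_noise = np.asarray(self.process_noise, dtype=float)

    @classmethod
    def from_seed(cls, phis, init_var: float = DEFAULT_INIT_VAR, q_diag: float = DEFAULT_Q_DIAG):
        phis = np.atleast_2d(np.asarray(phis, dtype=float))
        return cls(
            means=phis.copy(),
            covariances=np.repeat((init_var * np.eye(3))[None], phis.shape[0], axis=0),
            process_noise=q_diag * np.eye(3),
        )

    @property
    def n_units(self) -> int:
        return self.means.shape[0]

    def unit(self, c: int) -> ParamPosterior:
        return ParamPosterior(
            mean=self.means[c].copy(),
            covariance=self.covariances[c].copy(),
            process_noise=self.process_noise.copy(),
        )

    def step(self, intended_velocity: np.ndarray, spikes: np.ndarray, delta: float) -> None:
        """In-place predict + update of every unit with the shared regressor."""
        s = np.array([1.0, intended_velocity[0], intended_velocity[1]])
        cov = self.covariances + self.process_noise  # predict
        lam_d = np.minimum(np.exp(self.means @ s) * delta, P_MAX)  # per unit
        cs = cov @ s  # C x 3
        denom = 1.0 + lam_d * (cs @ s)
        scale = lam_d / denom
        cov -= scale[:, None, None] * cs[:, :, None] * cs[:, None, :]
        innov = np.asarray(spikes, dtype=float) - lam_d
        self.means += (cov @ s) * innov[:, None]
        self.covariances = cov


def adapt_ensemble(posteriors, intended_velocity, spike_vector, delta: float):
    """Predict + update every unit independently with the shared regressor.

    Accepts either an :class:`EnsemblePosterior` (updated in place and
    returned) or a sequence of :class:`ParamPosterior` (a new list is
    returned).
    """
    spikes = np.asarray(spike_vector)
    if isinstance(posteriors, EnsemblePosterior):
        if spikes.size != posteriors.n_units:
            raise ValueError("spike vector length does not match number of units")
        posteriors.step(np.asarray(intended_velocity, dtype=float), spikes, delta)
        return posteriors
    if spikes.size != len(posteriors):
        raise ValueError("spike vector length does not match number of units")
    s = np.array([1.0, intended_velocity[0], intended_velocity[1]])
    return [
        update_params(predict_params(p), s, int(n), delta)
        for p, n in zip(posteriors, spikes)
    ]


def glm_fit_batch(
    events: np.ndarray,
    intended_velocities: np.ndarray,
    delta: float,
    previous: np.ndarray | None = None,
) -> tuple[np.ndarray, bool]:
    """Batch maximum-likelihood fit of one unit's ``phi`` by Poisson GLM.

    Fits ``log E[N] = log Delta + [1, v~'] phi`` (the small-Delta Poisson
    limit of the Bernoulli spike-event model) with statsmodels.  Returns
    ``(phi, used_fallback)``; when the batch holds no spikes (or the fit
    fails) the previous estimate is carried and the flag is set.
    """
    import statsmodels.api as sm

    y = np.asarray(events, dtype=float).ravel()
    v = np.atleast_2d(np.asarray(intended_velocities, dtype=float))
    if y.size != v.shape[0]:
        raise ValueError("events and intended velocities disagree in length")
    fallback = previous if previous is not None else np.array([np.log(1.0), 0.0, 0.0])
    if y.sum() == 0:
        return np.asarray(fallback, dtype=float).copy(), True
    X = np.column_stack([np.ones_like(y), v])
    offset = np.full_like(y, np.log(delta))
    try:
        model = sm.GLM(y, X, family=sm.families.Poisson(), offset=offset)
        res = model.fit(maxiter=100, tol=1e-10)
        phi = np.asarray(res.params, dtype=float)
        if not np.all(np.isfinite(phi)):
            raise ValueError("non-finite GLM estimate")
    except Exception:
        return np.asarray(fallback, dtype=float).copy(), True
    return phi, False


def smoothbatch_update(
    previous: np.ndarray,
    batch_estimate: np.ndarray,
    batch_seconds: float = SMOOTHBATCH_BATCH_SECONDS,
    half_life_seconds: float = SMOOTHBATCH_HALF_LIFE_SECONDS,
) -> np.ndarray:
    """Exponential blend ``rho*previous + (1-rho)*batch`` with
    ``rho = 0.5**(batch/half_life)``."""
    if batch_seconds <= 0 or half_life_seconds <= 0:
        raise ValueError("durations must be positive")
    rho = 0.5 ** (batch_seconds / half_life_seconds)
    return rho * np.asarray(previous, dtype=float) + (1.0 - rho) * np.asarray(
        batch_estimate, dtype=float
    )


@dataclass
class SmoothBatchAdapter:
    """Accumulates spike events and intentions, refits at batch boundaries.

    Drop-in alternative to the spike-event filter for the adaptation slot
    of the closed-loop architecture: ``step`` buffers one bin and triggers
    a GLM refit + exponential blend whenever a full batch has elapsed.
    """

    phis: np.ndarray  # C x 3 current estimates
    delta: float
    batch_seconds: float = SMOOTHBATCH_BATCH_SECONDS
    half_life_seconds: float = SMOOTHBATCH_HALF_LIFE_SECONDS
    _buf_v: list = field(default_factory=list)
    _buf_n: list = field(default_factory=list)

    def __post_init__(self):
        self.phis = np.atleast_2d(np.asarray(self.phis, dtype=float)).copy()

    @property
    def n_units(self) -> int:
        return self.phis.shape[0]

    @property
    def means(self) -> np.ndarray:  # mirror of EnsemblePosterior interface
        return self.phis

    def step(self, intended_velocity, spikes, delta: float) -> None:
        self._buf_v.append(np.asarray(intended_velocity, dtype=float).copy())
        self._buf_n.append(np.asarray(spikes, dtype=np.uint8).copy())
        if len(self._buf_v) * self.delta >= self.batch_seconds:
            self._refit()

    def _refit(self) -> None:
        v = np.stack(self._buf_v)
        n = np.stack(self._buf_n)  # T x C
        for c in range(self.n_units):
            phi_ml, used_fallback = glm_fit_batch(
                n[:, c], v, self.delta, previous=self.phis[c]
            )
            if not used_fallback:
                self.phis[c] = smoothbatch_update(
                    self.phis[c], phi_ml, self.batch_seconds, self.half_life_seconds
                )
        self._buf_v.clear()
        self._buf_n.clear()
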