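"""Kinematic point-process filter (velocity PPF) with an optional assisted prior.

The decoder tracks a Gaussian posterior over the displayed cursor state
``x = [pos, vel]``.  The prior model is either the plain cursor dynamics
(random walk in velocity, ``L_a = 0``) or, during assisted training, the
feedback-controlled model

    x_t = (A - B L_a) x_{t-1} + B L_a x* + w_t,

which pulls the prediction toward the instructed target.  The update uses
every unit's binary spike event through the log-linear encoding model:
only the velocity block carries tuning (``alpha~ = [0, 0, alpha]``), so
this is a *velocity* PPF — the update touches velocity only and position
stays the integral of decoded velocity.  Units with zero estimated tuning
never move the posterior.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .dynamics import CursorDynamics
from .ofc import FeedbackGain, TargetState
from .point_process import P_MAX

__all__ = [
    "KinematicPosterior",
    "predict_kinematics",
    "update_kinematics",
    "decode_step",
]

#: Initial posterior variance on each state component.
DEFAULT_INIT_VAR = 1e-4


@dataclass
class KinematicPosterior:
    """Gaussian posterior over the displayed cursor state."""

    mean: np.ndarray  # 4-vector
    covariance: np.ndarray  # 4x4 symmetric PSD

    def __post_init__(self):
        self.mean = np.asarray(self.mean, dtype=float)
        self.covariance = np.asarray(self.covariance, dtype=float)

    @classmethod
    def initial(cls, position=(0.0, 0.0), init_var: float = DEFAULT_INIT_VAR):
        mean = np.array([position[0], position[1], 0.0, 0.0])
        cov = np.diag([0.0, 0.0, init_var, init_var])  # position is deterministic
        return cls(mean=mean, covariance=cov)

    @property
    def position(self) -> np.ndarray:
        return self.mean[:2]

    @property
    def velocity(self) -> np.ndarray:
        return self.mean[2:]


def predict_kinematics(
    post: KinematicPosterior,
    dyn: CursorDynamics,
    assist_gain: FeedbackGain | None = None,
    target: TargetState | None = None,
) -> KinematicPosterior:
    """One-step prediction under the (possibly assisted) prior model."""
    A = dyn.transition
    if assist_gain is not None:
        if target is None:
            raise ValueError("assisted prediction requires a target")
        BL = dyn.control @ assist_gain.gain
        Acl = A - BL
        mean = Acl @ post.mean + BL @ target.state
    else:
        Acl = A
        mean = A @ post.mean
    cov = Acl @ post.covariance @ Acl.T + dyn.noise_cov
    return KinematicPosterior(mean=mean, covariance=cov)


def update_kinematics(
    pred: KinematicPosterior,
    spike_vector: np.ndarray,
    param_means: np.ndarray,
    delta: float,
) -> KinematicPosterior:
    """Velocity-PPF update from one bin of binary spike events.

    ``param_means`` is the C x 3 matrix of current parameter estimates
    ``phi_c = [beta, alpha]``.  Rates are evaluated at the one-step
    predicted velocity.  The information update
    ``cov_v^-1 += sum_c alpha alpha' lambda*Delta`` and the innovation
    ``sum_c alpha (N_c - lambda*Delta)`` act on the 2x2 velocity block;
    position is kept at the predicted value (integral of decoded
    velocity).
    """
    phi = np.atleast_2d(np.asarray(param_means, dtype=float))
    spikes = np.asarray(spike_vector, dtype=float).ravel()
    if phi.shape[0] == 0 or spikes.size == 0:
        return KinematicPosterior(mean=pred.mean.copy(), covariance=pred.covariance.copy())
    if spikes.size != phi.shape[0]:
        raise ValueError("spike vector and parameter matrix disagree on unit count")
    alpha = phi[:, 1:]
    v_pred = pred.mean[2:]
    exponent = phi[:, 0] + alpha @ v_pred
    lam_d = np.minimum(np.exp(np.minimum(exponent, np.log(P_MAX / delta))) * delta, P_MAX)
    S = pred.covariance[2:, 2:]
    info_add = (alpha * lam_d[:, None]).T @ alpha  # 2x2
    S_new = np.linalg.inv(np.linalg.inv(S) + info_add)
    S_new = 0.5 * (S_new + S_new.T)
    innov = alpha.T @ (spikes - lam_d)
    mean = pred.mean.copy()
    mean[2:] = v_pred + S_new @ innov
    # velocity PPF: position is deterministic (the integral of decoded
    # velocity), so its covariance rows/columns are zeroed
    cov = np.zeros((4, 4))
    cov[2:, 2:] = S_new
    return KinematicPosterior(mean=mean, covariance=cov)


def decode_step(
    state: KinematicPosterior,
    dyn: CursorDynamics,
    assist_gain: FeedbackGain | None,
    target: TargetState | None,
    spike_vector: np.ndarray,
    param_means: np.ndarray,
    delta: float,
    clamp: bool = True,
) -> KinematicPosterior:
    """Predict, update, then clamp the decoded position to the workspace."""
    pred = predict_kinematics(state, dyn, assist_gain, target)
    post = update_kinematics(pred, spike_vector, param_means, delta)
    if clamp:
        post.mean = dyn.workspace.clamp(post.mean)
    return post
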