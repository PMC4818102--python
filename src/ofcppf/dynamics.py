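"""Linear state-space model of 2D cursor kinematics.

The cursor state is ``x = [pos_x, pos_y, vel_x, vel_y]`` (cm, cm/s) and
evolves at a fixed bin width ``delta`` (s) as

    x_t = A x_{t-1} + B u_{t-1} + w_{t-1},

where ``u`` is a 2D control command (cm/s per bin, scaled by ``delta``
through B), ``A`` integrates position from velocity and applies a scalar
velocity persistence ``a``, and ``w`` is white Gaussian noise with
covariance ``W = diag(0, 0, w, w)`` acting on velocity only.  Any state
with zero velocity is a fixed point of A, so target states are preserved
by the prior model.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

__all__ = [
    "Workspace",
    "CursorDynamics",
    "make_cursor_dynamics",
    "step_dynamics",
    "fit_dynamics_ml",
]

#: Default bin width in seconds (spike-event resolution).
DEFAULT_DELTA = 0.005


@dataclass(frozen=True)
class Workspace:
    """Rectangular workspace, centered on the origin by default.

    Positions are clamped to its bounds; the velocity component normal to
    a hit boundary is zeroed so the cursor slides along edges instead of
    sticking into them.
    """

    x_min: float = -12.0
    x_max: float = 12.0
    y_min: float = -12.0
    y_max: float = 12.0

    def clamp(self, state: np.ndarray) -> np.ndarray:
        """Clamp a 4-vector state in place-free fashion; returns a copy."""
        out = np.array(state, dtype=float)
        for i, (lo, hi) in enumerate(((self.x_min, self.x_max), (self.y_min, self.y_max))):
            if out[i] < lo:
                out[i] = lo
                out[2 + i] = 0.0
            elif out[i] > hi:
                out[i] = hi
                out[2 + i] = 0.0
        return out


@dataclass(frozen=True)
class CursorDynamics:
    """The (A, B, W) cursor model with its generating scalars."""

    transition: np.ndarray  # A, 4x4
    control: np.ndarray  # B, 4x2
    noise_cov: np.ndarray  # W, 4x4 (velocity block only)
    bin_width: float  # delta, s
    velocity_persistence: float  # a
    velocity_noise: float  # w, (cm/s)^2 per bin
    workspace: Workspace = field(default_factory=Workspace)

    @property
    def noise_std(self) -> float:
        return float(np.sqrt(self.velocity_noise))


def make_cursor_dynamics(
    a: float,
    w: float,
    delta: float = DEFAULT_DELTA,
    workspace: Workspace | None = None,
) -> CursorDynamics:
    """Build the cursor model from persistence ``a``, noise ``w``, bin ``delta``.

    A couples position to velocity through ``delta`` and scales velocity by
    ``a``; B injects the control into velocity scaled by ``delta``; W is
    ``diag(0, 0, w, w)``.
    """
    if delta <= 0:
        raise ValueError(f"bin width must be positive, got {delta}")
    if w < 0:
        raise ValueError(f"velocity noise must be non-negative, got {w}")
    A = np.array(
        [
            [1.0, 0.0, delta, 0.0],
            [0.0, 1.0, 0.0, delta],
            [0.0, 0.0, a, 0.0],
            [0.0, 0.0, 0.0, a],
        ]
    )
    B = np.array(
        [
            [0.0, 0.0],
            [0.0, 0.0],
            [delta, 0.0],
            [0.0, delta],
        ]
    )
    W = np.diag([0.0, 0.0, w, w])
    return CursorDynamics(
        transition=A,
        control=B,
        noise_cov=W,
        bin_width=delta,
        velocity_persistence=float(a),
        velocity_noise=float(w),
        workspace=workspace or Workspace(),
    )


def step_dynamics(
    dyn: CursorDynamics,
    state: np.ndarray,
    control: np.ndarray,
    noise_draw: np.ndarray | None = None,
    clamp: bool = True,
) -> np.ndarray:
    """One forward step ``A x + B u + w`` with optional velocity noise draw.

    ``noise_draw`` is a 2-vector added to the velocity components (already
    scaled; pass ``rng.normal(0, dyn.noise_std, 2)`` for model-consistent
    noise).  ``None`` means a noiseless step.
    """
    control = np.asarray(control, dtype=float)
    if not np.all(np.isfinite(control)):
        raise ValueError("control must be finite")
    out = dyn.transition @ np.asarray(state, dtype=float) + dyn.control @ control
    if noise_draw is not None:
        out[2:] += np.asarray(noise_draw, dtype=float)
    if clamp:
        out = dyn.workspace.clamp(out)
    return out


def fit_dynamics_ml(velocities: np.ndarray) -> tuple[float, float]:
    """Maximum-likelihood fit of (a, w) from uniformly sampled velocities.

    Per-dimension AR(1) regression through the origin,
    ``v_t = a v_{t-1} + eps``, with the sufficient statistics pooled across
    the two dimensions; ``w`` is the pooled residual variance per dimension.

    Parameters
    ----------
    velocities : array, shape (T, 2)
        Velocity samples at the model's bin width.  A (T, 4) array of full
        kinematic states is also accepted (velocity block is used).
    """
    v = np.asarray(velocities, dtype=float)
    if v.ndim != 2 or v.shape[0] < 2:
        raise ValueError("need at least two velocity samples of dimension 2")
    if v.shape[1] == 4:
        v = v[:, 2:]
    prev, curr = v[:-1], v[1:]
    denom = float(np.sum(prev * prev))
    if denom == 0.0:
        raise ValueError("degenerate fit: all-zero velocities")
    a = float(np.sum(prev * curr) / denom)
    resid = curr - a * prev
    # pooled across dimensions: total squared residual over 2*(T-1) scalars
    w = float(np.sum(resid * resid) / resid.size)
    return a, w
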