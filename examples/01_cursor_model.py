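"""Fit the cursor state-space model to naturalistic reach kinematics.

Builds the instant-OFC reach policy, generates noisy point-to-point cursor
movements with it, and recovers the velocity persistence ``a`` and
velocity noise ``w`` of the linear model by maximum likelihood — the
simulated analogue of fitting the prior model to a subject's own cursor
kinematics.
"""

import numpy as np

from ofcppf import (
    TargetState,
    fit_dynamics_ml,
    infer_intention,
    intention_weights,
    make_cursor_dynamics,
    solve_steady_state_gain,
)

rng = np.random.default_rng(0)
delta = 0.005
instant = make_cursor_dynamics(a=0.0, w=0.0, delta=delta)
gain = solve_steady_state_gain(instant, intention_weights())

# naturalistic movements: a smoothed OFC reach trace plus motor noise
x = np.zeros(4)
velocities = []
for reach in range(30):
    target = TargetState(rng.uniform(-6, 6, 2))
    for _ in range(int(1.5 / delta)):
        intended = infer_intention(gain, instant, x, target)
        v = 0.9 * x[2:] + 0.1 * intended[2:] + rng.normal(0, 0.15, 2)
        x = np.array([x[0] + delta * x[2], x[1] + delta * x[3], v[0], v[1]])
        velocities.append(v)

a_hat, w_hat = fit_dynamics_ml(np.asarray(velocities))
print(f"fitted velocity persistence a = {a_hat:.3f} (per {delta * 1e3:.0f} ms bin)")
print(f"fitted velocity noise       w = {w_hat:.3f} (cm/s)^2 per bin")
print("these two scalars fully determine the decoder's kinematic prior model")
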