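"""Infer a subject's intended velocity from feedback and the task goal.

Compares the infinite-horizon OFC intention model (which infers both the
direction and the speed of the intended movement) against the CursorGoal
baseline (which re-aims the decoded velocity at the target but keeps its
speed) at a few cursor states.
"""

import numpy as np

from ofcppf import (
    TargetState,
    cursorgoal_intention,
    infer_intention,
    intention_weights,
    make_cursor_dynamics,
    solve_steady_state_gain,
)

instant = make_cursor_dynamics(a=0.0, w=0.0, delta=0.005)
gain = solve_steady_state_gain(instant, intention_weights())
target = TargetState(np.array([6.5, 0.0]))

states = {
    "far from target, drifting sideways": np.array([0.0, 0.0, 0.0, 4.0]),
    "halfway, moving toward target": np.array([3.0, 0.5, 5.0, 0.0]),
    "at the target": np.array([6.5, 0.0, 0.0, 0.0]),
}
for label, x in states.items():
    v_ofc = infer_intention(gain, instant, x, target)[2:]
    v_cg = cursorgoal_intention(x, target, target_radius=1.2)
    print(f"{label}:")
    print(f"  OFC intention        = ({v_ofc[0]:6.2f}, {v_ofc[1]:6.2f}) cm/s")
    print(f"  CursorGoal intention = ({v_cg[0]:6.2f}, {v_cg[1]:6.2f}) cm/s")
print(
    "\nOFC scales intended speed with the remaining error (zero at the target);\n"
    "CursorGoal keeps the decoded speed and only re-aims it."
)
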