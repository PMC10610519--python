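"""Predicted cue-evoked dopamine transients on avoidance trials.

Builds the poor-avoider solution, then prints the peak of the cue-aligned
DA trace for reward trials and for shock trials conditioned on success and
failure.  On successful shock trials the posterior favours control, so the
trace shows a brief dip (the unreframed negative error) followed by a large
positive transient (the reframed error, applied after a 250 ms delay) —
the "damned if you don't" signal that energizes avoidance.
"""

from controlda import (
    ControlConfig,
    DAConfig,
    FreeParams,
    TaskConfig,
    condition_average_trace,
    control_posterior,
    solve_self_consistent,
)

cfg = TaskConfig.mixed_valence()
params = FreeParams.poor_avoider()
ctrl = ControlConfig.for_task(cfg, params.kappa)
sol = solve_self_consistent(cfg, params, ctrl)
dacfg = DAConfig.for_task(cfg.task)  # 5 s cue window, dt = 10 ms

for label, outcome in (("rew", "success"), ("shk", "success"),
                       ("shk", "fail")):
    trace = condition_average_trace(label, outcome, sol, ctrl, dacfg)
    peak_t = trace.t[trace.values.argmax()]
    print(f"{label}|{outcome}: peak dDA = {trace.values.max():+.3f} a.u. "
          f"at {peak_t:.2f} s, minimum = {trace.values.min():+.3f}")

for outcome in ("success", "fail"):
    p = control_posterior("shk", outcome, sol, ctrl)
    print(f"P(control | shock {outcome}) = {p:.3f}")
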