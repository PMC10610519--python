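"""Solve the mixed-valence avoidance task for both avoider groups.

Prints the average reward rate rho, the differential cue values, the cue TD
errors with and without reframing on shock trials, and the predicted
behaviour summary.  For poor avoiders the reward rate is negative, so the
neutral cue is relatively attractive, and the shock-cue TD error flips from
negative (no control) to positive (control): the prospect of shock is
recast as a prospect of safety.
"""

from controlda import (
    ControlConfig,
    FreeParams,
    TaskConfig,
    predict_behaviour,
    solve_self_consistent,
)

cfg = TaskConfig.mixed_valence()
for group, params in (("good", FreeParams.good_avoider()),
                      ("poor", FreeParams.poor_avoider())):
    ctrl = ControlConfig.for_task(cfg, params.kappa)
    sol = solve_self_consistent(cfg, params, ctrl)
    print(f"--- {group} avoiders (kappa = {params.kappa:.2f}) ---")
    print(f"rho = {sol.rho:+.4f} utility/s")
    print("cue values:",
          {lab: round(v, 3) for lab, v in sol.v_cue.items()})
    print(f"shock TD error: no control {sol.delta('shk', 0):+.3f}, "
          f"control {sol.delta('shk', 1):+.3f}")
    pred = predict_behaviour(sol, ctrl, params, cfg)
    print(pred.table[["success_rate", "rt_correct"]].round(3))
    print()
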