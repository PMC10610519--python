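"""Synthetic Go/No-Go sessions and the voltammetry-style trace analysis.

Simulates nine sessions from the fitted Go/No-Go model, attaches noisy
cue-aligned DA traces, preprocesses them (0.5 s moving-window smoothing,
0.5 s pre-cue baselining), integrates the first second after cue onset,
and runs the paired one-tailed t-test asking whether failed No-Go
large-reward trials carry more cue DA than successful ones — the model's
signature of control failure.
"""

from controlda import (
    ControlConfig,
    DAConfig,
    FreeParams,
    NoiseModel,
    TaskConfig,
    ngl_success_fail_test,
    sample_sessions,
    solve_self_consistent,
    summarize_sessions,
    synth_da_traces,
)

cfg = TaskConfig.go_nogo()
params = FreeParams.go_nogo_fit()
ctrl = ControlConfig.for_task(cfg, params.kappa)
sol = solve_self_consistent(cfg, params, ctrl)

sessions = sample_sessions(cfg, params, ctrl, n_trials=150, n_sessions=9,
                           seed=42, sol=sol)
summary = summarize_sessions(sessions, cfg)
print(summary.table[["success_rate", "rt_correct", "rt_error"]].round(3))

dacfg = DAConfig.for_task(cfg.task, pre_window=1.0)  # 3 s window + pre-cue
sessions = synth_da_traces(sessions, sol, dacfg, NoiseModel(sd=0.3), seed=42)
result = ngl_success_fail_test(sessions)
print(f"\npaired one-tailed t-test (failed > successful NGL): "
      f"t({result.df}) = {result.t:.2f}, p = {result.p:.3f}")
print("session-wise integrated DA (first 1 s):")
print(result.session_means.round(3).to_string(index=False))
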