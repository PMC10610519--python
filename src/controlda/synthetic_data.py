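"""Forward-sampled behaviour and noisy dopamine traces from known parameters.

Trials are drawn from the model's own generative policy — trial type from
the mix, control from kappa, action and latency from the solved
(Pavlovian-distorted) policy, success from the deadline or tone-offset
jitter — so every downstream stage (summaries, fitting, trace analysis) can
be exercised without any recorded data.  Latencies are drawn from the same
quadrature-discretized densities the analytic marginalization integrates,
making Monte-Carlo and analytic summaries directly comparable.

The trace analysis chain mirrors standard voltammetry preprocessing:
moving-window smoothing, pre-cue baselining, short-window integration, and
a paired one-tailed t-test across sessions comparing failed and successful
No-Go large-reward trials.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
import pandas as pd
from scipy import stats

from .control_policy import BehaviourSummary, ControlConfig, FreeParams
from .dopamine import DAConfig, DATrace, cue_da_trace
from .task_mdp import GO_LABELS, TASK_MIXED, TaskConfig, ValueSolution

__all__ = [
    "NoiseModel",
    "SyntheticSession",
    "sample_sessions",
    "synth_da_traces",
    "summarize_sessions",
    "fscv_preprocess",
    "ngl_success_fail_test",
    "write_sessions",
    "read_sessions",
]

TRIAL_COLUMNS = ("trial_type", "control", "action", "latency", "success",
                 "rt")


@dataclass(frozen=True)
class NoiseModel:
    """Additive i.i.d. Gaussian noise per trace bin (arbitrary units).

    ``sd=None`` calibrates the noise at generation time so that the
    single-trial signal-to-noise ratio at the kernel peak is about one
    (sd = mean absolute peak of the noiseless traces across conditions).
    ``drift_amplitude`` optionally adds a slow random-phase sinusoidal
    drift per trial.
    """

    sd: float | None = None
    drift_amplitude: float = 0.0
    drift_period: float = 10.0

    def __post_init__(self) -> None:
        if self.sd is not None and self.sd < 0:
            raise ValueError("noise sd must be non-negative")
        if self.drift_amplitude < 0:
            raise ValueError("drift amplitude must be non-negative")


@dataclass
class SyntheticSession:
    """One simulated session: trial records plus optional per-trial traces."""

    session_id: int
    trials: pd.DataFrame
    seed: int
    traces: np.ndarray | None = None
    trace_t: np.ndarray | None = None
    meta: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        missing = [c for c in TRIAL_COLUMNS if c not in self.trials.columns]
        if missing:
            raise ValueError(f"missing trial columns: {missing}")


def _draw_latency_index(rng: np.random.Generator, grid, density: np.ndarray,
                        size: int) -> np.ndarray:
    p = grid.weights * density
    p = p / p.sum()
    return rng.choice(len(p), size=size, p=p)


def sample_sessions(cfg: TaskConfig, params: FreeParams, ctrl: ControlConfig,
                    n_trials: int, n_sessions: int = 9, seed: int = 0,
                    sol: ValueSolution | None = None,
                    ) -> list[SyntheticSession]:
    """Forward-sample sessions of ``n_trials`` trials each from the model.

    A pre-solved ``ValueSolution`` for the same configuration can be passed
    to avoid re-solving.  Reproducible: the same seed yields identical
    sessions.
    """
    if sol is None:
        from .task_mdp import solve_self_consistent

        sol = solve_self_consistent(cfg, params, ctrl)
    rng = np.random.default_rng(seed)
    labels = list(cfg.labels)
    mix = np.array([cfg.trial_mix[lab] for lab in labels])
    tau = sol.grid.nodes
    sessions = []
    for sid in range(n_sessions):
        rows = []
        lab_idx = rng.choice(len(labels), size=n_trials, p=mix)
        for i in range(n_trials):
            label = labels[lab_idx[i]]
            kappa = ctrl.kappa.get(label, 0.0)
            C = int(rng.random() < kappa)
            if cfg.task == TASK_MIXED:
                press = rng.random() < sol.press_prob[(label, C)]
                if press:
                    j = _draw_latency_index(
                        rng, sol.grid, sol.latency_density[(label, C)], 1)[0]
                    latency = float(tau[j])
                    success = latency <= cfg.tau_D
                    rt = latency
                    action = "press"
                else:
                    latency = np.nan
                    success = False
                    rt = np.nan
                    action = "other"
            else:
                j = _draw_latency_index(
                    rng, sol.grid, sol.latency_density[(label, C)], 1)[0]
                latency = float(tau[j])
                rt = latency
                if label in GO_LABELS:
                    if latency > cfg.tau_D:
                        action = "leave"
                        success = False
                    else:
                        p_press = float(sol.go_p_press_t[label][j])
                        if rng.random() < p_press:
                            k = _draw_latency_index(
                                rng, sol.grid, sol.go_p_tau2[label][j], 1)[0]
                            success = bool(tau[k] <= cfg.tau_D - latency)
                            action = "press"
                        else:
                            action = "other"
                            success = False
                else:
                    offset = rng.uniform(*cfg.jitter)
                    success = bool(offset <= latency)
                    action = "leave"
            rows.append((label, C, action, latency, success, rt))
        trials = pd.DataFrame(rows, columns=TRIAL_COLUMNS)
        sessions.append(SyntheticSession(session_id=sid, trials=trials,
                                         seed=seed,
                                         meta={"task": cfg.task}))
    return sessions


def synth_da_traces(sessions: Sequence[SyntheticSession],
                    sol: ValueSolution, dacfg: DAConfig,
                    noise: NoiseModel = NoiseModel(), seed: int = 0,
                    ) -> list[SyntheticSession]:
    """Attach noisy cue-aligned DA traces to each trial of each session.

    With zero noise the traces equal the model's predicted traces exactly.
    """
    rng = np.random.default_rng(seed)
    t = dacfg.time_grid()
    clean: dict[tuple[str, int], np.ndarray] = {}
    for session in sessions:
        for label, C in set(zip(session.trials["trial_type"],
                                session.trials["control"])):
            if (label, C) not in clean:
                clean[(label, C)] = cue_da_trace(label, int(C), sol,
                                                 dacfg).values
    sd = noise.sd
    if sd is None:
        peaks = [np.abs(v).max() for v in clean.values()]
        nonzero = [p for p in peaks if p > 0]
        sd = float(np.mean(nonzero)) if nonzero else 1.0
    out = []
    for session in sessions:
        n = len(session.trials)
        traces = np.empty((n, t.size))
        for i, (label, C) in enumerate(zip(session.trials["trial_type"],
                                           session.trials["control"])):
            base = clean[(label, int(C))].copy()
            if noise.drift_amplitude > 0:
                phase = rng.uniform(0, 2 * np.pi)
                base = base + noise.drift_amplitude * np.sin(
                    2 * np.pi * t / noise.drift_period + phase)
            traces[i] = base + rng.normal(0.0, sd, size=t.size)
        out.append(SyntheticSession(
            session_id=session.session_id, trials=session.trials.copy(),
            seed=session.seed, traces=traces, trace_t=t.copy(),
            meta={**session.meta, "noise_sd": sd}))
    return out


def summarize_sessions(sessions: Sequence[SyntheticSession], cfg: TaskConfig,
                       error_rt_mode: str = "truncated",
                       ) -> BehaviourSummary:
    """Pool trials across sessions into a behaviour summary with RT SEs.

    Mixed-valence error RTs include only trials on which press was chosen;
    in ``"truncated"`` mode they are reported at the deadline (failure is
    only observed then), in ``"latent"`` mode at the sampled latency.
    """
    trials = pd.concat([s.trials for s in sessions], ignore_index=True)
    success: dict[str, float] = {}
    rtc: dict[str, float] = {}
    rte: dict[str, float] = {}
    se_c: dict[str, float] = {}
    se_e: dict[str, float] = {}

    def _mean_se(values: np.ndarray) -> tuple[float, float]:
        if values.size == 0:
            return np.nan, np.nan
        mean = float(np.mean(values))
        se = (float(np.std(values, ddof=1) / np.sqrt(values.size))
              if values.size > 1 else np.nan)
        return mean, se

    for label in cfg.labels:
        sub = trials[trials["trial_type"] == label]
        success[label] = float(sub["success"].mean()) if len(sub) else np.nan
        correct = sub[sub["success"]]
        rtc[label], se_c[label] = _mean_se(correct["rt"].to_numpy(float))
        if cfg.task == TASK_MIXED:
            errors = sub[(~sub["success"]) & (sub["action"] == "press")]
            rts = errors["rt"].to_numpy(float)
            if error_rt_mode == "truncated":
                rts = np.full_like(rts, cfg.tau_D)
        else:
            errors = sub[~sub["success"]]
            rts = errors["rt"].to_numpy(float)
        rts = rts[np.isfinite(rts)]
        rte[label], se_e[label] = _mean_se(rts)
    return BehaviourSummary.from_dicts(success, rtc, rte, se_c, se_e)


def fscv_preprocess(trace: DATrace, pre_window: float = 0.5,
                    smooth_window: float = 0.5) -> DATrace:
    """Smooth with a centered moving window, then subtract the pre-cue mean.

    The moving average renormalizes at the edges (averaging the samples
    actually inside the window), so constants map to constants and the
    operation is linear.  Requires at least ``pre_window`` seconds of signal
    before cue onset.
    """
    t = trace.t
    values = trace.values
    dt = trace.dt
    n_win = max(1, int(round(smooth_window / dt)))
    kernel = np.ones(n_win)
    smoothed = (np.convolve(values, kernel, mode="same")
                / np.convolve(np.ones_like(values), kernel, mode="same"))
    pre = (t >= -pre_window) & (t < 0)
    if t[0] > -pre_window + 1e-9 or not pre.any():
        raise ValueError(
            f"trace needs at least {pre_window} s of pre-cue samples")
    baseline = float(smoothed[pre].mean())
    return DATrace(t, smoothed - baseline, label=trace.label)


@dataclass(frozen=True)
class PairedTestResult:
    t: float
    df: int
    p: float
    session_means: pd.DataFrame


def ngl_success_fail_test(sessions: Sequence[SyntheticSession],
                          integrate_window: float = 1.0,
                          preprocess: bool = True,
                          pre_window: float = 0.5,
                          smooth_window: float = 0.5) -> PairedTestResult:
    """Paired one-tailed t-test of cue-evoked DA: failed vs successful NGL.

    For each session, the DA signal of every No-Go large-reward trial is
    (optionally) smoothed and baselined, integrated over the first
    ``integrate_window`` seconds after cue onset, and averaged separately
    over successful and failed trials.  The session-wise pairs then enter a
    paired t-test with alternative "failed > successful"
    (df = sessions - 1).  Sessions missing either condition are excluded
    with a warning; fewer than two usable sessions is an error.
    """
    rows = []
    for session in sessions:
        if session.traces is None or session.trace_t is None:
            raise ValueError("sessions must carry DA traces")
        t = session.trace_t
        mask = session.trials["trial_type"] == "ngl"
        if not mask.any():
            warnings.warn(f"session {session.session_id} has no NGL trials")
            continue
        sub = session.trials[mask]
        idx = np.flatnonzero(mask.to_numpy())
        integ = []
        window = (t >= 0) & (t <= integrate_window)
        for i in idx:
            trace = DATrace(t, session.traces[i])
            if preprocess:
                trace = fscv_preprocess(trace, pre_window, smooth_window)
            integ.append(np.trapezoid(trace.values[window], t[window]))
        integ = np.asarray(integ)
        succ = sub["success"].to_numpy(bool)
        if succ.all() or not succ.any():
            warnings.warn(
                f"session {session.session_id} lacks one NGL outcome; "
                "excluded from the paired test")
            continue
        rows.append({"session_id": session.session_id,
                     "mean_success": float(integ[succ].mean()),
                     "mean_fail": float(integ[~succ].mean())})
    if len(rows) < 2:
        raise ValueError("need at least two sessions with both NGL outcomes")
    frame = pd.DataFrame(rows)
    df = len(frame) - 1
    diffs = (frame["mean_fail"] - frame["mean_success"]).to_numpy()
    if np.all(diffs == diffs[0]) and diffs[0] == 0.0:
        # degenerate pairing (identical conditions): no evidence either way
        return PairedTestResult(t=0.0, df=df, p=0.5, session_means=frame)
    res = stats.ttest_rel(frame["mean_fail"], frame["mean_success"],
                          alternative="greater")
    return PairedTestResult(t=float(res.statistic), df=df,
                            p=float(res.pvalue), session_means=frame)


# ---------------------------------------------------------------------------
# CSV round trip
# ---------------------------------------------------------------------------

def write_sessions(sessions: Sequence[SyntheticSession], trials_path,
                   traces_path=None) -> None:
    """Write sessions as a trials CSV and (optionally) a long traces CSV."""
    frames = []
    for session in sessions:
        frame = session.trials.copy()
        frame.insert(0, "session_id", session.session_id)
        frame.insert(1, "trial", np.arange(len(frame)))
        frames.append(frame)
    pd.concat(frames, ignore_index=True).to_csv(trials_path, index=False)
    if traces_path is not None:
        chunks = []
        for session in sessions:
            if session.traces is None:
                continue
            n_trial, n_t = session.traces.shape
            chunks.append(pd.DataFrame({
                "session_id": np.repeat(session.session_id, n_trial * n_t),
                "trial": np.repeat(np.arange(n_trial), n_t),
                "time_s": np.tile(session.trace_t, n_trial),
                "dDA": session.traces.ravel(),
            }))
        if chunks:
            pd.concat(chunks, ignore_index=True).to_csv(traces_path,
                                                        index=False)


def read_sessions(trials_path, traces_path=None) -> list[SyntheticSession]:
    """Inverse of :func:`write_sessions`."""
    trials = pd.read_csv(trials_path)
    traces = pd.read_csv(traces_path) if traces_path is not None else None
    sessions = []
    for sid, group in trials.groupby("session_id"):
        group = group.sort_values("trial")
        tr = group[list(TRIAL_COLUMNS)].reset_index(drop=True)
        arr = t = None
        if traces is not None:
            sub = traces[traces["session_id"] == sid]
            if len(sub):
                t = np.sort(sub["time_s"].unique())
                arr = (sub.pivot(index="trial", columns="time_s",
                                 values="dDA").sort_index().to_numpy())
        sessions.append(SyntheticSession(session_id=int(sid), trials=tr,
                                         seed=-1, traces=arr, trace_t=t))
    return sessions
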