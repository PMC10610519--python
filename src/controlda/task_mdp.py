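"""Recurrent semi-Markov task models and the average-reward value solver.

Two tasks are modelled with the same skeleton.  A trial begins when a cue
reveals the trial type; an internal control decision may reframe the cue TD
error; an external choice (press-vs-other with a press latency, or a
nose-poke leave time plus a post-exit sub-choice) determines success or
failure; the inter-trial interval (plus a timeout penalty for failure in the
Go/No-Go task) then leads to the next trial.

Because the tasks recur, values are differential values in the average-reward
sense: the gain ``rho`` (utility per second) is the opportunity cost of time,
and the self-consistent solution couples ``rho``, the state values ``V``, the
cue TD errors ``delta``, and the (Pavlovian-distorted, control-mixed)
behavioural policy that generates the occupancies under which ``rho`` and
``V`` are correct.

The solver alternates (i) exact per-trial-type cue-value fixed points at
fixed ``rho``, with the pre-trial state as reference (``V(s_pre) = 0``), and
(ii) damped renewal-ratio updates of ``rho`` (expected utility per trial
cycle over expected cycle duration, under the current policy and trial mix).
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from typing import Mapping

import numpy as np
import pandas as pd
from scipy.optimize import brentq
from scipy.special import expit

from .control_policy import (
    ControlConfig,
    FreeParams,
    control_states,
    latency_density_from_q,
    press_logit,
)

__all__ = [
    "TASK_MIXED",
    "TASK_GONOGO",
    "TrialType",
    "TaskConfig",
    "LatencyGrid",
    "ValueSolution",
    "success_prob_nogo",
    "q_press_mv",
    "q_other_mv",
    "terminal_values",
    "v_out",
    "q_leave_gng",
    "solve_self_consistent",
]

TASK_MIXED = "mixed_valence"
TASK_GONOGO = "go_nogo"

LABELS: dict[str, tuple[str, ...]] = {
    TASK_MIXED: ("rew", "neu", "shk"),
    TASK_GONOGO: ("gs", "gl", "ngs", "ngl"),
}
GO_LABELS = ("gs", "gl")
NOGO_LABELS = ("ngs", "ngl")


@dataclass(frozen=True)
class TrialType:
    """A trial type within one of the two tasks."""

    task: str
    label: str

    def __post_init__(self) -> None:
        if self.task not in LABELS:
            raise ValueError(f"unknown task {self.task!r}")
        if self.label not in LABELS[self.task]:
            raise ValueError(
                f"label {self.label!r} invalid for task {self.task!r}")


@dataclass(frozen=True)
class TaskConfig:
    """Fixed structure, utilities and timings of one task.

    Parameters
    ----------
    task:
        ``"mixed_valence"`` or ``"go_nogo"``.
    trial_mix:
        Probability of each trial-type label; must sum to 1.
    utilities:
        Outcome utilities: ``{"rew", "neu", "shk"}`` for the mixed-valence
        task or ``{"S", "L"}`` (small / large reward) for Go/No-Go.
    r_O:
        Utility rate (per second) of the alternative activity *other*.
    c_p, c_f, c_l:
        Non-positive cost coefficients: hyperbolic press-vigour cost
        (``c_p / tau``), linear fixation cost rate (``c_f * tau``) and
        hyperbolic leaving-vigour cost (``c_l / tau``).
    tau_min, tau_max:
        Bounds (s) of the chooseable latency.
    tau_D:
        Press deadline (s).
    cue_to_lever:
        Interval (s) between cue onset and lever insertion (mixed-valence;
        the external choice is made at the cue but implemented from lever
        insertion).
    iti:
        Inter-trial interval (s): 20 s mixed-valence, 5 s Go/No-Go.
    penalty:
        Additional timeout (s) after failure (Go/No-Go only, 5 s).
    jitter:
        Bounds (s) of the uniformly jittered No-Go tone offset.
    """

    task: str
    trial_mix: Mapping[str, float]
    utilities: Mapping[str, float]
    r_O: float = 0.0
    c_p: float = -0.1
    c_f: float = 0.0
    c_l: float = 0.0
    tau_min: float = 0.5
    tau_max: float = 20.0
    tau_D: float = 10.0
    cue_to_lever: float = 0.0
    iti: float = 20.0
    penalty: float = 0.0
    jitter: tuple[float, float] = (1.7, 1.9)

    def __post_init__(self) -> None:
        if self.task not in LABELS:
            raise ValueError(f"unknown task {self.task!r}")
        labs = LABELS[self.task]
        if set(self.trial_mix) != set(labs):
            raise ValueError(f"trial_mix must cover exactly {labs}")
        total = sum(self.trial_mix.values())
        if abs(total - 1.0) > 1e-9:
            raise ValueError("trial_mix must sum to 1")
        if any(p < 0 for p in self.trial_mix.values()):
            raise ValueError("trial_mix entries must be non-negative")
        if not self.tau_min < self.tau_max:
            raise ValueError("need tau_min < tau_max")
        if self.tau_min <= 0:
            raise ValueError("tau_min must be positive")
        for name in ("c_p", "c_f", "c_l"):
            if getattr(self, name) > 0:
                raise ValueError(f"{name} must be non-positive")
        if self.r_O < 0:
            raise ValueError("r_O must be non-negative")
        if not self.jitter[0] < self.jitter[1]:
            raise ValueError("jitter bounds must be increasing")

    @property
    def labels(self) -> tuple[str, ...]:
        return LABELS[self.task]

    @classmethod
    def mixed_valence(cls, **overrides) -> "TaskConfig":
        """Active-avoidance mixed-valence task with its standard parameters.

        Reward utility 4, shock disutility -10, press-vigour cost -0.1,
        latencies on [0.5, 20] s with a 10 s deadline, 5 s cue-to-lever
        interval, 20 s ITI.  Trial types are assumed equiprobable.
        """
        base = dict(
            task=TASK_MIXED,
            trial_mix={"rew": 1 / 3, "neu": 1 / 3, "shk": 1 / 3},
            utilities={"rew": 4.0, "neu": 0.0, "shk": -10.0},
            r_O=0.0, c_p=-0.1,
            tau_min=0.5, tau_max=20.0, tau_D=10.0,
            cue_to_lever=5.0, iti=20.0, penalty=0.0,
        )
        base.update(overrides)
        return cls(**base)

    @classmethod
    def go_nogo(cls, **overrides) -> "TaskConfig":
        """Go/No-Go omission task with its standard parameters.

        Small / large reward utilities 1 / 2, 5 s ITI plus 5 s failure
        timeout, tone offset jittered uniformly on [1.7, 1.9] s.  The press
        deadline is not part of the published task description; 10 s is
        assumed, mirroring the avoidance task.  Costs and ``r_O`` are free
        parameters of the fit and usually supplied via ``FreeParams``.
        """
        base = dict(
            task=TASK_GONOGO,
            trial_mix={lab: 0.25 for lab in LABELS[TASK_GONOGO]},
            utilities={"S": 1.0, "L": 2.0},
            r_O=0.0, c_p=0.0, c_f=0.0, c_l=0.0,
            tau_min=0.5, tau_max=20.0, tau_D=10.0,
            cue_to_lever=0.0, iti=5.0, penalty=5.0,
        )
        base.update(overrides)
        return cls(**base)

    def success_utility(self, label: str) -> float:
        """Utility delivered on a successful trial of this type."""
        if self.task == TASK_MIXED:
            return float(self.utilities["rew"]) if label == "rew" else 0.0
        return float(self.utilities["S"] if label in ("gs", "ngs")
                     else self.utilities["L"])

    def failure_utility(self, label: str) -> float:
        """Utility delivered on a failed trial of this type."""
        if self.task == TASK_MIXED:
            return float(self.utilities["shk"]) if label == "shk" else 0.0
        return 0.0


@dataclass(frozen=True)
class LatencyGrid:
    """Quadrature grid discretizing the latency interval [tau_min, tau_max]."""

    nodes: np.ndarray
    weights: np.ndarray

    def __post_init__(self) -> None:
        nodes = np.asarray(self.nodes, dtype=float)
        weights = np.asarray(self.weights, dtype=float)
        object.__setattr__(self, "nodes", nodes)
        object.__setattr__(self, "weights", weights)
        if nodes.ndim != 1 or nodes.size < 2:
            raise ValueError("grid needs at least two nodes")
        if not np.all(np.diff(nodes) > 0):
            raise ValueError("nodes must be strictly increasing")
        if np.any(weights <= 0):
            raise ValueError("weights must be positive")
        span = nodes[-1] - nodes[0]
        if abs(weights.sum() - span) > 1e-9 * max(span, 1.0):
            raise ValueError("weights must integrate a constant to the span")

    @classmethod
    def uniform(cls, tau_min: float, tau_max: float, n: int = 200,
                ) -> "LatencyGrid":
        """Uniform grid with trapezoidal quadrature weights."""
        nodes = np.linspace(tau_min, tau_max, n)
        h = nodes[1] - nodes[0]
        weights = np.full(n, h)
        weights[0] = weights[-1] = h / 2
        return cls(nodes, weights)

    @classmethod
    def for_task(cls, cfg: TaskConfig, n: int = 200) -> "LatencyGrid":
        return cls.uniform(cfg.tau_min, cfg.tau_max, n)

    def mean(self, density: np.ndarray) -> float:
        return float(np.sum(self.weights * density * self.nodes))


@dataclass
class ValueSolution:
    """Self-consistent average-reward solution for one parameterization.

    Keyed dictionaries use the trial-type label, or ``(label, C)`` for
    quantities that depend on the control state.  ``v_cue`` is the
    differential value of the cue state under the actual behavioural policy;
    the states ``s0`` and ``s1`` share it (their instrumental values are
    identical — only the TD error differs between them).
    """

    task: str
    rho: float
    v_cue: dict[str, float]
    v_succ: dict[str, float]
    v_fail: dict[str, float]
    grid: LatencyGrid
    params: FreeParams
    ctrl: ControlConfig
    latency_density: dict[tuple[str, int], np.ndarray]
    success_prob: dict[tuple[str, int], float]
    rt_correct: dict[tuple[str, int], float]
    rt_error: dict[tuple[str, int], float]
    rt_correct_weight: dict[tuple[str, int], float]
    rt_error_weight: dict[tuple[str, int], float]
    exp_utility: dict[tuple[str, int], float]
    exp_duration: dict[tuple[str, int], float]
    residual: float
    converged: bool
    n_iter: int
    error_rt_mode: str
    # mixed-valence specifics
    q_press: dict[str, np.ndarray] = field(default_factory=dict)
    q_other: dict[str, float] = field(default_factory=dict)
    press_prob: dict[tuple[str, int], float] = field(default_factory=dict)
    # go/no-go specifics
    q_leave: dict[str, np.ndarray] = field(default_factory=dict)
    go_p_press_t: dict[str, np.ndarray] = field(default_factory=dict)
    go_p_tau2: dict[str, np.ndarray] = field(default_factory=dict)
    succ_given_tau: dict[str, np.ndarray] = field(default_factory=dict)

    def delta(self, label: str, control: int) -> float:
        """Cue TD error for (trial type, control state)."""
        if control == 0:
            return self.v_cue[label]
        if label not in self.ctrl.kappa:
            raise ValueError(f"trial type {label!r} is not controllable")
        return self.v_cue[label] - float(self.ctrl.baselines[label])

    @property
    def delta0(self) -> dict[str, float]:
        return {lab: self.delta(lab, 0) for lab in self.v_cue}

    @property
    def delta1(self) -> dict[str, float]:
        return {lab: self.delta(lab, 1) for lab in self.ctrl.kappa}

    def to_json(self, path=None) -> str:
        payload = {
            "task": self.task,
            "rho": self.rho,
            "v_pre": 0.0,
            "v_cue": self.v_cue,
            "v_succ": self.v_succ,
            "v_fail": self.v_fail,
            "delta0": self.delta0,
            "delta1": self.delta1,
            "success_prob": {f"{l}|C={c}": v
                             for (l, c), v in self.success_prob.items()},
            "press_prob": {f"{l}|C={c}": v
                           for (l, c), v in self.press_prob.items()},
            "residual": self.residual,
            "converged": self.converged,
            "n_iter": self.n_iter,
        }
        text = json.dumps(payload, indent=2, sort_keys=True)
        if path is not None:
            with open(path, "w") as fh:
                fh.write(text)
        return text

    def densities_frame(self) -> pd.DataFrame:
        """Latency densities in long format (tau, density, type, C)."""
        frames = []
        for (label, c), dens in self.latency_density.items():
            frames.append(pd.DataFrame({
                "tau": self.grid.nodes,
                "density": dens,
                "trial_type": label,
                "control_flag": c,
            }))
        return pd.concat(frames, ignore_index=True)


# ---------------------------------------------------------------------------
# Elementary operations
# ---------------------------------------------------------------------------

def success_prob_nogo(tau, cfg: TaskConfig):
    """Probability that the jittered tone offset precedes leaving at ``tau``.

    The tone offset is uniform on the jitter bounds; success on a No-Go
    trial requires the tone to have turned off before the nose-poke exit.
    """
    tau_arr = np.asarray(tau, dtype=float)
    if np.any(tau_arr < 0):
        raise ValueError("latency must be non-negative")
    lo, hi = cfg.jitter
    p = np.clip((tau_arr - lo) / (hi - lo), 0.0, 1.0)
    return float(p) if np.isscalar(tau) else p


def terminal_values(label: str, rho: float, cfg: TaskConfig,
                    ) -> tuple[float, float]:
    """Differential values of the success and failure terminal states.

    Terminal states deliver the outcome utility and charge the opportunity
    cost of the ITI (plus the timeout penalty after Go/No-Go failures).
    """
    if cfg.task == TASK_MIXED:
        v_succ = cfg.success_utility(label) - rho * cfg.iti
        v_fail = cfg.failure_utility(label) - rho * cfg.iti
    else:
        v_succ = cfg.success_utility(label) - rho * cfg.iti
        v_fail = -rho * (cfg.iti + cfg.penalty)
    return float(v_succ), float(v_fail)


def _effective(params: FreeParams, cfg: TaskConfig, name: str) -> float:
    v = getattr(params, name)
    return float(getattr(cfg, name)) if v is None else float(v)


def q_press_mv(label: str, tau, sol: "ValueSolution", cfg: TaskConfig):
    """Value of choosing *press* with completion latency ``tau``.

    Hyperbolic vigour cost ``c_p / tau``, the appropriate terminal value
    (success iff ``tau <= tau_D``), and the opportunity cost of the occupied
    time ``min(tau, tau_D)``.
    """
    tau_arr = np.asarray(tau, dtype=float)
    if np.any((tau_arr < cfg.tau_min) | (tau_arr > cfg.tau_max)):
        raise ValueError("latency outside [tau_min, tau_max]")
    c_p = _effective(sol.params, cfg, "c_p")
    succ = tau_arr <= cfg.tau_D
    q = (c_p / tau_arr
         + np.where(succ, sol.v_succ[label], sol.v_fail[label])
         - sol.rho * np.minimum(tau_arr, cfg.tau_D))
    return float(q) if np.isscalar(tau) else q


def q_other_mv(label: str, sol: "ValueSolution", cfg: TaskConfig) -> float:
    """Value of choosing the alternative activity *other* (press foregone)."""
    r_o = _effective(sol.params, cfg, "r_O")
    return float(r_o * cfg.tau_D + sol.v_fail[label] - sol.rho * cfg.tau_D)


def _go_tables(rho: float, cfg: TaskConfig, params: FreeParams,
               grid: LatencyGrid) -> dict[str, dict[str, np.ndarray]]:
    """Post-exit sub-choice quantities for Go trials, per leave time.

    For each leave time ``t`` on the grid: the press-latency softmax
    (inverse temperature ``beta_tau``) over press values, the expected press
    value, the logistic press-vs-other choice (inverse temperature ``beta``),
    the value of having left at ``t``, and the success probability, expected
    extra utility and expected extra duration of the post-exit period.
    Leave times at or beyond the deadline are certain failures.
    """
    t = grid.nodes
    tau2 = grid.nodes
    w = grid.weights
    c_p = _effective(params, cfg, "c_p")
    r_o = _effective(params, cfg, "r_O")
    out: dict[str, dict[str, np.ndarray]] = {}
    rem = cfg.tau_D - t  # remaining response window at exit
    open_rows = rem > 0
    for label in GO_LABELS:
        v_succ, v_fail = terminal_values(label, rho, cfg)
        reward = cfg.success_utility(label)
        ok = tau2[None, :] <= rem[:, None]
        q2 = np.where(ok,
                      c_p / tau2[None, :] + v_succ - rho * tau2[None, :],
                      c_p / tau2[None, :] + v_fail - rho * rem[:, None])
        logits = params.beta_tau * q2
        shifted = np.exp(logits - logits.max(axis=1, keepdims=True))
        p2 = shifted / np.sum(w[None, :] * shifted, axis=1, keepdims=True)
        q_bar = np.sum(w[None, :] * p2 * q2, axis=1)
        q_oth = (r_o - rho) * rem + v_fail
        p_press = expit(params.beta * (q_bar - q_oth))
        v_out_t = p_press * q_bar + (1.0 - p_press) * q_oth
        p_in_time = np.sum(w[None, :] * p2 * ok, axis=1)
        succ_t = p_press * p_in_time
        util_press = np.sum(w[None, :] * p2
                            * (c_p / tau2[None, :] + reward * ok), axis=1)
        dur_press = np.sum(w[None, :] * p2
                           * np.minimum(tau2[None, :], rem[:, None]), axis=1)
        util_t = p_press * util_press + (1.0 - p_press) * (r_o * rem)
        dur_t = p_press * dur_press + (1.0 - p_press) * rem
        # deadline already passed at exit: certain failure, nothing accrues
        v_out_t = np.where(open_rows, v_out_t, v_fail)
        p_press = np.where(open_rows, p_press, 0.0)
        succ_t = np.where(open_rows, succ_t, 0.0)
        util_t = np.where(open_rows, util_t, 0.0)
        dur_t = np.where(open_rows, dur_t, 0.0)
        out[label] = {
            "v_out": v_out_t, "p_press": p_press, "p_tau2": p2,
            "succ": succ_t, "util": util_t, "dur": dur_t,
        }
    return out


def v_out(label: str, t: float, sol: "ValueSolution", cfg: TaskConfig,
          ) -> float:
    """Value of having left the nose-poke ``t`` seconds after a Go cue."""
    if label not in GO_LABELS:
        raise ValueError("v_out is defined for Go trial types only")
    if not 0.0 <= t <= cfg.tau_D:
        raise ValueError("t must lie in [0, tau_D]")
    grid = sol.grid
    tau2 = grid.nodes
    w = grid.weights
    c_p = _effective(sol.params, cfg, "c_p")
    r_o = _effective(sol.params, cfg, "r_O")
    rem = cfg.tau_D - t
    if rem <= 0:
        return sol.v_fail[label]
    ok = tau2 <= rem
    q2 = np.where(ok,
                  c_p / tau2 + sol.v_succ[label] - sol.rho * tau2,
                  c_p / tau2 + sol.v_fail[label] - sol.rho * rem)
    logits = sol.params.beta_tau * q2
    shifted = np.exp(logits - logits.max())
    p2 = shifted / np.sum(w * shifted)
    q_bar = float(np.sum(w * p2 * q2))
    q_oth = (r_o - sol.rho) * rem + sol.v_fail[label]
    p_press = float(expit(sol.params.beta * (q_bar - q_oth)))
    return p_press * q_bar + (1.0 - p_press) * q_oth


def q_leave_gng(label: str, tau, sol: "ValueSolution", cfg: TaskConfig):
    """Value of leaving the nose-poke at latency ``tau``.

    Fixation cost accrues linearly, leaving vigour hyperbolically; leaving
    is non-interruptible, so the full costs are charged even when the tone
    ends earlier.  Go trials continue with the post-exit sub-choice; No-Go
    trials resolve by whether the tone offset preceded the exit.
    """
    tau_arr = np.atleast_1d(np.asarray(tau, dtype=float))
    if np.any((tau_arr < cfg.tau_min) | (tau_arr > cfg.tau_max)):
        raise ValueError("latency outside [tau_min, tau_max]")
    c_f = _effective(sol.params, cfg, "c_f")
    c_l = _effective(sol.params, cfg, "c_l")
    base = c_f * tau_arr + c_l / tau_arr - sol.rho * tau_arr
    if label in GO_LABELS:
        cont = np.array([
            v_out(label, min(x, cfg.tau_D), sol, cfg) if x <= cfg.tau_D
            else sol.v_fail[label]
            for x in tau_arr])
    else:
        p = success_prob_nogo(tau_arr, cfg)
        cont = p * sol.v_succ[label] + (1.0 - p) * sol.v_fail[label]
    q = base + cont
    return float(q[0]) if np.isscalar(tau) else q


# ---------------------------------------------------------------------------
# Self-consistent solver
# ---------------------------------------------------------------------------

def _solve_cue_value(evaluate, lo: float, hi: float) -> float:
    """Root of v - T(v) on a bracket that contains the range of T."""
    pad = 1.0 + 1e-6 * max(abs(lo), abs(hi))
    a, b = lo - pad, hi + pad
    fa = evaluate(a) - a
    fb = evaluate(b) - b
    if fa == 0.0:
        return a
    if fb == 0.0:
        return b
    if fa * fb > 0:  # pragma: no cover - bracket is constructed to contain T
        raise RuntimeError("cue-value bracket failed")
    return float(brentq(lambda v: evaluate(v) - v, a, b, xtol=1e-12))


def _mv_stats(rho: float, cfg: TaskConfig, params: FreeParams,
              ctrl: ControlConfig, grid: LatencyGrid, error_rt_mode: str):
    """Per-(type, C) policy statistics and renewal terms at fixed rho."""
    tau = grid.nodes
    w = grid.weights
    c_p = _effective(params, cfg, "c_p")
    r_o = _effective(params, cfg, "r_O")
    succ_mask = tau <= cfg.tau_D
    occupied = np.minimum(tau, cfg.tau_D)
    res: dict = {"q_press": {}, "q_other": {}, "per": {}, "v_cue": {}}
    for label in cfg.labels:
        v_succ, v_fail = terminal_values(label, rho, cfg)
        q_press = (c_p / tau + np.where(succ_mask, v_succ, v_fail)
                   - rho * occupied)
        q_other = r_o * cfg.tau_D + v_fail - rho * cfg.tau_D
        states = control_states(label, ctrl)

        def expected_action_value(v: float) -> float:
            total = 0.0
            for C, p_c in states:
                d = v if C == 0 else v - float(ctrl.baselines[label])
                dens = latency_density_from_q(q_press, d, params, grid)
                q_bar = float(np.sum(w * dens * q_press))
                p_press = float(expit(press_logit(q_bar - q_other, d,
                                                  params)))
                total += p_c * (p_press * q_bar + (1 - p_press) * q_other)
            return -rho * cfg.cue_to_lever + total

        bounds = [q_other, float(q_press.min()), float(q_press.max())]
        lo = -rho * cfg.cue_to_lever + min(bounds)
        hi = -rho * cfg.cue_to_lever + max(bounds)
        v = _solve_cue_value(expected_action_value, lo, hi)
        res["v_cue"][label] = v
        res["q_press"][label] = q_press
        res["q_other"][label] = q_other
        r_succ = cfg.success_utility(label)
        r_fail = cfg.failure_utility(label)
        for C, p_c in states:
            d = v if C == 0 else v - float(ctrl.baselines[label])
            dens = latency_density_from_q(q_press, d, params, grid)
            q_bar = float(np.sum(w * dens * q_press))
            p_press = float(expit(press_logit(q_bar - q_other, d, params)))
            p_in_time = float(np.sum(w * dens * succ_mask))
            succ = p_press * p_in_time
            util_press = float(np.sum(
                w * dens * (c_p / tau + np.where(succ_mask, r_succ, r_fail))))
            dur_press = float(np.sum(w * dens * occupied))
            util = (p_press * util_press
                    + (1 - p_press) * (r_o * cfg.tau_D + r_fail))
            dur = (cfg.cue_to_lever + p_press * dur_press
                   + (1 - p_press) * cfg.tau_D + cfg.iti)
            if p_in_time > 0:
                rt_c = float(np.sum(w * dens * succ_mask * tau)) / p_in_time
            else:
                rt_c = np.nan
            p_late = 1.0 - p_in_time
            if p_late > 1e-12:
                if error_rt_mode == "truncated":
                    rt_e = cfg.tau_D
                else:
                    rt_e = float(np.sum(w * dens * (~succ_mask) * tau)) / p_late
            else:
                rt_e = np.nan
            res["per"][(label, C)] = {
                "density": dens, "press_prob": p_press, "success": succ,
                "util": util, "dur": dur,
                "rt_correct": rt_c, "rt_correct_weight": succ,
                "rt_error": rt_e, "rt_error_weight": p_press * p_late,
            }
    return res


def _gng_stats(rho: float, cfg: TaskConfig, params: FreeParams,
               ctrl: ControlConfig, grid: LatencyGrid, error_rt_mode: str):
    tau = grid.nodes
    w = grid.weights
    c_f = _effective(params, cfg, "c_f")
    c_l = _effective(params, cfg, "c_l")
    go = _go_tables(rho, cfg, params, grid)
    res: dict = {"q_leave": {}, "per": {}, "v_cue": {}, "go": go,
                 "succ_given_tau": {}}
    base_cost = c_f * tau + c_l / tau
    for label in cfg.labels:
        v_succ, v_fail = terminal_values(label, rho, cfg)
        reward = cfg.success_utility(label)
        if label in GO_LABELS:
            tab = go[label]
            # nodes beyond the deadline are certain failures
            past = tau > cfg.tau_D
            cont = np.where(past, v_fail, tab["v_out"])
            q_leave = base_cost + cont - rho * tau
            succ_given = np.where(past, 0.0, tab["succ"])
            util_extra = np.where(past, 0.0, tab["util"])
            dur_extra = np.where(past, 0.0, tab["dur"])
        else:
            p = success_prob_nogo(tau, cfg)
            q_leave = (base_cost + p * v_succ + (1 - p) * v_fail - rho * tau)
            succ_given = p
            util_extra = p * reward
            dur_extra = np.zeros_like(tau)
        res["q_leave"][label] = q_leave
        res["succ_given_tau"][label] = succ_given
        states = control_states(label, ctrl)

        def expected_leave_value(v: float) -> float:
            total = 0.0
            for C, p_c in states:
                d = v if C == 0 else v - float(ctrl.baselines[label])
                dens = latency_density_from_q(q_leave, d, params, grid)
                total += p_c * float(np.sum(w * dens * q_leave))
            return total

        v = _solve_cue_value(expected_leave_value,
                             float(q_leave.min()), float(q_leave.max()))
        res["v_cue"][label] = v
        for C, p_c in states:
            d = v if C == 0 else v - float(ctrl.baselines[label])
            dens = latency_density_from_q(q_leave, d, params, grid)
            succ = float(np.sum(w * dens * succ_given))
            if label in GO_LABELS:
                util = float(np.sum(w * dens * (base_cost + util_extra)))
                dur = float(np.sum(w * dens * (tau + dur_extra)))
            else:
                util = float(np.sum(w * dens * (base_cost + util_extra)))
                dur = float(np.sum(w * dens * tau))
            dur += cfg.iti + (1.0 - succ) * cfg.penalty
            if succ > 1e-12:
                rt_c = float(np.sum(w * dens * succ_given * tau)) / succ
            else:
                rt_c = np.nan
            fail = 1.0 - succ
            if fail > 1e-12:
                rt_e = float(np.sum(w * dens * (1 - succ_given) * tau)) / fail
            else:
                rt_e = np.nan
            res["per"][(label, C)] = {
                "density": dens, "success": succ,
                "util": util, "dur": dur,
                "rt_correct": rt_c, "rt_correct_weight": succ,
                "rt_error": rt_e, "rt_error_weight": fail,
            }
    return res


def solve_self_consistent(cfg: TaskConfig, params: FreeParams,
                          ctrl: ControlConfig,
                          grid: LatencyGrid | None = None,
                          tol: float = 1e-8, max_iter: int = 10_000,
                          error_rt_mode: str = "truncated",
                          damping: float = 0.5) -> ValueSolution:
    """Solve for the jointly consistent (rho, V, delta, policy) fixed point.

    At each outer iteration the per-trial-type cue values are solved exactly
    (by root finding) given the current gain ``rho``; ``rho`` is then moved
    towards the renewal ratio — expected utility per trial cycle over
    expected cycle duration — under the policy those cue values induce, by a
    secant step on the renewal residual (with a damped fallback when the
    secant step is unreliable).  Iteration stops when one full update moves
    ``rho`` by at most ``tol``; the cue values are exact for each candidate
    ``rho``, so they move with it.

    Raises
    ------
    RuntimeError
        If the fixed point is not reached within ``max_iter`` renewal
        evaluations.
    """
    if tol <= 0:
        raise ValueError("tol must be positive")
    if error_rt_mode not in ("truncated", "latent"):
        raise ValueError("error_rt_mode must be 'truncated' or 'latent'")
    if grid is None:
        grid = LatencyGrid.for_task(cfg)
    stats_fn = _mv_stats if cfg.task == TASK_MIXED else _gng_stats
    mix = cfg.trial_mix

    def renewal(rho_val: float):
        stats = stats_fn(rho_val, cfg, params, ctrl, grid, error_rt_mode)
        num = den = 0.0
        for label in cfg.labels:
            p_lab = mix[label]
            for C, p_c in control_states(label, ctrl):
                rec = stats["per"][(label, C)]
                num += p_lab * p_c * rec["util"]
                den += p_lab * p_c * rec["dur"]
        return num / den - rho_val, stats

    rho = 0.0
    residual = np.inf
    converged = False
    stats = None
    rho_prev = f_prev = None
    for n_iter in range(1, max_iter + 1):
        f, stats = renewal(rho)
        residual = abs(f)
        if residual <= tol:
            converged = True
            break
        step = damping * f
        if f_prev is not None and f != f_prev:
            secant = -f * (rho - rho_prev) / (f - f_prev)
            if np.isfinite(secant) and abs(secant) <= 1.0:
                step = secant
        rho_prev, f_prev = rho, f
        rho = rho + step
    if not converged:
        raise RuntimeError(
            f"no fixed point in {max_iter} iterations (residual {residual:g})")
    v_cue = dict(stats["v_cue"])

    per = stats["per"]
    sol = ValueSolution(
        task=cfg.task,
        rho=rho,
        v_cue=v_cue,
        v_succ={lab: terminal_values(lab, rho, cfg)[0] for lab in cfg.labels},
        v_fail={lab: terminal_values(lab, rho, cfg)[1] for lab in cfg.labels},
        grid=grid,
        params=params,
        ctrl=ctrl,
        latency_density={k: rec["density"] for k, rec in per.items()},
        success_prob={k: rec["success"] for k, rec in per.items()},
        rt_correct={k: rec["rt_correct"] for k, rec in per.items()},
        rt_error={k: rec["rt_error"] for k, rec in per.items()},
        rt_correct_weight={k: rec["rt_correct_weight"]
                           for k, rec in per.items()},
        rt_error_weight={k: rec["rt_error_weight"] for k, rec in per.items()},
        exp_utility={k: rec["util"] for k, rec in per.items()},
        exp_duration={k: rec["dur"] for k, rec in per.items()},
        residual=residual,
        converged=converged,
        n_iter=n_iter,
        error_rt_mode=error_rt_mode,
    )
    if cfg.task == TASK_MIXED:
        sol.q_press = stats["q_press"]
        sol.q_other = stats["q_other"]
        sol.press_prob = {k: rec["press_prob"] for k, rec in per.items()}
    else:
        sol.q_leave = stats["q_leave"]
        sol.succ_given_tau = stats["succ_given_tau"]
        sol.go_p_press_t = {lab: stats["go"][lab]["p_press"]
                            for lab in GO_LABELS}
        sol.go_p_tau2 = {lab: stats["go"][lab]["p_tau2"]
                         for lab in GO_LABELS}
    return sol
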