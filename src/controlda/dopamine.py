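"""Forward model of cue-aligned dopamine transients.

The cue TD error is mapped to a dopaminergic drive asymmetrically — dopamine
principally signals transitions that are better than expected — and the
drive is convolved with a causal alpha kernel to produce a relative
dopamine-concentration trace in arbitrary units.  On control trials the
unreframed transient at cue onset is followed, after a short sub-second
delay, by the reframed transient; both are summed on the trace grid.
Outcome-conditioned averages mix the control and no-control traces with the
Bayesian posterior over control given the outcome.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import TYPE_CHECKING

import numpy as np
import pandas as pd

from .control_policy import ControlConfig, control_probability, control_states

if TYPE_CHECKING:  # pragma: no cover
    from .task_mdp import ValueSolution

__all__ = [
    "DAConfig",
    "DATrace",
    "da_component",
    "alpha_kernel",
    "cue_da_trace",
    "control_posterior",
    "condition_average_trace",
]


@dataclass(frozen=True)
class DAConfig:
    """Dopamine forward-model settings.

    ``alpha`` weights the positive part of the TD error against the negative
    part (0.8 throughout: a 4:1 asymmetry); ``xi`` is the alpha-kernel time
    constant (0.7 s, also the time of the kernel peak); ``tau_delay`` the
    latency with which control is applied after cue onset (250 ms); ``dt``
    the trace resolution; ``window`` the trace duration after the cue (5 s
    for the mixed-valence task, 3 s for Go/No-Go); ``pre_window`` an
    optional pre-cue segment included for baselining.
    """

    alpha: float = 0.8
    xi: float = 0.7
    tau_delay: float = 0.25
    dt: float = 0.01
    window: float = 5.0
    pre_window: float = 0.0

    def __post_init__(self) -> None:
        if not 0.0 <= self.alpha <= 1.0:
            raise ValueError("alpha must lie in [0, 1]")
        if self.xi <= 0 or self.dt <= 0:
            raise ValueError("xi and dt must be positive")
        if self.tau_delay < 0 or self.pre_window < 0:
            raise ValueError("tau_delay and pre_window must be non-negative")

    @classmethod
    def for_task(cls, task: str, **overrides) -> "DAConfig":
        from .task_mdp import TASK_MIXED

        window = 5.0 if task == TASK_MIXED else 3.0
        base = dict(window=window)
        base.update(overrides)
        return cls(**base)

    def time_grid(self) -> np.ndarray:
        n_pre = int(round(self.pre_window / self.dt))
        n_post = int(round(self.window / self.dt))
        return np.arange(-n_pre, n_post) * self.dt


@dataclass
class DATrace:
    """Cue-aligned relative dopamine signal on a uniform time grid."""

    t: np.ndarray
    values: np.ndarray
    label: str = ""

    def __post_init__(self) -> None:
        self.t = np.asarray(self.t, dtype=float)
        self.values = np.asarray(self.values, dtype=float)
        if self.t.shape != self.values.shape:
            raise ValueError("time grid and values must have equal length")
        if self.t.size >= 2:
            steps = np.diff(self.t)
            if not np.allclose(steps, steps[0], rtol=0, atol=1e-9):
                raise ValueError("time grid must be uniform")

    @property
    def dt(self) -> float:
        return float(self.t[1] - self.t[0])

    def to_frame(self, **extra) -> pd.DataFrame:
        frame = pd.DataFrame({"time_s": self.t, "dDA": self.values})
        frame["label"] = self.label
        for key, value in extra.items():
            frame[key] = value
        return frame


def da_component(delta: float, alpha: float = 0.8) -> float:
    """Asymmetric dopaminergic component of a TD error.

    ``alpha * [delta]_+ + (1 - alpha) * [delta]_-``: positive errors are
    conveyed at weight ``alpha``, negative ones at ``1 - alpha``.
    """
    d = np.asarray(delta, dtype=float)
    out = alpha * np.maximum(d, 0.0) + (1.0 - alpha) * np.minimum(d, 0.0)
    return float(out) if np.isscalar(delta) else out


def alpha_kernel(t, xi: float = 0.7):
    """Causal alpha function ``(t/xi) exp(1 - t/xi)``, unit peak at ``t=xi``."""
    t_arr = np.asarray(t, dtype=float)
    out = np.where(t_arr >= 0,
                   (t_arr / xi) * np.exp(1.0 - t_arr / xi), 0.0)
    return float(out) if np.isscalar(t) else out


def cue_da_trace(trial_type, control: int, sol: "ValueSolution",
                 dacfg: DAConfig) -> DATrace:
    """Predicted cue-aligned DA trace for one (trial type, control state).

    A TD impulse at cue onset carries the unreframed error; on control
    trials a second impulse at ``tau_delay`` carries the reframed error.
    Convolution with the alpha kernel of an impulse train reduces to a sum
    of shifted kernels.
    """
    label = getattr(trial_type, "label", trial_type)
    if control == 1 and dacfg.window <= dacfg.tau_delay:
        raise ValueError("trace window shorter than the control delay")
    t = dacfg.time_grid()
    values = (da_component(sol.delta(label, 0), dacfg.alpha)
              * alpha_kernel(t, dacfg.xi))
    if control == 1:
        values = values + (da_component(sol.delta(label, 1), dacfg.alpha)
                           * alpha_kernel(t - dacfg.tau_delay, dacfg.xi))
    return DATrace(t, values, label=f"{label}|C={control}")


def control_posterior(trial_type, outcome: str, sol: "ValueSolution",
                      ctrl: ControlConfig) -> float:
    """Posterior probability that control was deployed, given the outcome.

    Bayes' rule over the two control states, with the solved per-state
    success probabilities as the likelihood.
    """
    if outcome not in ("success", "fail"):
        raise ValueError("outcome must be 'success' or 'fail'")
    label = getattr(trial_type, "label", trial_type)
    kappa = control_probability(label, ctrl)
    if kappa == 0.0:
        return 0.0

    def likelihood(C: int) -> float:
        p_succ = sol.success_prob[(label, C)]
        return p_succ if outcome == "success" else 1.0 - p_succ

    num = kappa * likelihood(1)
    den = num + (1.0 - kappa) * likelihood(0)
    if den == 0.0:
        raise ValueError(f"outcome {outcome!r} has zero probability")
    return float(num / den)


def condition_average_trace(trial_type, outcome: str, sol: "ValueSolution",
                            ctrl: ControlConfig, dacfg: DAConfig) -> DATrace:
    """Outcome-conditioned average DA trace (posterior-weighted mixture)."""
    label = getattr(trial_type, "label", trial_type)
    states = control_states(label, ctrl)
    if len(states) == 1:
        trace = cue_da_trace(label, 0, sol, dacfg)
        return DATrace(trace.t, trace.values, label=f"{label}|{outcome}")
    p1 = control_posterior(label, outcome, sol, ctrl)
    t0 = cue_da_trace(label, 0, sol, dacfg)
    t1 = cue_da_trace(label, 1, sol, dacfg)
    values = (1.0 - p1) * t0.values + p1 * t1.values
    return DATrace(t0.t, values, label=f"{label}|{outcome}")
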