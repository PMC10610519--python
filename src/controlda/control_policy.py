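"""Cognitive-control decisions, cue TD errors, and Pavlovian-biased policies.

At cue onset the agent makes an internal decision about whether to deploy
self-control (``C = 1``) on the trial types where Pavlovian and instrumental
demands conflict (shock trials in the mixed-valence task; No-Go large-reward
trials in the Go/No-Go task).  Control substitutes a counterfactual baseline
``b`` — the full disutility of the shock, or the full utility of the reward
that stands to be lost — for the pre-trial reference in the cue-evoked
temporal-difference error:

    delta(s0) = V(s_cue) - V(s_pre)        (no control; V(s_pre) = 0 reference)
    delta(s1) = V(s_cue) - b               (control / reframing)

Because ``b`` lies beyond ``V(s_cue)`` on the relevant side, reframing flips
the sign of the cue TD error, converting e.g. the prospect of shock into the
prospect of safety.  The TD error then biases the external policy: positive
errors speed and energize responding, negative errors slow and suppress it,
via separate non-negative weights for instrumental value and for the positive
and negative parts of the TD error.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, fields, replace
from typing import TYPE_CHECKING, Mapping

import numpy as np
import pandas as pd
from scipy.special import expit

if TYPE_CHECKING:  # pragma: no cover - type-only imports
    from .task_mdp import LatencyGrid, TaskConfig, ValueSolution

__all__ = [
    "ControlConfig",
    "FreeParams",
    "TDRecord",
    "BehaviourSummary",
    "control_probability",
    "cue_td_error",
    "latency_distribution",
    "press_probability_mv",
    "predict_behaviour",
]


# ---------------------------------------------------------------------------
# Parameter containers
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class FreeParams:
    """Free parameters of the behavioural model (the fitted vector ``x``).

    Action-choice weights ``w_i`` (instrumental), ``w_p_plus``/``w_p_minus``
    (Pavlovian, positive/negative TD error) enter the press-vs-other logit;
    latency weights ``w_tau_i``, ``w_tau_v_plus``, ``w_tau_v_minus`` shape the
    latency / leave-time density.  ``beta`` and ``beta_tau`` are the inverse
    temperatures of the Go/No-Go post-exit sub-choice, and ``kappa`` the
    probability of deploying control on controllable trials.  For the
    Go/No-Go task the utility rate of *other* (``r_O``) and the fixation,
    leaving and pressing costs (``c_f``, ``c_l``, ``c_p``) are also free;
    ``None`` means "use the task-config value".
    """

    w_i: float = 0.0
    w_p_plus: float = 0.0
    w_p_minus: float = 0.0
    w_tau_i: float = 0.0
    w_tau_v_plus: float = 0.0
    w_tau_v_minus: float = 0.0
    beta: float = 1.0
    beta_tau: float = 1.0
    kappa: float = 0.0
    r_O: float | None = None
    c_f: float | None = None
    c_l: float | None = None
    c_p: float | None = None

    def __post_init__(self) -> None:
        for name in ("w_i", "w_p_plus", "w_p_minus", "w_tau_i",
                     "w_tau_v_plus", "w_tau_v_minus", "beta", "beta_tau"):
            if getattr(self, name) < 0:
                raise ValueError(f"{name} must be non-negative")
        if not 0.0 <= self.kappa <= 1.0:
            raise ValueError("kappa must lie in [0, 1]")
        if self.r_O is not None and self.r_O < 0:
            raise ValueError("r_O must be non-negative")
        for name in ("c_f", "c_l", "c_p"):
            v = getattr(self, name)
            if v is not None and v > 0:
                raise ValueError(f"{name} must be non-positive")

    def replace(self, **changes: float) -> "FreeParams":
        return replace(self, **changes)

    def l1_norm(self, names: tuple[str, ...] | None = None) -> float:
        """L1 norm of the (selected) parameter vector."""
        if names is None:
            names = tuple(f.name for f in fields(self))
        total = 0.0
        for name in names:
            v = getattr(self, name)
            if v is not None:
                total += abs(v)
        return total

    # -- presets transcribed from the fitted-parameter tables ---------------

    @classmethod
    def good_avoider(cls) -> "FreeParams":
        """Best-fitting mixed-valence parameters for good avoiders."""
        return cls(w_i=2.45, w_p_plus=0.00, w_p_minus=0.01,
                   w_tau_i=41.28, w_tau_v_plus=0.97, w_tau_v_minus=0.00,
                   kappa=0.36)

    @classmethod
    def poor_avoider(cls) -> "FreeParams":
        """Best-fitting mixed-valence parameters for poor avoiders."""
        return cls(w_i=0.01, w_p_plus=0.82, w_p_minus=0.74,
                   w_tau_i=0.00, w_tau_v_plus=1.06, w_tau_v_minus=0.00,
                   kappa=0.50)

    @classmethod
    def go_nogo_fit(cls) -> "FreeParams":
        """Best-fitting Go/No-Go parameters."""
        return cls(w_tau_i=1.94, w_tau_v_plus=11.63, w_tau_v_minus=0.01,
                   beta_tau=0.66, beta=2.95, kappa=0.50,
                   r_O=0.12, c_f=-0.44, c_l=-0.10, c_p=-0.00)


@dataclass(frozen=True)
class ControlConfig:
    """Which trial types admit control, with what probability and baseline.

    ``kappa`` maps controllable trial-type labels to the probability of
    deploying control; ``baselines`` maps the same labels to the reframing
    baseline ``b`` (the configured outcome utility: ``b_shk = r_shk``,
    ``b_ngl = r_L``).  All other trial types are forced ``C = 0``.
    """

    kappa: Mapping[str, float]
    baselines: Mapping[str, float]

    def __post_init__(self) -> None:
        for lab, k in self.kappa.items():
            if not 0.0 <= k <= 1.0:
                raise ValueError(f"kappa[{lab!r}] must lie in [0, 1]")
            if lab not in self.baselines:
                raise ValueError(f"no baseline for controllable type {lab!r}")

    @classmethod
    def for_task(cls, cfg: "TaskConfig", kappa: float) -> "ControlConfig":
        """Standard control structure for a task: one controllable type."""
        from .task_mdp import TASK_GONOGO, TASK_MIXED

        if cfg.task == TASK_MIXED:
            return cls(kappa={"shk": kappa},
                       baselines={"shk": cfg.utilities["shk"]})
        if cfg.task == TASK_GONOGO:
            return cls(kappa={"ngl": kappa},
                       baselines={"ngl": cfg.utilities["L"]})
        raise ValueError(f"unknown task {cfg.task!r}")

    def with_kappa(self, kappa: float) -> "ControlConfig":
        return ControlConfig(kappa={lab: kappa for lab in self.kappa},
                             baselines=dict(self.baselines))


@dataclass(frozen=True)
class TDRecord:
    """Cue TD error for one trial type under one control state."""

    trial_type: str
    control: int
    delta: float
    v_cue: float
    v_pre: float = 0.0
    baseline: float | None = None


@dataclass
class BehaviourSummary:
    """Per-trial-type success rates and mean reaction times.

    ``table`` is indexed by trial-type label with columns ``success_rate``,
    ``rt_correct``, ``rt_error``, ``se_rt_correct``, ``se_rt_error``.
    Standard errors are NaN for model-predicted summaries.
    """

    table: pd.DataFrame

    COLUMNS = ("success_rate", "rt_correct", "rt_error",
               "se_rt_correct", "se_rt_error")

    def __post_init__(self) -> None:
        missing = [c for c in self.COLUMNS if c not in self.table.columns]
        if missing:
            raise ValueError(f"missing columns: {missing}")
        rates = self.table["success_rate"]
        if ((rates < 0) | (rates > 1)).any():
            raise ValueError("success rates must lie in [0, 1]")

    @classmethod
    def from_dicts(cls, success: Mapping[str, float],
                   rt_correct: Mapping[str, float],
                   rt_error: Mapping[str, float],
                   se_rt_correct: Mapping[str, float] | None = None,
                   se_rt_error: Mapping[str, float] | None = None,
                   ) -> "BehaviourSummary":
        labels = list(success)
        table = pd.DataFrame(
            {
                "success_rate": [success[l] for l in labels],
                "rt_correct": [rt_correct.get(l, np.nan) for l in labels],
                "rt_error": [rt_error.get(l, np.nan) for l in labels],
                "se_rt_correct": [
                    (se_rt_correct or {}).get(l, np.nan) for l in labels],
                "se_rt_error": [
                    (se_rt_error or {}).get(l, np.nan) for l in labels],
            },
            index=pd.Index(labels, name="trial_type"),
        )
        return cls(table)

    def to_csv(self, path) -> None:
        self.table.to_csv(path)

    @classmethod
    def from_csv(cls, path) -> "BehaviourSummary":
        return cls(pd.read_csv(path, index_col="trial_type"))

    def success_rate(self, label: str) -> float:
        return float(self.table.at[label, "success_rate"])

    def rt(self, label: str, which: str = "correct") -> float:
        return float(self.table.at[label, f"rt_{which}"])


# ---------------------------------------------------------------------------
# Operations
# ---------------------------------------------------------------------------

def control_probability(trial_type, ctrl: ControlConfig) -> float:
    """Probability of deploying self-control on a trial of this type.

    The default choice is always ``C = 0``; only the controllable trial types
    carry a non-zero probability ``kappa``.
    """
    label = getattr(trial_type, "label", trial_type)
    return float(ctrl.kappa.get(label, 0.0))


def control_states(label: str, ctrl: ControlConfig) -> list[tuple[int, float]]:
    """(C, P(C)) pairs for a trial type; a single (0, 1) if uncontrollable."""
    k = control_probability(label, ctrl)
    if k == 0.0:
        return [(0, 1.0)]
    return [(0, 1.0 - k), (1, k)]


def cue_td_error(trial_type, control: int, sol: "ValueSolution",
                 ctrl: ControlConfig) -> TDRecord:
    """Cue-evoked TD error under one control state.

    ``C = 0`` leaves the pre-trial reference in place (``V(s_pre) = 0``);
    ``C = 1`` substitutes the counterfactual baseline ``b``.
    """
    label = getattr(trial_type, "label", trial_type)
    v_cue = sol.v_cue[label]
    if control == 0:
        return TDRecord(label, 0, v_cue - 0.0, v_cue)
    if label not in ctrl.kappa:
        raise ValueError(f"trial type {label!r} is not controllable")
    b = float(ctrl.baselines[label])
    return TDRecord(label, 1, v_cue - b, v_cue, baseline=b)


def _pavlovian_latency_penalty(delta: float, params: FreeParams,
                               tau: np.ndarray) -> np.ndarray:
    # [delta]_- is kept signed (min(delta, 0)), so the subtracted negative
    # term boosts long latencies for delta < 0.
    pos = max(delta, 0.0)
    neg = min(delta, 0.0)
    return (params.w_tau_v_plus * pos + params.w_tau_v_minus * neg) * tau


def latency_density_from_q(q: np.ndarray, delta: float, params: FreeParams,
                           grid: "LatencyGrid",
                           instrumental_weight: float | None = None,
                           ) -> np.ndarray:
    """Normalized latency density on the grid given action values ``q``.

    The unnormalized log-density is ``w * q - (w+ [d]+ + w- [d]-) tau`` with
    ``w`` the instrumental latency weight (``w_tau_i`` unless overridden).
    Normalization is by quadrature, so ``sum(weights * density) == 1``.
    """
    w = params.w_tau_i if instrumental_weight is None else instrumental_weight
    logits = w * np.asarray(q, dtype=float)
    logits = logits - _pavlovian_latency_penalty(delta, params, grid.nodes)
    finite = np.isfinite(logits)
    if not finite.any():
        raise ValueError("degenerate latency distribution: all logits -inf")
    shifted = np.exp(logits - logits[finite].max())
    z = float(np.sum(grid.weights * shifted))
    if not np.isfinite(z) or z <= 0:
        raise ValueError("degenerate latency distribution: zero mass")
    return shifted / z


def latency_distribution(trial_type, control: int, sol: "ValueSolution",
                         params: FreeParams,
                         grid: "LatencyGrid | None" = None) -> np.ndarray:
    """Latency (press-completion or nose-poke-exit) density for (type, C)."""
    label = getattr(trial_type, "label", trial_type)
    grid = grid if grid is not None else sol.grid
    q = sol.q_press[label] if label in sol.q_press else sol.q_leave[label]
    delta = sol.delta(label, control)
    return latency_density_from_q(q, delta, params, grid)


def press_logit(delta_q: float, delta: float, params: FreeParams) -> float:
    """Press logit against a zero *other* logit."""
    return (params.w_i * delta_q
            + params.w_p_plus * max(delta, 0.0)
            + params.w_p_minus * min(delta, 0.0))


def press_probability_mv(trial_type, control: int, sol: "ValueSolution",
                         params: FreeParams) -> float:
    """Probability of choosing *press* over *other* on a mixed-valence trial.

    The press logit combines the instrumental advantage of pressing (the
    latency-density expectation of the press value minus the value of
    *other*) with Pavlovian boosts from the positive and negative parts of
    the cue TD error.
    """
    label = getattr(trial_type, "label", trial_type)
    dens = latency_distribution(label, control, sol, params)
    q_bar = float(np.sum(sol.grid.weights * dens * sol.q_press[label]))
    delta_q = q_bar - sol.q_other[label]
    return float(expit(press_logit(delta_q, sol.delta(label, control),
                                   params)))


def predict_behaviour(sol: "ValueSolution", ctrl: ControlConfig,
                      params: FreeParams, cfg: "TaskConfig",
                      ) -> BehaviourSummary:
    """Marginalize the solved model into per-trial-type summary statistics.

    Success rates are kappa-mixtures of the per-control-state success
    probabilities; mean RTs are the latency-density means conditioned on the
    correct / error event, mixed across control states with weights
    proportional to P(C) times the probability of the conditioning event.
    """
    success: dict[str, float] = {}
    rtc: dict[str, float] = {}
    rte: dict[str, float] = {}
    for label in cfg.labels:
        s = c_num = c_den = e_num = e_den = 0.0
        for C, p_c in control_states(label, ctrl):
            s += p_c * sol.success_prob[(label, C)]
            wc = p_c * sol.rt_correct_weight[(label, C)]
            we = p_c * sol.rt_error_weight[(label, C)]
            if wc > 0 and math.isfinite(sol.rt_correct[(label, C)]):
                c_num += wc * sol.rt_correct[(label, C)]
                c_den += wc
            if we > 0 and math.isfinite(sol.rt_error[(label, C)]):
                e_num += we * sol.rt_error[(label, C)]
                e_den += we
        success[label] = s
        rtc[label] = c_num / c_den if c_den > 0 else np.nan
        rte[label] = e_num / e_den if e_den > 0 else np.nan
    return BehaviourSummary.from_dicts(success, rtc, rte)
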