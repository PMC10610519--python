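"""Behaviour-fitting objective and derivative-free optimization.

The error function compares model-predicted and observed summary statistics
per trial type: absolute success-rate differences, reaction-time differences
scaled by the data's standard errors (imprecise measurements count less),
an optional dopamine term — for the mixed-valence task, the absolute
difference between the model's peak cue-evoked DA on food and shock trials,
which the data show to be strikingly similar — and an L1 penalty on the
parameter vector.  Minimization is by bounded Nelder-Mead simplex with
multiple random restarts; no gradients are available through the
self-consistent solver.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field

import numpy as np

from .control_policy import (
    BehaviourSummary,
    ControlConfig,
    FreeParams,
    predict_behaviour,
)
from .dopamine import DAConfig, condition_average_trace
from .task_mdp import TASK_MIXED, LatencyGrid, TaskConfig, \
    solve_self_consistent

__all__ = ["FitConfig", "FitResult", "error_function", "fit"]

_DEFAULT_BOUNDS: dict[str, tuple[float, float]] = {
    "w_i": (0.0, 50.0),
    "w_p_plus": (0.0, 10.0),
    "w_p_minus": (0.0, 10.0),
    "w_tau_i": (0.0, 50.0),
    "w_tau_v_plus": (0.0, 20.0),
    "w_tau_v_minus": (0.0, 20.0),
    "beta": (0.0, 20.0),
    "beta_tau": (0.0, 20.0),
    "kappa": (0.0, 1.0),
    "r_O": (0.0, 2.0),
    "c_f": (-2.0, 0.0),
    "c_l": (-2.0, 0.0),
    "c_p": (-2.0, 0.0),
}


@dataclass(frozen=True)
class FitConfig:
    """Objective weights, free-parameter set, and optimizer settings.

    ``free`` names the ``FreeParams`` fields being optimized; ``bounds``
    constrain each of them.  Weight defaults follow the published fits:
    RT weights 0.25 (mixed-valence) or 0.018 (Go/No-Go), DA-term weight 0.1
    (mixed-valence only), L1 weight 0.01 only where instrumental weights can
    otherwise grow without bound (good avoiders).
    """

    w_rtc: float = 0.25
    w_rte: float = 0.25
    w_da: float = 0.1
    w_reg: float = 0.0
    free: tuple[str, ...] = ("w_i", "w_p_plus", "w_p_minus", "w_tau_i",
                             "w_tau_v_plus", "w_tau_v_minus", "kappa")
    bounds: dict = field(default_factory=dict)
    restarts: int = 20
    maxfev: int = 400
    seed: int = 0
    n_grid: int = 200
    solver_tol: float = 1e-8
    solver_max_iter: int = 300
    error_rt_mode: str = "truncated"

    def __post_init__(self) -> None:
        for name in ("w_rtc", "w_rte", "w_da", "w_reg"):
            if getattr(self, name) < 0:
                raise ValueError(f"{name} must be non-negative")
        merged = dict(_DEFAULT_BOUNDS)
        merged.update(self.bounds)
        object.__setattr__(self, "bounds", merged)
        unknown = [name for name in self.free if name not in merged]
        if unknown:
            raise ValueError(f"no bounds for free parameters {unknown}")

    @classmethod
    def mixed_valence_default(cls, good_avoider: bool = False,
                              **overrides) -> "FitConfig":
        base = dict(w_rtc=0.25, w_rte=0.25, w_da=0.1,
                    w_reg=0.01 if good_avoider else 0.0)
        base.update(overrides)
        return cls(**base)

    @classmethod
    def go_nogo_default(cls, **overrides) -> "FitConfig":
        base = dict(
            w_rtc=0.018, w_rte=0.018, w_da=0.0, w_reg=0.0,
            free=("w_tau_i", "w_tau_v_plus", "w_tau_v_minus", "beta_tau",
                  "beta", "kappa", "r_O", "c_f", "c_l", "c_p"))
        base.update(overrides)
        return cls(**base)


@dataclass
class FitResult:
    """Best parameter vector found, with its error breakdown."""

    params: FreeParams
    energy: float
    breakdown: dict[str, float]
    evaluations: int
    converged: bool
    seed: int
    restarts: int

    def to_json(self, path=None) -> str:
        payload = {
            "energy": self.energy,
            "breakdown": self.breakdown,
            "evaluations": self.evaluations,
            "converged": self.converged,
            "seed": self.seed,
            "restarts": self.restarts,
            "params": {k: v for k, v in self.params.__dict__.items()
                       if v is not None},
        }
        text = json.dumps(payload, indent=2, sort_keys=True)
        if path is not None:
            with open(path, "w") as fh:
                fh.write(text)
        return text


def _da_peak_mismatch(sol, ctrl: ControlConfig, dacfg: DAConfig) -> float:
    """|peak DA on food success trials - peak DA on shock success trials|."""
    rew = condition_average_trace("rew", "success", sol, ctrl, dacfg)
    shk = condition_average_trace("shk", "success", sol, ctrl, dacfg)
    sel = rew.t >= 0
    return float(abs(rew.values[sel].max() - shk.values[sel].max()))


def error_function(params: FreeParams, data: BehaviourSummary,
                   cfg: TaskConfig, ctrl: ControlConfig, fitcfg: FitConfig,
                   dacfg: DAConfig | None = None,
                   grid: LatencyGrid | None = None,
                   ) -> tuple[float, dict[str, float]]:
    """Total fitting error and its per-term breakdown for one parameter set.

    RT terms with an empty conditioning event (no correct or no error trials
    in model or data) are dropped; a zero data standard error combined with
    a non-zero RT weight is an error.
    """
    ctrl = ctrl.with_kappa(params.kappa)
    if grid is None:
        grid = LatencyGrid.uniform(cfg.tau_min, cfg.tau_max, fitcfg.n_grid)
    sol = solve_self_consistent(cfg, params, ctrl, grid=grid,
                                tol=fitcfg.solver_tol,
                                max_iter=fitcfg.solver_max_iter,
                                error_rt_mode=fitcfg.error_rt_mode)
    pred = predict_behaviour(sol, ctrl, params, cfg)
    e_succ = e_rtc = e_rte = 0.0
    for label in cfg.labels:
        e_succ += abs(pred.success_rate(label) - data.success_rate(label))
        for which, bucket in (("correct", "rtc"), ("error", "rte")):
            weight = fitcfg.w_rtc if which == "correct" else fitcfg.w_rte
            if weight == 0:
                continue
            model_rt = pred.rt(label, which)
            data_rt = data.rt(label, which)
            se = float(data.table.at[label, f"se_rt_{which}"])
            if np.isnan(model_rt) or np.isnan(data_rt) or np.isnan(se):
                continue
            if se == 0:
                raise ValueError(
                    f"zero standard error for rt_{which}[{label}] with "
                    "non-zero RT weight")
            term = abs(model_rt - data_rt) / se
            if which == "correct":
                e_rtc += term
            else:
                e_rte += term
    e_da = 0.0
    if fitcfg.w_da > 0 and cfg.task == TASK_MIXED:
        if dacfg is None:
            dacfg = DAConfig.for_task(cfg.task)
        e_da = _da_peak_mismatch(sol, ctrl, dacfg)
    e_reg = params.l1_norm(fitcfg.free)
    total = (e_succ + fitcfg.w_rtc * e_rtc + fitcfg.w_rte * e_rte
             + fitcfg.w_da * e_da + fitcfg.w_reg * e_reg)
    breakdown = {"success": e_succ, "rt_correct": e_rtc, "rt_error": e_rte,
                 "da": e_da, "regularization": e_reg, "total": total}
    return total, breakdown


def fit(data: BehaviourSummary, cfg: TaskConfig, ctrl: ControlConfig,
        fitcfg: FitConfig, base_params: FreeParams | None = None,
        dacfg: DAConfig | None = None) -> FitResult:
    """Multi-start bounded Nelder-Mead minimization of the error function.

    ``base_params`` supplies the values of parameters that are held fixed.
    Reproducible given ``fitcfg.seed``.
    """
    from scipy.optimize import minimize

    if base_params is None:
        base_params = FreeParams()
    rng = np.random.default_rng(fitcfg.seed)
    names = fitcfg.free
    lo = np.array([fitcfg.bounds[n][0] for n in names])
    hi = np.array([fitcfg.bounds[n][1] for n in names])
    grid = LatencyGrid.uniform(cfg.tau_min, cfg.tau_max, fitcfg.n_grid)
    evaluations = 0

    def objective(x: np.ndarray) -> float:
        nonlocal evaluations
        evaluations += 1
        x = np.clip(x, lo, hi)
        params = base_params.replace(**dict(zip(names, x)))
        try:
            total, _ = error_function(params, data, cfg, ctrl, fitcfg,
                                      dacfg=dacfg, grid=grid)
        except (RuntimeError, ValueError):
            return 1e6
        return total

    best_x = None
    best_e = np.inf
    any_success = False
    failures = []
    for _ in range(fitcfg.restarts):
        x0 = rng.uniform(lo, hi)
        res = minimize(objective, x0, method="Nelder-Mead",
                       bounds=list(zip(lo, hi)),
                       options={"maxfev": fitcfg.maxfev, "xatol": 1e-4,
                                "fatol": 1e-6})
        if np.isfinite(res.fun) and res.fun < 1e6:
            any_success = True
            if res.fun < best_e:
                best_e = float(res.fun)
                best_x = np.clip(res.x, lo, hi)
        else:
            failures.append(getattr(res, "message", "evaluation failed"))
    if not any_success or best_x is None:
        raise RuntimeError(
            "optimizer failed on all restarts: " + "; ".join(map(str,
                                                                 failures)))
    best_params = base_params.replace(**dict(zip(names, best_x)))
    total, breakdown = error_function(best_params, data, cfg, ctrl, fitcfg,
                                      dacfg=dacfg, grid=grid)
    return FitResult(params=best_params, energy=total, breakdown=breakdown,
                     evaluations=evaluations, converged=True,
                     seed=fitcfg.seed, restarts=fitcfg.restarts)
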