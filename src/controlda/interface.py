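"""Configuration loading, pipeline orchestration, and a thin CLI.

A single YAML document configures a run: which task, the free parameters,
the control structure, dopamine forward-model settings, fitting weights and
simulation sizes.  ``run_pipeline`` executes one named stage and writes CSV
and JSON artifacts plus a manifest recording the config snapshot, seeds and
outputs, so identical inputs reproduce identical outputs.
"""

from __future__ import annotations

import dataclasses
import importlib.resources
import json
import logging
from dataclasses import dataclass, field
from pathlib import Path

import click
import pandas as pd
import yaml

from . import __version__
from .control_policy import (
    BehaviourSummary,
    ControlConfig,
    FreeParams,
    cue_td_error,
    predict_behaviour,
)
from .dopamine import DAConfig, condition_average_trace
from .fitting import FitConfig, fit
from .synthetic_data import (
    NoiseModel,
    ngl_success_fail_test,
    sample_sessions,
    summarize_sessions,
    synth_da_traces,
    write_sessions,
)
from .task_mdp import (
    TASK_GONOGO,
    TASK_MIXED,
    LatencyGrid,
    TaskConfig,
    solve_self_consistent,
)

__all__ = ["RunConfig", "RunManifest", "load_config", "example_config_path",
           "run_pipeline", "main"]

log = logging.getLogger("controlda")

COMMANDS = ("solve", "predict", "fit", "simulate", "analyze")


@dataclass
class RunConfig:
    """Validated, structured view of one YAML run configuration."""

    task: TaskConfig
    params: FreeParams
    ctrl: ControlConfig
    da: DAConfig
    fit: FitConfig
    n_grid: int = 200
    solver_tol: float = 1e-8
    max_iter: int = 10_000
    error_rt_mode: str = "truncated"
    simulate_n_trials: int = 500
    simulate_n_sessions: int = 9
    noise: NoiseModel = field(default_factory=NoiseModel)
    fit_data: str | None = None
    raw: dict = field(default_factory=dict)

    def grid(self) -> LatencyGrid:
        return LatencyGrid.uniform(self.task.tau_min, self.task.tau_max,
                                   self.n_grid)


def _validation_error(section: str, exc: Exception) -> ValueError:
    return ValueError(f"invalid config section {section!r}: {exc}")


def load_config(path) -> RunConfig:
    """Parse and validate a YAML run configuration."""
    with open(path) as fh:
        raw = yaml.safe_load(fh) or {}
    task_section = dict(raw.get("task") or {})
    name = task_section.pop("name", None)
    if name not in (TASK_MIXED, TASK_GONOGO):
        raise ValueError(
            f"config field task.name must be one of "
            f"({TASK_MIXED!r}, {TASK_GONOGO!r}), got {name!r}")
    try:
        factory = (TaskConfig.mixed_valence if name == TASK_MIXED
                   else TaskConfig.go_nogo)
        if "trial_mix" in task_section:
            task_section["trial_mix"] = dict(task_section["trial_mix"])
        if "jitter" in task_section:
            task_section["jitter"] = tuple(task_section["jitter"])
        task = factory(**task_section)
    except (TypeError, ValueError) as exc:
        raise _validation_error("task", exc) from exc
    try:
        params = FreeParams(**(raw.get("params") or {}))
    except (TypeError, ValueError) as exc:
        raise _validation_error("params", exc) from exc
    control_section = raw.get("control") or {}
    try:
        kappa = float(control_section.get("kappa", params.kappa))
        ctrl = ControlConfig.for_task(task, kappa)
    except (TypeError, ValueError) as exc:
        raise _validation_error("control", exc) from exc
    try:
        da = DAConfig.for_task(name, **(raw.get("da") or {}))
    except (TypeError, ValueError) as exc:
        raise _validation_error("da", exc) from exc
    fit_section = dict(raw.get("fit") or {})
    fit_data = fit_section.pop("data", None)
    if "free" in fit_section:
        fit_section["free"] = tuple(fit_section["free"])
    try:
        if name == TASK_MIXED:
            fitcfg = FitConfig.mixed_valence_default(**fit_section)
        else:
            fitcfg = FitConfig.go_nogo_default(**fit_section)
    except (TypeError, ValueError) as exc:
        raise _validation_error("fit", exc) from exc
    solver = raw.get("solver") or {}
    sim = raw.get("simulate") or {}
    noise = NoiseModel(sd=sim.get("noise_sd"),
                       drift_amplitude=sim.get("drift_amplitude", 0.0))
    return RunConfig(
        task=task, params=params, ctrl=ctrl, da=da, fit=fitcfg,
        n_grid=int(solver.get("n_grid", 200)),
        solver_tol=float(solver.get("tol", 1e-8)),
        max_iter=int(solver.get("max_iter", 10_000)),
        error_rt_mode=str(solver.get("error_rt_mode", "truncated")),
        simulate_n_trials=int(sim.get("n_trials", 500)),
        simulate_n_sessions=int(sim.get("n_sessions", 9)),
        noise=noise, fit_data=fit_data, raw=raw,
    )


def example_config_path(name: str) -> Path:
    """Path of a packaged example configuration.

    Available: ``mixed_valence_good``, ``mixed_valence_poor``, ``go_nogo``.
    """
    resource = importlib.resources.files("controlda") / "configs" / (
        f"{name}.yaml")
    if not resource.is_file():
        raise FileNotFoundError(f"no packaged config named {name!r}")
    return Path(str(resource))


@dataclass
class RunManifest:
    """Record of one pipeline run: inputs, seeds, versions, outputs."""

    command: str
    config_path: str
    config: dict
    seed: int
    version: str
    outputs: list[str] = field(default_factory=list)
    status: str = "ok"

    def write(self, out_dir: Path) -> Path:
        path = out_dir / "manifest.json"
        with open(path, "w") as fh:
            json.dump(dataclasses.asdict(self), fh, indent=2, sort_keys=True)
        return path


def _solve(rc: RunConfig):
    return solve_self_consistent(rc.task, rc.params, rc.ctrl,
                                 grid=rc.grid(), tol=rc.solver_tol,
                                 max_iter=rc.max_iter,
                                 error_rt_mode=rc.error_rt_mode)


def run_pipeline(command: str, config_path, seed: int = 0,
                 out_dir="runs", log_level: str = "INFO") -> RunManifest:
    """Execute one pipeline stage and write its artifacts.

    solve     -> solution.json + latency_densities.csv
    predict   -> behaviour.csv + da_traces.csv + td_errors.json
    fit       -> fit_result.json + fitted_params.csv
    simulate  -> trials.csv + traces.csv + behaviour.csv
    analyze   -> analysis.json (preprocessing + paired NGL t-test)
    """
    logging.basicConfig(level=getattr(logging, log_level.upper(), "INFO"))
    if command not in COMMANDS:
        raise ValueError(f"unknown command {command!r}; pick from {COMMANDS}")
    rc = load_config(config_path)
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    manifest = RunManifest(command=command, config_path=str(config_path),
                           config=rc.raw, seed=seed, version=__version__)

    def record(path: Path) -> Path:
        manifest.outputs.append(str(path))
        return path

    log.info("running %s (seed %d) -> %s", command, seed, out)
    if command == "solve":
        sol = _solve(rc)
        sol.to_json(record(out / "solution.json"))
        sol.densities_frame().to_csv(record(out / "latency_densities.csv"),
                                     index=False)
        log.info("rho = %.6f (converged in %d iterations)", sol.rho,
                 sol.n_iter)
    elif command == "predict":
        sol = _solve(rc)
        pred = predict_behaviour(sol, rc.ctrl, rc.params, rc.task)
        pred.to_csv(record(out / "behaviour.csv"))
        frames = []
        for label in rc.task.labels:
            for outcome in ("success", "fail"):
                trace = condition_average_trace(label, outcome, sol, rc.ctrl,
                                                rc.da)
                frames.append(trace.to_frame(trial_type=label,
                                             condition=outcome))
        pd.concat(frames, ignore_index=True).to_csv(
            record(out / "da_traces.csv"), index=False)
        tds = {}
        for label in rc.task.labels:
            tds[f"{label}|C=0"] = cue_td_error(label, 0, sol, rc.ctrl).delta
            if label in rc.ctrl.kappa:
                tds[f"{label}|C=1"] = cue_td_error(label, 1, sol,
                                                   rc.ctrl).delta
        with open(record(out / "td_errors.json"), "w") as fh:
            json.dump(tds, fh, indent=2, sort_keys=True)
    elif command == "fit":
        if not rc.fit_data:
            raise ValueError("config section fit needs a 'data' CSV path")
        data = BehaviourSummary.from_csv(rc.fit_data)
        fitcfg = dataclasses.replace(rc.fit, seed=seed)
        result = fit(data, rc.task, rc.ctrl, fitcfg, base_params=rc.params,
                     dacfg=rc.da)
        result.to_json(record(out / "fit_result.json"))
        rows = [{"parameter": n, "value": getattr(result.params, n)}
                for n in fitcfg.free]
        pd.DataFrame(rows).to_csv(record(out / "fitted_params.csv"),
                                  index=False)
    elif command == "simulate":
        sol = _solve(rc)
        sessions = sample_sessions(rc.task, rc.params, rc.ctrl,
                                   n_trials=rc.simulate_n_trials,
                                   n_sessions=rc.simulate_n_sessions,
                                   seed=seed, sol=sol)
        dacfg = dataclasses.replace(rc.da, pre_window=max(rc.da.pre_window,
                                                          1.0))
        sessions = synth_da_traces(sessions, sol, dacfg, rc.noise, seed=seed)
        write_sessions(sessions, record(out / "trials.csv"),
                       record(out / "traces.csv"))
        summarize_sessions(sessions, rc.task,
                           rc.error_rt_mode).to_csv(
            record(out / "behaviour.csv"))
    elif command == "analyze":
        if rc.task.task != TASK_GONOGO:
            raise ValueError("analyze requires the go_nogo task (NGL test)")
        sol = _solve(rc)
        sessions = sample_sessions(rc.task, rc.params, rc.ctrl,
                                   n_trials=rc.simulate_n_trials,
                                   n_sessions=rc.simulate_n_sessions,
                                   seed=seed, sol=sol)
        dacfg = dataclasses.replace(rc.da, pre_window=max(rc.da.pre_window,
                                                          1.0))
        sessions = synth_da_traces(sessions, sol, dacfg, rc.noise, seed=seed)
        result = ngl_success_fail_test(sessions)
        report = {"t": result.t, "df": result.df, "p_one_tailed": result.p,
                  "n_sessions": len(result.session_means)}
        with open(record(out / "analysis.json"), "w") as fh:
            json.dump(report, fh, indent=2, sort_keys=True)
    manifest.write(out)
    return manifest


@click.command()
@click.argument("command", type=click.Choice(COMMANDS))
@click.option("--config", "config_path", required=True,
              type=click.Path(exists=True), help="YAML run configuration.")
@click.option("--seed", default=0, show_default=True, type=int)
@click.option("--out", "out_dir", default="runs", show_default=True)
@click.option("--log-level", default="INFO", show_default=True)
def main(command: str, config_path: str, seed: int, out_dir: str,
         log_level: str) -> None:
    """Run one stage of the modelling pipeline."""
    run_pipeline(command, config_path, seed=seed, out_dir=out_dir,
                 log_level=log_level)
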