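"""Task structure, elementary value operations, and the solver fixed point."""

from types import SimpleNamespace

import numpy as np
import pytest

from controlda import (
    ControlConfig,
    FreeParams,
    LatencyGrid,
    TaskConfig,
    TrialType,
    q_leave_gng,
    q_other_mv,
    q_press_mv,
    solve_self_consistent,
    success_prob_nogo,
    terminal_values,
    v_out,
)


def _fake_sol(**kw):
    """Duck-typed stand-in for a ValueSolution in elementary-op tests."""
    defaults = dict(rho=0.0, params=FreeParams(),
                    v_succ={}, v_fail={}, grid=None)
    defaults.update(kw)
    return SimpleNamespace(**defaults)


class TestTrialTypesAndConfigs:
    def test_label_must_match_task(self):
        TrialType("mixed_valence", "shk")
        TrialType("go_nogo", "ngl")
        with pytest.raises(ValueError):
            TrialType("mixed_valence", "ngl")
        with pytest.raises(ValueError):
            TrialType("bogus", "shk")

    @pytest.mark.parametrize("bad", [
        dict(trial_mix={"rew": 0.5, "neu": 0.5, "shk": 0.5}),
        dict(c_p=0.2),
        dict(tau_min=5.0, tau_max=2.0),
        dict(jitter=(1.9, 1.7)),
        dict(r_O=-1.0),
    ])
    def test_config_validation(self, bad):
        with pytest.raises(ValueError):
            TaskConfig.mixed_valence(**bad)

    def test_grid_invariants(self):
        grid = LatencyGrid.uniform(0.5, 20.0, 200)
        assert np.all(np.diff(grid.nodes) > 0)
        assert np.all(grid.weights > 0)
        assert grid.weights.sum() == pytest.approx(19.5)
        with pytest.raises(ValueError):
            LatencyGrid(np.array([1.0, 0.5]), np.array([0.5, 0.5]))


class TestNogoSuccessGeometry:
    @pytest.mark.parametrize("tau, expected", [
        (1.6, 0.0),            # below the lower jitter bound
        (1.7, 0.0),
        (1.8, 0.5),            # uniform CDF midpoint
        (1.9, 1.0),            # upper jitter bound: certain success
        (5.0, 1.0),
    ])
    def test_uniform_cdf(self, tau, expected, gng_cfg):
        assert success_prob_nogo(tau, gng_cfg) == pytest.approx(expected)

    def test_negative_latency_rejected(self, gng_cfg):
        with pytest.raises(ValueError):
            success_prob_nogo(-0.1, gng_cfg)


class TestMixedValenceValues:
    def test_press_value_hand_arithmetic(self, mv_cfg):
        sol = _fake_sol(rho=0.1, v_succ={"rew": 3.0}, v_fail={"rew": 0.0})
        # c_p/tau + V_succ - rho*tau = -0.1 + 3 - 0.1
        assert q_press_mv("rew", 1.0, sol, mv_cfg) == pytest.approx(2.8)

    def test_press_value_costless_limit(self, mv_cfg):
        sol = _fake_sol(params=FreeParams(c_p=0.0),
                        v_succ={"neu": 1.23}, v_fail={"neu": -1.0})
        assert q_press_mv("neu", 2.0, sol, mv_cfg) == pytest.approx(1.23)

    def test_press_past_deadline_uses_failure_value(self, mv_cfg):
        sol = _fake_sol(rho=0.2, v_succ={"shk": 5.0}, v_fail={"shk": -7.0})
        # tau = 15 > tau_D = 10: failure value, time charge rho * tau_D
        expected = -0.1 / 15.0 - 7.0 - 0.2 * 10.0
        assert q_press_mv("shk", 15.0, sol, mv_cfg) == pytest.approx(expected)

    def test_press_latency_out_of_range(self, mv_cfg):
        sol = _fake_sol(v_succ={"rew": 0.0}, v_fail={"rew": 0.0})
        with pytest.raises(ValueError):
            q_press_mv("rew", 0.1, sol, mv_cfg)

    def test_other_value(self, mv_cfg):
        sol = _fake_sol(rho=0.05, params=FreeParams(r_O=0.2),
                        v_fail={"neu": -1.0})
        assert q_other_mv("neu", sol, mv_cfg) == pytest.approx(0.5)
        sol0 = _fake_sol(v_fail={"neu": -1.0})
        assert q_other_mv("neu", sol0, mv_cfg) == pytest.approx(-1.0)


class TestTerminalValues:
    def test_mixed_valence_at_zero_gain(self, mv_cfg):
        assert terminal_values("rew", 0.0, mv_cfg) == (4.0, 0.0)
        assert terminal_values("shk", 0.0, mv_cfg) == (0.0, -10.0)
        assert terminal_values("neu", 0.0, mv_cfg) == (0.0, 0.0)

    def test_iti_opportunity_cost(self, mv_cfg):
        v_succ, v_fail = terminal_values("rew", 0.1, mv_cfg)
        assert v_succ == pytest.approx(4.0 - 2.0)
        assert v_fail == pytest.approx(-2.0)

    def test_go_nogo(self, gng_cfg):
        assert terminal_values("gl", 0.0, gng_cfg)[1] == 0.0
        v_succ, v_fail = terminal_values("gl", 0.1, gng_cfg)
        assert v_succ == pytest.approx(2.0 - 0.5)
        assert v_fail == pytest.approx(-1.0)


class TestGoNogoValues:
    @staticmethod
    def _toy_sol(gng_cfg, beta=1.0, beta_tau=1.0, rho=0.0):
        params = FreeParams(beta=beta, beta_tau=beta_tau,
                            r_O=0.0, c_p=0.0, c_f=0.0, c_l=0.0)
        grid = LatencyGrid.for_task(gng_cfg, 400)
        return SimpleNamespace(rho=rho, params=params, grid=grid,
                               v_succ={"gl": 1.0, "gs": 1.0},
                               v_fail={"gl": 0.0, "gs": 0.0})

    def test_exit_value_against_brute_force_grid(self, gng_cfg):
        """v_out matches a direct quadrature of the post-exit sub-choice."""
        sol = self._toy_sol(gng_cfg)
        for t in (0.0, 2.0, 7.5):
            tau2 = sol.grid.nodes
            w = sol.grid.weights
            rem = gng_cfg.tau_D - t
            q2 = np.where(tau2 <= rem, 1.0 - 0.0 * tau2, 0.0)
            p2 = np.exp(q2 - q2.max())
            p2 /= np.sum(w * p2)
            q_bar = np.sum(w * p2 * q2)
            p_press = 1.0 / (1.0 + np.exp(-(q_bar - 0.0)))
            expected = p_press * q_bar
            assert v_out("gl", t, sol, gng_cfg) == pytest.approx(
                expected, rel=1e-9)

    def test_exit_at_deadline_is_failure_value(self, gng_cfg):
        sol = self._toy_sol(gng_cfg)
        sol.v_fail = {"gl": -0.4, "gs": -0.4}
        assert v_out("gl", gng_cfg.tau_D, sol, gng_cfg) == pytest.approx(-0.4)

    def test_greedy_limit_takes_better_option(self, gng_cfg):
        sol = self._toy_sol(gng_cfg, beta=1e3, beta_tau=1e3)
        # press (value ~1) dominates other (value 0): v_out -> max press value
        assert v_out("gl", 1.0, sol, gng_cfg) == pytest.approx(1.0, abs=0.01)

    def test_v_out_domain(self, gng_cfg):
        sol = self._toy_sol(gng_cfg)
        with pytest.raises(ValueError):
            v_out("gl", gng_cfg.tau_D + 1.0, sol, gng_cfg)
        with pytest.raises(ValueError):
            v_out("ngl", 1.0, sol, gng_cfg)

    def test_nogo_leave_value_hand_arithmetic(self, gng_cfg):
        params = FreeParams(c_f=-0.44, c_l=-0.10, c_p=0.0, r_O=0.0)
        grid = LatencyGrid.for_task(gng_cfg, 100)
        sol = SimpleNamespace(rho=0.0, params=params, grid=grid,
                              v_succ={"ngl": 1.0}, v_fail={"ngl": 0.0})
        # tau = 2 s: certain success; -0.88 - 0.05 + 1
        assert q_leave_gng("ngl", 2.0, sol, gng_cfg) == pytest.approx(0.07)

    def test_nogo_early_exit_certain_failure(self, gng_cfg):
        params = FreeParams(c_f=0.0, c_l=0.0, c_p=0.0, r_O=0.0)
        grid = LatencyGrid.for_task(gng_cfg, 100)
        sol = SimpleNamespace(rho=0.0, params=params, grid=grid,
                              v_succ={"ngl": 5.0}, v_fail={"ngl": -1.0})
        assert q_leave_gng("ngl", 1.5, sol, gng_cfg) == pytest.approx(-1.0)

    def test_go_leave_reduces_to_exit_value_without_costs(self, gng_cfg):
        sol = self._toy_sol(gng_cfg)
        tau = 3.0
        assert q_leave_gng("gl", tau, sol, gng_cfg) == pytest.approx(
            v_out("gl", tau, sol, gng_cfg))


class TestSelfConsistentSolver:
    def test_all_zero_task_has_zero_gain_and_values(self):
        cfg = TaskConfig.mixed_valence(
            utilities={"rew": 0.0, "neu": 0.0, "shk": 0.0}, c_p=0.0)
        params = FreeParams()
        ctrl = ControlConfig.for_task(cfg, 0.0)
        sol = solve_self_consistent(cfg, params, ctrl)
        assert sol.rho == pytest.approx(0.0, abs=1e-10)
        assert all(abs(v) < 1e-8 for v in sol.v_cue.values())

    def test_renewal_reward_rate_closed_form(self):
        """Forced press with uniform latency: rho = r / (cycle time)."""
        cfg = TaskConfig.mixed_valence(
            trial_mix={"rew": 1.0, "neu": 0.0, "shk": 0.0},
            tau_D=20.0, c_p=0.0)
        params = FreeParams(w_i=50.0)  # press with certainty
        ctrl = ControlConfig.for_task(cfg, 0.0)
        sol = solve_self_consistent(cfg, params, ctrl)
        mean_tau = 0.5 * (cfg.tau_min + cfg.tau_max)
        expected = 4.0 / (cfg.cue_to_lever + mean_tau + cfg.iti)
        assert sol.press_prob[("rew", 0)] == pytest.approx(1.0, abs=1e-9)
        assert sol.rho == pytest.approx(expected, rel=1e-6)

    def test_poor_avoider_regime(self, poor_setup):
        """Negative gain makes the neutral cue relatively attractive."""
        _, _, _, sol = poor_setup
        assert sol.rho < 0
        assert sol.v_cue["neu"] > 0

    def test_fixed_point_residual(self, poor_setup, gng_setup):
        for sol in (poor_setup[3], gng_setup[3]):
            assert sol.converged
            assert sol.residual <= 1e-8

    def test_differential_value_consistency(self, poor_setup, gng_setup):
        """Trial-mix-weighted cue value vanishes at the fixed point.

        With V(s_pre) = 0 as reference, the cycle identity requires the
        expected cue value over trial types to be zero.
        """
        for cfg, _, ctrl, sol in (poor_setup, gng_setup):
            mean = sum(cfg.trial_mix[l] * sol.v_cue[l] for l in cfg.labels)
            assert mean == pytest.approx(0.0, abs=1e-6)

    def test_gain_monotone_in_outcome_utilities(self):
        params = FreeParams.poor_avoider()

        def gain(r_rew, r_shk):
            cfg = TaskConfig.mixed_valence(
                utilities={"rew": r_rew, "neu": 0.0, "shk": r_shk})
            ctrl = ControlConfig.for_task(cfg, params.kappa)
            return solve_self_consistent(cfg, params, ctrl).rho

        assert gain(6.0, -10.0) >= gain(4.0, -10.0)
        assert gain(4.0, -14.0) <= gain(4.0, -10.0)

    def test_grid_refinement_stability(self, mv_cfg):
        params = FreeParams.poor_avoider()
        ctrl = ControlConfig.for_task(mv_cfg, params.kappa)
        rho200 = solve_self_consistent(
            mv_cfg, params, ctrl, grid=LatencyGrid.for_task(mv_cfg, 200)).rho
        rho400 = solve_self_consistent(
            mv_cfg, params, ctrl, grid=LatencyGrid.for_task(mv_cfg, 400)).rho
        assert abs(rho400 - rho200) < 1e-3

    def test_nonconvergence_reports_residual(self, mv_cfg):
        params = FreeParams.poor_avoider()
        ctrl = ControlConfig.for_task(mv_cfg, params.kappa)
        with pytest.raises(RuntimeError, match="residual"):
            solve_self_consistent(mv_cfg, params, ctrl, max_iter=2)

    def test_densities_normalized(self, poor_setup, gng_setup):
        for _, _, _, sol in (poor_setup, gng_setup):
            for dens in sol.latency_density.values():
                assert np.sum(sol.grid.weights * dens) == pytest.approx(1.0)

    def test_solution_export_round_trip(self, tmp_path, poor_setup):
        _, _, _, sol = poor_setup
        path = tmp_path / "solution.json"
        sol.to_json(path)
        import json

        payload = json.loads(path.read_text())
        assert payload["rho"] == pytest.approx(sol.rho)
        frame = sol.densities_frame()
        assert set(frame.columns) == {"tau", "density", "trial_type",
                                      "control_flag"}
        assert len(frame) == len(sol.latency_density) * sol.grid.nodes.size
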