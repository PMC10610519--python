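"""Forward sampling, trace synthesis, and the voltammetry analysis chain."""

from types import SimpleNamespace

import numpy as np
import pandas as pd
import pytest

from controlda import (
    DAConfig,
    DATrace,
    NoiseModel,
    cue_da_trace,
    fscv_preprocess,
    ngl_success_fail_test,
    predict_behaviour,
    sample_sessions,
    summarize_sessions,
    synth_da_traces,
)
from controlda.synthetic_data import (
    SyntheticSession,
    read_sessions,
    write_sessions,
)


class TestSampling:
    def test_same_seed_reproduces_sessions(self, poor_setup):
        cfg, params, ctrl, sol = poor_setup
        a = sample_sessions(cfg, params, ctrl, 200, n_sessions=2, seed=11,
                            sol=sol)
        b = sample_sessions(cfg, params, ctrl, 200, n_sessions=2, seed=11,
                            sol=sol)
        for sa, sb in zip(a, b):
            pd.testing.assert_frame_equal(sa.trials, sb.trials)

    def test_degenerate_policy_yields_identical_trials(self, poor_setup):
        """Press probability one and a point-mass latency density collapse
        every trial onto the same record."""
        cfg, params, ctrl, sol = poor_setup
        grid = sol.grid
        point = np.zeros_like(grid.nodes)
        j = 10
        point[j] = 1.0 / grid.weights[j]
        fake = SimpleNamespace(
            grid=grid,
            press_prob={(lab, C): 1.0 for lab in cfg.labels for C in (0, 1)},
            latency_density={(lab, C): point for lab in cfg.labels
                             for C in (0, 1)},
        )
        sessions = sample_sessions(cfg, params, ctrl, 100, n_sessions=1,
                                   seed=0, sol=fake)
        trials = sessions[0].trials
        assert (trials["action"] == "press").all()
        assert trials["latency"].nunique() == 1
        assert trials["latency"].iloc[0] == pytest.approx(grid.nodes[j])

    @pytest.mark.parametrize("setup", ["poor_setup", "gng_setup"])
    def test_empirical_rates_match_analytic_marginal(self, setup, request):
        cfg, params, ctrl, sol = request.getfixturevalue(setup)
        sessions = sample_sessions(cfg, params, ctrl, 10_000, n_sessions=1,
                                   seed=7, sol=sol)
        summary = summarize_sessions(sessions, cfg)
        pred = predict_behaviour(sol, ctrl, params, cfg)
        trials = sessions[0].trials
        for label in cfg.labels:
            n = int((trials["trial_type"] == label).sum())
            p = pred.success_rate(label)
            se = max(np.sqrt(p * (1 - p) / n), 1e-4)
            assert abs(summary.success_rate(label) - p) < 3 * se

    def test_latencies_within_grid_bounds(self, gng_setup):
        cfg, params, ctrl, sol = gng_setup
        sessions = sample_sessions(cfg, params, ctrl, 500, n_sessions=1,
                                   seed=1, sol=sol)
        lat = sessions[0].trials["latency"].dropna()
        assert lat.between(cfg.tau_min, cfg.tau_max).all()


class TestTraceSynthesis:
    def test_noiseless_traces_equal_model_traces(self, gng_setup):
        cfg, params, ctrl, sol = gng_setup
        dacfg = DAConfig.for_task(cfg.task, pre_window=1.0)
        sessions = sample_sessions(cfg, params, ctrl, 50, n_sessions=1,
                                   seed=2, sol=sol)
        sessions = synth_da_traces(sessions, sol, dacfg,
                                   NoiseModel(sd=0.0), seed=2)
        trials = sessions[0].trials
        for i in range(len(trials)):
            clean = cue_da_trace(trials["trial_type"][i],
                                 int(trials["control"][i]), sol, dacfg)
            assert np.allclose(sessions[0].traces[i], clean.values)

    def test_noise_averages_out(self, gng_setup):
        cfg, params, ctrl, sol = gng_setup
        dacfg = DAConfig.for_task(cfg.task, pre_window=1.0)
        sessions = sample_sessions(cfg, params, ctrl, 800, n_sessions=1,
                                   seed=3, sol=sol)
        noisy = synth_da_traces(sessions, sol, dacfg, NoiseModel(sd=0.5),
                                seed=3)
        clean = synth_da_traces(sessions, sol, dacfg, NoiseModel(sd=0.0),
                                seed=3)
        residual = noisy[0].traces - clean[0].traces
        assert abs(residual.mean()) < 3 * 0.5 / np.sqrt(residual.size)

    def test_default_noise_calibrated_to_peak(self, gng_setup):
        cfg, params, ctrl, sol = gng_setup
        dacfg = DAConfig.for_task(cfg.task, pre_window=1.0)
        sessions = sample_sessions(cfg, params, ctrl, 20, n_sessions=1,
                                   seed=4, sol=sol)
        out = synth_da_traces(sessions, sol, dacfg, NoiseModel(), seed=4)
        sd = out[0].meta["noise_sd"]
        assert sd > 0  # SNR ~ 1 at the kernel peak


class TestPreprocessing:
    t = np.arange(-100, 300) * 0.01  # 1 s pre-cue, 3 s post

    def test_constant_maps_to_zero(self):
        trace = DATrace(self.t, np.full(self.t.size, 3.7))
        out = fscv_preprocess(trace)
        assert np.allclose(out.values, 0.0, atol=1e-12)

    def test_step_becomes_ramp_of_window_width(self):
        """Smoothing a step with a centered boxcar yields a linear ramp of
        width one window; checked against an independent filter oracle."""
        from scipy.ndimage import uniform_filter1d

        values = np.where(self.t >= 0.5, 1.0, 0.0)
        out = fscv_preprocess(DATrace(self.t, values), smooth_window=0.5)
        oracle = uniform_filter1d(values, size=50, mode="nearest")
        interior = slice(50, values.size - 50)
        assert np.allclose(out.values[interior], oracle[interior], atol=0.03)
        ramp = (self.t >= 0.3) & (self.t <= 0.7)
        assert np.all(np.diff(out.values[ramp]) >= -1e-12)
        assert np.allclose(out.values[self.t < 0.2], 0.0, atol=1e-9)
        assert np.allclose(out.values[self.t > 0.8], 1.0, atol=1e-9)

    def test_linear_in_input(self):
        rng = np.random.default_rng(0)
        x = rng.normal(size=self.t.size)
        y = rng.normal(size=self.t.size)
        fx = fscv_preprocess(DATrace(self.t, x)).values
        fy = fscv_preprocess(DATrace(self.t, y)).values
        fxy = fscv_preprocess(DATrace(self.t, 2.0 * x - 0.5 * y)).values
        assert np.allclose(fxy, 2.0 * fx - 0.5 * fy, atol=1e-10)

    def test_flat_baseline_is_preserved(self):
        """A trace already flat and zero before the cue is unchanged in its
        baseline: preprocessing twice equals preprocessing once."""
        values = np.where(self.t >= 1.0, np.sin(self.t), 0.0)
        once = fscv_preprocess(DATrace(self.t, values))
        twice = fscv_preprocess(DATrace(once.t, once.values))
        assert np.allclose(
            twice.values[:150],  # well before the second smoothing reaches 1s
            fscv_preprocess(DATrace(self.t, once.values)).values[:150])

    def test_requires_precue_samples(self):
        t = np.arange(0, 300) * 0.01
        with pytest.raises(ValueError):
            fscv_preprocess(DATrace(t, np.zeros(t.size)))


def _session_with_traces(sid, succ_vals, fail_vals, t):
    """One session with NGL trials whose integrated DA is controlled."""
    n = len(succ_vals) + len(fail_vals)
    trials = pd.DataFrame({
        "trial_type": ["ngl"] * n,
        "control": [0] * n,
        "action": ["leave"] * n,
        "latency": [2.0] * n,
        "success": [True] * len(succ_vals) + [False] * len(fail_vals),
        "rt": [2.0] * n,
    })
    traces = np.array([np.full(t.size, v)
                       for v in list(succ_vals) + list(fail_vals)])
    return SyntheticSession(session_id=sid, trials=trials, seed=0,
                            traces=traces, trace_t=t)


class TestNglPairedTest:
    t = np.arange(-100, 300) * 0.01

    def test_identical_conditions_give_zero_statistic(self):
        sessions = [_session_with_traces(i, [0.3, 0.3], [0.3], self.t)
                    for i in range(4)]
        res = ngl_success_fail_test(sessions, preprocess=False)
        assert res.t == 0.0
        assert res.df == 3

    def test_matches_textbook_paired_t(self):
        """Session means are constants, so the statistic must equal the
        hand-computed paired t for those pairs."""
        succ = [0.1, 0.2, 0.15, 0.05, 0.3]
        fail = [0.4, 0.5, 0.2, 0.35, 0.45]
        sessions = [_session_with_traces(i, [s], [f], self.t)
                    for i, (s, f) in enumerate(zip(succ, fail))]
        res = ngl_success_fail_test(sessions, preprocess=False)
        # integration over 1 s of a constant-c trace gives c
        d = np.array(fail) - np.array(succ)
        expected_t = d.mean() / (d.std(ddof=1) / np.sqrt(d.size))
        assert res.t == pytest.approx(expected_t, rel=1e-6)
        assert res.df == len(succ) - 1
        from scipy import stats

        assert res.p == pytest.approx(
            stats.t.sf(expected_t, df=res.df), rel=1e-6)

    def test_incomplete_sessions_excluded_with_warning(self):
        good = [_session_with_traces(i, [0.1], [0.4 + i * 0.1], self.t)
                for i in range(3)]
        lame = _session_with_traces(9, [0.2], [], self.t)
        with pytest.warns(UserWarning, match="lacks one NGL outcome"):
            res = ngl_success_fail_test(good + [lame], preprocess=False)
        assert res.df == 2

    def test_too_few_sessions_is_an_error(self):
        sessions = [_session_with_traces(0, [0.1], [0.2], self.t)]
        with pytest.raises(ValueError):
            ngl_success_fail_test(sessions, preprocess=False)

    def test_synthetic_gng_pipeline_df(self, gng_setup):
        """Nine synthetic sessions produce the expected df = 8."""
        cfg, params, ctrl, sol = gng_setup
        dacfg = DAConfig.for_task(cfg.task, pre_window=1.0)
        sessions = sample_sessions(cfg, params, ctrl, 80, n_sessions=9,
                                   seed=5, sol=sol)
        sessions = synth_da_traces(sessions, sol, dacfg, NoiseModel(sd=0.3),
                                   seed=5)
        res = ngl_success_fail_test(sessions)
        assert res.df == 8
        assert np.isfinite(res.t)
        assert 0.0 <= res.p <= 1.0


class TestSessionIO:
    def test_csv_round_trip(self, tmp_path, gng_setup):
        cfg, params, ctrl, sol = gng_setup
        dacfg = DAConfig.for_task(cfg.task, pre_window=0.5, dt=0.05)
        sessions = sample_sessions(cfg, params, ctrl, 20, n_sessions=2,
                                   seed=6, sol=sol)
        sessions = synth_da_traces(sessions, sol, dacfg, NoiseModel(sd=0.1),
                                   seed=6)
        trials_path = tmp_path / "trials.csv"
        traces_path = tmp_path / "traces.csv"
        write_sessions(sessions, trials_path, traces_path)
        back = read_sessions(trials_path, traces_path)
        assert len(back) == 2
        for orig, rt in zip(sessions, back):
            pd.testing.assert_frame_equal(
                orig.trials.reset_index(drop=True), rt.trials,
                check_dtype=False)
            assert np.allclose(orig.traces, rt.traces)
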