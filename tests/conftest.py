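import pytest

from controlda import (
    ControlConfig,
    FreeParams,
    TaskConfig,
    solve_self_consistent,
)


@pytest.fixture(scope="session")
def mv_cfg():
    return TaskConfig.mixed_valence()


@pytest.fixture(scope="session")
def gng_cfg():
    return TaskConfig.go_nogo()


@pytest.fixture(scope="session")
def poor_setup(mv_cfg):
    """Converged poor-avoider mixed-valence solution."""
    params = FreeParams.poor_avoider()
    ctrl = ControlConfig.for_task(mv_cfg, params.kappa)
    sol = solve_self_consistent(mv_cfg, params, ctrl)
    return mv_cfg, params, ctrl, sol


@pytest.fixture(scope="session")
def good_setup(mv_cfg):
    """Converged good-avoider mixed-valence solution."""
    params = FreeParams.good_avoider()
    ctrl = ControlConfig.for_task(mv_cfg, params.kappa)
    sol = solve_self_consistent(mv_cfg, params, ctrl)
    return mv_cfg, params, ctrl, sol


@pytest.fixture(scope="session")
def gng_setup(gng_cfg):
    """Converged Go/No-Go solution at the fitted parameters."""
    params = FreeParams.go_nogo_fit()
    ctrl = ControlConfig.for_task(gng_cfg, params.kappa)
    sol = solve_self_consistent(gng_cfg, params, ctrl)
    return gng_cfg, params, ctrl, sol
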