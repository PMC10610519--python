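"""Opponent-stabilized plasticity of the counterfactual baseline.

Reframing poses a stability puzzle: the reframed cue TD error is persistently
non-zero, so ordinary TD plasticity acting on the counterfactual baseline
state would relearn it away — the baseline V(s_fail) drifts towards the cue
value until the error cancels.  An opponent prediction error, subtracted from
the dopaminergic one inside the update, halts that drift: the baseline is
stationary exactly where the two errors agree.

Updates here are pure functions of a small state; proportionality constants
are absorbed into the learning rate.
"""

from __future__ import annotations

from dataclasses import dataclass, replace
from typing import Callable

import pandas as pd

__all__ = ["OpponentState", "naive_update", "opponent_update", "simulate"]


@dataclass(frozen=True)
class OpponentState:
    """Counterfactual baseline, the cue value it is measured against, and
    the (exogenous) opponent error."""

    v_fail: float
    v_cue: float = 0.0
    delta_tilde: float = 0.0
    eta: float = 0.1

    def __post_init__(self) -> None:
        if self.eta <= 0:
            raise ValueError("learning rate eta must be positive")

    @property
    def delta(self) -> float:
        """Dopaminergic prediction error, recomputed from the current state."""
        return self.v_cue - self.v_fail


def naive_update(state: OpponentState) -> OpponentState:
    """One step of unopposed TD plasticity on the baseline.

    Drives delta to zero, i.e. unlearns the reframing.
    """
    return replace(state, v_fail=state.v_fail + state.eta * state.delta)


def opponent_update(state: OpponentState) -> OpponentState:
    """One step of opponent-stabilized plasticity.

    The baseline moves in proportion to delta - delta_tilde, so it is
    stationary exactly when the dopaminergic and opponent errors agree; the
    map is a contraction for eta < 2 and converges to
    v_fail = v_cue - delta_tilde.
    """
    step = state.eta * (state.delta - state.delta_tilde)
    return replace(state, v_fail=state.v_fail + step)


def simulate(update: Callable[[OpponentState], OpponentState],
             state: OpponentState, n_steps: int) -> pd.DataFrame:
    """Iterate an update rule, returning the trajectory as a data frame."""
    rows = []
    for step in range(n_steps + 1):
        rows.append({"step": step, "v_fail": state.v_fail,
                     "delta": state.delta,
                     "delta_tilde": state.delta_tilde})
        if step < n_steps:
            state = update(state)
    return pd.DataFrame(rows)
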