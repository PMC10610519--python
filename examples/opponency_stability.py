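"""Why the reframed baseline survives: naive vs opponent plasticity.

Under naive TD plasticity the counterfactual baseline V(s_fail) is dragged
onto the cue value until the reframed error vanishes, silently dismantling
the reframing.  With an opponent prediction error subtracted inside the
update, the baseline is stationary exactly where the dopaminergic and
opponent errors agree.
"""

from controlda import OpponentState, naive_update, opponent_update, simulate

start = OpponentState(v_fail=-10.0, v_cue=-3.0, delta_tilde=7.0, eta=0.2)

naive = simulate(naive_update, start, 60)
print("naive plasticity: V(s_fail) %.2f -> %.4f, delta %.2f -> %.6f"
      % (naive["v_fail"].iloc[0], naive["v_fail"].iloc[-1],
         naive["delta"].iloc[0], naive["delta"].iloc[-1]))

opp = simulate(opponent_update, start, 60)
print("opponent rule:    V(s_fail) %.2f -> %.4f, delta %.2f -> %.6f"
      % (opp["v_fail"].iloc[0], opp["v_fail"].iloc[-1],
         opp["delta"].iloc[0], opp["delta"].iloc[-1]))
print("(delta stays at delta_tilde = %.1f: reframing is stable)"
      % start.delta_tilde)
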