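# controlda

Average-reward reinforcement-learning models of Pavlovian–instrumental
conflict, with dopamine treated as a *controlled controller*: a cognitive
control mechanism that manipulates the cue-evoked dopaminergic prediction
error itself.

## The problem

Pavlovian biases couple predicted value to action: appetitive predictions
energize responding, aversive predictions suppress it.  This collides with
task demands in two classic paradigms:

- **Active avoidance** (mixed-valence task): a tone warns of shock unless
  the animal presses a lever within 10 s.  The shock cue predicts negative
  value, which promotes freezing — the opposite of what is needed.
- **Omission / Go–No-Go**: reward is delivered only if a prepotent response
  is withheld while the tone plays.  The reward cue predicts positive
  value, which promotes action — again the opposite of what is needed.

The model resolves the conflict through *reframing*: with probability κ the
agent deploys control, which substitutes a counterfactual baseline `b` for
the pre-trial reference in the cue TD error,

    δ(s⁰) = V(s_cue) − V(s_pre),      V(s_pre) = 0   (no control)
    δ(s¹) = V(s_cue) − b                              (control)

with `b = r_shk` (full shock disutility) on shock trials and `b = r_L`
(full large-reward utility) on No-Go large-reward trials.  Because `b` lies
beyond `V(s_cue)`, reframing flips the sign of δ — the prospect of shock
becomes the prospect of safety, and the prospect of reward becomes the
prospect of its loss — harmonizing the Pavlovian bias with the
instrumental requirement.

Around this core the package provides:

- `controlda.task_mdp` — both tasks as recurrent semi-Markov decision
  problems in the average-reward setting, with hyperbolic vigour costs and
  latency choice, and a solver for the self-consistent fixed point
  {ρ, V, δ, policy};
- `controlda.control_policy` — the control decision, the Pavlovian-biased
  action and latency policies (`p(τ) ∝ exp{w_τⁱ Q(τ) − (w_τᵛ⁺[δ]₊ +
  w_τᵛ⁻[δ]₋)τ}` and the analogous press-vs-other logit), and analytic
  behaviour summaries;
- `controlda.dopamine` — the asymmetric DA code
  `δ^DA = α[δ]₊ + (1−α)[δ]₋` (α = 0.8), convolution with the alpha kernel
  `f(t) = (t/ξ)e^{1−t/ξ}` (ξ = 0.7 s), the 250 ms control delay, and
  outcome-conditioned trace mixtures via the posterior over control;
- `controlda.opponency` — the opponent learning rule
  `ΔV(s_fail) ∝ δ − δ̃` that keeps the counterfactual baseline from being
  unlearned;
- `controlda.fitting` — the summary-statistic objective
  `E(x) = Σ_χ|e^succ| + w_rtc Σ|e^rtc|/s^rtc + w_rte Σ|e^rte|/s^rte +
  w_DA e^DA + w_reg‖x‖₁` and a multi-start Nelder-Mead fitter;
- `controlda.synthetic_data` — forward-sampled sessions and noisy DA
  traces, voltammetry-style preprocessing, and the paired one-tailed
  t-test comparing failed and successful No-Go large-reward trials;
- `controlda.interface` — YAML configs, a `run_pipeline` orchestrator with
  manifests, and a thin `controlda` CLI.

## Worked example

`examples/solve_avoidance.py` solves the avoidance task for both fitted
avoider groups:

```
--- poor avoiders (kappa = 0.50) ---
rho = -0.0156 utility/s
cue values: {'rew': 4.135, 'neu': 0.44, 'shk': -4.575}
shock TD error: no control -4.575, control +5.425
            success_rate  rt_correct
trial_type
rew                0.969       0.721
neu                0.582       2.527
shk                0.503       0.740
```

Because shocks outweigh rewards, the average reward rate ρ is negative and
the neutral cue value is *positive* (a trial on which nothing bad happens
is better than average).  The shock-cue TD error is negative without
control and flips to +5.43 under reframing, and shock-trial success sits
near 50% — the poor-avoider signature.  `examples/dopamine_traces.py`
turns the same solution into DA transients:

```
rew|success: peak dDA = +3.308 a.u. at 0.70 s, minimum = +0.000
shk|success: peak dDA = +3.406 a.u. at 0.99 s, minimum = -0.622
shk|fail:    peak dDA = +0.000 a.u. at 0.00 s, minimum = -0.873
```

On successful shock trials the predicted transient is net positive and
nearly equal in peak to the reward-trial transient (the striking
similarity seen in the recorded data), with a brief initial dip before
control is applied; failed trials show pure suppression.  The other
examples cover opponency stability, synthetic-session analysis (the
paired NGL t-test reports `t(8)` on nine sessions), and parameter
recovery, where fitting 20 000 synthetic Go/No-Go trials returns
κ = 0.516 against a generating value of 0.50.

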