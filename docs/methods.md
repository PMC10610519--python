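# Methods

## Model overview

Both tasks are recurrent semi-Markov decision problems analysed in the
average-reward framework.  A trial begins at a pre-trial state `s_pre`
(the reference state, `V(s_pre) ≡ 0`, reflecting long, subjectively
uncertain inter-trial intervals).  A cue reveals the trial type χ; an
internal decision is then taken about deploying self-control (C = 1 with
probability κ_χ, and only on the conflicted trial types — shock trials in
the avoidance task, No-Go large-reward trials in the omission task; all
other types are forced C = 0).  An external decision determines success or
failure, the outcome and inter-trial interval follow, and the next trial
begins.  The gain ρ (utility per second) acts as the opportunity cost of
time and is shared across trial types.

The control decision does not change the instrumental problem — the states
`s⁰` and `s¹` have identical instrumental values — it changes only the
cue-evoked TD error, by substituting a counterfactual baseline for the
pre-trial reference:

    δ_χ(s⁰) = V_χ(s_cue) − V(s_pre),
    δ_χ(s¹) = V_χ(s_cue) − b_χ,

with `b_shk = r_shk` and `b_ngl = r_L`.  The TD error, in turn, biases
behaviour through non-negative Pavlovian weights on its positive and
negative parts, in both the action choice and the latency density.

### Mixed-valence (active avoidance) task

Trial types rew / neu / shk with outcome utilities 4 / 0 / −10; the
external choice between *press* (with a completion latency
τ ∈ [0.5, 20] s, deadline τ_D = 10 s) and *other* (an alternative activity
with utility rate r_O).  Press value:
`Q(press, τ) = c_p/τ + V(s′) − ρ·min(τ, τ_D)` where `s′` is the success
state iff τ ≤ τ_D; other: `Q(other) = r_O τ_D + V(s_fail) − ρ τ_D`.  The
vigour cost is hyperbolic (c_p/τ, shorter latencies cost more).  The
external choice is made at the cue; implementation starts at lever
insertion 5 s later, an interval charged to the trial cycle.  Terminal
values deliver the outcome utility minus ρ times the 20 s ITI.  Success on
any trial type means completing a press before the deadline.

### Go/No-Go (omission) task

Trial types gs / gl / ngs / ngl with rewards r_S = 1, r_L = 2.  The
external choice is the nose-poke leave time τ, with a linear fixation cost
rate c_f and hyperbolic leaving-vigour cost c_l/τ; leaving is
non-interruptible, so full costs accrue even when the tone ends earlier.
On No-Go trials success is the probability that the jittered tone offset
(uniform on [1.7, 1.9] s) precedes the exit.  On Go trials a post-exit,
purely instrumental sub-choice follows between pressing (latency softmax
with inverse temperature β^τ, then a logistic press-vs-other choice with
inverse temperature β) and *other*.  Success states pay the reward minus
ρ·τ_I (τ_I = 5 s); failures cost an additional τ_P = 5 s timeout.

### Policies

Latency / leave-time density:
`p(τ) ∝ exp{w_τⁱ Q(τ) − (w_τᵛ⁺ [δ]₊ + w_τᵛ⁻ [δ]₋) τ}` with
`[x]₊ = max(x, 0)` and `[x]₋ = min(x, 0)` kept signed, so positive errors
speed responding and negative errors slow it.  Press-vs-other choice
(avoidance task): logistic with press logit
`wⁱ ΔQ + w^{p+}[δ]₊ + w^{p−}[δ]₋` against a zero *other* logit — the only
reading of the two-option choice under which positive errors boost
pressing.  With all Pavlovian weights zero, behaviour is exactly invariant
to δ and hence to κ.

## Dopamine forward model

The dopaminergic component of the TD error is asymmetric,
`δ^DA = α[δ]₊ + (1−α)[δ]₋` with α = 0.8 (a 4:1 gain asymmetry favouring
better-than-expected transitions).  Concentration changes are the
convolution of TD impulses with the unit-peak alpha kernel
`f(t) = (t/ξ) e^{1−t/ξ}`, ξ = 0.7 s.  On control trials the unreframed
impulse at cue onset is followed by the reframed impulse after
τ_delay = 250 ms, and the two filtered transients are **summed** (the
delayed signal is described as following the initial one; a
replace-or-correct combination rule would be an alternative reading — the
sum is the package's choice and is isolated in `cue_da_trace`).
Outcome-conditioned averages weight the C = 0 and C = 1 traces by the
Bayes posterior over control given success or failure, using the solved
per-control-state success probabilities as likelihoods.  Traces are in
arbitrary units on a 10 ms grid over 5 s (avoidance) or 3 s (Go/No-Go)
after the cue; no attempt is made to calibrate to concentration units, and
movement- and outcome-period release is out of scope.

## Solver

The self-consistent solution couples ρ, the cue values, the TD errors and
the behavioural policy.  Two nested fixed points are solved:

1. **Cue values at fixed ρ.**  For each trial type, the cue value v
   satisfies `v = T(v)`, where T maps v to the policy-weighted expected
   action value (the policy depends on v through δ).  T's range is bounded
   by the extreme action values, so a root of `v − T(v)` is bracketed and
   found by Brent's method (xtol 1e−12).  This replaces naive damped
   iteration, which can oscillate or diverge when Pavlovian weights are
   large.
2. **Gain.**  ρ is a root of the renewal residual
   `E[utility per trial cycle]/E[cycle duration] − ρ`, with expectations
   under the current policy and trial mix.  The update is a guarded secant
   step (fallback: damped step, factor 0.5); iteration stops when one full
   update moves ρ by at most `tol` (default 1e−8, default cap 10 000
   evaluations; the fitter caps at 300 so that pathological parameter
   draws fail fast rather than burn the budget).

At the fixed point the trial-mix-weighted mean cue value is zero (the
cycle identity with `V(s_pre) = 0`); the test suite asserts this, the
renewal closed form on degenerate tasks, monotonicity of ρ in the outcome
utilities, and stability under grid refinement.

Latency integrals use a uniform 200-node grid on [τ_min, τ_max] with
trapezoidal weights (quadrature-normalized densities).  The Go-trial
post-exit tables are O(n²) in the grid size and are recomputed once per
candidate ρ.

### Behaviour summaries

Success rates marginalize the per-control-state success probabilities over
κ.  Mean RTs are latency-density means conditioned on the correct or error
event (avoidance: press before / after the deadline, error RTs counting
only trials on which press was chosen; Go/No-Go: exit latency split by
eventual success), mixed over control states with weights proportional to
P(C) times the conditioning-event probability.  Avoidance error RTs are
reported at the deadline by default (`error_rt_mode="truncated"`: the
failure is only observed when the deadline passes); the latent conditional
mean `E[τ | τ > τ_D]` is available as `"latent"`.

## Opponency

Ordinary TD plasticity applied to the counterfactual baseline,
`ΔV(s_fail) ∝ δ`, converges on `V(s_fail) = V(s_cue)` and zeroes the
reframed error — unlearning the mechanism.  The opponent rule
`ΔV(s_fail) ∝ δ − δ̃` is stationary exactly at `δ = δ̃` and is a linear
contraction for learning rates η < 2, converging to
`V(s_fail) = V(s_cue) − δ̃`.  The opponent error δ̃ is supplied exogenously
(constant or trace); its own dynamics, and plasticity-gating alternatives
to opponency, are not modelled.  The same rule covers the No-Go baseline
`s_succ` with signs mirrored.

## Fitting

Objective per task:
`E(x) = Σ_χ |e^succ_χ| + w_rtc Σ_χ |e^rtc_χ|/s^rtc_χ +
w_rte Σ_χ |e^rte_χ|/s^rte_χ + w_DA e^DA + w_reg ‖x‖₁`, where the e-terms
are model-minus-data differences of the summary statistics and the s-terms
are the data's standard errors.  Defaults: w_rtc = w_rte = 0.25
(avoidance) or 0.018 (Go/No-Go); w_DA = 0.1 on the avoidance task only,
where e^DA is the absolute difference between the model's peak cue-window
DA on food and on shock success trials (the recorded transients are
strikingly similar, and this term is what makes κ identifiable when
Pavlovian weights vanish); w_reg = 0.01 only for good avoiders, whose
instrumental weights are otherwise unbounded along a flat direction.  RT
terms with an empty conditioning event are dropped; a zero standard error
with a non-zero RT weight is an error.

Optimization is bounded Nelder-Mead with uniform random restarts (default
20; the recovery experiments use 3 with 300 evaluations each), seeded and
recorded in the result.  Good- and poor-avoider data sets are fitted
independently.

## Synthetic data

The generator forward-samples the model's own policy: trial type from the
mix, control from κ, action and latency from the solved densities, success
from the deadline or a drawn tone offset.  Latencies are drawn from the
quadrature-discretized density (node probabilities `w_i p_i`), so
Monte-Carlo summaries and the analytic marginalization differ only by
estimator noise — the oracle-equivalence tests compare them at 20 000
trials within three standard errors.  Default session structure is nine
sessions (matching the degrees of freedom reported for the trace
analysis), configurable.

DA traces add i.i.d. Gaussian noise per 10 ms bin; the default amplitude
is calibrated at generation time so the single-trial SNR at the kernel
peak is about one (the recorded voltammetry signal is described as highly
variable but not quantified).  An optional slow sinusoidal drift is
available.  What the generator does *not* emulate: measurement chemistry
(chemometric current-to-concentration conversion), movement/outcome-period
release, cue generalization, session nonstationarity, or trial-to-trial
learning.  Passing tests therefore demonstrate internal consistency of
the pipeline and recoverability under the model's own assumptions, not
fidelity to any recorded data set.

Preprocessing mirrors the standard voltammetry chain: 0.5 s moving-window
smoothing (centered — the trailing alternative is configurable via the
window arguments; centering is the package's choice since the published
description does not say), 0.5 s pre-cue baselining, integration of the
first second after cue onset, session-wise averaging, and a paired
one-tailed t-test (failed > successful No-Go large-reward trials,
df = sessions − 1).  Sessions missing either outcome are excluded with a
warning; an all-zero pairing returns t = 0, p = 0.5 by convention.

## Design choices where the sources were open

- **Hyperbolic vs linear costs**: press and leave vigour costs are
  `c/τ` (shorter latencies are more demanding); the fixation cost is
  `c_f·τ` (a rate accrued over time in the nose-poke).
- **Trial mix**: equiprobable trial types (1/3 avoidance, 1/4 Go/No-Go);
  proportions are not part of the published task descriptions and are
  exposed in `TaskConfig`.
- **Go/No-Go press deadline**: τ_D = 10 s, mirroring the avoidance task;
  not stated for the omission task.
- **Cue values under the behavioural policy**: V is computed under the
  actual (Pavlovian-distorted, κ-mixed) policy rather than the
  instrumental optimum, because cue values must reflect realized success
  rates.
- **Error-trial RTs** (avoidance): deadline-truncated by default, latent
  conditional mean optional; only chosen-press trials enter.
- **DA combination rule on control trials**: sum of the two transients.

## Known limitations

- The cue-value root is not guaranteed unique under strong Pavlovian
  positive feedback; Brent's method returns one root in the bracket, and
  the fitter treats slow-converging parameter regions as failed
  evaluations (penalty 1e6).
- No uncertainty quantification on fitted parameters; point estimates
  only, as in the fits the defaults are transcribed from.
- Behaviour at the published Go/No-Go parameter values depends on the
  assumed deadline and trial mix; absolute success levels on Go-small
  trials are sensitive to these unpublished constants.
- The 1 s trace integration and the t-test operate on synthetic traces;
  the package never downloads or bundles recorded data.
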