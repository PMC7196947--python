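# Methods

## Task model

The simulated probabilistic reversal learning task has two options
(left/right).  One option is the high-probability side and pays reward with
`p_high = 0.8`; the other pays with `p_low = 0.2`.  Outcomes are sampled
independently per trial, so the previous outcome never changes the next
trial's odds.  After 8 consecutive responses at the high-probability option
— responses, not wins — the contingencies reverse.  The initial high side is
a seeded fair coin flip.

Sessions are fixed-length in *trials* (default 200); wall-clock duration,
inter-trial timing, reward consumption and cue events are not modeled.  The
10-s time-out after a loss is carried as metadata only.  Response latencies
have a slot in the data model but are never simulated, because no generative
latency model is part of the analysis.

Reproducibility: each session consumes a single seeded RNG stream; the first
draw picks the initial high side, then each trial draws (choice, outcome) in
that order.  Cohort generation derives per-session seeds from one master
stream; the grid study derives per-cell seed sequences from (base seed, cell
indices) so cell results are independent of execution order.

## Agent models

All models start both option values at `Q = 0.5` and update only the chosen
option by the reward prediction error `RPE = outcome − Q_chosen` (outcome 1
for a win, 0 for a loss):

* **RW1** `Q ← Q + α·RPE`, free parameters {α, β}.
* **RW2** win trials use α⁺, loss trials α⁻; {α⁺, α⁻, β}.
* **RW3** RW2 plus stickiness: the softmax input for option *s* is
  `β·Q_s + π·ϕ_s`, where ϕ_s = 1 iff *s* was chosen on the previous trial
  (both ϕ are 0 on trial 1); {α⁺, α⁻, π, β}.
* **RW4** Rescorla-Wagner/Pearce-Hall hybrid:
  `Q ← Q + α·γ·RPE`, `γ ← (1−η)·γ + η·|RPE|`, `γ₀ = 1`; {α, η, β}.
  The associability γ raises the effective learning rate when outcomes are
  surprising (e.g., right after a reversal).  The hybrid carries no
  stickiness term.
* **RANDOM** every choice has probability 0.5; no parameters.  Its session
  log-likelihood is `T·log 0.5`.

Choice probabilities are logistic in the input difference; they are computed
via the sign-aware `log1p(exp(·))` form, so arbitrarily large `|β·Q + π|`
cannot overflow.  RW1/RW2/RW4 have no π parameter at all (it is not a
fixed-at-zero parameter), so the free-parameter counts entering AIC/BIC are
2, 3, 4, 3 and 0.

Nesting identities used as correctness checks: RW3(π=0) ≡ RW2,
RW2(α⁺=α⁻) ≡ RW1, RW4(η=0) ≡ RW1, exact to numerical precision.

## Parameter estimation

Per session and model the posterior `P(θ|data) ∝ P(data|θ)·P(θ)` is
evaluated on a dense rectangular grid.  Priors:

| parameter | prior | grid (default) |
|---|---|---|
| α, α⁺, α⁻, η | Beta(1.5, 1.5) | 41 points on [0.004, 0.996] |
| π | Normal(0.5, 0.5²) | 21 points on [−2, 3] |
| β | Normal(2, 2²), renormalized on the grid support | 21 points on [0, 10] |

Negative β (systematically anti-value choice) is excluded; the normal prior
is renormalized over [0, 10] so it remains a proper density.  The second
argument of every normal prior is a standard deviation.

Point estimates are **marginal posterior means**: the grid is normalized
with uniform Riemann weights and each parameter's marginal is averaged over
its axis.  AIC/BIC use the *maximum* log-likelihood over the grid (the prior
plays no role in the penalized criteria); the likelihood at the
marginal-mean estimate is stored for diagnostics.

Grid resolutions were chosen so that a full five-model fit of a 200-trial
session costs about one second on one CPU — the four-dimensional RW3 grid
(41×41×21×21 ≈ 7.4×10⁵ nodes × 200 trials) dominates — while doubling every
axis moves estimates by well under 0.02.  Likelihood evaluation is
vectorized: value trajectories depend only on the learning parameters, so
they are computed once per learning-rate combination, and the softmax terms
are folded over (β, π) as products of `1 + exp(−z)` over short trial blocks
with one `log` per block (each factor is ≤ 1 + e¹³ under the default grid
bounds, so 32-trial blocks cannot overflow).

Numerical notes: with uniform Riemann weights the rectangle rule slightly
overweights the β truncation boundary; on a *prior-only* (empty) posterior
this biases the β mean by ≈ 0.09 at the default resolution.  Real sessions
concentrate the likelihood far from the boundary and are unaffected.  The
marginal mean of a symmetric multimodal posterior sits at the midpoint; that
is a property of the mean, reported as such.

## Model selection

Session evidences are `−AIC/2` (the conventional log-evidence proxy for
criterion values).  Group-level selection is random-effects Bayesian model
selection: session model assignments are drawn from unknown population
frequencies `r ~ Dirichlet(α₀=1,…,1)`, and a variational scheme iterates
responsibilities `u_nk ∝ exp(ev_nk + ψ(α_k) − ψ(Σα))` and concentrations
`α_k = α₀ + Σ_n u_nk` until `max|Δα| < 10⁻⁶` (cap 500 iterations;
non-convergence is flagged on the result, not raised).

The exceedance probability EP_k = P(r_k is largest) is estimated from 10⁶
seeded Dirichlet draws (Monte Carlo SE ≤ 5×10⁻⁴); for K = 2 it has a closed
form through the Beta marginal, used as an independent cross-check.  The
Bayes omnibus risk is `BOR = 1/(1 + exp(F₁ − F₀))` where F₁ is the
variational free energy of the random-effects model and
`F₀ = Σ_n logsumexp_k(ev_nk − log K)` is the evidence of the null model in
which all models are equally frequent.  The protected exceedance probability
is `PXP_k = EP_k·(1 − BOR) + BOR/K`.

## Synthetic cohorts and what they show

`generate_cohort` draws per-session parameters from the estimation priors
truncated to the grid supports and simulates agents on the exact task.  This
emulates a multi-session rodent dataset in the features the models see
(trial-by-trial choices, outcomes, reversal structure, ~200 trials/session)
but not in features real data have: no session-to-session stability within
subjects (draws are i.i.d.), no satiety/engagement drift, no latencies, no
omissions.  Recovery results on these cohorts therefore bound what the
pipeline can do when its assumptions hold; they do not certify the models as
the true generative process of animal behavior.

The model-recovery study (the acceptance computation) uses 196 sessions of
200 trials generated by RW3: fitting all five candidates and running
RFX-BMS on AIC evidences returns PXP ≈ 1 for RW3.  Parameter recovery on
such cohorts gives rank correlations of roughly 0.65–0.9 (β and π recover
best; the two learning rates are noisier, as expected in a two-armed task
where win and loss updates partly trade off).

## Parameter-grid simulation study

`run_parameter_grid` sweeps α⁺, α⁻ ∈ {0, 0.05, …, 1} × π ∈ {−0.5, 0, 0.5,
1, 1.5} at β = 1.686 with 50 sessions of 200 trials per cell by default, and
records per-cell means/SDs of reversals, reward fraction, win-stay and
lose-switch.  `percentile_region` marks cells at or above a given percentile
of cell means (linear interpolation).  Robust qualitative signatures, also
asserted by the tests at a reduced 11×11×3 / 20-sim scale: win-stay rises
with π wherever learning is fast; an α⁺ = α⁻ = 0 agent earns 50% reward at
any π (stickiness alone cannot find the rich side); reversal counts peak
when both learning rates and π are high.  β sweeps are supported through
`GridSpec` but are not part of the default study.

## Design choices and limitations

* The reversal counter counts *responses* at the high side regardless of
  outcome, and win-stay/lose-switch exclude the final trial (no successor);
  empty denominators yield missing values, never zeros.
* The group effect-size summary `(mean_T − mean_C)/SD_C` (control-SD
  denominator, n−1) is asymmetric by construction.
* Estimation is per-session MAP on a grid; no hierarchical/population-level
  or gradient-based estimation is provided.
* The RW4 hybrid uses the standard associability formulation stated above;
  variants with sticky choice or decaying initial associability are out of
  scope.
* Zero-trial sessions are accepted only by `evaluate_posterior_grid`
  (returning the gridded prior); fitting and metrics require at least one
  trial.
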