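# Methods

## Neuron and population model

Each agent is a population of N Spike-Response-Model neurons sharing a
frozen input spike pattern that encodes the current game state (one
pattern per blackjack hand value per role; a single pattern for the
one-state inspector game).  Patterns are drawn once from independent
homogeneous Poisson processes (default 6 Hz per afferent) and replayed
with identical spike times on every presentation, so the only stochastic
elements during play are the escape noise and the decision readout.

The membrane potential is

    u(t) = u_rest + Σ_j w_j PSP_j(t) + Σ_{t_f < t} κ(t − t_f)

with double-exponential postsynaptic kernels
ε(τ) = ε₀(e^{−τ/τ_m} − e^{−τ/τ_s}) and exponential reset
κ(τ) = −κ₀ e^{−τ/τ_m}.  Firing is stochastic with instantaneous rate
ρ(u) = ρ₀ e^{(u−θ)/Δu}; on the discrete grid the neuron fires in a step
of width Δt with probability min(1, ρΔt).  The exponential escape
function is the one choice for which ρ′/ρ is constant, which collapses
the likelihood gradient to the two-term eligibility trace below.

Defaults (all configurable): Δt = 1 ms, pattern duration 500 ms, 100
afferents, τ_m = 10 ms, τ_s = 2.5 ms, u_rest = 0, ε₀ = 1, κ₀ = 1,
ρ₀ = 0.01/ms, θ = 1, Δu = 0.2, N = 50, connection probability 0.5,
readout slope λ = 1.  Kernel amplitudes and the reset strength are in
arbitrary units; κ₀ = 1 (= 5Δu) gives a strong relative refractoriness
without silencing the neuron.  None of the table-level results depend on
these values.

### Initial operating point

The behavioral prior before learning is random 50/50 choice.  Because
the decision sigmoid is centred at A = N/2, this requires neurons to
fire with probability ≈ 1/2 per pattern.  `PRLAgent` therefore shifts
the resting potential so that a zero-weight neuron spikes with
probability 1/2 during one pattern presentation
(u_rest = θ + Δu·ln(ln2/(ρ₀T)), the `chance_bias` option).  Without this
bias the population sits far below threshold, the activity is pinned at
A ≈ 0 and, since silent neurons (σ = 0) receive no update, learning
never starts.

## Likelihood and eligibility

`log_likelihood` uses the clamped point-process form

    log P(y|x, w) = Σ_{t_f ∈ y} log(ρ(u(t_f)) Δt) − Σ_t ρ(u(t)) Δt,

with u including the reset kernels of the *given* output train.  With
this form the eligibility trace

    e_j = (1/Δu) [ Σ_{t_f} PSP_j(t_f) − c · Σ_t min(1, ρ(u_t)Δt) PSP_j(t) ]

is, for balance factor c = 1 and below hazard saturation, the exact
gradient ∂ log P/∂w_j (the duality is tested numerically to 1e−4
relative error).  Two numerical guards keep long runs stable without
affecting the unsaturated regime: the escape-rate exponent is capped at
500 to avoid float overflow, and the hazard in the negative eligibility
term saturates at 1, mirroring the Bernoulli simulator's probability
clipping.  The Bernoulli simulator and the point-process density agree
to O((ρΔt)²); the enumeration-normalization test is run at ρΔt ≈ 1e−5
where the discrepancy is below 1e−9.

The factor c (`neg_term_factor`) exposes the robustness manipulations:
c = 0 reduces the rule to pre/post spike-pairing STDP, c = 2 doubles the
balancing term.

## Learning rules

**pRL.**  After each episode, Δw_ij = Σ_d η(R − R̄[s_d]) f′_d σ_{i,d}
e_{ij,d}, masked by the fixed Bernoulli(0.5) connectivity.  The reward
baseline R̄ is a running mean (rate γ = 0.05) kept *per stimulus* so the
reward factor averages to zero for each state individually; for
multi-decision blackjack episodes each decision's factor uses its own
state's baseline, and every visited state's baseline is updated with the
terminal reward.  For the single-state inspector game this is identical
to a global baseline.  Defaults η = 0.05 (library) — the dynamics
examples and scaled-down tests use η = 0.1 with 100 ms patterns, which
rescales learning time without changing the attractor structure.

**pCOV.**  Binary neurons σ ~ Bernoulli(logistic(w·x)) on fixed binary
patterns; the update ν R′ f′ (σ − σ̄) x with σ̄ analytic, a running
average, or 0 (three variants).  The rule is a covariance rule, not a
gradient rule: its fixed points satisfy the matching law but need not be
Nash.  The demonstration configuration (N = 10, readout λ = 0.3,
ν = 5) is chosen so that near-deterministic decision rates are
*expressible* by the readout (with N = 20, λ = 1 the most extreme
reachable rate is 0.096) and the per-neuron covariance feedback is
strong enough to act at desk scale; in this regime a fraction of runs
collapses to a deterministic non-Nash pair (e.g. always-work /
always-inspect) while others keep mixing, which is the qualitative
dichotomy of interest.

**SARSA.**  Undiscounted episodic Q update with softmax action
selection (α = 0.1, β = 3 defaults).  Both games are short episodes, so
no discounting is used.  At the inspector game's mixed equilibrium both
actions of each player have equal value; softmax then returns 1/2
regardless of β, so the policy cannot express p_shirk = i ≠ 1/2 — the
structural reason TD learning fails here, asserted as a root-search
test.

**Roth–Erev.**  Propensities initialized to s·X̄ with X̄ the mean payoff
under uniform play; RE1 adds the reward to the chosen action's
propensity, RE3 spreads a fraction ε to the other action and decays all
propensities by φ.  Propensities are floored at 1e−6 to keep the choice
rule defined if rewards are non-positive.

## Games and exact solvers

**Blackjack.**  Infinite standard decks: card value 10 has probability
4/13, each of {2..9, 11} has 1/13.  The hand is the running sum of
i.i.d. draws from 0 (the initial two cards are simply the first two
forced draws, valid because every modeled stopping value exceeds the
largest card).  The stopping distribution P_s iterates exact rational
convolution of the sub-s mass with the card distribution; mass above 21
is aggregated as bust.  The expected bank payoff matrix averages the
±1 payoff (gambler bust loses immediately; ties go to the bank) over
the product distribution for gambler stops 11–18 × croupier stops
13–19; outside this range drawing is forced (hand < 11 cannot bust) or
stopping is forced (hand ≥ 20 busts with certainty on any draw).  The
saddle-point finder returns every entry maximal in its row and minimal
in its column.  A 32-card-deck variant is provided but has no printed
reference values and is only structurally tested.

**Inspector game.**  Payoffs (employee, employer): (work, inspect) →
(0.5, 2−i), (work, pass) → (0.5, 2), (shirk, inspect) → (0, 1−i),
(shirk, pass) → (1, 0), with inspection cost i ∈ (0, 1).  The mixed
equilibrium solver solves the two indifference equations generically
from the payoff matrices and flags degenerate games; for these payoffs
it returns p_shirk = i, p_inspect = 1/2, employee value 1/2, employer
value 2 − 2i.

## Analytics

Decision sequences are summarized by exponential running means
(r_t = (1−α) r_{t−1} + α d_t, r₀ = 0.5 the random-choice prior,
α = 0.02 default), binned rate changes (bin means, successive
differences, re-smoothed) and windowed per-state strategy estimates
(draw frequency over the last k visits, flagged when fewer visits
exist).  `run_match` orchestrates any pairing of learners and fixed
policies on either game, supports the stepped inspection-cost block
protocol, and writes a trajectory CSV plus JSON summary; everything is
deterministic given the master seed.

## What the synthetic world does and does not establish

All inputs are generated internally: frozen Poisson patterns, sampled
cards, and the printed payoff tables.  The exact solvers are compared
against published values to 4 decimal places, so those results carry no
simulation caveat.  The learning-dynamics results are scaled down
(populations of 10–20 neurons, 50 afferents, 100–200 ms patterns,
1e4–2e4 trials) relative to a fit to human behavior, which this package
does not attempt (the behavioral data and the fitted η, γ, α, β values
are not available).  A green dynamics test therefore establishes the
qualitative claims — gradient ascent, convergence of the shirk rate to
i, counteractive oscillations, pCOV's non-Nash collapses, softmax's
structural failure — not quantitative agreement with human learning
curves.

One protocol substitution: the employer algorithm used in the original
primate/human experiments is not publicly specified, so opponents are
fixed strategies, Nash-mixing policies, or learners.  Note that against
an employer inspecting at exactly 1/2 the employee is *indifferent*
(work and shirk both pay 0.5), so no gradient drives the shirk rate
anywhere; convergence of the shirk rate to i is therefore demonstrated
in the two-learner setting, where the opponent's adaptation supplies
the restoring force.

## Known limitations

- Spike times live on the Δt grid; no within-step interpolation, no
  event-driven simulation.
- The episodic rule assumes reward immediately after the episode; no
  low-pass (online) eligibility chaining for delayed reward.
- The decision readout is an abstract logistic unit, not a neural
  integrator.
- pRL blackjack training at full scale (both roles, 1e5+ games) is
  computationally heavy in pure Python/numpy; the shipped dynamics
  demonstrations use the inspector game, where convergence is reachable
  in minutes.
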