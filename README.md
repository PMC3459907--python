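# popgrad

Population reinforcement learning with spiking neurons for two-player
games, with exact game-theoretic solvers and classical learner baselines.

## The scientific problem

How can a population of noisy spiking neurons learn optimal strategies in
games against other adaptive agents?  In such multi-agent settings
optimality means a **Nash equilibrium** — a strategy profile where no
player gains by deviating unilaterally — which may be *pure*
(deterministic, as in a simplified blackjack) or *mixed* (stochastic, as
in the inspector game, where the equilibrium requires randomizing with
specific probabilities).

`popgrad` implements a spike-based **population reinforcement learning
(pRL)** rule and the environments and reference solvers needed to study
it.  The package is aimed at computational neuroscientists and
neuroeconomists who want a compact, fully testable implementation of

- Spike-Response-Model (SRM) neurons with exponential escape noise,
  driven by frozen Poisson spike patterns that encode game states;
- a population decision readout: activity `A = Σ_i σ_i` (σ_i = 1 iff
  neuron *i* spiked) mapped to a behavioral decision via
  `P(D=1|A) = logistic((A − N/2)/(λ√N))`;
- the four-factor synaptic update applied at the end of each episode,

  `Δw_ij = R′ · Σ_d f′_d · σ_{i,d} · e_{ij,d}`

  with reward-prediction error `R′ = η (R − R̄)`, decision feedback
  `f′ = ∂ log P(D|A)/∂A`, the neuron's spike/no-spike code σ, and the
  eligibility trace `e_ij = ∂ log P(spike train)/∂w_ij`, which for the
  exponential escape rate is
  `e_j = (1/Δu)[Σ_{t^f} PSP_j(t^f) − Σ_t ρ(u_t) PSP_j(t) Δt]`.
  The expected update follows the gradient of the expected reward;
- comparison learners: the population covariance rule (pCOV, replacing
  the eligibility trace by `σ − ⟨σ⟩` on binary neurons), tabular SARSA
  with a softmax policy, and the Roth–Erev propensity models RE1/RE3;
- exact solvers: the blackjack stopping-value distributions and expected
  payoff matrix (rational arithmetic), its saddle point (pure Nash), and
  the generic 2×2 indifference solver for the inspector game's mixed
  Nash equilibrium.

## Worked example

Solving the simplified blackjack game exactly
(`python examples/blackjack_solution.py`):

```
Expected bank payoff (rows: gambler stop value, cols: croupier):
        13      14      15      16      17      18      19
11  0.2982  0.3164  0.3027  0.2544  0.1689  0.0436 -0.1237
...
15  0.0119  0.0706  0.1289  0.1555  0.1450  0.0940 -0.0008
...

Saddle point(s): [(15, 16)]
At the pure Nash equilibrium the gambler stops at 15, the croupier at 16;
the bank earns +0.1555 per game on average.
```

Each entry is the exact expected payoff of the bank when the gambler
draws while below the row value and the croupier while below the column
value; the saddle entry 0.1555 (maximal in its row, minimal in its
column) is the game's unique pure Nash equilibrium — the gambler cannot
lose less, and the bank cannot win more, by deviating alone.

Two spiking populations learning the inspector game
(`python examples/prl_inspector_learning.py`, inspection cost i = 0.2):

```
trials        shirk rate   inspect rate
     0-2000     0.338        0.724
  2000-4000     0.200        0.683
  4000-6000     0.191        0.572
  6000-8000     0.172        0.528
  8000-10000    0.176        0.489
 10000-12000    0.185        0.464

second half:  shirk 0.178 (Nash 0.2), inspect 0.494 (Nash 0.5)
```

The employee's shirk rate converges to the inspection cost and the
employer's inspect rate oscillates around 1/2 — the mixed Nash
equilibrium that SARSA-softmax, pCOV and Roth–Erev learning fail to
reach (see `examples/baseline_learners.py`).

Other examples: `spiking_neuron_demo.py` (eligibility trace =
log-likelihood gradient, checked numerically) and
`inspector_equilibrium.py` (the mixed equilibrium across costs).

## Acceptance script

`scripts/acceptance.py` recomputes the package's headline quantities
from scratch — three entries of the exact blackjack payoff matrix, two
values of the stopping-value distributions, and the employee's
equilibrium payoff in the inspector game — and writes them to JSON:

```
python scripts/acceptance.py --seed 1 --out results/acceptance.json
```
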