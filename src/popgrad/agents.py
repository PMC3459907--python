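"""Game-playing agents wrapping the learning rules.

Every agent exposes the same two-method episodic interface:

``act(state_key, rng) -> int``
    choose the binary action (1 = draw / shirk / inspect depending on the
    game role) for the given state, recording whatever the learner needs;

``finish(reward) -> None``
    deliver the terminal reward of the episode and apply the learning
    update to all decisions recorded since the previous ``finish``.

Fixed (non-learning) policies implement the same interface with a no-op
``finish``.
"""

from __future__ import annotations

from dataclasses import dataclass, replace

import numpy as np

from .spiking import (
    KernelParams, EscapeParams, SpikePattern, generate_frozen_pattern, psp_matrix,
)
from .population import PopulationConfig, decision_prob, decision_feedback
from .plasticity import (
    LearnConfig, RewardEstimator, reward_prediction_error, prl_update,
)
from .baselines import QTable, PropensityVector, softmax_policy, re1_update, re3_update, sarsa_update

__all__ = [
    "PRLAgent", "PCOVAgent", "SarsaAgent", "REAgent",
    "FixedStoppingPolicy", "MixedPolicy",
]


class PRLAgent:
    """Population of spiking neurons trained with the pRL rule.

    Each game state is encoded by a frozen Poisson spike pattern; the
    population is simulated once per decision, the behavioral decision is
    read out from the population activity, and at episode end the
    four-factor update R' * f' * sigma * e is applied.
    """

    def __init__(
        self,
        state_keys,
        pop_cfg: PopulationConfig | None = None,
        kernels: KernelParams | None = None,
        escape: EscapeParams | None = None,
        learn_cfg: LearnConfig | None = None,
        n_channels: int = 100,
        pattern_rate_hz: float = 6.0,
        pattern_duration_ms: float = 500.0,
        weight_init_sd: float = 0.1,
        chance_bias: bool = True,
        seed: int = 0,
    ):
        self.pop_cfg = pop_cfg or PopulationConfig()
        self.kernels = kernels or KernelParams()
        self.escape = escape or EscapeParams()
        self.learn_cfg = learn_cfg or LearnConfig()
        if chance_bias:
            # Choice behavior starts at random 50/50: shift the resting
            # potential so that a zero-weight neuron fires with probability
            # 1/2 per pattern, putting the initial activity near N/2.
            esc, T = self.escape, pattern_duration_ms
            u0 = esc.theta + esc.delta_u * np.log(np.log(2.0) / (esc.rho0 * T))
            self.kernels = replace(self.kernels, u_rest=u0)
        rng = np.random.default_rng(seed)
        n = self.pop_cfg.n_neurons
        self.patterns: dict = {}
        self._psp: dict = {}
        for key in state_keys:
            pat = generate_frozen_pattern(
                n_channels, pattern_rate_hz, pattern_duration_ms,
                seed=int(rng.integers(2**31)), pattern_id=str(key),
            )
            self.patterns[key] = pat
            _, psp = psp_matrix(pat, self.kernels, self.escape.dt)
            self._psp[key] = psp
        self.mask = (rng.random((n, n_channels)) < self.pop_cfg.connect_prob).astype(float)
        self.weights = rng.normal(0.0, weight_init_sd, (n, n_channels)) * self.mask
        self.estimator = RewardEstimator()
        self._episode: list[dict] = []

    # -- population simulation, vectorized across neurons ------------------
    def _simulate_population(self, key, rng: np.random.Generator):
        psp = self._psp[key]
        esc, ker = self.escape, self.kernels
        u = self.kernels.u_rest + self.weights @ psp  # (N, n_steps)
        n, n_steps = u.shape
        decay = np.exp(-esc.dt / ker.tau_m)
        reset = np.zeros(n)
        fired = np.zeros((n, n_steps), dtype=bool)
        u_eff = np.empty_like(u)
        for k in range(n_steps):
            uk = u[:, k] + reset
            u_eff[:, k] = uk
            p = np.minimum(1.0, esc.rate(uk) * esc.dt)
            fired[:, k] = rng.random(n) < p
            reset = (reset - ker.kappa_amp * fired[:, k]) * decay
        return fired, u_eff, psp

    def act(self, state_key, rng: np.random.Generator) -> int:
        fired, u_eff, psp = self._simulate_population(state_key, rng)
        sigma = fired.any(axis=1).astype(float)
        A = int(sigma.sum())
        p_one = decision_prob(A, self.pop_cfg)
        D = int(rng.random() < p_one)
        f_prime = decision_feedback(D, A, self.pop_cfg)
        # eligibility for all neurons at once (two-term form, masked);
        # hazard saturates at 1 like the Bernoulli simulator
        hazard = np.minimum(self.escape.rate(u_eff) * self.escape.dt, 1.0)
        pos = fired.astype(float) @ psp.T
        neg = hazard @ psp.T
        elig = (pos - self.learn_cfg.neg_term_factor * neg) / self.escape.delta_u
        elig *= self.mask
        self._episode.append({
            "state_key": state_key, "f_prime": f_prime, "sigma": sigma,
            "elig": elig, "A": A, "p_one": p_one, "D": D,
        })
        return D

    def finish(self, reward: float) -> None:
        if not self._episode:
            return
        r_primes = []
        for rec in self._episode:
            rp, _ = reward_prediction_error(
                reward, rec["state_key"], self.estimator, self.learn_cfg
            )
            r_primes.append(rp)
        self.weights = prl_update(self.weights, self._episode, r_primes, self.mask)
        self._episode = []


class PCOVAgent:
    """Population of binary neurons trained with the covariance rule.

    Neurons respond sigma_i ~ Bernoulli(logistic(w_i . x)) to a fixed
    binary input pattern per state; the population decision is read out
    exactly as for pRL.  The update replaces the eligibility trace by the
    response deviation sigma - sigma_center.
    """

    def __init__(
        self,
        state_keys,
        pop_cfg: PopulationConfig | None = None,
        learn_cfg: LearnConfig | None = None,
        n_inputs: int = 50,
        input_density: float = 0.5,
        weight_init_sd: float = 0.1,
        center_mode: str = "analytic",  # "analytic" | "running" | "none"
        seed: int = 0,
    ):
        if center_mode not in ("analytic", "running", "none"):
            raise ValueError("center_mode must be analytic, running or none")
        self.pop_cfg = pop_cfg or PopulationConfig()
        self.learn_cfg = learn_cfg or LearnConfig(rbar_scope="global")
        self.center_mode = center_mode
        rng = np.random.default_rng(seed)
        n = self.pop_cfg.n_neurons
        self.x = {
            key: (rng.random(n_inputs) < input_density).astype(float)
            for key in state_keys
        }
        self.weights = rng.normal(0.0, weight_init_sd, (n, n_inputs))
        self.estimator = RewardEstimator()
        self._running_center = np.full(n, 0.5)
        self._episode: list[dict] = []

    def act(self, state_key, rng: np.random.Generator) -> int:
        x = self.x[state_key]
        mean = 1.0 / (1.0 + np.exp(-(self.weights @ x)))
        sigma = (rng.random(mean.size) < mean).astype(float)
        A = int(sigma.sum())
        p_one = decision_prob(A, self.pop_cfg)
        D = int(rng.random() < p_one)
        f_prime = decision_feedback(D, A, self.pop_cfg)
        if self.center_mode == "analytic":
            center = mean
        elif self.center_mode == "running":
            center = self._running_center.copy()
            self._running_center = 0.95 * self._running_center + 0.05 * sigma
        else:
            center = np.zeros_like(mean)
        self._episode.append({
            "state_key": state_key, "x": x, "sigma": sigma, "center": center,
            "f_prime": f_prime, "A": A, "p_one": p_one, "D": D,
        })
        return D

    def finish(self, reward: float) -> None:
        for rec in self._episode:
            rp, _ = reward_prediction_error(
                reward, rec["state_key"], self.estimator, self.learn_cfg
            )
            dev = rec["sigma"] - rec["center"]
            self.weights = self.weights + (
                self.learn_cfg.nu * rp * rec["f_prime"] * dev[:, None] * rec["x"][None, :]
            )
        self._episode = []


class SarsaAgent:
    """Tabular SARSA with softmax action selection, undiscounted episodic."""

    def __init__(self, alpha: float = 0.1, beta: float = 3.0):
        self.table = QTable(alpha=alpha, beta=beta)
        self._episode: list[tuple] = []

    def act(self, state_key, rng: np.random.Generator) -> int:
        qv = self.table.values(state_key, (0, 1))
        probs = softmax_policy(qv, self.table.beta)
        action = int(rng.random() < probs[1])
        self._episode.append((state_key, action))
        return action

    def finish(self, reward: float) -> None:
        if not self._episode:
            return
        # intermediate steps carry zero reward; terminal step the payoff
        for (s, a), (s2, a2) in zip(self._episode, self._episode[1:]):
            sarsa_update(self.table, s, a, 0.0, s2, a2, terminal=False)
        s, a = self._episode[-1]
        sarsa_update(self.table, s, a, reward, None, None, terminal=True)
        self._episode = []


class REAgent:
    """Roth-Erev learner (RE1, or RE3 when eps/phi are nonzero)."""

    def __init__(self, pv: PropensityVector, variant: str = "re1"):
        if variant not in ("re1", "re3"):
            raise ValueError("variant must be re1 or re3")
        self.pv = pv
        self.variant = variant
        self._last_action: int | None = None

    def act(self, state_key, rng: np.random.Generator) -> int:
        probs = self.pv.probabilities
        action = int(rng.random() < probs[1])
        self._last_action = action
        return action

    def finish(self, reward: float) -> None:
        if self._last_action is None:
            return
        update = re1_update if self.variant == "re1" else re3_update
        self.pv = update(self.pv, self._last_action, reward)
        self._last_action = None


@dataclass
class FixedStoppingPolicy:
    """Blackjack threshold player: draw (action 1) while hand < stop_value."""

    stop_value: int

    def act(self, state_key, rng: np.random.Generator) -> int:
        return int(state_key < self.stop_value)

    def finish(self, reward: float) -> None:
        pass


@dataclass
class MixedPolicy:
    """Stationary stochastic policy: action 1 with fixed probability."""

    p_one: float

    def act(self, state_key, rng: np.random.Generator) -> int:
        return int(rng.random() < self.p_one)

    def finish(self, reward: float) -> None:
        pass
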