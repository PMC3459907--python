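"""Classical learner baselines: SARSA with softmax, and Roth-Erev rules.

SARSA estimates action values Q(s, a) with the undiscounted episodic
update Q <- Q + alpha * (r + Q(s', a') - Q(s, a)) (the bootstrap term is
dropped at episode end) and selects actions with the softmax policy
p_a proportional to exp(beta * Q_a).

The Roth-Erev models keep per-action propensities q_k; the choice
probability is q_k / sum(q).  RE1 adds the received reward to the chosen
action's propensity.  RE3 additionally spreads a fraction eps of the
reward to the other action (generalization) and decays all propensities
by phi (forgetting); with eps = phi = 0 it reduces to RE1.  Initial
propensities are strength * Xbar where Xbar is the player's expected
payoff under uniformly random play by both sides.
"""

from __future__ import annotations

from dataclasses import dataclass, field
import warnings

import numpy as np

__all__ = [
    "QTable", "PropensityVector", "softmax_policy", "sarsa_update",
    "re_init", "re1_update", "re3_update",
]


@dataclass
class QTable:
    """State-action value estimates with softmax policy parameters."""

    alpha: float = 0.1
    beta: float = 3.0
    q: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        if not 0 < self.alpha <= 1:
            raise ValueError("alpha must be in (0, 1]")
        if self.beta <= 0:
            raise ValueError("beta must be positive")

    def value(self, state, action) -> float:
        return self.q.get((state, action), 0.0)

    def values(self, state, actions) -> np.ndarray:
        return np.array([self.value(state, a) for a in actions])


@dataclass
class PropensityVector:
    """Roth-Erev per-action propensities and model parameters."""

    q_k: np.ndarray
    eps_gen: float = 0.0
    phi: float = 0.0

    def __post_init__(self) -> None:
        self.q_k = np.asarray(self.q_k, dtype=float)
        if not 0 <= self.eps_gen < 1:
            raise ValueError("eps_gen must be in [0, 1)")
        if not 0 <= self.phi < 1:
            raise ValueError("phi must be in [0, 1)")

    @property
    def probabilities(self) -> np.ndarray:
        return self.q_k / self.q_k.sum()


def softmax_policy(qvalues: np.ndarray, beta: float) -> np.ndarray:
    """Action probabilities p_a proportional to exp(beta * q_a)."""
    q = np.asarray(qvalues, dtype=float)
    if q.size < 2:
        raise ValueError("need at least two actions")
    if beta <= 0:
        raise ValueError("beta must be positive")
    z = beta * q
    z -= z.max()  # numerical stabilization
    e = np.exp(z)
    return e / e.sum()


def sarsa_update(
    tab: QTable, s, a, r: float, s_next, a_next, terminal: bool
) -> QTable:
    """One SARSA step, undiscounted episodic form."""
    bootstrap = 0.0 if terminal else tab.value(s_next, a_next)
    td_error = r + bootstrap - tab.value(s, a)
    tab.q[(s, a)] = tab.value(s, a) + tab.alpha * td_error
    return tab


_PROPENSITY_FLOOR = 1e-6


def re_init(
    payoff_matrix: np.ndarray,
    strength: float,
    n_actions: int,
    eps_gen: float = 0.0,
    phi: float = 0.0,
) -> PropensityVector:
    """Initial propensities q_k = strength * Xbar.

    ``payoff_matrix`` holds this player's payoffs, rows indexed by own
    action; Xbar is the mean payoff when both players randomize uniformly.
    Non-positive Xbar (possible for the employer at high inspection cost)
    is floored at a small positive constant with a warning.
    """
    if strength <= 0:
        raise ValueError("strength must be positive")
    xbar = float(np.mean(np.asarray(payoff_matrix, dtype=float)))
    q0 = strength * xbar
    if q0 <= 0:
        warnings.warn(
            "average uniform-play payoff is non-positive; flooring initial "
            "propensities at a small positive constant",
            stacklevel=2,
        )
        q0 = _PROPENSITY_FLOOR
    return PropensityVector(np.full(n_actions, q0), eps_gen=eps_gen, phi=phi)


def re1_update(pv: PropensityVector, action: int, reward: float) -> PropensityVector:
    """Basic reinforcement: add the reward to the chosen action's propensity."""
    pv.q_k = pv.q_k.copy()
    pv.q_k[action] += reward
    pv.q_k = np.maximum(pv.q_k, _PROPENSITY_FLOOR)
    return pv


def re3_update(pv: PropensityVector, action: int, reward: float) -> PropensityVector:
    """Reinforcement with generalization (eps) and forgetting (phi).

    q_j <- (1-phi) q_j + reward * (1-eps)  for the chosen action,
    q_j <- (1-phi) q_j + reward * eps      for the other action(s).
    """
    q = (1.0 - pv.phi) * pv.q_k
    n_other = max(pv.q_k.size - 1, 1)
    for j in range(q.size):
        if j == action:
            q[j] += reward * (1.0 - pv.eps_gen)
        else:
            q[j] += reward * pv.eps_gen / n_other
    pv.q_k = np.maximum(q, _PROPENSITY_FLOOR)
    return pv
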