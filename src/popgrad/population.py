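"""Population activity readout and probabilistic behavioral decision.

Each of the N population neurons contributes a binary spike/no-spike code
sigma_i; the population activity A = sum_i sigma_i is read out by a
decision unit that chooses the behavioral decision D = 1 with logistic
probability

    P(D=1 | A) = 1 / (1 + exp(-(A - N/2) / (lambda * sqrt(N)))).

Centering at N/2 and scaling by sqrt(N) keeps the sigmoid argument of the
same order as the binomial fluctuations of A.  The decision feedback

    f'(D, A) = d log P(D|A) / dA = (D - P(D=1|A)) / (lambda * sqrt(N))

is the global, population-level credit signal broadcast to the synapses.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .spiking import SpikeTrain

__all__ = [
    "PopulationConfig", "DecisionOutcome", "population_activity",
    "decision_prob", "decision_feedback", "sample_decision",
]


@dataclass(frozen=True)
class PopulationConfig:
    """Population size, afferent connectivity and readout slope."""

    n_neurons: int = 50
    connect_prob: float = 0.5
    readout_scale: float = 1.0  # lambda, slope of the decision sigmoid

    def __post_init__(self) -> None:
        if self.n_neurons < 1:
            raise ValueError("n_neurons must be >= 1")
        if not 0 < self.connect_prob <= 1:
            raise ValueError("connect_prob must be in (0, 1]")
        if self.readout_scale <= 0:
            raise ValueError("readout_scale must be positive")

    @property
    def scale(self) -> float:
        """Denominator of the sigmoid argument, lambda * sqrt(N)."""
        return self.readout_scale * np.sqrt(self.n_neurons)


@dataclass
class DecisionOutcome:
    """One behavioral decision: per-neuron codes, activity, probability, D."""

    sigma: np.ndarray
    activity: int
    p_one: float
    decision: int


def population_activity(trains: list[SpikeTrain]) -> int:
    """Number of neurons that emitted at least one output spike."""
    if not trains:
        raise ValueError("empty population")
    return int(sum(t.fired for t in trains))


def _check_activity(A: float, cfg: PopulationConfig) -> None:
    if not 0 <= A <= cfg.n_neurons:
        raise ValueError(f"activity {A} outside [0, {cfg.n_neurons}]")


def decision_prob(A: float, cfg: PopulationConfig) -> float:
    """P(D=1 | A), logistic in the centred, sqrt(N)-scaled activity."""
    _check_activity(A, cfg)
    z = (A - cfg.n_neurons / 2.0) / cfg.scale
    return float(1.0 / (1.0 + np.exp(-z)))


def decision_feedback(D: int, A: float, cfg: PopulationConfig) -> float:
    """Score of the decision: d log P(D|A)/dA = (D - p) / (lambda sqrt(N))."""
    if D not in (0, 1):
        raise ValueError("D must be 0 or 1")
    p = decision_prob(A, cfg)
    return (D - p) / cfg.scale


def sample_decision(p: float, seed: int | np.random.Generator) -> int:
    """Draw D ~ Bernoulli(p), seed-deterministic."""
    if not 0 < p < 1:
        raise ValueError("p must lie strictly in (0, 1)")
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    return int(rng.random() < p)
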