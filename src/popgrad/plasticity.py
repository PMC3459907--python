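"""Learning rules: population reinforcement learning (pRL) and pCOV.

The pRL weight update for synapse (i, j) after an episode is the product
of four factors -- reward-prediction error, decision feedback, the
neuron's own spike/no-spike decision, and a synaptic eligibility trace:

    delta w_ij = R' * sum_d f'_d * sigma_{i,d} * e_{ij,d}

The eligibility trace is the gradient of the log-likelihood of the emitted
spike train with respect to the synaptic weight.  For the exponential
escape rate it takes the two-term form

    e_j = (1/delta_u) * [ sum_{t_f} PSP_j(t_f)
                          - sum_k rho(u(t_k)) * PSP_j(t_k) * dt ]

whose positive term depends on post-synaptic spike timing (Hebbian
pre-post pairing) and whose negative term depends on the membrane
potential; the two balance so that e is zero on average under the model.
``neg_term_factor`` scales the negative term to probe robustness (0 turns
the rule into pure pre-post STDP, 2 doubles the balance term).

The reward factor R' = eta * (R - Rbar) subtracts a running-mean reward
estimate Rbar, kept per stimulus by default so that the reward factor
averages to zero for each stimulus individually.

pCOV replaces the eligibility trace by the deviation of a binary neuron's
response from its mean, sigma - <sigma>, yielding a covariance rule that
does not follow the reward gradient.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .spiking import EscapeParams, SpikeTrain

__all__ = [
    "LearnConfig", "RewardEstimator", "eligibility_trace",
    "reward_prediction_error", "prl_update", "binary_forward", "pcov_update",
]


@dataclass(frozen=True)
class LearnConfig:
    """Learning-rule hyperparameters.

    eta : pRL learning rate (absorbed into the reward signal R').
    gamma_rbar : update rate of the running mean reward estimate.
    rbar_scope : "per_state" keeps one estimate per stimulus, "global" one
        overall (identical for single-state tasks such as the inspector
        game).
    neg_term_factor : multiplier on the negative eligibility term.
    nu : pCOV learning rate.
    rbar_init : prior value of the reward estimate before the first visit.
    """

    eta: float = 0.05
    gamma_rbar: float = 0.05
    rbar_scope: str = "per_state"
    neg_term_factor: float = 1.0
    nu: float = 0.05
    rbar_init: float = 0.0

    def __post_init__(self) -> None:
        if self.eta <= 0:
            raise ValueError("eta must be positive")
        if not 0 < self.gamma_rbar <= 1:
            raise ValueError("gamma_rbar must be in (0, 1]")
        if self.neg_term_factor < 0:
            raise ValueError("neg_term_factor must be >= 0")
        if self.nu <= 0:
            raise ValueError("nu must be positive")
        if self.rbar_scope not in ("per_state", "global"):
            raise ValueError("rbar_scope must be 'per_state' or 'global'")


_GLOBAL_KEY = "__global__"


@dataclass
class RewardEstimator:
    """Running-mean reward estimate Rbar, per state or global."""

    rbar: dict = field(default_factory=dict)

    def get(self, state_key, cfg: LearnConfig) -> float:
        key = _GLOBAL_KEY if cfg.rbar_scope == "global" else state_key
        return self.rbar.get(key, cfg.rbar_init)

    def update(self, state_key, R: float, cfg: LearnConfig) -> None:
        key = _GLOBAL_KEY if cfg.rbar_scope == "global" else state_key
        old = self.rbar.get(key, cfg.rbar_init)
        self.rbar[key] = (1.0 - cfg.gamma_rbar) * old + cfg.gamma_rbar * R


def eligibility_trace(
    psp: np.ndarray,
    output: SpikeTrain,
    u: np.ndarray,
    escape: EscapeParams,
    cfg: LearnConfig | None = None,
) -> np.ndarray:
    """Per-afferent eligibility for one neuron and one decision period.

    Parameters
    ----------
    psp : (n_channels, n_steps) PSP traces on the simulation grid.
    output : the neuron's emitted spike train (times on the grid).
    u : membrane-potential trace including resets, same grid.
    """
    cfg = cfg or LearnConfig()
    psp = np.asarray(psp, dtype=float)
    u = np.asarray(u, dtype=float)
    if psp.ndim != 2 or psp.shape[1] != u.size:
        raise ValueError("psp and membrane trace must share the time grid")
    fire_idx = np.asarray(np.rint(np.asarray(output.spikes) / escape.dt), dtype=int)
    pos = psp[:, fire_idx].sum(axis=1) if fire_idx.size else np.zeros(psp.shape[0])
    # saturate the hazard where the Bernoulli simulator clips the firing
    # probability at 1; below saturation this is exactly rho(u)*dt and the
    # trace is the exact weight gradient of log_likelihood
    hazard = np.minimum(escape.rate(u) * escape.dt, 1.0)
    neg = psp @ hazard
    return (pos - cfg.neg_term_factor * neg) / escape.delta_u


def reward_prediction_error(
    R: float, state_key, est: RewardEstimator, cfg: LearnConfig
) -> tuple[float, RewardEstimator]:
    """Reward feedback R' = eta * (R - Rbar[state]); updates Rbar in place.

    Returns the (scaled) reward-prediction error and the estimator.
    """
    if not np.isfinite(R):
        raise ValueError("reward must be finite")
    r_prime = cfg.eta * (R - est.get(state_key, cfg))
    est.update(state_key, R, cfg)
    return r_prime, est


def prl_update(
    weights: np.ndarray,
    decisions: list[dict],
    r_prime: float | list[float],
    mask: np.ndarray | None = None,
) -> np.ndarray:
    """Apply the pRL rule for one episode.

    ``decisions`` holds one record per decision period d, each a dict with
    keys ``"f_prime"`` (scalar), ``"sigma"`` (length-N 0/1 array) and
    ``"elig"`` ((N, n_afferents) eligibility matrix).  ``r_prime`` is the
    terminal reward factor, either one scalar for the whole episode or one
    value per decision (per-state reward baselines).  Masked-out synapses
    are never updated.
    """
    weights = np.asarray(weights, dtype=float)
    if not decisions:
        raise ValueError("episode contains no decision records")
    if np.isscalar(r_prime):
        r_list = [float(r_prime)] * len(decisions)
    else:
        r_list = [float(r) for r in r_prime]
        if len(r_list) != len(decisions):
            raise ValueError("need one r_prime per decision record")
    delta = np.zeros_like(weights)
    for rec, rp in zip(decisions, r_list):
        try:
            fp, sigma, elig = rec["f_prime"], rec["sigma"], rec["elig"]
        except KeyError as exc:
            raise ValueError(f"decision record missing field {exc}") from exc
        sigma = np.asarray(sigma, dtype=float)
        elig = np.asarray(elig, dtype=float)
        if elig.shape != weights.shape or sigma.size != weights.shape[0]:
            raise ValueError("decision record shapes do not match weights")
        delta += rp * fp * sigma[:, None] * elig
    if mask is not None:
        delta = delta * mask
    return weights + delta


def binary_forward(
    weights: np.ndarray, x: np.ndarray, seed: int | np.random.Generator
) -> tuple[int, float]:
    """Binary neuron: sigma ~ Bernoulli(logistic(w . x)).

    Returns the sampled response and its analytic mean <sigma>.
    """
    weights = np.asarray(weights, dtype=float)
    x = np.asarray(x, dtype=float)
    sigma_mean = float(1.0 / (1.0 + np.exp(-weights @ x)))
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    return int(rng.random() < sigma_mean), sigma_mean


def pcov_update(
    weights: np.ndarray,
    x: np.ndarray,
    sigma: int,
    sigma_center: float,
    f_prime: float,
    r_prime: float,
    cfg: LearnConfig,
) -> np.ndarray:
    """Population covariance rule for one binary neuron.

        w <- w + nu * R' * f' * (sigma - sigma_center) * x

    ``sigma_center`` is the analytic mean <sigma>, a running average, or 0
    for the no-subtraction variant.
    """
    weights = np.asarray(weights, dtype=float)
    x = np.asarray(x, dtype=float)
    return weights + cfg.nu * r_prime * f_prime * (sigma - sigma_center) * x
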