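"""Spike-Response-Model neurons with escape noise.

A neuron's membrane potential is the sum of a resting potential, PSP
kernels triggered by presynaptic spikes, and reset kernels triggered by
its own output spikes:

    u(t) = u_rest + sum_j w_j * PSP_j(t) + sum_{t_f < t} kappa(t - t_f)

with a double-exponential postsynaptic kernel

    eps(tau) = eps_amp * (exp(-tau/tau_m) - exp(-tau/tau_s)),  tau > 0

and an exponential reset kernel kappa(tau) = -kappa_amp * exp(-tau/tau_m).
Spiking is stochastic ("escape noise"): at each time step of width dt the
neuron fires with probability min(1, rho(u) * dt), where the instantaneous
rate is exponential in the potential,

    rho(u) = rho0 * exp((u - theta) / delta_u).

The exponential escape function makes rho'/rho constant (= 1/delta_u),
which is what gives the eligibility trace in :mod:`popgrad.plasticity`
its simple two-term form.

Stimuli are "frozen" Poisson patterns: spike times are drawn once from
homogeneous Poisson processes and then replayed identically on every
presentation of the same game state.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field

import numpy as np

__all__ = [
    "KernelParams", "EscapeParams", "SpikePattern", "SpikeTrain",
    "generate_frozen_pattern", "psp_trace", "psp_matrix",
    "simulate_neuron", "log_likelihood", "escape_rate",
]


@dataclass(frozen=True)
class KernelParams:
    """Membrane/synaptic kernel parameters (times in ms, potentials a.u.)."""

    tau_m: float = 10.0
    tau_s: float = 2.5
    u_rest: float = 0.0
    eps_amp: float = 1.0
    kappa_amp: float = 1.0  # applied negatively (after-spike reset)

    def __post_init__(self) -> None:
        if self.tau_m <= 0 or self.tau_s <= 0:
            raise ValueError("time constants must be positive")
        if self.tau_s == self.tau_m:
            raise ValueError("tau_s must differ from tau_m (kernel degenerate)")
        if self.eps_amp <= 0:
            raise ValueError("eps_amp must be positive")
        if self.kappa_amp < 0:
            raise ValueError("kappa_amp must be non-negative")

    def eps(self, tau: np.ndarray) -> np.ndarray:
        """Postsynaptic kernel, zero for tau <= 0."""
        tau = np.asarray(tau, dtype=float)
        out = self.eps_amp * (np.exp(-tau / self.tau_m) - np.exp(-tau / self.tau_s))
        return np.where(tau > 0, out, 0.0)

    def kappa(self, tau: np.ndarray) -> np.ndarray:
        """Reset kernel (negative), zero for tau <= 0."""
        tau = np.asarray(tau, dtype=float)
        out = -self.kappa_amp * np.exp(-tau / self.tau_m)
        return np.where(tau > 0, out, 0.0)


@dataclass(frozen=True)
class EscapeParams:
    """Escape-noise firing parameters.

    rho0 is the rate at threshold (1/ms), theta the threshold potential,
    delta_u the width of the escape noise, dt the simulation step (ms).
    """

    rho0: float = 0.01
    theta: float = 1.0
    delta_u: float = 0.2
    dt: float = 1.0

    def __post_init__(self) -> None:
        if self.rho0 <= 0 or self.delta_u <= 0 or self.dt <= 0:
            raise ValueError("rho0, delta_u and dt must be positive")

    def rate(self, u: np.ndarray) -> np.ndarray:
        z = (np.asarray(u, dtype=float) - self.theta) / self.delta_u
        # cap the exponent well below float64 overflow; rates this large are
        # saturated (fire with probability 1) in the Bernoulli simulator
        return self.rho0 * np.exp(np.minimum(z, 500.0))


def escape_rate(u: np.ndarray, escape: EscapeParams) -> np.ndarray:
    """Instantaneous firing rate rho(u) = rho0 * exp((u - theta)/delta_u)."""
    return escape.rate(u)


@dataclass
class SpikePattern:
    """Frozen multi-channel input spike pattern encoding one game state."""

    n_channels: int
    duration: float  # ms
    spikes: list[np.ndarray]  # per-channel sorted spike times (ms)
    pattern_id: str = ""

    def __post_init__(self) -> None:
        if len(self.spikes) != self.n_channels:
            raise ValueError("spikes must have one entry per channel")
        self.spikes = [np.asarray(s, dtype=float) for s in self.spikes]
        for s in self.spikes:
            if s.size and (s.min() < 0 or s.max() >= self.duration):
                raise ValueError("spike times must lie in [0, duration)")
            if np.any(np.diff(s) <= 0):
                raise ValueError("spike times must be strictly increasing")

    def to_json(self) -> str:
        return json.dumps({
            "pattern_id": self.pattern_id,
            "n_channels": self.n_channels,
            "duration_ms": self.duration,
            "spikes": [[float(f"{t:.10g}") for t in ch] for ch in self.spikes],
        })

    @classmethod
    def from_json(cls, s: str) -> "SpikePattern":
        d = json.loads(s)
        return cls(
            n_channels=d["n_channels"],
            duration=d["duration_ms"],
            spikes=[np.asarray(ch, dtype=float) for ch in d["spikes"]],
            pattern_id=d.get("pattern_id", ""),
        )


@dataclass
class SpikeTrain:
    """Output spike train of one neuron for one decision period."""

    spikes: np.ndarray = field(default_factory=lambda: np.empty(0))

    def __post_init__(self) -> None:
        self.spikes = np.asarray(self.spikes, dtype=float)

    @property
    def fired(self) -> int:
        """Spike/no-spike decision sigma: 1 iff at least one output spike."""
        return int(self.spikes.size > 0)


def generate_frozen_pattern(
    n_channels: int, rate: float, duration: float, seed: int, pattern_id: str = ""
) -> SpikePattern:
    """Draw a frozen Poisson spike pattern.

    Parameters
    ----------
    n_channels : number of afferent spike trains.
    rate : Poisson rate in Hz.
    duration : pattern length in ms.
    seed : RNG seed; the same seed reproduces identical spike times.
    """
    if n_channels < 1:
        raise ValueError("n_channels must be >= 1")
    if rate <= 0 or duration <= 0:
        raise ValueError("rate and duration must be positive")
    rng = np.random.default_rng(seed)
    rate_per_ms = rate / 1000.0
    spikes = []
    for _ in range(n_channels):
        n = rng.poisson(rate_per_ms * duration)
        t = np.sort(rng.uniform(0.0, duration, size=n))
        # Poisson process gives distinct times a.s.; enforce strictness anyway
        t = np.unique(t)
        spikes.append(t)
    return SpikePattern(n_channels, duration, spikes, pattern_id)


def _time_grid(duration: float, dt: float) -> np.ndarray:
    n_steps = int(round(duration / dt))
    return np.arange(n_steps) * dt


def psp_trace(
    pattern: SpikePattern, channel: int, kernels: KernelParams, grid: np.ndarray
) -> np.ndarray:
    """PSP(t) = sum over spikes t_s <= t of eps(t - t_s), on the given grid."""
    if not 0 <= channel < pattern.n_channels:
        raise IndexError("channel out of range")
    ts = pattern.spikes[channel]
    if ts.size == 0:
        return np.zeros_like(np.asarray(grid, dtype=float))
    tau = np.asarray(grid, dtype=float)[:, None] - ts[None, :]
    return kernels.eps(tau).sum(axis=1)


def psp_matrix(
    pattern: SpikePattern, kernels: KernelParams, dt: float
) -> tuple[np.ndarray, np.ndarray]:
    """All-channel PSP traces on the simulation grid.

    Returns (grid, psp) with psp of shape (n_channels, n_steps). The grid
    is the left-edge grid t_k = k*dt covering [0, duration). Patterns are
    frozen, so callers cache this per game state.
    """
    grid = _time_grid(pattern.duration, dt)
    psp = np.zeros((pattern.n_channels, grid.size))
    for j in range(pattern.n_channels):
        psp[j] = psp_trace(pattern, j, kernels, grid)
    return grid, psp


def _membrane_with_resets(
    base_u: np.ndarray, fire_idx: np.ndarray, grid: np.ndarray, kernels: KernelParams
) -> np.ndarray:
    """Add reset-kernel contributions of the given output spikes to base_u."""
    u = base_u.copy()
    for k in fire_idx:
        tau = grid - grid[k]
        u += kernels.kappa(tau)
    return u


def simulate_neuron(
    weights_row: np.ndarray,
    pattern: SpikePattern,
    kernels: KernelParams,
    escape: EscapeParams,
    seed: int | np.random.Generator,
    psp: np.ndarray | None = None,
) -> tuple[SpikeTrain, dict]:
    """Simulate one SRM neuron over one presentation of the pattern.

    At each grid step the neuron fires with probability min(1, rho(u)*dt);
    output spikes feed back through the reset kernel.  Returns the sampled
    spike train and a dict of traces ("grid", "u", "psp") needed by the
    learning rule.

    ``psp`` may pass a precomputed ``psp_matrix`` result to avoid
    recomputation for frozen patterns.
    """
    weights_row = np.asarray(weights_row, dtype=float)
    if weights_row.shape != (pattern.n_channels,):
        raise ValueError(
            f"weights_row has length {weights_row.size}, "
            f"pattern has {pattern.n_channels} channels"
        )
    if psp is None:
        grid, psp = psp_matrix(pattern, kernels, escape.dt)
    else:
        grid = _time_grid(pattern.duration, escape.dt)
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)

    base_u = kernels.u_rest + weights_row @ psp
    u = base_u.copy()
    fire_idx: list[int] = []
    n_steps = grid.size
    for k in range(n_steps):
        p = min(1.0, escape.rate(u[k]) * escape.dt)
        if rng.random() < p:
            fire_idx.append(k)
            tau = grid[k + 1:] - grid[k]
            u[k + 1:] += -kernels.kappa_amp * np.exp(-tau / kernels.tau_m)
    train = SpikeTrain(grid[np.asarray(fire_idx, dtype=int)])
    return train, {"grid": grid, "u": u, "psp": psp}


def log_likelihood(
    weights_row: np.ndarray,
    pattern: SpikePattern,
    output: SpikeTrain,
    kernels: KernelParams,
    escape: EscapeParams,
    psp: np.ndarray | None = None,
) -> float:
    """Log-density of an output spike train under the escape-noise model.

    The clamped point-process log-likelihood

        log P = sum_{t_f in output} log(rho(u(t_f)) * dt) - sum_k rho(u(t_k)) * dt

    where u includes the reset kernels triggered by the *given* output
    spikes.  The survival sum runs over the whole grid (the continuous-time
    integral of rho), so the Eq.-8-style eligibility trace is exactly its
    weight gradient.
    """
    out_t = np.asarray(output.spikes, dtype=float)
    if out_t.size and (out_t.min() < 0 or out_t.max() >= pattern.duration):
        raise ValueError("output spikes outside the pattern window")
    weights_row = np.asarray(weights_row, dtype=float)
    if weights_row.shape != (pattern.n_channels,):
        raise ValueError("weights_row length mismatch")
    if psp is None:
        grid, psp = psp_matrix(pattern, kernels, escape.dt)
    else:
        grid = _time_grid(pattern.duration, escape.dt)
    fire_idx = np.asarray(np.rint(out_t / escape.dt), dtype=int)
    base_u = kernels.u_rest + weights_row @ psp
    u = _membrane_with_resets(base_u, fire_idx, grid, kernels)
    rho = escape.rate(u)
    log_p = float(np.sum(np.log(rho[fire_idx] * escape.dt))) if fire_idx.size else 0.0
    log_p -= float(np.sum(rho) * escape.dt)
    return log_p
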