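"""One spiking neuron: frozen stimulus, escape-noise firing, eligibility.

Generates a frozen Poisson input pattern, simulates a Spike Response
Model neuron with escape noise on it, and verifies numerically that the
synaptic eligibility trace is the gradient of the spike-train
log-likelihood -- the property that makes the population learning rule a
policy-gradient procedure.
"""

import numpy as np

import popgrad as pg

kernels = pg.KernelParams()
escape = pg.EscapeParams(rho0=0.05, theta=0.3, delta_u=0.3, dt=1.0)
pattern = pg.generate_frozen_pattern(n_channels=5, rate=60.0, duration=50.0, seed=1)
weights = np.random.default_rng(0).normal(0, 0.3, 5)

train, traces = pg.simulate_neuron(weights, pattern, kernels, escape, seed=17)
print(f"input spikes per channel: {[len(s) for s in pattern.spikes]}")
print(f"output spike times (ms): {train.spikes}")
print(f"spike/no-spike code sigma = {train.fired}")

ll = pg.log_likelihood(weights, pattern, train, kernels, escape)
elig = pg.eligibility_trace(traces["psp"], train, traces["u"], escape)
print(f"\nlog-likelihood of the emitted train: {ll:.4f}")
print(f"eligibility trace e_j: {np.round(elig, 4)}")

h = 1e-5
fd = np.empty(5)
for j in range(5):
    wp, wm = weights.copy(), weights.copy()
    wp[j] += h
    wm[j] -= h
    fd[j] = (pg.log_likelihood(wp, pattern, train, kernels, escape)
             - pg.log_likelihood(wm, pattern, train, kernels, escape)) / (2 * h)
print(f"numerical d logL / d w_j: {np.round(fd, 4)}")
print("\nThe two vectors agree: the trace stores exactly how each synapse")
print("should change to make the emitted spike train more likely.")
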