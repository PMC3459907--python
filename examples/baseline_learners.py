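"""Why the classical baselines miss the mixed Nash equilibrium.

SARSA with a softmax policy cannot represent the equilibrium at all: at
the mixed Nash profile both actions have equal value, so softmax returns
(0.5, 0.5) for every inverse temperature, never (i, 1-i).  The Roth-Erev
heuristics drift away from the equilibrium as well.  This script shows
the softmax obstruction and a short RE1-vs-RE1 run.
"""

import numpy as np

import popgrad as pg

i = 0.2
cfg = pg.InspectorConfig(i)
nash = pg.inspector_mixed_nash(cfg)
a, b = cfg.payoff_matrices()
q = np.array([nash["p_inspect"], 1 - nash["p_inspect"]])
q_employee = a @ q
print(f"employee action values at the Nash profile (work, shirk): {q_employee}")
for beta in (0.1, 1.0, 10.0, 1000.0):
    p = pg.softmax_policy(q_employee, beta)
    print(f"  softmax(beta={beta:>6}): p_shirk = {p[1]:.3f}   (Nash wants {i})")
print("Equal values give p_shirk = 0.5 for every beta: softmax cannot")
print("express the mixed equilibrium unless i = 0.5.\n")

match = pg.run_match(pg.ExperimentConfig(
    game="inspector", player_a="re1", player_b="re1",
    blocks=[(5000, i)], master_seed=4))
blk = match.summary["blocks"][0]
print(f"RE1 vs RE1, 5000 trials at i = {i}:")
print(f"  mean shirk rate   {blk['mean_shirk']:.3f}  (Nash {i})")
print(f"  mean inspect rate {blk['mean_inspect']:.3f}  (Nash 0.5)")
print("Basic reinforcement does not follow the reward gradient and its")
print("rates need not settle at the equilibrium values.")
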