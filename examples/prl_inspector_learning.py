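"""Two spiking populations learn the mixed Nash equilibrium.

Two pRL agents (small populations, for a quick run) play the inspector
game with inspection cost i = 0.2.  The block-averaged shirk rate should
approach i and the inspect rate oscillate around 1/2 -- the mixed Nash
equilibrium -- with the characteristic counteractive oscillations of two
gradient learners exploiting each other's deviations.
"""

import popgrad as pg


def agent(seed):
    return pg.PRLAgent(
        ["inspector"],
        pop_cfg=pg.PopulationConfig(n_neurons=20, connect_prob=0.5),
        learn_cfg=pg.LearnConfig(rbar_scope="global", eta=0.1),
        n_channels=50, pattern_duration_ms=100.0, seed=seed)


i, n = 0.2, 12000
cfg = pg.ExperimentConfig(game="inspector", player_a=agent(11),
                          player_b=agent(22), blocks=[(n, i)], master_seed=3)
traj = pg.run_match(cfg)
df = traj.rows

print(f"inspector game, cost i = {i}: Nash is shirk = {i}, inspect = 0.5\n")
print("trials        shirk rate   inspect rate")
for lo in range(0, n, 2000):
    sub = df.iloc[lo:lo + 2000]
    print(f"{lo:>6}-{lo + 2000:<6}   {sub['action_a'].mean():.3f}        "
          f"{sub['action_b'].mean():.3f}")
half = df.iloc[n // 2:]
print(f"\nsecond half:  shirk {half['action_a'].mean():.3f} (Nash {i}), "
      f"inspect {half['action_b'].mean():.3f} (Nash 0.5)")
print("The employee's shirk rate settles at the inspection cost while the")
print("employer's inspect rate orbits 1/2: the mixed Nash equilibrium.")
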