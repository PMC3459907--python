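"""Exact solution of the simplified blackjack game.

Computes the stopping-value distributions, the expected bank payoff for
every threshold strategy pair, and the saddle point (the pure Nash
equilibrium) of this zero-sum game.
"""

import popgrad as pg
from popgrad.games import BUST

matrix = pg.mean_payoff_matrix()
print("Expected bank payoff (rows: gambler stop value, cols: croupier):")
print(matrix.to_frame().round(4))

saddle = pg.find_saddle_point(matrix)
print(f"\nSaddle point(s): {saddle}")
s, b = saddle[0]
print(f"At the pure Nash equilibrium the gambler stops at {s}, the croupier "
      f"at {b}; the bank earns {matrix.entry(s, b):+.4f} per game on average "
      f"(the gambler loses the same amount).")

for sv in (15, 16):
    d = pg.stopping_distribution(sv)
    print(f"\nFinal-hand distribution when stopping at {sv}:")
    print(d.to_series().round(4).to_string())
    print(f"bust probability: {d.prob(BUST):.4f}")
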