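"""Game environments and exact analytic solvers.

Blackjack (the simplified 18th-century form): a gambler, then a croupier,
draws cards one after the other, each aiming at a hand value close to but
not above 21; exceeding 21 (busting) loses immediately, and in a standoff
(equal hands) the bank wins.  Both players follow threshold strategies --
draw while the hand value is below a stopping value s, stop at or above
it.  With an infinite number of standard decks the card distribution is
constant across draws (ace = 11 with mass 1/13, ten/jack/queen/king = 10
with mass 4/13, 2..9 each 1/13), so the distribution of the final hand
under a stopping value, and hence the expected bank payoff for every
strategy pair, can be computed exactly by iterating the drawing recursion
with rational arithmetic.  The resulting payoff matrix of this zero-sum
game has a unique saddle point (gambler stops at 15, croupier at 16): the
pure Nash equilibrium.

Inspector game: a 2x2 bimatrix game between a lazy employee (work/shirk)
and an employer (inspect/pass) paying inspection cost i.  Payoffs
(employee, employer): (work, inspect) -> (0.5, 2-i); (work, pass) ->
(0.5, 2); (shirk, inspect) -> (0, 1-i); (shirk, pass) -> (1, 0).  The game
has a unique mixed Nash equilibrium found from the two indifference
conditions; there the employee shirks with probability i and the employer
inspects with probability 1/2.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from fractions import Fraction

import numpy as np
import pandas as pd

__all__ = [
    "CardDistribution", "StoppingPMF", "PayoffMatrix", "InspectorConfig",
    "BUST", "infinite_deck", "thirty_two_card_deck", "stopping_distribution",
    "bank_payoff", "mean_payoff_matrix", "find_saddle_point",
    "play_blackjack_episode", "inspector_step", "inspector_mixed_nash",
    "GAMBLER_RANGE", "CROUPIER_RANGE",
]

#: marker for hand values above 21
BUST = "bust"

#: hand values at which the gambler's draw/stop decision is modeled;
#: below, drawing is safe (forced); above, the range is not on the
#: payoff-matrix axes.
GAMBLER_RANGE = range(11, 19)
#: same for the croupier
CROUPIER_RANGE = range(13, 20)

#: hand value from which drawing busts with certainty (minimum card 2)
_FORCED_STOP = 20


@dataclass(frozen=True)
class CardDistribution:
    """Probability mass over single-card values (2..11), exact rationals."""

    pmf: dict

    def __post_init__(self) -> None:
        total = sum(self.pmf.values())
        if total != 1 and abs(float(total) - 1.0) > 1e-12:
            raise ValueError("card probabilities must sum to 1")
        if any(p < 0 for p in self.pmf.values()):
            raise ValueError("card probabilities must be non-negative")
        vals = sorted(self.pmf)
        cum = np.cumsum([float(self.pmf[v]) for v in vals])
        object.__setattr__(self, "_values", np.array(vals))
        object.__setattr__(self, "_cum", cum / cum[-1])

    def sample(self, rng: np.random.Generator) -> int:
        return int(self._values[np.searchsorted(self._cum, rng.random(), side="right")])


def infinite_deck() -> CardDistribution:
    """Infinite standard decks: value 10 has mass 4/13, others 1/13."""
    pmf = {v: Fraction(1, 13) for v in list(range(2, 10)) + [11]}
    pmf[10] = Fraction(4, 13)
    return CardDistribution(pmf)


def thirty_two_card_deck() -> CardDistribution:
    """Infinite-deck approximation of a 32-card (piquet) deck.

    Values 7, 8, 9, 11 from four cards each, value 10 from sixteen
    (ten/jack/queen/king).  No printed oracle exists for this variant.
    """
    pmf = {v: Fraction(4, 32) for v in [7, 8, 9, 11]}
    pmf[10] = Fraction(16, 32)
    return CardDistribution(pmf)


@dataclass
class StoppingPMF:
    """Distribution of the final hand value under stopping value s."""

    s: int
    pmf: dict  # final value in {s..21} or BUST -> probability (Fraction)

    def __post_init__(self) -> None:
        total = sum(self.pmf.values())
        if abs(float(total) - 1.0) > 1e-12:
            raise ValueError("stopping pmf must sum to 1")

    def prob(self, final) -> float:
        return float(self.pmf.get(final, 0))

    def to_series(self) -> pd.Series:
        """Float probabilities over s..21 and bust, in table column order."""
        idx = list(range(self.s, 22)) + [BUST]
        return pd.Series([self.prob(f) for f in idx], index=idx, name=f"s={self.s}")


def stopping_distribution(s: int, cards: CardDistribution | None = None) -> StoppingPMF:
    """Exact distribution of the final hand value when drawing while < s.

    Starts with all mass on hand 0 and repeatedly convolves the sub-s mass
    with the card distribution until no mass remains below s; mass above
    21 is aggregated into the bust outcome.  Exact rational arithmetic
    throughout.
    """
    if not 2 <= s <= 21:
        raise ValueError("stopping value must lie in [2, 21]")
    cards = cards or infinite_deck()
    dist: dict = {0: Fraction(1)}
    while any(isinstance(h, int) and h < s for h in dist):
        new: dict = {}
        for h, p in dist.items():
            if isinstance(h, int) and h < s:
                for c, pc in cards.pmf.items():
                    h2 = h + c
                    key = BUST if h2 > 21 else h2
                    new[key] = new.get(key, Fraction(0)) + p * pc
            else:
                new[h] = new.get(h, Fraction(0)) + p
        dist = new
    return StoppingPMF(s, dist)


def bank_payoff(h_gambler, h_croupier) -> int:
    """Bank's payoff (+1/-1) given both final hands (int or BUST).

    The gambler busts -> the bank wins immediately; otherwise a busted
    croupier loses; otherwise the bank wins any standoff (ties go to the
    croupier).
    """
    if h_gambler == BUST:
        return 1
    if h_croupier == BUST:
        return -1
    return 1 if h_croupier >= h_gambler else -1


@dataclass
class PayoffMatrix:
    """Expected bank payoff per (gambler stop value, croupier stop value)."""

    rows: list  # gambler stopping values
    cols: list  # croupier stopping values
    entries: np.ndarray

    def entry(self, s: int, b: int) -> float:
        return float(self.entries[self.rows.index(s), self.cols.index(b)])

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(self.entries, index=self.rows, columns=self.cols)


def mean_payoff_matrix(cards: CardDistribution | None = None) -> PayoffMatrix:
    """Exact expected bank payoff for every modeled strategy pair.

    Rows: gambler stopping values 11..18; columns: croupier 13..19.  Each
    entry averages the +/-1 bank payoff over the product of the two
    stopping distributions.  The gambler's expected payoff is the negative
    entry (zero-sum).
    """
    cards = cards or infinite_deck()
    rows, cols = list(GAMBLER_RANGE), list(CROUPIER_RANGE)
    dists = {s: stopping_distribution(s, cards) for s in set(rows) | set(cols)}
    entries = np.empty((len(rows), len(cols)))
    for i, s in enumerate(rows):
        for j, b in enumerate(cols):
            val = Fraction(0)
            for f, pf in dists[s].pmf.items():
                for g, pg in dists[b].pmf.items():
                    val += pf * pg * bank_payoff(f, g)
            entries[i, j] = float(val)
    return PayoffMatrix(rows, cols, entries)


def find_saddle_point(m: PayoffMatrix) -> list[tuple[int, int]]:
    """All entries that are maximal in their row and minimal in their column.

    The row player (bank-maximizing gambler axis carries the bank's
    payoff) maximizes, the column player minimizes; a saddle point is a
    pure Nash equilibrium of the zero-sum game.  Returns an empty list if
    none exists.
    """
    e = m.entries
    out = []
    for i, s in enumerate(m.rows):
        for j, b in enumerate(m.cols):
            if e[i, j] >= e[i, :].max() and e[i, j] <= e[:, j].min():
                out.append((s, b))
    return out


@dataclass
class BlackjackEpisode:
    """Full log of one blackjack game."""

    gambler_cards: list = field(default_factory=list)
    croupier_cards: list = field(default_factory=list)
    gambler_decisions: list = field(default_factory=list)  # (hand, drew)
    croupier_decisions: list = field(default_factory=list)
    gambler_final: object = None
    croupier_final: object = None
    bank_reward: int = 0

    @property
    def gambler_reward(self) -> int:
        return -self.bank_reward


def _play_hand(policy, modeled, cards, rng, cards_log, decisions_log):
    """Draw cards until the policy stops, busts, or the forced-stop bound."""
    hand = 0
    while True:
        if hand >= _FORCED_STOP:
            break
        if hand in modeled:
            draw = bool(policy(hand, rng))
            decisions_log.append((hand, int(draw)))
            if not draw:
                break
        elif hand >= modeled.stop:
            break  # above the modeled range: stop (certain-loss region)
        c = cards.sample(rng)
        cards_log.append(c)
        hand += c
        if hand > 21:
            return BUST
    return hand


def play_blackjack_episode(
    gambler_policy,
    croupier_policy,
    cards: CardDistribution | None = None,
    seed: int | np.random.Generator = 0,
) -> BlackjackEpisode:
    """Play one game: gambler draws first, then the croupier.

    Policies are callables ``policy(hand_value, rng) -> draw (truthy)``
    consulted only for hand values in the modeled decision ranges
    ([11, 18] gambler, [13, 19] croupier); below the range another card is
    drawn automatically (safe), above it the player stops.  Terminal
    rewards are +/-1 via :func:`bank_payoff`.
    """
    cards = cards or infinite_deck()
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    ep = BlackjackEpisode()
    ep.gambler_final = _play_hand(
        gambler_policy, GAMBLER_RANGE, cards, rng, ep.gambler_cards, ep.gambler_decisions
    )
    if ep.gambler_final == BUST:
        ep.croupier_final = None  # croupier need not play
        ep.bank_reward = 1
        return ep
    ep.croupier_final = _play_hand(
        croupier_policy, CROUPIER_RANGE, cards, rng, ep.croupier_cards, ep.croupier_decisions
    )
    ep.bank_reward = bank_payoff(ep.gambler_final, ep.croupier_final)
    return ep


# ---------------------------------------------------------------------------
# Inspector game


@dataclass(frozen=True)
class InspectorConfig:
    """Inspection cost i; payoff table fixed as documented above."""

    cost_i: float = 0.2

    def __post_init__(self) -> None:
        if not 0 < self.cost_i < 1:
            raise ValueError("inspection cost must lie in (0, 1)")

    def payoff_matrices(self) -> tuple[np.ndarray, np.ndarray]:
        """(employee, employer) payoffs; rows (work, shirk), cols (inspect, pass)."""
        i = self.cost_i
        a = np.array([[0.5, 0.5], [0.0, 1.0]])
        b = np.array([[2.0 - i, 2.0], [1.0 - i, 0.0]])
        return a, b


def inspector_step(a_employee: str, a_employer: str, cfg: InspectorConfig) -> tuple[float, float]:
    """Payoffs (employee, employer) for one round."""
    emp, boss = cfg.payoff_matrices()
    row = {"work": 0, "shirk": 1}[a_employee]
    col = {"inspect": 0, "pass": 1}[a_employer]
    return float(emp[row, col]), float(boss[row, col])


def inspector_mixed_nash(cfg: InspectorConfig) -> dict:
    """Mixed Nash equilibrium of the 2x2 bimatrix game, by indifference.

    Solves the generic interior conditions: the employer mixes so the
    employee is indifferent between work and shirk, and vice versa.  For
    the stated payoffs this yields p_shirk = i and p_inspect = 1/2, but
    the solver works from the payoff matrices, not these constants.

    Returns a dict with keys ``p_shirk``, ``p_inspect``, ``v_employee``,
    ``v_employer``, ``interior`` (False flags a degenerate game with no
    interior mixed equilibrium).
    """
    a, b = cfg.payoff_matrices()
    # employer mixes q = (q_inspect, 1-q_inspect) so employee rows are equal
    denom_q = (a[0, 0] - a[0, 1]) - (a[1, 0] - a[1, 1])
    # employee mixes p = (p_work, 1-p_work) so employer columns are equal
    denom_p = (b[0, 0] - b[0, 1]) - (b[1, 0] - b[1, 1])
    if denom_q == 0 or denom_p == 0:
        return {"interior": False, "p_shirk": np.nan, "p_inspect": np.nan,
                "v_employee": np.nan, "v_employer": np.nan}
    q_inspect = (a[1, 1] - a[0, 1]) / denom_q
    p_work = (b[1, 1] - b[1, 0]) / denom_p
    if not (0 < q_inspect < 1 and 0 < p_work < 1):
        return {"interior": False, "p_shirk": np.nan, "p_inspect": np.nan,
                "v_employee": np.nan, "v_employer": np.nan}
    p = np.array([p_work, 1 - p_work])
    q = np.array([q_inspect, 1 - q_inspect])
    return {
        "interior": True,
        "p_shirk": float(1 - p_work),
        "p_inspect": float(q_inspect),
        "v_employee": float(p @ a @ q),
        "v_employer": float(p @ b @ q),
    }
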