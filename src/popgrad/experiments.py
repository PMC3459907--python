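"""Match orchestration and running-rate analytics.

``run_match`` plays two agents (or fixed policies) against each other for
a configured number of trials of blackjack or the inspector game, logs a
per-trial trajectory, and computes the smoothed decision rates used to
characterize learning: exponential running means of the 0/1 decision
sequences (initialized at 0.5, the random-choice prior), binned rate
changes, and windowed per-state strategy estimates.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from .agents import (
    PRLAgent, PCOVAgent, SarsaAgent, REAgent, FixedStoppingPolicy, MixedPolicy,
)
from .baselines import re_init
from .games import (
    GAMBLER_RANGE, CROUPIER_RANGE, InspectorConfig, infinite_deck,
    inspector_step, inspector_mixed_nash, play_blackjack_episode,
)

__all__ = [
    "ExperimentConfig", "Trajectory", "running_rate", "rate_change_series",
    "estimate_strategy", "run_match",
]


def running_rate(decisions, alpha: float, init: float = 0.5) -> np.ndarray:
    """Exponential running mean r_t = (1-alpha) r_{t-1} + alpha d_t."""
    if not 0 < alpha <= 1:
        raise ValueError("alpha must be in (0, 1]")
    d = np.asarray(decisions, dtype=float)
    out = np.empty(d.size)
    r = float(init)
    for t, x in enumerate(d):
        r = (1.0 - alpha) * r + alpha * x
        out[t] = r
    return out


def rate_change_series(rates, bin_width: int, alpha2: float) -> np.ndarray:
    """Binned first differences of a rate series, re-smoothed.

    Bins the series into windows of ``bin_width``, takes bin means, then
    the differences between succeeding bins, low-pass filtered once more
    with rate ``alpha2``.  Output length is floor(T / bin_width) - 1.
    """
    if bin_width < 1:
        raise ValueError("bin_width must be >= 1")
    r = np.asarray(rates, dtype=float)
    n_bins = r.size // bin_width
    if n_bins < 2:
        raise ValueError("series too short for two bins")
    means = r[: n_bins * bin_width].reshape(n_bins, bin_width).mean(axis=1)
    diffs = np.diff(means)
    return running_rate(diffs, alpha2, init=0.0)


def estimate_strategy(history, state, window: int) -> dict:
    """Fraction of draw (action 1) decisions in the last visits to a state.

    ``history`` is a sequence of (state, action) pairs.  Returns a dict
    with ``rate`` (nan if the state was never visited), ``n`` visits used
    and ``partial`` (True when fewer than ``window`` visits exist).
    """
    if window < 1:
        raise ValueError("window must be >= 1")
    visits = [a for s, a in history if s == state]
    if not visits:
        return {"rate": float("nan"), "n": 0, "partial": True}
    tail = visits[-window:]
    return {
        "rate": float(np.mean(tail)),
        "n": len(tail),
        "partial": len(tail) < window,
    }


@dataclass
class ExperimentConfig:
    """Configuration of one learner-vs-learner (or vs fixed) match.

    ``player_a`` / ``player_b`` are either learner spec strings
    ("prl", "pcov", "td", "re1", "re3", "fixed:<x>" with x a blackjack
    stopping value or an inspector action-1 probability) or agent objects
    implementing ``act``/``finish``.  For the inspector game ``blocks`` is
    a list of (n_trials, inspection_cost) pairs emulating the stepped-cost
    protocol; for blackjack ``n_trials`` games are played.
    """

    game: str = "inspector"
    player_a: object = "prl"
    player_b: object = "prl"
    n_trials: int = 1000
    blocks: list = field(default_factory=list)  # inspector: [(n, cost_i), ...]
    master_seed: int = 0
    smoothing_alpha: float = 0.02
    output_dir: str | None = None

    def __post_init__(self) -> None:
        if self.game not in ("blackjack", "inspector"):
            raise ValueError("game must be 'blackjack' or 'inspector'")
        if self.n_trials < 1:
            raise ValueError("n_trials must be >= 1")
        if not 0 < self.smoothing_alpha <= 1:
            raise ValueError("smoothing_alpha must be in (0, 1]")


@dataclass
class Trajectory:
    """Per-trial log and summary of one match."""

    rows: pd.DataFrame
    summary: dict


def _state_keys(game: str, role: str):
    if game == "blackjack":
        return list(GAMBLER_RANGE) if role == "a" else list(CROUPIER_RANGE)
    return ["inspector"]


def _build_agent(spec, game: str, role: str, cost_i: float, seed: int):
    if hasattr(spec, "act"):
        return spec
    if not isinstance(spec, str):
        raise ValueError(f"unknown learner spec: {spec!r}")
    keys = _state_keys(game, role)
    if spec.startswith("fixed:"):
        x = float(spec.split(":", 1)[1])
        if game == "blackjack":
            return FixedStoppingPolicy(int(x))
        return MixedPolicy(x)
    if spec == "prl":
        return PRLAgent(keys, seed=seed)
    if spec == "pcov":
        return PCOVAgent(keys, seed=seed)
    if spec == "td":
        return SarsaAgent()
    if spec in ("re1", "re3"):
        cfg = InspectorConfig(cost_i)
        emp, boss = cfg.payoff_matrices()
        payoffs = emp if role == "a" else boss
        kwargs = {"eps_gen": 0.1, "phi": 0.1} if spec == "re3" else {}
        return REAgent(re_init(payoffs, strength=10.0, n_actions=2, **kwargs), variant=spec)
    raise ValueError(f"unknown learner spec: {spec!r}")


def run_match(cfg: ExperimentConfig) -> Trajectory:
    """Play the configured match; deterministic given ``master_seed``.

    Returns the trajectory (per-trial rows plus a JSON-able summary) and,
    when ``output_dir`` is set, writes ``trajectory.csv`` and
    ``summary.json`` there.
    """
    rng = np.random.default_rng(cfg.master_seed)
    seed_a, seed_b = (int(rng.integers(2**31)) for _ in range(2))
    if cfg.game == "inspector":
        blocks = cfg.blocks or [(cfg.n_trials, 0.2)]
        first_cost = blocks[0][1]
    else:
        blocks, first_cost = [(cfg.n_trials, 0.0)], 0.0
    agent_a = _build_agent(cfg.player_a, cfg.game, "a", first_cost, seed_a)
    agent_b = _build_agent(cfg.player_b, cfg.game, "b", first_cost, seed_b)

    rows = []
    trial = 0
    for n_block, cost in blocks:
        icfg = InspectorConfig(cost) if cfg.game == "inspector" else None
        for _ in range(n_block):
            if cfg.game == "inspector":
                act_a = agent_a.act("inspector", rng)  # 1 = shirk
                act_b = agent_b.act("inspector", rng)  # 1 = inspect
                r_a, r_b = inspector_step(
                    "shirk" if act_a else "work",
                    "inspect" if act_b else "pass",
                    icfg,
                )
                rows.append({
                    "trial": trial, "block_cost": cost, "state_a": "inspector",
                    "action_a": act_a, "action_b": act_b,
                    "reward_a": r_a, "reward_b": r_b,
                })
            else:
                decisions_a: list[tuple] = []
                decisions_b: list[tuple] = []

                def policy_a(hand, episode_rng):
                    d = agent_a.act(hand, episode_rng)
                    decisions_a.append((hand, d))
                    return d

                def policy_b(hand, episode_rng):
                    d = agent_b.act(hand, episode_rng)
                    decisions_b.append((hand, d))
                    return d

                ep = play_blackjack_episode(policy_a, policy_b, infinite_deck(), rng)
                r_a, r_b = ep.gambler_reward, ep.bank_reward
                rows.append({
                    "trial": trial, "block_cost": cost,
                    "final_a": str(ep.gambler_final), "final_b": str(ep.croupier_final),
                    "decisions_a": decisions_a, "decisions_b": decisions_b,
                    "action_a": decisions_a[-1][1] if decisions_a else np.nan,
                    "action_b": decisions_b[-1][1] if decisions_b else np.nan,
                    "reward_a": r_a, "reward_b": r_b,
                })
            agent_a.finish(r_a)
            agent_b.finish(r_b)
            trial += 1

    df = pd.DataFrame(rows)
    summary: dict = {"n_trials": trial, "game": cfg.game,
                     "mean_reward_a": float(df["reward_a"].mean()),
                     "mean_reward_b": float(df["reward_b"].mean())}
    if cfg.game == "inspector":
        df["shirk_rate"] = running_rate(df["action_a"], cfg.smoothing_alpha)
        df["inspect_rate"] = running_rate(df["action_b"], cfg.smoothing_alpha)
        block_stats = []
        start = 0
        for n_block, cost in blocks:
            sub = df.iloc[start:start + n_block]
            nash = inspector_mixed_nash(InspectorConfig(cost))
            block_stats.append({
                "cost_i": cost,
                "n": int(len(sub)),
                "mean_shirk": float(sub["action_a"].mean()),
                "mean_inspect": float(sub["action_b"].mean()),
                "mean_reward_a": float(sub["reward_a"].mean()),
                "mean_reward_b": float(sub["reward_b"].mean()),
                "nash_dist_shirk": float(abs(sub["action_a"].mean() - nash["p_shirk"])),
                "nash_dist_inspect": float(abs(sub["action_b"].mean() - nash["p_inspect"])),
            })
            start += n_block
        summary["blocks"] = block_stats
    else:
        history_a = [d for r in rows for d in r["decisions_a"]]
        history_b = [d for r in rows for d in r["decisions_b"]]
        summary["strategy_a"] = {
            str(s): estimate_strategy(history_a, s, window=100)["rate"]
            for s in GAMBLER_RANGE
        }
        summary["strategy_b"] = {
            str(s): estimate_strategy(history_b, s, window=100)["rate"]
            for s in CROUPIER_RANGE
        }

    if cfg.output_dir:
        out = Path(cfg.output_dir)
        out.mkdir(parents=True, exist_ok=True)
        df.to_csv(out / "trajectory.csv", index=False)
        (out / "summary.json").write_text(json.dumps(summary, indent=2))
    return Trajectory(df, summary)
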