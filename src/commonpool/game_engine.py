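"""Resource dynamics of the four-player harvesting game.

The group shares a pool that starts at 230 points. Each round every
player privately requests up to 20 points; the pool is reduced by the
sum of fulfilled harvests and then partially replenished: a uniform
integer draw between 17% and 23% of the post-harvest pool is added, and
the result is damped by a running total that weights the previous pool
value by one third. The game ends when the pool hits 0 or after 109
rounds, whichever comes first.
"""

from __future__ import annotations

import enum
from dataclasses import dataclass, field, replace
from fractions import Fraction

import numpy as np

N_PLAYERS = 4


class TerminationReason(str, enum.Enum):
    RUNNING = "running"
    EXHAUSTED = "exhausted"
    MAX_TRIALS = "max_trials"


class ShortfallRule(str, enum.Enum):
    """How to fulfil requests when their sum exceeds the remaining pool."""

    PROPORTIONAL = "proportional"
    EQUAL_SPLIT = "equal_split"
    CLIP_IN_ORDER = "clip_in_order"


class GameStateError(RuntimeError):
    """Raised when an operation is applied to a terminated game."""


def _round_half_up(x: float) -> int:
    # deterministic half-up rounding; avoids Python's banker's rounding
    return int(np.floor(x + 0.5))


def _frac_mul_round(frac: float, value: int) -> int:
    """round_half_up(frac * value), exact for arbitrarily large ints."""
    if value <= 2**52:
        return _round_half_up(frac * value)
    f = Fraction(frac).limit_denominator(10**9)
    v = f * value
    return (2 * v.numerator + v.denominator) // (2 * v.denominator)


@dataclass(frozen=True)
class EngineConfig:
    """Parameters of the pool dynamics.

    ``previous_weight`` is the running-total damping weight w: the
    post-replenishment pool is ``w * R_prev + (1 - w) * (R_post + increment)``,
    rounded to the nearest integer point.
    """

    initial_resource: int = 230
    harvest_cap: int = 20
    replenish_low_frac: float = 0.17
    replenish_high_frac: float = 0.23
    previous_weight: float = 1.0 / 3.0
    max_trials: int = 109
    shortfall_rule: ShortfallRule = ShortfallRule.PROPORTIONAL

    def __post_init__(self) -> None:
        if self.initial_resource < 0:
            raise ValueError("initial_resource must be non-negative")
        if self.harvest_cap <= 0:
            raise ValueError("harvest_cap must be positive")
        if not (0.0 < self.replenish_low_frac <= self.replenish_high_frac < 1.0):
            raise ValueError(
                "replenishment fractions must satisfy 0 < low <= high < 1"
            )
        if not (0.0 <= self.previous_weight < 1.0):
            raise ValueError("previous_weight must be in [0, 1)")
        if self.max_trials <= 0:
            raise ValueError("max_trials must be positive")
        object.__setattr__(self, "shortfall_rule", ShortfallRule(self.shortfall_rule))

    @property
    def mean_multiplier(self) -> float:
        """Expected growth factor applied to the post-harvest pool."""
        return 1.0 + 0.5 * (self.replenish_low_frac + self.replenish_high_frac)

    def to_dict(self) -> dict:
        return {
            "initial_resource": self.initial_resource,
            "harvest_cap": self.harvest_cap,
            "replenish_low_frac": self.replenish_low_frac,
            "replenish_high_frac": self.replenish_high_frac,
            "previous_weight": self.previous_weight,
            "max_trials": self.max_trials,
            "shortfall_rule": self.shortfall_rule.value,
        }

    @classmethod
    def from_dict(cls, d: dict) -> "EngineConfig":
        return cls(**d)


@dataclass(frozen=True)
class GameState:
    resource: int
    cumulative_points: np.ndarray = field(
        default_factory=lambda: np.zeros(N_PLAYERS, dtype=int)
    )
    trial_index: int = 0
    terminated: bool = False
    termination_reason: TerminationReason = TerminationReason.RUNNING

    def __post_init__(self) -> None:
        if self.resource < 0:
            raise ValueError("resource must be non-negative")
        pts = np.asarray(self.cumulative_points, dtype=int)
        if pts.shape != (N_PLAYERS,) or np.any(pts < 0):
            raise ValueError("cumulative_points must be a non-negative 4-vector")
        object.__setattr__(self, "cumulative_points", pts)


def initial_state(config: EngineConfig) -> GameState:
    return GameState(resource=config.initial_resource)


def _apportion(requests: np.ndarray, available: int, rule: ShortfallRule) -> np.ndarray:
    """Split ``available`` points among requests summing to more than it."""
    if rule is ShortfallRule.PROPORTIONAL:
        total = requests.sum()
        quota = available * requests / total
        fulfilled = np.floor(quota).astype(int)
        # largest-remainder: hand out the leftover points one by one,
        # ties broken by player position
        leftover = available - fulfilled.sum()
        remainders = quota - np.floor(quota)
        order = np.lexsort((np.arange(len(requests)), -remainders))
        for i in order[:leftover]:
            fulfilled[i] += 1
        return fulfilled
    if rule is ShortfallRule.EQUAL_SPLIT:
        # water-filling: equal shares capped by each request
        fulfilled = np.zeros_like(requests)
        remaining = available
        active = requests > 0
        while remaining > 0 and active.any():
            share = max(remaining // active.sum(), 1)
            for i in np.flatnonzero(active):
                take = min(share, requests[i] - fulfilled[i], remaining)
                fulfilled[i] += take
                remaining -= take
                if fulfilled[i] == requests[i]:
                    active[i] = False
                if remaining == 0:
                    break
        return fulfilled
    if rule is ShortfallRule.CLIP_IN_ORDER:
        fulfilled = np.zeros_like(requests)
        remaining = available
        for i, r in enumerate(requests):
            take = min(r, remaining)
            fulfilled[i] = take
            remaining -= take
        return fulfilled
    raise ValueError(f"unknown shortfall rule: {rule}")


def apply_harvests(
    state: GameState, requests, config: EngineConfig
) -> tuple[GameState, np.ndarray]:
    """Deduct the group's harvests from the pool.

    Returns the post-harvest state and the fulfilled harvest vector.
    When the requests exceed the remaining pool, the pool is split
    according to ``config.shortfall_rule`` and the pool drops to 0.
    """
    if state.terminated:
        raise GameStateError("cannot harvest from a terminated game")
    req = np.asarray(requests, dtype=int)
    if req.shape != (N_PLAYERS,):
        raise ValueError(f"requests must be a {N_PLAYERS}-vector")
    if np.any(req < 0) or np.any(req > config.harvest_cap):
        raise ValueError(
            f"each request must lie in [0, {config.harvest_cap}], got {req.tolist()}"
        )
    total = int(req.sum())
    if total <= state.resource:
        fulfilled = req.copy()
    else:
        fulfilled = _apportion(req, state.resource, config.shortfall_rule)
    new_state = replace(
        state,
        resource=state.resource - int(fulfilled.sum()),
        cumulative_points=state.cumulative_points + fulfilled,
    )
    return new_state, fulfilled


def replenish(
    previous_resource: int,
    post_harvest_resource: int,
    config: EngineConfig,
    rng: np.random.Generator,
) -> int:
    """Stochastic pool restoration after a round of harvests.

    An integer increment is drawn uniformly between 17% and 23% (the
    configured fractions) of the post-harvest pool, then the result is
    damped against the pool value at the start of the round:

        R_new = round(w * R_prev + (1 - w) * (R_post + increment))
    """
    if previous_resource < 0 or post_harvest_resource < 0:
        raise ValueError("resource values must be non-negative")
    increment = _draw_increment(post_harvest_resource, config, rng)
    return _combine(previous_resource, post_harvest_resource, increment, config)


def _draw_increment(
    post_harvest_resource: int, config: EngineConfig, rng: np.random.Generator
) -> int:
    lo = _frac_mul_round(config.replenish_low_frac, post_harvest_resource)
    hi = _frac_mul_round(config.replenish_high_frac, post_harvest_resource)
    if hi >= 2**62:  # astronomically large pools overflow integer sampling
        width = hi - lo + 1
        return lo + (width * int(rng.random() * 2**53)) // 2**53
    return int(rng.integers(lo, hi + 1))


def _combine(
    previous_resource: int, post_harvest_resource: int, increment: int, config: EngineConfig
) -> int:
    w = config.previous_weight
    total = post_harvest_resource + increment
    if max(previous_resource, total) > 2**52:
        fw = Fraction(w).limit_denominator(10**9)
        v = fw * previous_resource + (1 - fw) * total
        return (2 * v.numerator + v.denominator) // (2 * v.denominator)
    return _round_half_up(w * previous_resource + (1.0 - w) * total)


def step(
    state: GameState, requests, config: EngineConfig, rng: np.random.Generator
) -> tuple[GameState, np.ndarray, int]:
    """Advance the game by one round: harvest, replenish, check termination.

    Returns ``(new_state, fulfilled, increment)`` where ``increment`` is
    the raw replenishment draw (0 if the pool was exhausted and no
    replenishment occurred).
    """
    resource_before = state.resource
    harvested, fulfilled = apply_harvests(state, requests, config)
    trial_index = state.trial_index + 1
    if harvested.resource == 0:
        new_state = replace(
            harvested,
            trial_index=trial_index,
            terminated=True,
            termination_reason=TerminationReason.EXHAUSTED,
        )
        return new_state, fulfilled, 0
    increment = _draw_increment(harvested.resource, config, rng)
    new_resource = _combine(resource_before, harvested.resource, increment, config)
    terminated = trial_index >= config.max_trials
    new_state = replace(
        harvested,
        resource=new_resource,
        trial_index=trial_index,
        terminated=terminated,
        termination_reason=(
            TerminationReason.MAX_TRIALS if terminated else TerminationReason.RUNNING
        ),
    )
    return new_state, fulfilled, increment
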