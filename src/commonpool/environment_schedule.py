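"""Confederate environments and the pseudorandom block schedule.

The participant plays with three scripted co-players (confederates).
The game opens with a 5-trial warm-up in which the confederates jointly
hold the pool near its starting value, followed by eight 13-trial
blocks: two repetitions each of four social environments in which one
or two confederates saliently over- or under-harvest while the rest
apply gentle downward pressure. One-over blocks are never adjacent to
two-over blocks, and one-under blocks never adjacent to two-under
blocks.

Confederate harvest levels are calibrated against the engine's expected
dynamics rather than hard-coded: a level is expressed as the per-
confederate pool-sustaining share plus an offset chosen so the role
imposes a target drift (points per trial) on the pool.
"""

from __future__ import annotations

import enum
import json
from dataclasses import dataclass, field

import numpy as np

from commonpool.game_engine import EngineConfig, _round_half_up

WARMUP_LENGTH = 5
BLOCK_LENGTH = 13
REPEATS_PER_ENVIRONMENT = 2
N_CONFEDERATES = 3

#: Default drift (pool points per trial at the initial pool value,
#: + grows the pool) each role imposes beyond its baseline share.
DEFAULT_ROLE_DRIFTS = {
    "over": -7.0,
    "under": 7.0,
    "neutral": -0.6,
    "maintain": 0.0,
}


class Role(str, enum.Enum):
    OVER = "over"
    UNDER = "under"
    NEUTRAL = "neutral"
    MAINTAIN = "maintain"


class EnvironmentLabel(str, enum.Enum):
    WARMUP = "warmup"
    ONE_OVER = "one_over"
    TWO_OVER = "two_over"
    ONE_UNDER = "one_under"
    TWO_UNDER = "two_under"


_SALIENT = {
    EnvironmentLabel.ONE_OVER: (Role.OVER, 1),
    EnvironmentLabel.TWO_OVER: (Role.OVER, 2),
    EnvironmentLabel.ONE_UNDER: (Role.UNDER, 1),
    EnvironmentLabel.TWO_UNDER: (Role.UNDER, 2),
}

_MAIN_LABELS = tuple(_SALIENT)

# forbidden neighbours: one-over next to two-over, one-under next to two-under
_FORBIDDEN_ADJACENT = {
    frozenset({EnvironmentLabel.ONE_OVER, EnvironmentLabel.TWO_OVER}),
    frozenset({EnvironmentLabel.ONE_UNDER, EnvironmentLabel.TWO_UNDER}),
}


class CalibrationError(RuntimeError):
    """Raised when no feasible harvest level satisfies a role's drift."""


@dataclass(frozen=True)
class Environment:
    """One social environment: a label plus per-confederate role tags."""

    label: EnvironmentLabel
    salient_roles: tuple[Role, Role, Role]

    def __post_init__(self) -> None:
        if len(self.salient_roles) != N_CONFEDERATES:
            raise ValueError("salient_roles must tag all three confederates")
        if self.label is EnvironmentLabel.WARMUP:
            if any(r is not Role.MAINTAIN for r in self.salient_roles):
                raise ValueError("warm-up confederates must all be 'maintain'")
        else:
            role, count = _SALIENT[self.label]
            if sum(r is role for r in self.salient_roles) != count:
                raise ValueError(
                    f"{self.label.value} requires exactly {count} {role.value} confederate(s)"
                )
            if any(
                r is not role and r is not Role.NEUTRAL for r in self.salient_roles
            ):
                raise ValueError("non-salient confederates must be 'neutral'")

    @property
    def over_present(self) -> int:
        return int(self.label in (EnvironmentLabel.ONE_OVER, EnvironmentLabel.TWO_OVER))


@dataclass(frozen=True)
class Schedule:
    """Ordered (environment, block length) pairs covering the whole game."""

    blocks: tuple[tuple[Environment, int], ...]
    total_trials: int = field(init=False)

    def __post_init__(self) -> None:
        object.__setattr__(
            self, "total_trials", sum(length for _, length in self.blocks)
        )

    def trial_environments(self) -> list[Environment]:
        """Environment in force at each of the game's trials, in order."""
        out: list[Environment] = []
        for env, length in self.blocks:
            out.extend([env] * length)
        return out

    def to_json(self) -> str:
        payload = {
            "total_trials": self.total_trials,
            "blocks": [
                {
                    "label": env.label.value,
                    "salient_roles": [r.value for r in env.salient_roles],
                    "length": length,
                }
                for env, length in self.blocks
            ],
            "trial_labels": [e.label.value for e in self.trial_environments()],
        }
        return json.dumps(payload, indent=2)


def _assign_roles(
    label: EnvironmentLabel, rng: np.random.Generator
) -> tuple[Role, Role, Role]:
    if label is EnvironmentLabel.WARMUP:
        return (Role.MAINTAIN,) * N_CONFEDERATES
    role, count = _SALIENT[label]
    roles = [Role.NEUTRAL] * N_CONFEDERATES
    for i in rng.choice(N_CONFEDERATES, size=count, replace=False):
        roles[i] = role
    return tuple(roles)


def generate_schedule(rng: np.random.Generator | int) -> Schedule:
    """Sample a valid block order: warm-up first, then the eight main blocks.

    Rejection-samples permutations of the two-repetition block multiset
    until the adjacency constraints hold; which confederates carry the
    salient roles is randomized per block.
    """
    if not isinstance(rng, np.random.Generator):
        rng = np.random.default_rng(rng)
    labels = list(_MAIN_LABELS) * REPEATS_PER_ENVIRONMENT
    while True:
        order = [labels[i] for i in rng.permutation(len(labels))]
        ok = all(
            frozenset({a, b}) not in _FORBIDDEN_ADJACENT
            for a, b in zip(order, order[1:])
        )
        if ok:
            break
    blocks = [
        (
            Environment(EnvironmentLabel.WARMUP, _assign_roles(EnvironmentLabel.WARMUP, rng)),
            WARMUP_LENGTH,
        )
    ]
    blocks.extend(
        (Environment(label, _assign_roles(label, rng)), BLOCK_LENGTH) for label in order
    )
    return Schedule(blocks=tuple(blocks))


@dataclass(frozen=True)
class ConfederatePolicy:
    """A scripted co-player's harvesting rule.

    ``target_drift`` is the pool change per trial (in points) the role
    should impose beyond the confederates' joint sustaining level;
    negative values deplete the pool. ``noise_half_width`` is the
    half-width of the uniform integer jitter on emitted harvests.
    """

    role: Role
    target_drift: float
    noise_half_width: int = 1

    def __post_init__(self) -> None:
        if self.noise_half_width < 0:
            raise ValueError("noise_half_width must be non-negative")


def default_policies(
    noise_half_width: int = 1,
) -> dict[Role, ConfederatePolicy]:
    return {
        role: ConfederatePolicy(role, DEFAULT_ROLE_DRIFTS[role.value], noise_half_width)
        for role in Role
    }


def _sustain_total(resource: float, config: EngineConfig) -> float:
    """Total group harvest at which the expected pool update is flat."""
    rho = 0.5 * (config.replenish_low_frac + config.replenish_high_frac)
    return resource * rho / (1.0 + rho)


def _drift_sensitivity(config: EngineConfig) -> float:
    """Expected pool-drift change per extra harvested point (negative)."""
    return -(1.0 - config.previous_weight) * config.mean_multiplier


def _role_level(
    role: Role,
    target_drift: float,
    resource: float,
    config: EngineConfig,
) -> float:
    """Harvest level realizing a role's drift at the current pool value.

    Warm-up maintainers split the whole sustaining budget three ways (the
    confederates alone hold the pool level). In the main environments the
    baseline is the four-player fair share — the participant's share is
    left untouched — and the role's drift offset scales with the pool so
    pressure eases as the pool shrinks.
    """
    if role is Role.MAINTAIN:
        return _sustain_total(resource, config) / N_CONFEDERATES
    share = _sustain_total(resource, config) / 4.0
    scale = resource / config.initial_resource
    offset = target_drift / _drift_sensitivity(config) * scale
    if target_drift > 0:
        # pool-growing roles ease off as the pool approaches 1.5x its
        # starting value: with capped harvests a large pool replenishes
        # faster than the group can drain it, so unchecked growth would
        # run away
        hi = 1.5 * config.initial_resource
        damp = np.clip((hi - resource) / (hi - config.initial_resource), 0.0, 1.0)
        offset *= damp
    return share + offset


def confederate_harvest(
    policy: ConfederatePolicy,
    current_resource: int,
    config: EngineConfig,
    rng: np.random.Generator,
) -> int:
    """Integer harvest emitted by a confederate at the current pool value."""
    if current_resource < 0:
        raise ValueError("current_resource must be non-negative")
    if current_resource == 0:
        return 0
    level = _role_level(policy.role, policy.target_drift, current_resource, config)
    jitter = (
        int(rng.integers(-policy.noise_half_width, policy.noise_half_width + 1))
        if policy.noise_half_width > 0
        else 0
    )
    harvest = _round_half_up(level) + jitter
    return int(np.clip(harvest, 0, config.harvest_cap))


def calibrate_roles(
    config: EngineConfig,
    reference_resource: int,
    drifts: dict[str, float] | None = None,
) -> dict[Role, float]:
    """Solve for each role's harvest level at a reference pool value.

    The 'maintain' level is the root of the expected-update equation for
    three confederates holding the pool constant; the other roles offset
    the four-player fair share to impose their target drift. Raises
    :class:`CalibrationError` when a level falls outside
    [0, harvest_cap].
    """
    if reference_resource <= 0:
        raise ValueError("reference_resource must be positive")
    drifts = {**DEFAULT_ROLE_DRIFTS, **(drifts or {})}
    levels = {
        role: _role_level(role, drifts[role.value], reference_resource, config)
        for role in Role
    }
    for role, level in levels.items():
        if not (0.0 <= level <= config.harvest_cap):
            raise CalibrationError(
                f"{role.value} level {level:.2f} outside [0, {config.harvest_cap}] "
                f"at reference resource {reference_resource}"
            )
    return levels
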