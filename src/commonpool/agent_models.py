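"""Synthetic participant policies (the cohort generator).

No generative participant model exists for the original task, so this
module supplies one with exactly the statistical structure the
downstream regression assumes: the trial-to-trial harvest adjustment
(ΔHarvest) is linear in the participant's previous harvest, the current
pool value, an overharvester-present indicator, and a cubic polynomial
in the rank of the previous harvest within the group's norm, plus
additive Gaussian noise. The requested harvest is the previous harvest
plus the adjustment, rounded then clipped to [0, cap].

Two default parameter sets mirror the qualitative treatment contrast:
the control set (T+) has strong negative self-correction and a steep
S-shaped rank response (large upward adjustments after low-ranked
harvests, large downward after high-ranked ones); the depleted set (T–)
has attenuated self-correction and a flattened rank response, which
makes its harvesting more aggressive and less norm-sensitive.
"""

from __future__ import annotations

import enum
from dataclasses import dataclass, field, replace

import numpy as np

from commonpool.game_engine import _round_half_up
from commonpool.norm_statistics import RankFeatures


class Treatment(str, enum.Enum):
    T_PLUS = "T_plus"
    T_MINUS = "T_minus"


@dataclass(frozen=True)
class AgentParams:
    """Coefficients of the ΔHarvest policy for one treatment group."""

    intercept: float
    coef_prev_harvest: float
    coef_resource: float
    coef_over_present: float
    coef_rank1: float
    coef_rank2: float
    coef_rank3: float
    noise_sd: float = 2.0
    treatment_tag: Treatment = Treatment.T_PLUS

    def __post_init__(self) -> None:
        if self.noise_sd < 0:
            raise ValueError("noise_sd must be non-negative")
        object.__setattr__(self, "treatment_tag", Treatment(self.treatment_tag))

    @property
    def rank_coefs(self) -> tuple[float, float, float]:
        return (self.coef_rank1, self.coef_rank2, self.coef_rank3)

    def to_dict(self) -> dict:
        return {
            "intercept": self.intercept,
            "coef_prev_harvest": self.coef_prev_harvest,
            "coef_resource": self.coef_resource,
            "coef_over_present": self.coef_over_present,
            "coef_rank1": self.coef_rank1,
            "coef_rank2": self.coef_rank2,
            "coef_rank3": self.coef_rank3,
            "noise_sd": self.noise_sd,
            "treatment_tag": self.treatment_tag.value,
        }

    @classmethod
    def from_dict(cls, d: dict) -> "AgentParams":
        return cls(**d)


_DEFAULTS = {
    # Strong self-correction; steep cubic rank response whose slope is
    # greatest at the extremes of the rank scale.
    Treatment.T_PLUS: AgentParams(
        intercept=2.0,
        coef_prev_harvest=-0.70,
        coef_resource=0.035,
        coef_over_present=1.0,
        coef_rank1=-18.0,
        coef_rank2=36.0,
        coef_rank3=-24.0,
        noise_sd=2.0,
        treatment_tag=Treatment.T_PLUS,
    ),
    # Attenuated self-correction and a flattened rank response: harvests
    # settle near the top of the group distribution and adjust weakly.
    Treatment.T_MINUS: AgentParams(
        intercept=1.0,
        coef_prev_harvest=-0.35,
        coef_resource=0.012,
        coef_over_present=1.2,
        coef_rank1=-2.0,
        coef_rank2=4.0,
        coef_rank3=-3.0,
        noise_sd=2.0,
        treatment_tag=Treatment.T_MINUS,
    ),
}


def default_params(treatment_tag: Treatment | str) -> AgentParams:
    """Documented default parameter set for a treatment group."""
    try:
        tag = Treatment(treatment_tag)
    except ValueError as exc:
        raise ValueError(f"unknown treatment tag: {treatment_tag!r}") from exc
    return _DEFAULTS[tag]


@dataclass(frozen=True)
class CohortSpec:
    """A two-group synthetic cohort: sizes, parameter sets, master seed."""

    n_per_group: int = 16
    params_T_plus: AgentParams = field(
        default_factory=lambda: default_params(Treatment.T_PLUS)
    )
    params_T_minus: AgentParams = field(
        default_factory=lambda: default_params(Treatment.T_MINUS)
    )
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_per_group < 1:
            raise ValueError("n_per_group must be at least 1")

    def to_dict(self) -> dict:
        return {
            "n_per_group": self.n_per_group,
            "params_T_plus": self.params_T_plus.to_dict(),
            "params_T_minus": self.params_T_minus.to_dict(),
            "seed": self.seed,
        }

    @classmethod
    def from_dict(cls, d: dict) -> "CohortSpec":
        d = dict(d)
        d["params_T_plus"] = AgentParams.from_dict(d["params_T_plus"])
        d["params_T_minus"] = AgentParams.from_dict(d["params_T_minus"])
        return cls(**d)


def delta_mean(
    params: AgentParams,
    own_last_harvest: float,
    rank_features: RankFeatures,
    resource: float,
    over_present: int,
) -> float:
    """Deterministic part of the harvest adjustment."""
    return (
        params.intercept
        + params.coef_prev_harvest * own_last_harvest
        + params.coef_resource * resource
        + params.coef_over_present * over_present
        + params.coef_rank1 * rank_features.rank
        + params.coef_rank2 * rank_features.rank2
        + params.coef_rank3 * rank_features.rank3
    )


def agent_step(
    params: AgentParams,
    own_last_harvest: int,
    rank_features: RankFeatures,
    resource: int,
    over_present: int,
    rng: np.random.Generator,
    harvest_cap: int = 20,
) -> int:
    """Draw the participant's next harvest request.

    ΔHarvest = linear mean + Gaussian noise; the request is the previous
    harvest plus ΔHarvest, rounded to an integer and clipped to
    [0, harvest_cap] (round first, then clip).
    """
    if over_present not in (0, 1):
        raise ValueError("over_present must be 0 or 1")
    delta = delta_mean(params, own_last_harvest, rank_features, resource, over_present)
    if params.noise_sd > 0:
        delta += rng.normal(0.0, params.noise_sd)
    request = _round_half_up(own_last_harvest + delta)
    return int(np.clip(request, 0, harvest_cap))


def attenuated_copy(params: AgentParams, **overrides) -> AgentParams:
    """Convenience: a modified copy of a parameter set."""
    return replace(params, **overrides)
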