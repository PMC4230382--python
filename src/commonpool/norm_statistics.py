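"""Descriptive social norms as beta distributions and rank features.

Each round's four harvests define a descriptive social norm: a beta
distribution scaled to the harvest support [0, 20] and fitted to the
four values by method of moments. A player's relative rank is the
norm's cumulative density at their own harvest — their position within
the group's harvest distribution. The regression downstream uses the
rank together with its square and cube.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import special

SUPPORT = (0.0, 20.0)
#: scaled values are clipped away from the boundary before fitting so a
#: harvest of exactly 0 or 20 cannot break moment feasibility
CLIP_EPS = 1e-3
N_HARVESTS = 4


@dataclass(frozen=True)
class BetaNorm:
    """A fitted norm: beta(alpha, beta) on harvests rescaled to [0, 1].

    ``degenerate`` marks samples with zero variance or infeasible
    moments (variance >= m(1-m) on the [0, 1] scale); rank queries on a
    degenerate norm fall back to the midrank convention over the raw
    harvests, which are retained in ``harvests``.
    """

    alpha: float
    beta: float
    degenerate: bool
    harvests: tuple[float, ...]

    def __post_init__(self) -> None:
        if not self.degenerate and (self.alpha <= 0 or self.beta <= 0):
            raise ValueError("non-degenerate norm requires alpha > 0 and beta > 0")

    @property
    def mean(self) -> float:
        """Mean of the fitted norm on the harvest scale."""
        if self.degenerate:
            return float(np.mean(self.harvests))
        return SUPPORT[1] * self.alpha / (self.alpha + self.beta)


@dataclass(frozen=True)
class RankFeatures:
    rank: float
    rank2: float
    rank3: float


def _validate_harvests(harvests) -> np.ndarray:
    arr = np.asarray(harvests, dtype=float)
    if arr.shape != (N_HARVESTS,):
        raise ValueError(f"expected exactly {N_HARVESTS} harvests, got shape {arr.shape}")
    if np.any(arr < SUPPORT[0]) or np.any(arr > SUPPORT[1]):
        raise ValueError(f"harvests must lie in [{SUPPORT[0]:g}, {SUPPORT[1]:g}]")
    return arr


def fit_norm(harvests) -> BetaNorm:
    """Fit the round's social norm to four harvests by method of moments.

    Moments use the population (n-divisor) variance of the harvests
    rescaled to [0, 1]. Feasibility is judged on the raw rescaled
    values; the moment equations are then solved on boundary-clipped
    values:

        t = m(1-m)/v - 1,  alpha = m t,  beta = (1-m) t
    """
    arr = _validate_harvests(harvests)
    x = arr / SUPPORT[1]
    m_raw, v_raw = float(x.mean()), float(x.var())
    if v_raw <= 0.0 or v_raw >= m_raw * (1.0 - m_raw):
        return BetaNorm(np.nan, np.nan, True, tuple(arr))
    xc = np.clip(x, CLIP_EPS, 1.0 - CLIP_EPS)
    m, v = float(xc.mean()), float(xc.var())
    t = m * (1.0 - m) / v - 1.0
    return BetaNorm(m * t, (1.0 - m) * t, False, tuple(arr))


def rank_in_norm(value: float, norm: BetaNorm) -> float:
    """Relative rank of a harvest: the norm's cumulative density at it.

    A rank near 0 means the harvest sits at the bottom of the group's
    distribution, near 1 at the top. For degenerate norms the fallback
    is the midrank of ``value`` among the stored harvests:
    (#smaller + 0.5 * #equal) / 4.
    """
    value = float(value)
    if not (SUPPORT[0] <= value <= SUPPORT[1]):
        raise ValueError(f"value {value} outside support {SUPPORT}")
    if norm.degenerate:
        arr = np.asarray(norm.harvests)
        smaller = np.sum(arr < value)
        equal = np.sum(arr == value)
        return float((smaller + 0.5 * equal) / len(arr))
    return float(special.betainc(norm.alpha, norm.beta, value / SUPPORT[1]))


def build_rank_features(own_last_harvest: float, all_last_harvests) -> RankFeatures:
    """Rank of a player's last harvest within the group's last four.

    The norm is fitted to all four harvests, the player's own included.
    """
    arr = _validate_harvests(all_last_harvests)
    if not np.any(arr == float(own_last_harvest)):
        raise ValueError("own_last_harvest must be one of the four harvests")
    norm = fit_norm(arr)
    r = rank_in_norm(own_last_harvest, norm)
    return RankFeatures(rank=r, rank2=r**2, rank3=r**3)
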