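"""Endgame outcomes and group-level contingency statistics.

Per game: the participant's total points, the final pool value, whether
the pool was exhausted, and the number of completed trials. Across a
cohort: per-group means with standard errors, exhaustion counts, and
the uncorrected Pearson chi-square on the 2x2 exhausted-by-treatment
table.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Iterable, Sequence

import numpy as np
import pandas as pd

from commonpool.agent_models import Treatment


@dataclass(frozen=True)
class GameOutcome:
    game_id: str
    treatment: Treatment
    total_points_participant: int
    final_resource: int
    exhausted: bool
    n_trials_completed: int

    def __post_init__(self) -> None:
        object.__setattr__(self, "treatment", Treatment(self.treatment))
        if self.exhausted and self.final_resource != 0:
            raise ValueError("exhausted games must end with a resource of 0")
        if self.total_points_participant < 0 or self.final_resource < 0:
            raise ValueError("points and resource must be non-negative")
        if self.n_trials_completed < 0:
            raise ValueError("n_trials_completed must be non-negative")


@dataclass(frozen=True)
class ContingencyTable2x2:
    """Counts for exhausted/not (rows) by treatment T-/T+ (columns).

    Layout: a = T- exhausted, b = T- not exhausted,
            c = T+ exhausted, d = T+ not exhausted.
    """

    a: int
    b: int
    c: int
    d: int
    row_labels: tuple[str, str] = ("exhausted", "not_exhausted")
    col_labels: tuple[str, str] = (Treatment.T_MINUS.value, Treatment.T_PLUS.value)

    def __post_init__(self) -> None:
        if min(self.a, self.b, self.c, self.d) < 0:
            raise ValueError("counts must be non-negative")

    @property
    def total(self) -> int:
        return self.a + self.b + self.c + self.d

    @property
    def margins(self) -> tuple[int, int, int, int]:
        return (self.a + self.b, self.c + self.d, self.a + self.c, self.b + self.d)

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            [[self.a, self.b], [self.c, self.d]],
            index=pd.Index(self.col_labels, name="treatment"),
            columns=pd.Index(self.row_labels, name="outcome"),
        )


def chi_square_2x2(table: ContingencyTable2x2) -> tuple[float, int]:
    """Uncorrected Pearson chi-square for a 2x2 table, df = 1.

    Closed form N(ad - bc)^2 / ((a+b)(c+d)(a+c)(b+d)). No continuity
    correction is applied. Raises on a zero margin, where the statistic
    is undefined.
    """
    if table.total <= 0:
        raise ValueError("table total must be positive")
    if min(table.margins) == 0:
        raise ValueError(
            "chi-square undefined: zero margin in table "
            f"(margins {table.margins})"
        )
    a, b, c, d = table.a, table.b, table.c, table.d
    num = table.total * (a * d - b * c) ** 2
    den = np.prod([float(m) for m in table.margins])
    return float(num / den), 1


def _group_summary(values: Sequence[float]) -> tuple[float, float, bool]:
    arr = np.asarray(values, dtype=float)
    mean = float(arr.mean())
    if len(arr) < 2:
        return mean, 0.0, True  # SE undefined for a single game; flagged
    return mean, float(arr.std(ddof=1) / np.sqrt(len(arr))), False


def summarize_outcomes(outcomes: Iterable[GameOutcome]) -> pd.DataFrame:
    """Per-treatment means and standard errors of the endgame measures."""
    outcomes = list(outcomes)
    if not outcomes:
        raise ValueError("no outcomes to summarize")
    rows = []
    for treatment in Treatment:
        group = [o for o in outcomes if o.treatment is treatment]
        if not group:
            raise ValueError(f"no outcomes for treatment group {treatment.value}")
        points = [o.total_points_participant for o in group]
        final = [o.final_resource for o in group]
        mp, sep, flag_p = _group_summary(points)
        mf, sef, flag_f = _group_summary(final)
        rows.append(
            {
                "treatment": treatment.value,
                "n_games": len(group),
                "mean_total_points": mp,
                "se_total_points": sep,
                "mean_final_resource": mf,
                "se_final_resource": sef,
                "n_exhausted": sum(o.exhausted for o in group),
                "prop_exhausted": sum(o.exhausted for o in group) / len(group),
                "se_undefined": flag_p or flag_f,
            }
        )
    return pd.DataFrame(rows)


def exhaustion_table(outcomes: Iterable[GameOutcome]) -> ContingencyTable2x2:
    """Cross-tabulate exhaustion by treatment group."""
    outcomes = list(outcomes)
    groups = {t: [o for o in outcomes if o.treatment is t] for t in Treatment}
    for t, group in groups.items():
        if not group:
            raise ValueError(f"missing treatment group {t.value}")
    minus = groups[Treatment.T_MINUS]
    plus = groups[Treatment.T_PLUS]
    return ContingencyTable2x2(
        a=sum(o.exhausted for o in minus),
        b=sum(not o.exhausted for o in minus),
        c=sum(o.exhausted for o in plus),
        d=sum(not o.exhausted for o in plus),
    )
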