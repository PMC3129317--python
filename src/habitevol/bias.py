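"""Chi-square test for bias in which states act as evolutionary progenitors.

Null hypothesis: each life-habit category is equally likely to be the source
of a transition, i.e. the per-source transition counts (row sums of the
transition matrix) follow a uniform multinomial.  Pearson's statistic
X^2 = sum (obs - exp)^2 / exp with exp = total/m is referred to a chi-squared
distribution with m - 1 degrees of freedom.  Two groupings are supported:

``six_state``
    every state of the matrix is its own category (for the study's table:
    cementing, byssal, free-living, recessing, gliding, nestling — states
    with zero observed transitions stay in the category set).
``permanent_merged``
    cementing and nestling are pooled into one "permanent attachment"
    category, reducing the number of sparse cells.

No continuity correction is applied.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Mapping

from scipy import stats

from .io import state_label
from .transitions import TransitionMatrix

GROUPINGS = ("six_state", "permanent_merged")

#: life-habit codes pooled under the merged grouping
_PERMANENT_CODES = (1, 6)  # cementing, nestling
_PERMANENT_LABEL = "permanent attachment"


@dataclass
class BiasTestResult:
    observed: dict[str, int]
    expected: float
    statistic: float
    df: int
    p_value: float
    grouping: str

    def to_dict(self) -> dict:
        return {
            "grouping": self.grouping,
            "observed": self.observed,
            "expected_per_category": self.expected,
            "statistic": self.statistic,
            "df": self.df,
            "p_value": self.p_value,
        }


def source_counts(
    matrix: TransitionMatrix, grouping: str = "six_state"
) -> dict[str, int]:
    """Per-category transition-source counts (row sums), under a grouping."""
    if grouping not in GROUPINGS:
        raise ValueError(f"unknown grouping {grouping!r}; expected one of {GROUPINGS}")
    rows = matrix.counts.sum(axis=1)
    if grouping == "six_state":
        return {state_label(code): int(rows[code]) for code in matrix.state_space}
    out: dict[str, int] = {}
    merged = 0
    have_permanent = False
    for code in matrix.state_space:
        if code in _PERMANENT_CODES:
            merged += int(rows[code])
            have_permanent = True
        else:
            out[state_label(code)] = int(rows[code])
    if have_permanent:
        out = {_PERMANENT_LABEL: merged, **out}
    return out


def chi_square_uniform(
    counts: Mapping[str, int], grouping: str | None = None
) -> BiasTestResult:
    """Pearson chi-square of observed category counts against uniform expectation."""
    observed = {k: int(v) for k, v in counts.items()}
    values = list(observed.values())
    total = sum(values)
    if total <= 0:
        raise ValueError("chi-square test needs a positive total count")
    m = len(values)
    if m < 2:
        raise ValueError("chi-square test needs at least two categories")
    stat, p = stats.chisquare(values)  # uniform expectation by default
    return BiasTestResult(
        observed=observed,
        expected=total / m,
        statistic=float(stat),
        df=m - 1,
        p_value=float(p),
        grouping=grouping or ("six_state" if m == 6 else f"{m}_categories"),
    )


def bias_test(matrix: TransitionMatrix, grouping: str = "six_state") -> BiasTestResult:
    """Convenience: row sums under a grouping, then the uniform chi-square."""
    return chi_square_uniform(source_counts(matrix, grouping), grouping=grouping)
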