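"""Published reference results for the Coventry cycleway case study.

The Coventry appraisal (a 6-km separated cycleway, local adult population
173,169, cost $12,800,491 international) reported break-even points for a
shift from each of the four lower cycling-frequency levels into level 1,
plus a one-way sensitivity grid.  These printed figures are inputs for
cross-checks and for the arithmetic summary statistics (per-cyclist value,
cyclists per km); they were produced with the WHO HEAT tool, whose
background datasets this package does not reproduce, so the engine here is
not expected to match the dollar magnitudes exactly.

Shares are fractions of the total population; values are international
dollars discounted over the ten-year horizon.
"""

from __future__ import annotations

from typing import NamedTuple

__all__ = [
    "ReferenceScenario",
    "ReferenceSensitivityRow",
    "COVENTRY_SCENARIOS",
    "COVENTRY_SCENARIO_1_VALUES",
    "COVENTRY_SENSITIVITY",
]


class ReferenceScenario(NamedTuple):
    source_level: int
    shifted_share: float        # fraction of total population moved to level 1
    new_regular_cyclists: int   # as reported


#: Break-even scenarios, one per source level 2..5.
COVENTRY_SCENARIOS: tuple[ReferenceScenario, ...] = (
    ReferenceScenario(source_level=2, shifted_share=0.01242, new_regular_cyclists=2151),
    ReferenceScenario(source_level=3, shifted_share=0.00863, new_regular_cyclists=1494),
    ReferenceScenario(source_level=4, shifted_share=0.00808, new_regular_cyclists=1399),
    ReferenceScenario(source_level=5, shifted_share=0.00793, new_regular_cyclists=1373),
)

#: Scenario 1 (shift from level 2) discounted domain values, international $.
COVENTRY_SCENARIO_1_VALUES: dict[str, float] = {
    "physical_activity": 15_743_658.0,
    "air_pollution": -801_133.0,
    "crash_risk": -2_212_084.0,
    "carbon": 70_049.0,
}


class ReferenceSensitivityRow(NamedTuple):
    label: str
    bcr: float
    regular_cyclist_share: float   # post level-1 share of the population at break-even
    absolute_regular_cyclists: int
    additional_vs_base: int


#: One-way sensitivity grid (level-2 source scenario re-solved per variation).
COVENTRY_SENSITIVITY: tuple[ReferenceSensitivityRow, ...] = (
    ReferenceSensitivityRow("age 20-44 years", 0.173, 0.07900, 13_680, 9_798),
    ReferenceSensitivityRow("age 45-64 years", 1.976, 0.01615, 2_797, -1_086),
    ReferenceSensitivityRow("VSL $3,408,800", 0.805, 0.02550, 4_416, 533),
    ReferenceSensitivityRow("VSL $5,113,200", 1.203, 0.02035, 3_524, -358),
    ReferenceSensitivityRow("discount rate 6.50%", 0.914, 0.02350, 4_069, 187),
    ReferenceSensitivityRow("discount rate 3.50%", 1.094, 0.02130, 3_688, -194),
    ReferenceSensitivityRow("time horizon 5 years", 0.403, 0.04080, 7_065, 3_183),
    ReferenceSensitivityRow("time horizon 15 years", 1.469, 0.01845, 3_195, -687),
    ReferenceSensitivityRow("baseline trip length 3.28 km", 0.797, 0.02550, 4_416, 533),
    ReferenceSensitivityRow("baseline trip length 4.92 km", 1.203, 0.02035, 3_524, -358),
    ReferenceSensitivityRow("baseline trips/day 1.6", 0.797, 0.02550, 4_416, 533),
    ReferenceSensitivityRow("baseline trips/day 2.4", 1.203, 0.02035, 3_524, -358),
    ReferenceSensitivityRow("post trip length 3.28 km", 0.722, 0.04910, 8_503, 4_620),
    ReferenceSensitivityRow("post trip length 4.92 km", 2.726, 0.00458, 793, -3_089),
    ReferenceSensitivityRow("post trips/day 1.6", 0.722, 0.04910, 8_503, 4_620),
    ReferenceSensitivityRow("post trips/day 2.4", 2.726, 0.00458, 793, -3_089),
    ReferenceSensitivityRow("take-up time 2 years", 0.922, 0.02340, 4_052, 170),
    ReferenceSensitivityRow("take-up time 3 years", 0.851, 0.02455, 4_251, 369),
    ReferenceSensitivityRow("take-up time 5 years", 0.713, 0.02745, 4_753, 871),
    ReferenceSensitivityRow("proportion in traffic 100%", 0.977, 0.02280, 3_948, 66),
)
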