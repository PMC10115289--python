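"""One-way deterministic sensitivity analysis.

Each variation replaces a single model parameter, then reports two things:
the BCR that the base-case break-even shift (level 2 → level 1) would
achieve under the varied parameter, and the new break-even requirement
(share, absolute number of regular cyclists, and the difference from the
base case) when the solver is rerun under that parameter.

Two kinds of trip-pattern variation are distinguished: *baseline*
variations change the behaviour applied to both the pre and post states
(everyone's trips change), while *post* variations change only the
behaviour of the post-intervention state (only the new cycling pattern
changes) — the latter moves the BCR much further because it shrinks or
grows the incremental volume directly.
"""

from __future__ import annotations

import math
from typing import Any, Optional, Sequence, Tuple

from pydantic import BaseModel, ConfigDict

from .breakeven import (
    AlreadyCostSavingError,
    BreakEvenInfeasibleError,
    ScenarioShift,
    apply_shift,
    round_half_up,
    solve_breakeven,
)
from .config import AppraisalConfig, TravelBehaviour
from .engine import appraise
from .synthetic import COHORT_MORTALITY

__all__ = [
    "Variation",
    "SensitivityRow",
    "run_variation",
    "sensitivity_table",
    "standard_variations",
]

#: Parameters a Variation may name.
VARIABLE_PARAMETERS = (
    "age_group",
    "annual_mortality_rate",
    "vsl",
    "discount_rate",
    "horizon_years",
    "takeup_years",
    "trip_length_km",
    "trips_per_day",
    "post_trip_length_km",
    "post_trips_per_day",
    "in_traffic_fraction",
    "modal_shift",
)


class Variation(BaseModel):
    """A single-parameter replacement, with a human-readable label."""

    model_config = ConfigDict(frozen=True)

    parameter: str
    value: Any
    label: str


class SensitivityRow(BaseModel):
    """One row of the sensitivity grid.

    ``absolute_regular_cyclists`` counts everyone at level 1 after the
    re-solved break-even shift (pre-existing regular cyclists included);
    ``additional_vs_base`` subtracts the base-case absolute count.  When
    the break-even is infeasible under the variation (the source level
    cannot supply enough cyclists) the row is flagged and the solver
    fields are NaN/0, with the BCR at the base shift still reported.
    """

    model_config = ConfigDict(frozen=True)

    variation: Variation
    bcr_at_base_shift: float
    breakeven_share: float
    absolute_regular_cyclists: int
    additional_vs_base: int
    feasible: bool = True


def _apply_variation(
    config: AppraisalConfig, v: Variation
) -> Tuple[AppraisalConfig, Optional[TravelBehaviour]]:
    """Return the varied config and (if any) a post-only behaviour."""
    p = v.parameter
    if p == "age_group":
        band = tuple(v.value)
        if band not in COHORT_MORTALITY:
            raise ValueError(f"no mortality rate known for age band {band}")
        pop = config.population.model_copy(
            update={"age_band": band, "annual_mortality_rate": COHORT_MORTALITY[band]}
        )
        return config.model_copy(update={"population": pop}), None
    if p == "annual_mortality_rate":
        pop = config.population.model_copy(update={"annual_mortality_rate": float(v.value)})
        return config.model_copy(update={"population": pop}), None
    if p in ("vsl", "discount_rate", "horizon_years", "takeup_years"):
        econ = config.economics.model_copy(update={p: v.value})
        return config.model_copy(update={"economics": econ}), None
    if p in ("trip_length_km", "trips_per_day"):
        behaviour = config.behaviour.model_copy(update={p: float(v.value)})
        return config.model_copy(update={"behaviour": behaviour}), None
    if p in ("post_trip_length_km", "post_trips_per_day"):
        field = p.removeprefix("post_")
        return config, config.behaviour.model_copy(update={field: float(v.value)})
    if p in ("in_traffic_fraction", "modal_shift"):
        risks = config.risks.model_copy(update={p: v.value})
        return config.model_copy(update={"risks": risks}), None
    raise ValueError(f"unknown parameter {p!r}; known: {VARIABLE_PARAMETERS}")


def _signed_post(config: AppraisalConfig, source_level: int, share: float):
    """Post distribution for a signed shift: positive moves people from the
    source level to level 1, negative moves them back."""
    from .config import CyclingDistribution

    baseline = config.population.baseline
    shares = list(baseline.shares)
    shares[0] += share
    shares[source_level - 1] -= share
    return CyclingDistribution(shares=tuple(shares))


def _solve_negative_shift(
    config: AppraisalConfig,
    source_level: int,
    tolerance: float,
    post_behaviour: Optional[TravelBehaviour],
) -> float:
    baseline = config.population.baseline
    lo, hi = -baseline.shares[0], 0.0

    def bcr_at(share: float) -> float:
        return appraise(config, _signed_post(config, source_level, share), post_behaviour).bcr

    if bcr_at(lo) > 1.0:
        raise BreakEvenInfeasibleError(
            "BCR above 1 even with no regular cyclists at all"
        )
    for _ in range(200):
        mid = 0.5 * (lo + hi)
        bcr = bcr_at(mid)
        if abs(bcr - 1.0) <= tolerance:
            return mid
        if bcr < 1.0:
            lo = mid
        else:
            hi = mid
    raise RuntimeError("negative-shift bisection did not converge")


def run_variation(
    config: AppraisalConfig,
    base_shift: ScenarioShift,
    v: Variation,
    tolerance: float = 1e-6,
) -> SensitivityRow:
    """Evaluate one variation against the base-case break-even shift."""
    varied, post_behaviour = _apply_variation(config, v)
    baseline = varied.population.baseline
    pop_size = varied.population.size

    post_at_base = apply_shift(baseline, base_shift)
    bcr = appraise(varied, post_at_base, post_behaviour).bcr

    base_absolute = round_half_up((baseline.shares[0] + base_shift.shifted_share) * pop_size)
    try:
        solved = solve_breakeven(
            varied, base_shift.source_level, tolerance, post_behaviour=post_behaviour
        )
        share = solved.scenario.shifted_share
    except AlreadyCostSavingError:
        # A post-only behaviour boost can put BCR above 1 with no shift at
        # all; the equilibrium then sits at a *negative* shift (fewer
        # regular cyclists than baseline), found by bisecting downward.
        share = _solve_negative_shift(
            varied, base_shift.source_level, tolerance, post_behaviour
        )
    except BreakEvenInfeasibleError:
        return SensitivityRow(
            variation=v,
            bcr_at_base_shift=bcr,
            breakeven_share=float("nan"),
            absolute_regular_cyclists=0,
            additional_vs_base=0,
            feasible=False,
        )
    absolute = round_half_up((baseline.shares[0] + share) * pop_size)
    return SensitivityRow(
        variation=v,
        bcr_at_base_shift=bcr,
        breakeven_share=share,
        absolute_regular_cyclists=absolute,
        additional_vs_base=absolute - base_absolute,
    )


def sensitivity_table(
    config: AppraisalConfig,
    base_shift: ScenarioShift,
    variations: Sequence[Variation],
    tolerance: float = 1e-6,
) -> list[SensitivityRow]:
    """Run every variation, preserving order; per-row failures become
    infeasible-flagged rows rather than aborting the table."""
    if not variations:
        raise ValueError("need at least one variation")
    rows = []
    for v in variations:
        rows.append(run_variation(config, base_shift, v, tolerance))
    return rows


def standard_variations(config: AppraisalConfig) -> list[Variation]:
    """The standard one-way grid: age cohorts, VSL ±20%, discount ±1.5
    percentage points, horizons 5 and 15 years, trip length and trip count
    ±20% (baseline and post separately), take-up 2/3/5 years, and 100%
    in-traffic cycling."""
    econ, b = config.economics, config.behaviour
    fmt = lambda x: f"{x:,.0f}"  # noqa: E731
    return [
        Variation(parameter="age_group", value=(20, 44), label="age 20-44 years"),
        Variation(parameter="age_group", value=(45, 64), label="age 45-64 years"),
        Variation(parameter="vsl", value=0.8 * econ.vsl, label=f"VSL ${fmt(0.8 * econ.vsl)}"),
        Variation(parameter="vsl", value=1.2 * econ.vsl, label=f"VSL ${fmt(1.2 * econ.vsl)}"),
        Variation(
            parameter="discount_rate",
            value=econ.discount_rate + 0.015,
            label=f"discount rate {100 * (econ.discount_rate + 0.015):.2f}%",
        ),
        Variation(
            parameter="discount_rate",
            value=econ.discount_rate - 0.015,
            label=f"discount rate {100 * (econ.discount_rate - 0.015):.2f}%",
        ),
        Variation(parameter="horizon_years", value=5, label="time horizon 5 years"),
        Variation(parameter="horizon_years", value=15, label="time horizon 15 years"),
        Variation(
            parameter="trip_length_km",
            value=0.8 * b.trip_length_km,
            label=f"baseline trip length {0.8 * b.trip_length_km:.2f} km",
        ),
        Variation(
            parameter="trip_length_km",
            value=1.2 * b.trip_length_km,
            label=f"baseline trip length {1.2 * b.trip_length_km:.2f} km",
        ),
        Variation(
            parameter="trips_per_day",
            value=0.8 * b.trips_per_day,
            label=f"baseline trips/day {0.8 * b.trips_per_day:.1f}",
        ),
        Variation(
            parameter="trips_per_day",
            value=1.2 * b.trips_per_day,
            label=f"baseline trips/day {1.2 * b.trips_per_day:.1f}",
        ),
        Variation(
            parameter="post_trip_length_km",
            value=0.8 * b.trip_length_km,
            label=f"post trip length {0.8 * b.trip_length_km:.2f} km",
        ),
        Variation(
            parameter="post_trip_length_km",
            value=1.2 * b.trip_length_km,
            label=f"post trip length {1.2 * b.trip_length_km:.2f} km",
        ),
        Variation(
            parameter="post_trips_per_day",
            value=0.8 * b.trips_per_day,
            label=f"post trips/day {0.8 * b.trips_per_day:.1f}",
        ),
        Variation(
            parameter="post_trips_per_day",
            value=1.2 * b.trips_per_day,
            label=f"post trips/day {1.2 * b.trips_per_day:.1f}",
        ),
        Variation(parameter="takeup_years", value=2.0, label="take-up time 2 years"),
        Variation(parameter="takeup_years", value=3.0, label="take-up time 3 years"),
        Variation(parameter="takeup_years", value=5.0, label="take-up time 5 years"),
        Variation(parameter="in_traffic_fraction", value=1.0, label="proportion in traffic 100%"),
    ]
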