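"""Break-even solver: how much behaviour change pays for the cycleway.

For each source frequency level (2–5), finds the share of the total
population that must move from that level to level 1 ("daily or almost
daily" — regular cycling) for the discounted benefits to exactly offset
the construction cost (BCR = 1:1), then summarises across the four
scenarios: mean new regular cyclists, cyclists required per km of
cycleway, and the annual value generated per additional regular cyclist.
"""

from __future__ import annotations

import math
from typing import Optional, Sequence

from pydantic import BaseModel, ConfigDict

from .config import (
    AppraisalConfig,
    CyclingDistribution,
    EconomicParams,
    InterventionSpec,
    TravelBehaviour,
)
from .engine import AppraisalResult, appraise

__all__ = [
    "ScenarioShift",
    "BreakEvenResult",
    "BreakEvenSummary",
    "BreakEvenInfeasibleError",
    "AlreadyCostSavingError",
    "round_half_up",
    "apply_shift",
    "solve_breakeven",
    "summarize",
    "ppp_convert",
]


class BreakEvenInfeasibleError(ValueError):
    """BCR stays below 1 even when the whole source level shifts."""


class AlreadyCostSavingError(ValueError):
    """BCR is at or above 1 with no behaviour change at all."""


class ScenarioShift(BaseModel):
    """A shift of a population share from one source level to level 1."""

    model_config = ConfigDict(frozen=True)

    source_level: int
    shifted_share: float


class BreakEvenResult(BaseModel):
    """Solved break-even point for one source-level scenario."""

    model_config = ConfigDict(frozen=True)

    scenario: ScenarioShift
    new_regular_cyclists: int
    post: CyclingDistribution
    bcr_achieved: float
    per_km_cyclists: float
    per_cyclist_annual_value: float


class BreakEvenSummary(BaseModel):
    """Averages across the four source-level scenarios.

    ``mean_share_of_population`` (mean count / population size) and
    ``mean_shifted_share`` (mean of the four solved shares) are both
    reported; they differ slightly because counts are rounded per
    scenario.
    """

    model_config = ConfigDict(frozen=True)

    mean_new_regular_cyclists: int
    mean_shifted_share: float
    mean_share_of_population: Optional[float]
    cyclists_per_km: float
    per_cyclist_annual_value: float


def round_half_up(x: float) -> int:
    """Round to the nearest integer, halves away from zero."""
    return int(math.floor(x + 0.5)) if x >= 0 else -int(math.floor(-x + 0.5))


def apply_shift(baseline: CyclingDistribution, shift: ScenarioShift) -> CyclingDistribution:
    """Move ``shifted_share`` of the population from the source level to level 1.

    Only the two involved components change; total mass is conserved
    exactly (the source share is reduced by the exact amount added to
    level 1).
    """
    if not 2 <= shift.source_level <= 5:
        raise ValueError(f"source_level must be in 2..5, got {shift.source_level}")
    if shift.shifted_share < 0:
        raise ValueError(f"shifted_share must be ≥ 0, got {shift.shifted_share}")
    src = shift.source_level - 1
    if shift.shifted_share > baseline.shares[src] + 1e-12:
        raise ValueError(
            f"cannot shift {shift.shifted_share} from level {shift.source_level}: "
            f"only {baseline.shares[src]} available"
        )
    shares = list(baseline.shares)
    shares[0] += shift.shifted_share
    shares[src] -= shift.shifted_share
    return CyclingDistribution(shares=tuple(shares))


def _bcr_at(
    config: AppraisalConfig,
    source_level: int,
    share: float,
    post_behaviour: Optional[TravelBehaviour],
) -> AppraisalResult:
    post = apply_shift(
        config.population.baseline,
        ScenarioShift(source_level=source_level, shifted_share=share),
    )
    return appraise(config, post, post_behaviour)


def solve_breakeven(
    config: AppraisalConfig,
    source_level: int,
    tolerance: float = 1e-6,
    post_behaviour: Optional[TravelBehaviour] = None,
    max_iter: int = 200,
) -> BreakEvenResult:
    """Bisect on the shifted share until |BCR − 1| ≤ tolerance.

    The discounted benefit is monotone increasing in the shifted share
    (each shifted person adds cycling volume), which bisection requires;
    this is asserted on the bracket endpoints.  The initial upper probe is
    the share that would lift level 1 to 5% of the population (a 400%
    increase on a 1% baseline — the customary planning target), widened to
    the full source share if that is not enough.

    Raises :class:`AlreadyCostSavingError` if BCR ≥ 1 with zero shift and
    :class:`BreakEvenInfeasibleError` if BCR < 1 even after exhausting the
    source level.
    """
    if tolerance <= 0:
        raise ValueError("tolerance must be > 0")
    baseline = config.population.baseline
    max_share = baseline.shares[source_level - 1]

    bcr_zero = _bcr_at(config, source_level, 0.0, post_behaviour).bcr
    if bcr_zero >= 1.0:
        raise AlreadyCostSavingError(
            f"BCR = {bcr_zero:.4f} with no behaviour change: already cost-saving"
        )
    bcr_full = _bcr_at(config, source_level, max_share, post_behaviour).bcr
    if bcr_full < 1.0 - tolerance:
        raise BreakEvenInfeasibleError(
            f"infeasible: source level {source_level} exhausted at BCR {bcr_full:.4f}"
        )
    assert bcr_full > bcr_zero, "benefit must be monotone increasing in the shifted share"

    lo, hi = 0.0, max_share
    probe = min(max(0.05 - baseline.shares[0], 0.0), max_share)
    if probe > 0.0:
        if _bcr_at(config, source_level, probe, post_behaviour).bcr >= 1.0:
            hi = probe
        else:
            lo = probe

    share = hi
    result = _bcr_at(config, source_level, share, post_behaviour)
    for _ in range(max_iter):
        mid = 0.5 * (lo + hi)
        result = _bcr_at(config, source_level, mid, post_behaviour)
        share = mid
        if abs(result.bcr - 1.0) <= tolerance:
            break
        if result.bcr < 1.0:
            lo = mid
        else:
            hi = mid
    else:
        raise RuntimeError(
            f"bisection did not reach |BCR - 1| ≤ {tolerance} in {max_iter} iterations"
        )

    pop = config.population
    econ = config.economics
    count = round_half_up(share * pop.size)
    per_cyclist = (
        config.intervention.cost_intl_dollars / (count * econ.horizon_years)
        if count > 0
        else float("nan")
    )
    return BreakEvenResult(
        scenario=ScenarioShift(source_level=source_level, shifted_share=share),
        new_regular_cyclists=count,
        post=apply_shift(baseline, ScenarioShift(source_level=source_level, shifted_share=share)),
        bcr_achieved=result.bcr,
        per_km_cyclists=count / config.intervention.cycleway_length_km,
        per_cyclist_annual_value=per_cyclist,
    )


def summarize(
    results: Sequence[BreakEvenResult],
    intervention: InterventionSpec,
    econ: EconomicParams,
    population_size: Optional[int] = None,
) -> BreakEvenSummary:
    """Average the scenario break-even points into the headline numbers.

    Counts are averaged and rounded half-up; cyclists per km divides the
    rounded mean count by the cycleway length; the per-cyclist annual
    value spreads the intervention cost over the mean count and the
    horizon (at break-even, benefits equal cost, so this is the annual
    value one additional regular cyclist generates).
    """
    if not results:
        raise ValueError("need at least one break-even result")
    mean_count_raw = math.fsum(r.new_regular_cyclists for r in results) / len(results)
    mean_count = round_half_up(mean_count_raw)
    mean_share = math.fsum(r.scenario.shifted_share for r in results) / len(results)
    share_of_pop = mean_count_raw / population_size if population_size else None
    return BreakEvenSummary(
        mean_new_regular_cyclists=mean_count,
        mean_shifted_share=mean_share,
        mean_share_of_population=share_of_pop,
        cyclists_per_km=mean_count / intervention.cycleway_length_km,
        per_cyclist_annual_value=intervention.cost_intl_dollars / (mean_count * econ.horizon_years),
    )


def ppp_convert(amount: float, econ: EconomicParams) -> float:
    """Convert international dollars to pounds via the PPP coefficient."""
    return amount * econ.ppp_coefficient
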