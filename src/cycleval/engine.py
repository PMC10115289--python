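"""Comparative risk assessment engine.

Turns a change in the population's cycling-frequency distribution into
four domain impacts — physical activity, air pollution, crash risk and
carbon emissions — each expressed as an annual steady-state quantity
(deaths/year or tonnes CO2/year) and as a discounted monetary value over
the appraisal horizon, and combines them into a benefit-cost ratio (BCR)
against the intervention cost.

The model is a steady-state-to-steady-state comparison: no individual
simulation, no recurrent events.  The three mortality domains are
monetised with the value of a statistical life (VSL); carbon with a
damage cost per tonne.  Annual values ramp up linearly over the take-up
time and are discounted to present value.
"""

from __future__ import annotations

import math
from typing import Literal, Optional, Sequence, Tuple

from pydantic import BaseModel, ConfigDict

from .config import (
    DEFAULT_LEVELS,
    AppraisalConfig,
    CyclingDistribution,
    EconomicParams,
    FrequencyLevel,
    PopulationSpec,
    RiskParams,
    TravelBehaviour,
    annual_km,
    validate_config,
    validate_distribution,
)

__all__ = [
    "DomainImpact",
    "AppraisalResult",
    "CYCLING_SPEED_KMH",
    "HOURS_PER_YEAR",
    "mortality_rr",
    "pa_deaths",
    "ap_deaths",
    "crash_deaths",
    "carbon_tonnes",
    "discounted_stream",
    "total_annual_km",
    "appraise",
]

#: Assumed average cycling speed, used only to convert cycling km into
#: hours of air-pollution exposure.
CYCLING_SPEED_KMH = 14.0

HOURS_PER_YEAR = 8760.0

DOMAINS = ("physical_activity", "air_pollution", "crash_risk", "carbon")


class DomainImpact(BaseModel):
    """Annual steady-state impact and discounted value for one domain.

    Negative ``annual_deaths_delta`` means deaths averted; negative
    ``annual_tonnes_co2_delta`` means emissions reduced.  Positive
    ``discounted_value`` is a benefit.  Mortality domains carry a zero
    tonnes field and the carbon domain a zero deaths field.
    """

    model_config = ConfigDict(frozen=True)

    domain: Literal["physical_activity", "air_pollution", "crash_risk", "carbon"]
    annual_deaths_delta: float
    annual_tonnes_co2_delta: float
    discounted_value: float


class AppraisalResult(BaseModel):
    """The four domain impacts plus total benefit and BCR."""

    model_config = ConfigDict(frozen=True)

    impacts: Tuple[DomainImpact, DomainImpact, DomainImpact, DomainImpact]
    total_benefit: float
    bcr: float

    def impact(self, domain: str) -> DomainImpact:
        for imp in self.impacts:
            if imp.domain == domain:
                return imp
        raise KeyError(domain)


def mortality_rr(volume_km_per_year: float, risks: RiskParams) -> float:
    """All-cause mortality relative risk at a given annual cycling volume.

    Linear in volume through (0, 1) and (reference volume, rr_reference),
    capped at ``max_volume_ratio`` times the reference volume, beyond which
    additional cycling confers no further mortality benefit.
    """
    if volume_km_per_year < 0:
        raise ValueError(f"cycling volume must be ≥ 0, got {volume_km_per_year}")
    ratio = min(volume_km_per_year / risks.reference_volume_km_per_year, risks.max_volume_ratio)
    return 1.0 - (1.0 - risks.rr_reference) * ratio


def _expected_deaths(
    dist: CyclingDistribution,
    pop: PopulationSpec,
    behaviour: TravelBehaviour,
    risks: RiskParams,
    levels: Sequence[FrequencyLevel],
) -> float:
    return math.fsum(
        pop.size * share * pop.annual_mortality_rate * mortality_rr(annual_km(lv, behaviour), risks)
        for share, lv in zip(dist.shares, levels)
    )


def pa_deaths(
    baseline: CyclingDistribution,
    post: CyclingDistribution,
    pop: PopulationSpec,
    behaviour: TravelBehaviour,
    risks: RiskParams,
    levels: Sequence[FrequencyLevel] = DEFAULT_LEVELS,
    post_behaviour: Optional[TravelBehaviour] = None,
) -> float:
    """Change in annual deaths attributable to physical activity.

    Expected deaths under the post distribution minus under baseline, where
    each level's mortality is the background rate scaled by the relative
    risk at that level's cycling volume.  Negative = deaths averted.

    ``post_behaviour`` lets the post state use a different trip pattern
    from baseline (defaults to the same behaviour).
    """
    pb = post_behaviour if post_behaviour is not None else behaviour
    return _expected_deaths(post, pop, pb, risks, levels) - _expected_deaths(
        baseline, pop, behaviour, risks, levels
    )


def ap_deaths(shift_km_per_year: float, risks: RiskParams, pop: PopulationSpec) -> float:
    """Extra annual deaths from air-pollution exposure while cycling.

    The incremental population cycling volume implies hours spent cycling
    (at :data:`CYCLING_SPEED_KMH`); during the in-traffic fraction of those
    hours the inhaled dose exceeds rest by ``(ventilation_ratio − 1) ×
    PM2.5``.  The resulting annual-average equivalent exposure increase is
    converted to deaths through a proportional hazard on the background
    mortality rate.  Always ≥ 0 (a disbenefit).
    """
    if shift_km_per_year < 0:
        raise ValueError(f"shifted km must be ≥ 0, got {shift_km_per_year}")
    person_years_of_exposure = shift_km_per_year / CYCLING_SPEED_KMH / HOURS_PER_YEAR
    excess_dose_ugm3 = (
        risks.pm25_ugm3 * (risks.ventilation_ratio - 1.0) * risks.in_traffic_fraction
    )
    return (
        pop.annual_mortality_rate
        * risks.er_slope_per_ugm3
        * excess_dose_ugm3
        * person_years_of_exposure
    )


def crash_deaths(extra_km_per_year: float, risks: RiskParams) -> float:
    """Extra annual cyclist fatalities from the incremental km cycled."""
    if extra_km_per_year < 0:
        raise ValueError(f"extra km must be ≥ 0, got {extra_km_per_year}")
    return extra_km_per_year * risks.crash_fatalities_per_100M_km / 1e8


def carbon_tonnes(extra_cycling_km_per_year: float, risks: RiskParams) -> float:
    """Change in annual tonnes of CO2 (negative = emissions saved).

    Each incremental cycling km displaces km on the prior modes in the
    modal-shift proportions; walking has a zero emission factor.
    """
    if extra_cycling_km_per_year < 0:
        raise ValueError(f"extra km must be ≥ 0, got {extra_cycling_km_per_year}")
    grams = math.fsum(
        extra_cycling_km_per_year * share * risks.emission_factor_g_per_km[mode]
        for mode, share in risks.modal_shift.items()
    )
    return -grams / 1e6


def discounted_stream(
    annual_value: float,
    econ: EconomicParams,
    timing: Literal["end", "mid"] = "end",
) -> float:
    """Present value of a steady-state annual value over the horizon.

    Benefits start the year after construction and ramp up linearly over
    the take-up time: the year-``t`` payment is ``min(t / takeup_years, 1)
    × annual_value``, discounted at the annual rate with end-of-year
    timing (``timing="mid"`` discounts mid-year instead).
    """
    r = econ.discount_rate
    total = 0.0
    for t in range(1, econ.horizon_years + 1):
        uptake = min(t / econ.takeup_years, 1.0)
        exponent = t if timing == "end" else t - 0.5
        total += uptake * annual_value * (1.0 + r) ** (-exponent)
    return total


def total_annual_km(
    dist: CyclingDistribution,
    pop: PopulationSpec,
    behaviour: TravelBehaviour,
    levels: Sequence[FrequencyLevel] = DEFAULT_LEVELS,
) -> float:
    """Population total cycling km/year under a distribution."""
    return math.fsum(
        pop.size * share * annual_km(lv, behaviour) for share, lv in zip(dist.shares, levels)
    )


def appraise(
    config: AppraisalConfig,
    post: CyclingDistribution,
    post_behaviour: Optional[TravelBehaviour] = None,
) -> AppraisalResult:
    """Run the four-domain appraisal of moving baseline → post.

    Air pollution, crash risk and carbon act on the incremental population
    cycling volume; physical activity acts on the full distribution change.
    Mortality domains are valued at the VSL, carbon at the damage cost per
    tonne; each annual value is discounted over the horizon with the
    take-up ramp.  BCR is total discounted benefit over intervention cost.
    """
    problems = validate_config(config)
    problems += [f"post.{p}" for p in validate_distribution(post)]
    if problems:
        raise ValueError("invalid appraisal inputs: " + "; ".join(problems))

    pop, behaviour, econ, risks = (
        config.population,
        config.behaviour,
        config.economics,
        config.risks,
    )
    pb = post_behaviour if post_behaviour is not None else behaviour

    km_delta = total_annual_km(post, pop, pb, config.levels) - total_annual_km(
        pop.baseline, pop, behaviour, config.levels
    )
    # Exposure domains are linear and symmetric in the km delta; evaluate on
    # the magnitude and restore the sign so reduced cycling is handled too.
    sign = 1.0 if km_delta >= 0 else -1.0
    abs_km = abs(km_delta)

    pa = pa_deaths(pop.baseline, post, pop, behaviour, risks, config.levels, post_behaviour)
    ap = sign * ap_deaths(abs_km, risks, pop)
    crash = sign * crash_deaths(abs_km, risks)
    co2 = sign * carbon_tonnes(abs_km, risks)

    impacts = (
        DomainImpact(
            domain="physical_activity",
            annual_deaths_delta=pa,
            annual_tonnes_co2_delta=0.0,
            discounted_value=discounted_stream(-pa * econ.vsl, econ),
        ),
        DomainImpact(
            domain="air_pollution",
            annual_deaths_delta=ap,
            annual_tonnes_co2_delta=0.0,
            discounted_value=discounted_stream(-ap * econ.vsl, econ),
        ),
        DomainImpact(
            domain="crash_risk",
            annual_deaths_delta=crash,
            annual_tonnes_co2_delta=0.0,
            discounted_value=discounted_stream(-crash * econ.vsl, econ),
        ),
        DomainImpact(
            domain="carbon",
            annual_deaths_delta=0.0,
            annual_tonnes_co2_delta=co2,
            discounted_value=discounted_stream(-co2 * econ.carbon_damage_cost, econ),
        ),
    )
    total = math.fsum(imp.discounted_value for imp in impacts)
    return AppraisalResult(
        impacts=impacts,
        total_benefit=total,
        bcr=total / config.intervention.cost_intl_dollars,
    )
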