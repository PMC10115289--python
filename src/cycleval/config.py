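"""Parameter bundle for a cycleway appraisal run.

The appraisal model is driven entirely by one :class:`AppraisalConfig`
object: a local adult population with its distribution over five cycling
frequency levels, the travel behaviour of a cycling day, the economic
valuation parameters, the background risk parameters, and the intervention
(construction cost and cycleway length).

Types are deliberately permissive at construction time; all invariants are
enforced in one place, :func:`validate_config`, which reports every broken
rule rather than raising on the first.  This keeps negative testing (the
violation injector in :mod:`cycleval.synthetic`) and user-facing error
reporting on the same code path.
"""

from __future__ import annotations

import math
from typing import Tuple

from pydantic import BaseModel, ConfigDict

__all__ = [
    "FrequencyLevel",
    "CyclingDistribution",
    "PopulationSpec",
    "TravelBehaviour",
    "EconomicParams",
    "RiskParams",
    "InterventionSpec",
    "AppraisalConfig",
    "DEFAULT_LEVELS",
    "MODES",
    "SHARE_SUM_TOL",
    "annual_km",
    "validate_config",
    "validate_distribution",
]

#: Tolerance on probability mass sums (cycling shares, modal shift shares).
SHARE_SUM_TOL = 1e-9

#: Transport modes that new cycling kilometres can be drawn from.
MODES = ("public_transport", "car", "walking")


class _Model(BaseModel):
    model_config = ConfigDict(extra="forbid", frozen=True)


class FrequencyLevel(_Model):
    """One of the five cycling-frequency categories.

    ``index`` runs from 1 ("daily or almost daily", the *regular cyclist*
    category) to 5 ("never").  ``cycling_days_per_year`` converts the
    categorical frequency into an exposure volume; days strictly decrease
    with index and level 5 is exactly zero.
    """

    index: int
    label: str
    cycling_days_per_year: float


#: Default days-per-year mapping for the five levels: midpoints of the
#: category ranges (6/wk, 2/wk, 2/mo, 0.5/mo, never).  Configurable via
#: ``AppraisalConfig.levels``.
DEFAULT_LEVELS: Tuple[FrequencyLevel, ...] = (
    FrequencyLevel(index=1, label="daily or almost daily", cycling_days_per_year=312.0),
    FrequencyLevel(index=2, label="one to three days a week", cycling_days_per_year=104.0),
    FrequencyLevel(index=3, label="one to three days a month", cycling_days_per_year=24.0),
    FrequencyLevel(index=4, label="less than once a month", cycling_days_per_year=6.0),
    FrequencyLevel(index=5, label="never", cycling_days_per_year=0.0),
)


class CyclingDistribution(_Model):
    """Shares of the population at each of the five frequency levels.

    Shares are proportions (not percent); they must each lie in [0, 1]
    and sum to 1 within :data:`SHARE_SUM_TOL`.
    """

    shares: Tuple[float, float, float, float, float]

    def share_of(self, level_index: int) -> float:
        """Share at a 1-based frequency level index."""
        return self.shares[level_index - 1]


class PopulationSpec(_Model):
    """The local adult population exposed to the intervention."""

    size: int
    age_band: Tuple[int, int]
    annual_mortality_rate: float
    baseline: CyclingDistribution


class TravelBehaviour(_Model):
    """What a cycling day looks like: trips taken and km per trip.

    Downstream results depend on these only through their product
    (km cycled per cycling day), so a ±20% change to either field is
    indistinguishable from the same change to the other.
    """

    trips_per_day: float
    trip_length_km: float


class EconomicParams(_Model):
    """Monetisation and discounting parameters.

    ``vsl`` is the value of a statistical life in international dollars;
    ``ppp_coefficient`` converts international $ to £ (multiplicative);
    ``takeup_years`` is the time for cycling demand to ramp from zero to
    its steady state after construction; ``carbon_damage_cost`` is the
    damage cost of one tonne of CO2 in international $.
    """

    vsl: float
    discount_rate: float
    horizon_years: int
    takeup_years: float
    ppp_coefficient: float
    carbon_damage_cost: float


class RiskParams(_Model):
    """Background dose-response and exposure parameters.

    * Physical activity: all-cause mortality relative risk ``rr_reference``
      at a reference cycling volume, interpolated linearly in volume and
      capped at ``max_volume_ratio`` times the reference.
    * Air pollution: ambient PM2.5, a ventilation multiplier while cycling,
      the fraction of cycling done in traffic, and a proportional mortality
      increase per µg/m³ of annual-average equivalent dose.
    * Crash risk: fatalities per 100 million km cycled.
    * Carbon: shares of new cycling km drawn from each prior mode, and
      per-mode tailpipe emission factors (g CO2/km; walking is 0).
    """

    rr_reference: float
    reference_volume_km_per_year: float
    max_volume_ratio: float
    pm25_ugm3: float
    ventilation_ratio: float
    er_slope_per_ugm3: float
    in_traffic_fraction: float
    crash_fatalities_per_100M_km: float
    modal_shift: dict[str, float]
    emission_factor_g_per_km: dict[str, float]


class InterventionSpec(_Model):
    """The capital investment being appraised."""

    cost_intl_dollars: float
    cycleway_length_km: float


class AppraisalConfig(_Model):
    """Everything one appraisal run needs."""

    population: PopulationSpec
    behaviour: TravelBehaviour
    economics: EconomicParams
    risks: RiskParams
    intervention: InterventionSpec
    levels: Tuple[FrequencyLevel, ...] = DEFAULT_LEVELS


def annual_km(level: FrequencyLevel, behaviour: TravelBehaviour) -> float:
    """Kilometres cycled per year by one person at a frequency level.

    The trip pattern is assumed constant across the year, so this is just
    cycling days × trips per cycling day × km per trip (zero for "never").
    """
    return level.cycling_days_per_year * behaviour.trips_per_day * behaviour.trip_length_km


def validate_distribution(dist: CyclingDistribution, prefix: str = "shares") -> list[str]:
    """Invariant violations of a cycling distribution (empty list = valid)."""
    problems: list[str] = []
    for i, s in enumerate(dist.shares, start=1):
        if not (0.0 <= s <= 1.0):
            problems.append(f"{prefix}[{i}] = {s} not in [0, 1]")
    total = math.fsum(dist.shares)
    if abs(total - 1.0) > SHARE_SUM_TOL:
        problems.append(f"{prefix} sum ≠ 1 (got {total!r})")
    return problems


def _validate_levels(levels: Tuple[FrequencyLevel, ...]) -> list[str]:
    problems: list[str] = []
    if len(levels) != 5 or [lv.index for lv in levels] != [1, 2, 3, 4, 5]:
        problems.append("levels: must be five levels indexed 1..5 in order")
        return problems
    days = [lv.cycling_days_per_year for lv in levels]
    if any(d < 0 for d in days):
        problems.append("levels: cycling_days_per_year must be nonnegative")
    if any(a <= b for a, b in zip(days[1:], days[2:])) or days[0] <= days[1]:
        problems.append("levels: cycling_days_per_year must strictly decrease with index")
    if days[4] != 0.0:
        problems.append("levels: level 5 ('never') must have 0 cycling days")
    return problems


def validate_config(config: AppraisalConfig) -> list[str]:
    """Check every model invariant; return one message per violation.

    An empty list means the configuration is valid.  Each message names the
    offending field and the rule broken; nothing raises, so callers can
    collect and present all problems at once.
    """
    v: list[str] = []
    pop, econ, risks = config.population, config.economics, config.risks

    v += _validate_levels(config.levels)

    if pop.size <= 0:
        v.append(f"population.size = {pop.size} must be > 0")
    if not (0.0 < pop.annual_mortality_rate < 1.0):
        v.append(
            f"population.annual_mortality_rate = {pop.annual_mortality_rate} not in (0, 1)"
        )
    if pop.age_band[0] >= pop.age_band[1]:
        v.append(f"population.age_band = {pop.age_band} must be increasing")
    v += [f"population.baseline.{p}" for p in validate_distribution(pop.baseline)]

    if config.behaviour.trips_per_day <= 0:
        v.append("behaviour.trips_per_day must be > 0")
    if config.behaviour.trip_length_km <= 0:
        v.append("behaviour.trip_length_km must be > 0")

    if econ.vsl <= 0:
        v.append(f"economics.vsl = {econ.vsl} must be > 0")
    if econ.discount_rate < 0:
        v.append("economics.discount_rate must be ≥ 0")
    if econ.horizon_years < 1:
        v.append("economics.horizon_years must be ≥ 1")
    if econ.takeup_years <= 0:
        v.append("economics.takeup_years must be > 0")
    elif econ.takeup_years > econ.horizon_years:
        v.append(
            f"economics.takeup_years = {econ.takeup_years} exceeds horizon_years"
        )
    if econ.ppp_coefficient <= 0:
        v.append("economics.ppp_coefficient must be > 0")
    if econ.carbon_damage_cost <= 0:
        v.append("economics.carbon_damage_cost must be > 0")

    if not (0.0 < risks.rr_reference <= 1.0):
        v.append(f"risks.rr_reference = {risks.rr_reference} not in (0, 1]")
    if risks.reference_volume_km_per_year <= 0:
        v.append("risks.reference_volume_km_per_year must be > 0")
    if risks.max_volume_ratio <= 0:
        v.append("risks.max_volume_ratio must be > 0")
    elif (
        0.0 < risks.rr_reference <= 1.0
        and (1.0 - risks.rr_reference) * risks.max_volume_ratio >= 1.0
    ):
        v.append(
            "risks: (1 - rr_reference) × max_volume_ratio ≥ 1 drives relative risk to 0"
        )
    if risks.pm25_ugm3 < 0:
        v.append("risks.pm25_ugm3 must be ≥ 0")
    if risks.ventilation_ratio < 1.0:
        v.append("risks.ventilation_ratio must be ≥ 1")
    if risks.er_slope_per_ugm3 < 0:
        v.append("risks.er_slope_per_ugm3 must be ≥ 0")
    if not (0.0 <= risks.in_traffic_fraction <= 1.0):
        v.append("risks.in_traffic_fraction must be in [0, 1]")
    if risks.crash_fatalities_per_100M_km < 0:
        v.append("risks.crash_fatalities_per_100M_km must be ≥ 0")

    if set(risks.modal_shift) != set(MODES):
        v.append(f"risks.modal_shift keys must be exactly {set(MODES)}")
    else:
        if any(s < 0 for s in risks.modal_shift.values()):
            v.append("risks.modal_shift shares must be ≥ 0")
        total = math.fsum(risks.modal_shift.values())
        if abs(total - 1.0) > SHARE_SUM_TOL:
            v.append(f"risks.modal_shift: modal shares sum ≠ 1 (got {total!r})")
    if set(risks.emission_factor_g_per_km) != set(MODES):
        v.append(f"risks.emission_factor_g_per_km keys must be exactly {set(MODES)}")
    else:
        if any(e < 0 for e in risks.emission_factor_g_per_km.values()):
            v.append("risks.emission_factor_g_per_km must be ≥ 0")
        if risks.emission_factor_g_per_km["walking"] != 0.0:
            v.append("risks.emission_factor_g_per_km['walking'] must be 0")

    if config.intervention.cost_intl_dollars <= 0:
        v.append("intervention.cost_intl_dollars must be > 0")
    if config.intervention.cycleway_length_km <= 0:
        v.append("intervention.cycleway_length_km must be > 0")

    return v
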