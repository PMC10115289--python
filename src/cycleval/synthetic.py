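"""Fixture and random-configuration generator.

:func:`coventry_fixture` is the base case every example and test starts
from: the Coventry separated-cycleway appraisal with its published
population, baseline cycling distribution, cost and economic parameters,
completed with documented defaults for the background risk parameters
(which the case study inherited from the HEAT tool's internal datasets
and did not publish).

:func:`sample_configs` draws randomised but always-valid configurations
for property testing, and :func:`inject_violation` produces configs that
break exactly one named invariant for negative testing.
"""

from __future__ import annotations

from typing import Optional

import numpy as np
from pydantic import BaseModel, ConfigDict

from .config import (
    AppraisalConfig,
    CyclingDistribution,
    EconomicParams,
    InterventionSpec,
    PopulationSpec,
    RiskParams,
    TravelBehaviour,
    validate_config,
)

__all__ = [
    "GeneratorSpec",
    "coventry_fixture",
    "sample_configs",
    "inject_violation",
    "VIOLATION_FIELDS",
]

#: Annual all-cause mortality rates (deaths per person-year) for the age
#: cohorts the sensitivity analysis swaps in, approximating England & Wales
#: period rates for adults.
COHORT_MORTALITY = {
    (20, 64): 2.3e-3,
    (20, 44): 8.5e-4,
    (45, 64): 4.6e-3,
}


def coventry_fixture() -> AppraisalConfig:
    """The Coventry cycleway base case.

    Published inputs: local adult population 173,169 with baseline cycling
    distribution (1, 9, 15, 25, 50)% over the five frequency levels; cost
    $12,800,491 international (the printed PPP conversion of £8,594,000,
    pinned as authoritative); 6 km of cycleway; VSL $4,260,000; 5% annual
    discount; 10-year horizon; 1-year take-up; PPP coefficient 0.667865;
    modal shift 50/30/20 from public transport/car/walking; 50% of cycling
    in traffic; 2.0 trips/day of 4.1 km on a cycling day.

    Background risk defaults (not published with the case study; values
    follow the public health-economic-assessment literature): mortality
    relative risk 0.90 at a reference cycling volume of 1,200 km/year
    (~100 min/week), capped at twice the reference; urban PM2.5 of
    10 µg/m³ with a 2× ventilation rate while cycling and a 0.8% mortality
    increase per µg/m³; 1.8 cyclist fatalities per 100 million km; bus and
    car emission factors of 80 and 171 g CO2 per km; carbon damage cost
    $100 per tonne.
    """
    return AppraisalConfig(
        population=PopulationSpec(
            size=173_169,
            age_band=(20, 64),
            annual_mortality_rate=COHORT_MORTALITY[(20, 64)],
            baseline=CyclingDistribution(shares=(0.01, 0.09, 0.15, 0.25, 0.50)),
        ),
        behaviour=TravelBehaviour(trips_per_day=2.0, trip_length_km=4.1),
        economics=EconomicParams(
            vsl=4_260_000.0,
            discount_rate=0.05,
            horizon_years=10,
            takeup_years=1.0,
            ppp_coefficient=0.667865,
            carbon_damage_cost=100.0,
        ),
        risks=RiskParams(
            rr_reference=0.90,
            reference_volume_km_per_year=1_200.0,
            max_volume_ratio=2.0,
            pm25_ugm3=10.0,
            ventilation_ratio=2.0,
            er_slope_per_ugm3=0.008,
            in_traffic_fraction=0.5,
            crash_fatalities_per_100M_km=1.8,
            modal_shift={"public_transport": 0.5, "car": 0.3, "walking": 0.2},
            emission_factor_g_per_km={"public_transport": 80.0, "car": 171.0, "walking": 0.0},
        ),
        intervention=InterventionSpec(cost_intl_dollars=12_800_491.0, cycleway_length_km=6.0),
    )


class GeneratorSpec(BaseModel):
    """Sampling plan for random valid configurations.

    ``ranges`` overrides individual sampling intervals; unspecified
    parameters use the defaults below.  Cycling shares are drawn from a
    symmetric Dirichlet (each level's share has expectation 1/5), VSL
    log-uniformly, and the rest uniformly.
    """

    model_config = ConfigDict(frozen=True)

    seed: int
    n_configs: int = 1
    ranges: dict[str, tuple[float, float]] = {}


_DEFAULT_RANGES: dict[str, tuple[float, float]] = {
    "log10_vsl": (6.0, 7.0),
    "discount_rate": (0.0, 0.1),
    "horizon_years": (5, 20),
    "takeup_years": (1.0, 5.0),
    "pop_size": (5e4, 5e5),
    "annual_mortality_rate": (1e-3, 1e-2),
    "trips_per_day": (1.0, 3.0),
    "trip_length_km": (2.0, 8.0),
    "cost_intl_dollars": (1e6, 5e7),
    "cycleway_length_km": (1.0, 20.0),
    "rr_reference": (0.80, 0.97),
    "max_volume_ratio": (1.0, 3.0),
    "reference_volume_km_per_year": (800.0, 2000.0),
    "pm25_ugm3": (5.0, 25.0),
    "crash_fatalities_per_100M_km": (0.5, 5.0),
    "carbon_damage_cost": (20.0, 250.0),
    "dirichlet_alpha": (1.0, 1.0),
}


def sample_configs(spec: GeneratorSpec) -> list[AppraisalConfig]:
    """Draw ``n_configs`` valid configurations, deterministic in the seed."""
    ranges = dict(_DEFAULT_RANGES)
    for key, interval in spec.ranges.items():
        if key not in ranges:
            raise ValueError(f"unknown sampling range {key!r}")
        lo, hi = interval
        if not lo <= hi:
            raise ValueError(f"degenerate range for {key!r}: {interval}")
        ranges[key] = (lo, hi)

    rng = np.random.default_rng(spec.seed)
    base = coventry_fixture()

    def u(key: str) -> float:
        lo, hi = ranges[key]
        return float(rng.uniform(lo, hi))

    configs: list[AppraisalConfig] = []
    for _ in range(spec.n_configs):
        shares = rng.dirichlet(np.full(5, ranges["dirichlet_alpha"][0]))
        modal = rng.dirichlet(np.ones(3))
        horizon = int(rng.integers(int(ranges["horizon_years"][0]), int(ranges["horizon_years"][1]) + 1))
        takeup = min(u("takeup_years"), float(horizon))
        config = AppraisalConfig(
            population=PopulationSpec(
                size=int(u("pop_size")),
                age_band=(20, 64),
                annual_mortality_rate=u("annual_mortality_rate"),
                baseline=CyclingDistribution(shares=tuple(float(s) for s in shares)),
            ),
            behaviour=TravelBehaviour(trips_per_day=u("trips_per_day"), trip_length_km=u("trip_length_km")),
            economics=EconomicParams(
                vsl=10.0 ** u("log10_vsl"),
                discount_rate=u("discount_rate"),
                horizon_years=horizon,
                takeup_years=takeup,
                ppp_coefficient=base.economics.ppp_coefficient,
                carbon_damage_cost=u("carbon_damage_cost"),
            ),
            risks=base.risks.model_copy(
                update=dict(
                    rr_reference=u("rr_reference"),
                    max_volume_ratio=u("max_volume_ratio"),
                    reference_volume_km_per_year=u("reference_volume_km_per_year"),
                    pm25_ugm3=u("pm25_ugm3"),
                    in_traffic_fraction=float(rng.uniform(0.0, 1.0)),
                    crash_fatalities_per_100M_km=u("crash_fatalities_per_100M_km"),
                    modal_shift={
                        "public_transport": float(modal[0]),
                        "car": float(modal[1]),
                        "walking": float(modal[2]),
                    },
                )
            ),
            intervention=InterventionSpec(
                cost_intl_dollars=u("cost_intl_dollars"),
                cycleway_length_km=u("cycleway_length_km"),
            ),
        )
        problems = validate_config(config)
        assert not problems, f"generator produced an invalid config: {problems}"
        configs.append(config)
    return configs


#: Field names :func:`inject_violation` understands, with the single
#: invariant each one breaks.
VIOLATION_FIELDS = (
    "shares_sum",
    "modal_shift",
    "vsl",
    "mortality_rate",
    "discount_rate",
    "takeup",
    "trip_length",
    "cost",
    "in_traffic",
    "crash_rate",
)


def inject_violation(config: AppraisalConfig, field: str) -> AppraisalConfig:
    """Return a copy of ``config`` failing exactly one named invariant."""
    if field == "shares_sum":
        pop = config.population.model_copy(
            update={"baseline": CyclingDistribution(shares=(0.06, 0.09, 0.15, 0.25, 0.50))}
        )
        return config.model_copy(update={"population": pop})
    if field == "modal_shift":
        risks = config.risks.model_copy(
            update={"modal_shift": {"public_transport": 0.6, "car": 0.3, "walking": 0.2}}
        )
        return config.model_copy(update={"risks": risks})
    if field == "vsl":
        econ = config.economics.model_copy(update={"vsl": -1.0})
        return config.model_copy(update={"economics": econ})
    if field == "mortality_rate":
        pop = config.population.model_copy(update={"annual_mortality_rate": 1.5})
        return config.model_copy(update={"population": pop})
    if field == "discount_rate":
        econ = config.economics.model_copy(update={"discount_rate": -0.01})
        return config.model_copy(update={"economics": econ})
    if field == "takeup":
        econ = config.economics.model_copy(
            update={"takeup_years": config.economics.horizon_years + 1.0}
        )
        return config.model_copy(update={"economics": econ})
    if field == "trip_length":
        behaviour = config.behaviour.model_copy(update={"trip_length_km": -4.1})
        return config.model_copy(update={"behaviour": behaviour})
    if field == "cost":
        iv = config.intervention.model_copy(update={"cost_intl_dollars": 0.0})
        return config.model_copy(update={"intervention": iv})
    if field == "in_traffic":
        risks = config.risks.model_copy(update={"in_traffic_fraction": 1.5})
        return config.model_copy(update={"risks": risks})
    if field == "crash_rate":
        risks = config.risks.model_copy(update={"crash_fatalities_per_100M_km": -0.1})
        return config.model_copy(update={"risks": risks})
    raise ValueError(f"unknown violation field {field!r}; known: {VIOLATION_FIELDS}")
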