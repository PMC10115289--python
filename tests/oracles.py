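"""Independent vectorised reimplementation of the appraisal model.

Used as the oracle for grid-search cross-checks of the break-even solver;
deliberately shares no code with the engine (plain numpy, a single
closed-form expression per domain).
"""

import numpy as np


def oracle_bcr_grid(config, source_level, shares):
    """BCR as a function of the shifted share, vectorised over shares."""
    pop, b, econ, risks = (
        config.population,
        config.behaviour,
        config.economics,
        config.risks,
    )
    days = np.array([lv.cycling_days_per_year for lv in config.levels])
    km_per_person = days * b.trips_per_day * b.trip_length_km
    rr = 1.0 - (1.0 - risks.rr_reference) * np.minimum(
        km_per_person / risks.reference_volume_km_per_year, risks.max_volume_ratio
    )
    base = np.array(pop.baseline.shares)
    post = np.tile(base, (len(shares), 1))
    post[:, 0] += shares
    post[:, source_level - 1] -= shares

    pa = pop.size * pop.annual_mortality_rate * (post @ rr - base @ rr)
    dkm = pop.size * (post @ km_per_person - base @ km_per_person)
    ap = (
        pop.annual_mortality_rate
        * risks.er_slope_per_ugm3
        * risks.pm25_ugm3
        * (risks.ventilation_ratio - 1.0)
        * risks.in_traffic_fraction
        * dkm
        / 14.0
        / 8760.0
    )
    crash = dkm * risks.crash_fatalities_per_100M_km / 1e8
    co2 = -dkm * sum(
        risks.modal_shift[m] * risks.emission_factor_g_per_km[m] for m in risks.modal_shift
    ) / 1e6
    t = np.arange(1, econ.horizon_years + 1, dtype=float)
    disc = float(
        np.sum(np.minimum(t / econ.takeup_years, 1.0) * (1.0 + econ.discount_rate) ** (-t))
    )
    annual = (-pa - ap - crash) * econ.vsl + (-co2) * econ.carbon_damage_cost
    return disc * annual / config.intervention.cost_intl_dollars
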