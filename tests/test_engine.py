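"""Comparative risk assessment engine: dose-response, four domains,
discounting, and the structural invariants of the appraisal."""

import math

import numpy as np
import pytest

from cycleval.breakeven import ScenarioShift, apply_shift
from cycleval.config import CyclingDistribution, EconomicParams
from cycleval.engine import (
    ap_deaths,
    appraise,
    carbon_tonnes,
    crash_deaths,
    discounted_stream,
    mortality_rr,
    pa_deaths,
)
from cycleval.synthetic import GeneratorSpec, sample_configs


def _shifted(config, share=0.01, source=2):
    return apply_shift(
        config.population.baseline,
        ScenarioShift(source_level=source, shifted_share=share),
    )


class TestMortalityRR:
    def test_zero_volume_is_null_risk(self, coventry):
        assert mortality_rr(0.0, coventry.risks) == 1.0

    def test_reference_volume_gives_reference_rr(self, coventry):
        assert mortality_rr(
            coventry.risks.reference_volume_km_per_year, coventry.risks
        ) == pytest.approx(coventry.risks.rr_reference)

    def test_volume_cap(self, coventry):
        """Beyond the cap, extra volume confers no extra protection."""
        risks = coventry.risks.model_copy(
            update={"rr_reference": 0.9, "max_volume_ratio": 2.0}
        )
        vol = 3.0 * risks.reference_volume_km_per_year
        assert mortality_rr(vol, risks) == pytest.approx(0.8)

    def test_negative_volume_rejected(self, coventry):
        with pytest.raises(ValueError):
            mortality_rr(-1.0, coventry.risks)


class TestDomainDeltas:
    def test_no_change_no_deaths(self, coventry):
        pop = coventry.population
        assert pa_deaths(
            pop.baseline, pop.baseline, pop, coventry.behaviour, coventry.risks
        ) == 0.0

    def test_shift_to_regular_cycling_averts_deaths(self, coventry):
        pop = coventry.population
        for source in (2, 3, 4, 5):
            post = _shifted(coventry, 0.005, source)
            assert (
                pa_deaths(pop.baseline, post, pop, coventry.behaviour, coventry.risks) < 0
            )

    def test_pa_deaths_linear_in_population_size(self, coventry):
        pop = coventry.population
        double = pop.model_copy(update={"size": 2 * pop.size})
        post = _shifted(coventry)
        one = pa_deaths(pop.baseline, post, pop, coventry.behaviour, coventry.risks)
        two = pa_deaths(pop.baseline, post, double, coventry.behaviour, coventry.risks)
        assert two == pytest.approx(2.0 * one, rel=1e-12)

    def test_air_pollution_zero_cases(self, coventry):
        assert ap_deaths(0.0, coventry.risks, coventry.population) == 0.0
        no_traffic = coventry.risks.model_copy(update={"in_traffic_fraction": 0.0})
        assert ap_deaths(1e6, no_traffic, coventry.population) == 0.0

    def test_air_pollution_is_a_disbenefit(self, coventry):
        assert ap_deaths(1e6, coventry.risks, coventry.population) > 0.0

    def test_crash_unit_arithmetic(self, coventry):
        risks = coventry.risks.model_copy(update={"crash_fatalities_per_100M_km": 0.67})
        assert crash_deaths(1e8, risks) == pytest.approx(0.67)
        assert crash_deaths(0.0, risks) == 0.0
        with pytest.raises(ValueError):
            crash_deaths(-1.0, risks)

    def test_carbon_zero_and_walking_only(self, coventry):
        assert carbon_tonnes(0.0, coventry.risks) == 0.0
        walk = coventry.risks.model_copy(
            update={"modal_shift": {"public_transport": 0.0, "car": 0.0, "walking": 1.0}}
        )
        assert carbon_tonnes(1e6, walk) == 0.0

    def test_carbon_emissions_fall_under_default_shares(self, coventry):
        assert carbon_tonnes(1e6, coventry.risks) < 0.0


class TestDiscountedStream:
    def test_undiscounted_full_uptake(self):
        econ = EconomicParams(
            vsl=1.0, discount_rate=0.0, horizon_years=10, takeup_years=1.0,
            ppp_coefficient=1.0, carbon_damage_cost=1.0,
        )
        assert discounted_stream(100.0, econ) == pytest.approx(1000.0)

    def test_five_percent_ten_years(self):
        # Independent term-by-term sum: 100 × Σ_{t=1..10} 1.05^-t = 772.17
        econ = EconomicParams(
            vsl=1.0, discount_rate=0.05, horizon_years=10, takeup_years=1.0,
            ppp_coefficient=1.0, carbon_damage_cost=1.0,
        )
        assert discounted_stream(100.0, econ) == pytest.approx(772.17, abs=0.005)

    def test_matches_vectorised_summation_oracle(self):
        """1,000 random parameter draws agree with an independent numpy
        summation to 1e-10 relative."""
        rng = np.random.default_rng(20230419)
        for _ in range(1000):
            horizon = int(rng.integers(1, 40))
            econ = EconomicParams(
                vsl=1.0,
                discount_rate=float(rng.uniform(0.0, 0.15)),
                horizon_years=horizon,
                takeup_years=float(rng.uniform(0.25, horizon)),
                ppp_coefficient=1.0,
                carbon_damage_cost=1.0,
            )
            value = float(rng.uniform(-1e6, 1e6))
            t = np.arange(1, horizon + 1, dtype=float)
            expected = float(
                np.sum(
                    np.minimum(t / econ.takeup_years, 1.0)
                    * value
                    * (1.0 + econ.discount_rate) ** (-t)
                )
            )
            got = discounted_stream(value, econ)
            assert got == pytest.approx(expected, rel=1e-10, abs=1e-10)

    def test_monotone_directions(self):
        base = EconomicParams(
            vsl=1.0, discount_rate=0.05, horizon_years=10, takeup_years=2.0,
            ppp_coefficient=1.0, carbon_damage_cost=1.0,
        )
        v = discounted_stream(100.0, base)
        assert discounted_stream(100.0, base.model_copy(update={"discount_rate": 0.06})) < v
        assert discounted_stream(100.0, base.model_copy(update={"takeup_years": 3.0})) < v
        assert discounted_stream(100.0, base.model_copy(update={"horizon_years": 11})) > v
        assert discounted_stream(100.0, base.model_copy(update={"horizon_years": 5})) < v

    def test_mid_year_timing_exceeds_end_year(self):
        econ = EconomicParams(
            vsl=1.0, discount_rate=0.05, horizon_years=10, takeup_years=1.0,
            ppp_coefficient=1.0, carbon_damage_cost=1.0,
        )
        assert discounted_stream(100.0, econ, timing="mid") > discounted_stream(100.0, econ)


class TestAppraise:
    def test_no_change_means_no_value(self, coventry):
        result = appraise(coventry, coventry.population.baseline)
        assert all(imp.discounted_value == 0.0 for imp in result.impacts)
        assert result.total_benefit == 0.0
        assert result.bcr == 0.0

    def test_sign_pattern_for_any_shift_to_regular_cycling(self, coventry):
        """Physical activity and carbon are benefits; air pollution and
        crash risk are disbenefits — for every source level."""
        for source in (2, 3, 4, 5):
            result = appraise(coventry, _shifted(coventry, 0.005, source))
            assert result.impact("physical_activity").discounted_value > 0
            assert result.impact("air_pollution").discounted_value < 0
            assert result.impact("crash_risk").discounted_value < 0
            assert result.impact("carbon").discounted_value > 0

    def test_total_is_sum_of_domains_on_random_configs(self):
        for config in sample_configs(GeneratorSpec(seed=7, n_configs=25)):
            baseline = config.population.baseline
            share = 0.5 * baseline.shares[1]
            post = apply_shift(
                baseline, ScenarioShift(source_level=2, shifted_share=share)
            )
            result = appraise(config, post)
            total = math.fsum(imp.discounted_value for imp in result.impacts)
            assert result.total_benefit == pytest.approx(total, rel=1e-6)
            assert result.bcr == pytest.approx(
                total / config.intervention.cost_intl_dollars, rel=1e-9
            )

    def test_linear_in_population_size(self, coventry):
        post = _shifted(coventry)
        pop2 = coventry.population.model_copy(update={"size": 2 * coventry.population.size})
        doubled = coventry.model_copy(update={"population": pop2})
        r1 = appraise(coventry, post)
        r2 = appraise(doubled, post)
        for a, b in zip(r1.impacts, r2.impacts):
            assert b.discounted_value == pytest.approx(2.0 * a.discounted_value, rel=1e-9)
        assert r2.bcr == pytest.approx(2.0 * r1.bcr, rel=1e-9)

    def test_vsl_linearity_leaves_carbon_unchanged(self, coventry):
        post = _shifted(coventry)
        r1 = appraise(coventry, post)
        econ = coventry.economics.model_copy(update={"vsl": 1.2 * coventry.economics.vsl})
        r2 = appraise(coventry.model_copy(update={"economics": econ}), post)
        for domain in ("physical_activity", "air_pollution", "crash_risk"):
            assert r2.impact(domain).discounted_value == pytest.approx(
                1.2 * r1.impact(domain).discounted_value, rel=1e-12
            )
        assert r2.impact("carbon").discounted_value == pytest.approx(
            r1.impact("carbon").discounted_value, rel=1e-12
        )

    def test_output_is_function_of_trip_volume_product_only(self, coventry):
        """trips/day ×1.2 and trip length ×1.2 give identical appraisals."""
        post = _shifted(coventry)
        b = coventry.behaviour
        via_trips = coventry.model_copy(
            update={"behaviour": b.model_copy(update={"trips_per_day": 1.2 * b.trips_per_day})}
        )
        via_length = coventry.model_copy(
            update={"behaviour": b.model_copy(update={"trip_length_km": 1.2 * b.trip_length_km})}
        )
        r1, r2 = appraise(via_trips, post), appraise(via_length, post)
        for a, c in zip(r1.impacts, r2.impacts):
            assert c.discounted_value == pytest.approx(a.discounted_value, rel=1e-12)
        assert r2.bcr == pytest.approx(r1.bcr, rel=1e-12)

    def test_bcr_monotone_in_economic_parameters(self, coventry):
        post = _shifted(coventry)
        base_bcr = appraise(coventry, post).bcr

        def bcr_with(**updates):
            econ = coventry.economics.model_copy(update=updates)
            return appraise(coventry.model_copy(update={"economics": econ}), post).bcr

        assert bcr_with(horizon_years=15) > base_bcr > bcr_with(horizon_years=5)
        assert bcr_with(vsl=1.2 * coventry.economics.vsl) > base_bcr
        assert bcr_with(vsl=0.8 * coventry.economics.vsl) < base_bcr
        assert bcr_with(discount_rate=0.035) > base_bcr > bcr_with(discount_rate=0.065)
        assert base_bcr > bcr_with(takeup_years=2.0) > bcr_with(takeup_years=5.0)

    def test_invalid_config_rejected(self, coventry):
        from cycleval.synthetic import inject_violation

        bad = inject_violation(coventry, "vsl")
        with pytest.raises(ValueError, match="invalid appraisal inputs"):
            appraise(bad, _shifted(coventry))
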