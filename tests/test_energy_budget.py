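"""Unit and property tests for the individual-level metabolic equations."""

import math

import numpy as np
import pytest
from hypothesis import given, strategies as st

from wormbudget import (
    CocoonState,
    DailyEnvironment,
    EnergyBudgetParams,
    Stage,
    WormState,
    allocate_day,
    arrhenius_factor,
    assimilated_energy,
    cocoon_day,
    ingestion_rate,
    maintenance_rate,
    max_growth_increment,
    max_reproduction_allocation,
    vb_mass_at_age,
)
from wormbudget.energy_budget import initial_cocoon

TEMPS = st.floats(min_value=278.0, max_value=303.0)


class TestArrhenius:
    def test_unity_at_reference_temperature(self, params):
        assert arrhenius_factor(params.Tref, params) == pytest.approx(1.0)

    def test_value_at_20C(self, params):
        # direct evaluation of exp((-E/k)(1/T - 1/Tref))
        assert arrhenius_factor(293.15, params) == pytest.approx(0.8471207, rel=1e-6)

    @given(t1=TEMPS, t2=TEMPS)
    def test_strictly_increasing_in_temperature(self, params, t1, t2):
        if t1 < t2:
            assert arrhenius_factor(t1, params) < arrhenius_factor(t2, params)

    def test_rejects_nonpositive_temperature(self, params):
        with pytest.raises(ValueError):
            arrhenius_factor(0.0, params)


class TestMaintenance:
    def test_one_gram_at_reference(self, params):
        # 967 * exp(-0.25/(8.62e-5 * 298.15))
        assert maintenance_rate(1.0, 298.15, params) == pytest.approx(0.0576579, rel=1e-5)

    def test_rejects_nonpositive_mass(self, params):
        with pytest.raises(ValueError):
            maintenance_rate(0.0, 298.15, params)

    @given(m=st.floats(min_value=0.011, max_value=0.5), t=TEMPS)
    def test_three_quarter_power_law(self, params, m, t):
        assert maintenance_rate(2 * m, t, params) == pytest.approx(
            2 ** 0.75 * maintenance_rate(m, t, params)
        )


class TestIngestion:
    def test_half_saturation(self, params):
        # X = h gives half the maximum for a 1-g worm at Tref
        assert ingestion_rate(1.0, params.Tref, params.h, params) == pytest.approx(0.35)

    def test_saturates_at_igmax(self, params):
        assert ingestion_rate(1.0, params.Tref, 1e12, params) == pytest.approx(0.70, rel=1e-6)

    def test_zero_food_zero_intake(self, params):
        assert ingestion_rate(0.3, params.Tref, 0.0, params) == 0.0

    def test_rejects_negative_food(self, params):
        with pytest.raises(ValueError):
            ingestion_rate(0.3, params.Tref, -1.0, params)

    @given(t1=TEMPS, t2=TEMPS)
    def test_monotone_in_temperature(self, params, t1, t2):
        if t1 < t2:
            assert ingestion_rate(0.3, t1, 5.0, params) < ingestion_rate(0.3, t2, 5.0, params)


class TestAssimilation:
    @pytest.mark.parametrize(
        "ingested, ae, expected",
        [(0.35, 0.5, 3.71), (0.0, 0.5, 0.0), (1.0, 1.0, 21.2)],
    )
    def test_examples(self, params, ingested, ae, expected):
        p = params.replace(Ae=ae)
        assert assimilated_energy(ingested, p) == pytest.approx(expected)

    def test_rejects_negative_intake(self, params):
        with pytest.raises(ValueError):
            assimilated_energy(-0.1, params)


class TestGrowth:
    def test_zero_at_asymptotic_mass(self, params):
        assert max_growth_increment(params.Mm, params.Tref, params) == 0.0

    def test_hatchling_increment(self, params):
        assert max_growth_increment(0.011, params.Tref, params) == pytest.approx(
            0.0050015, rel=1e-4
        )

    def test_clamped_above_asymptote(self, params):
        assert max_growth_increment(0.6, params.Tref, params) == 0.0

    def test_maximised_at_eight_twentysevenths_of_mm(self, params):
        # stationary point of the growth cubic
        m_star = 8.0 / 27.0 * params.Mm
        best = max_growth_increment(m_star, params.Tref, params)
        for m in np.linspace(params.Mb, params.Mm, 200):
            assert max_growth_increment(float(m), params.Tref, params) <= best + 1e-15

    def test_vb_boundary_values(self, params):
        assert vb_mass_at_age(0.0, params) == pytest.approx(0.011)
        assert vb_mass_at_age(1e5, params) == pytest.approx(0.50)

    def test_vb_rejects_negative_age(self, params):
        with pytest.raises(ValueError):
            vb_mass_at_age(-1.0, params)

    def test_daily_integration_tracks_closed_form(self, params):
        """Daily stepping of the growth increment converges onto the
        closed-form curve: within 1% until maturity when starting from a
        0.1-g juvenile, and within 0.1% of the asymptotic approach after 100
        days from a hatchling.  (From the hatchling mass the one-day step
        transiently undershoots the continuous curve by a few percent while
        the growth timescale is comparable to the step.)"""
        # age at which the closed form passes 0.1 g
        a = 1 - (params.Mb / params.Mm) ** (1 / 3)
        t0 = -3 / params.rB * math.log((1 - (0.1 / params.Mm) ** (1 / 3)) / a)
        m = 0.1
        day = 0
        while m < params.Mp:
            m += max_growth_increment(m, params.Tref, params)
            day += 1
            assert m == pytest.approx(vb_mass_at_age(t0 + day, params), rel=0.01)
        m = params.Mb
        for day in range(1, 101):
            m += max_growth_increment(m, params.Tref, params)
        assert m == pytest.approx(vb_mass_at_age(100, params), rel=0.001)


class TestReproductionAllocation:
    def test_examples(self, params):
        assert max_reproduction_allocation(0.4, params.Tref, params) == pytest.approx(0.0728)
        assert max_reproduction_allocation(1.0, params.Tref, params) == pytest.approx(0.182)

    @given(m=st.floats(min_value=0.25, max_value=0.5), t=TEMPS)
    def test_linear_in_mass(self, params, m, t):
        assert max_reproduction_allocation(m / 2, t, params) == pytest.approx(
            max_reproduction_allocation(m, t, params) / 2
        )


def _env(params, T=None, X=0.0):
    return DailyEnvironment(T=T if T is not None else params.Tref, SM=60.0, X=X)


class TestAllocateDay:
    def test_unconstrained_juvenile_grows_at_maximum_rate(self, params):
        state = WormState(Stage.JUVENILE, M=0.05, reserve=0.1)
        new, ledger = allocate_day(state, _env(params, X=1e9), False, params)
        assert ledger.mass_delta == pytest.approx(
            max_growth_increment(0.05, params.Tref, params), rel=1e-12
        )
        assert not ledger.died

    def test_starvation_boundary_death(self, params):
        state = WormState(Stage.JUVENILE, M=params.Mb, reserve=0.0)
        new, ledger = allocate_day(state, _env(params, X=0.0), False, params)
        assert ledger.died
        assert new.M < params.Mb

    def test_reproduction_continues_without_food_above_reserve_threshold(self, params):
        """Adults keep allocating reserve energy to reproduction while their
        reserve sits above half capacity, even with no food at all."""
        m = 0.4
        state = WormState(Stage.ADULT, M=m, reserve=0.9 * m * params.Ec)
        new, ledger = allocate_day(state, _env(params, X=0.0), True, params)
        assert ledger.repro_spent > 0
        assert new.repro_pool + ledger.cocoons_produced * params.Mc * (
            params.Ec + params.Es
        ) == pytest.approx(ledger.repro_spent)

    def test_no_reproduction_without_mate(self, params):
        state = WormState(Stage.ADULT, M=0.4, reserve=0.9 * 0.4 * params.Ec)
        _, ledger = allocate_day(state, _env(params, X=1e9), False, params)
        assert ledger.repro_spent == 0.0

    def test_cocoon_emission_consumes_pool(self, params):
        cost = params.Mc * (params.Ec + params.Es)
        state = WormState(Stage.ADULT, M=0.5, reserve=0.5, repro_pool=cost * 0.95)
        _, ledger = allocate_day(state, _env(params, X=1e9), True, params)
        assert ledger.cocoons_produced == 1

    def test_rejects_cocoon_stage(self, params):
        with pytest.raises(ValueError):
            allocate_day(WormState(Stage.COCOON, M=0.015), _env(params), False, params)

    def test_unmated_adult_outgrows_mated_adult(self, params):
        """Without a partner, reproduction stops and the worm grows larger
        under food-limited conditions."""
        mated = WormState(Stage.ADULT, M=0.3, reserve=0.3 * 0.5 * params.Ec)
        single = mated
        env = _env(params, X=0.05)
        for _ in range(100):
            mated, _ = allocate_day(mated, env, True, params)
            single, _ = allocate_day(single, env, False, params)
        assert single.M > mated.M + 0.05

    def test_mated_adult_never_exceeds_closed_form_curve(self, params):
        """Reproduction has priority over growth, so a reproducing adult
        stays at or below the optimal growth curve (1% headroom for the
        daily discretisation of the continuous curve)."""
        state = WormState(Stage.ADULT, M=params.Mp, reserve=0.0)
        # age at which the closed form reaches the maturity mass
        offset = -3 / params.rB * math.log(
            (1 - (params.Mp / params.Mm) ** (1 / 3))
            / (1 - (params.Mb / params.Mm) ** (1 / 3))
        )
        for day in range(1, 150):
            state, _ = allocate_day(state, _env(params, X=1e9), True, params)
            assert state.M <= vb_mass_at_age(day + offset, params) * 1.01

    @given(
        m=st.floats(min_value=0.011, max_value=0.5),
        reserve_frac=st.floats(min_value=0.0, max_value=1.0),
        pool=st.floats(min_value=0.0, max_value=0.2),
        t=TEMPS,
        x=st.floats(min_value=0.0, max_value=50.0),
        adult=st.booleans(),
        mate=st.booleans(),
    )
    def test_energy_conservation_and_reserve_bounds(
        self, params, m, reserve_frac, pool, t, x, adult, mate
    ):
        """Every day's ledger closes to < 1e-9 kJ and the reserve stays in
        [0, M*Ec]."""
        stage = Stage.ADULT if adult else Stage.JUVENILE
        state = WormState(stage, M=m, reserve=reserve_frac * m * params.Ec, repro_pool=pool)
        new, led = allocate_day(state, _env(params, T=t, X=x), mate, params)
        inflow = led.assimilated + led.reserve_withdrawn + params.Ec * led.catabolised_g
        outflow = (
            led.maintenance_paid
            + led.repro_spent
            + led.growth_spent
            + led.reserve_deposited
            + led.discarded
        )
        assert abs(inflow - outflow) < 1e-9
        assert new.reserve == pytest.approx(
            state.reserve + led.reserve_delta, abs=1e-12
        )
        assert new.M == pytest.approx(state.M + led.mass_delta, abs=1e-12)
        assert -1e-12 <= new.reserve <= new.M * params.Ec + 1e-9
        assert new.repro_pool >= 0


class TestCocoonDay:
    def test_hatches_on_day_23_at_reference_temperature(self, params):
        c = initial_cocoon(params)
        for day in range(1, 40):
            c, hatchling, died = cocoon_day(c, params.Tref, params)
            assert not died
            if hatchling is not None:
                assert day == 23
                assert hatchling.stage is Stage.JUVENILE
                assert hatchling.M == params.Mb
                return
        pytest.fail("cocoon never hatched")

    def test_endowment_survives_incubation(self, params):
        """23 days of maintenance at Tref (~0.057 kJ) stays below the
        0.105 kJ endowment, so the hatchling keeps a positive reserve."""
        c = initial_cocoon(params)
        hatchling = None
        while hatchling is None:
            c, hatchling, died = cocoon_day(c, params.Tref, params)
            assert not died
        expected = params.Mc * params.Ec - 23 * maintenance_rate(params.Mc, params.Tref, params)
        assert hatchling.reserve == pytest.approx(expected, rel=1e-9)
        assert hatchling.reserve > 0

    def test_warmer_incubation_hatches_earlier(self, params):
        def hatch_day(T):
            c = initial_cocoon(params)
            for day in range(1, 100):
                c, h, died = cocoon_day(c, T, params)
                if h is not None:
                    return day
            return None

        assert hatch_day(303.15) < hatch_day(params.Tref) == 23

    def test_dies_when_endowment_exhausted(self, params):
        c = CocoonState(reserve=1e-6)
        c2, h, died = cocoon_day(c, params.Tref, params)
        assert died and c2 is None and h is None


class TestParams:
    def test_defaults_are_internally_consistent(self):
        p = EnergyBudgetParams()
        assert p.Mb < p.Mp < p.Mm
        assert 0 < p.Ae <= 1

    @pytest.mark.parametrize(
        "bad", [{"Ae": 1.5}, {"Mp": 0.6}, {"rB": -0.1}, {"B0": 0.0}]
    )
    def test_invalid_values_rejected(self, bad):
        with pytest.raises(ValueError):
            EnergyBudgetParams(**bad)

    def test_from_dict_rejects_unknown_names(self):
        with pytest.raises(ValueError):
            EnergyBudgetParams.from_dict({"Ae": 0.5, "bogus": 1.0})
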