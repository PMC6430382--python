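"""Annual transition, projection, and their independent oracles."""

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

import chinook_pva as cp
from chinook_pva.lifecycle import EnvironmentYear, PopulationState
from chinook_pva.params import ValidationError


def _neutral_params(**over):
    """Round-number configuration for hand-checkable arithmetic."""
    base = dict(
        productivity=2.0,
        capacity_above_dam=1e12,
        fraction_above_dam=0.5,
        fry_survival_below_dam=0.5,
        reservoir_survival=0.5,
        dam_passage_proportion=0.5,
        pathway_proportions=(0.5, 0.25, 0.25),
        lower_river_survival=(0.4, 0.2, 0.8),
        estuary_coefficients={
            "intercept": 0.0, "pdo_may": 0.0, "upwelling_may": 0.0,
            "upwelling_sept": 0.0, "delta_length": 0.0329,
        },
        prespawn_coefficients={
            "intercept": 0.0, "late_summer_temp": 0.0, "wild_fraction": 0.0,
        },
        maturation_schedule=(1.0, 1.0, 1.0),
        ocean_annual_survival=0.5,
    )
    base.update(over)
    return cp.default_parameters().evolve(**base)


class TestBevertonHolt:
    def test_saturates_at_capacity(self):
        assert cp.beverton_holt(1e15, 2.0, 1000.0) == pytest.approx(1000.0, rel=1e-3)

    def test_no_spawners_no_fry(self):
        assert cp.beverton_holt(0.0, 2.0, 1000.0) == 0.0

    def test_closed_form(self):
        # independent evaluation: 2*100 / (1 + 200/1000)
        assert cp.beverton_holt(100, 2.0, 1000.0) == pytest.approx(200 / 1.2)

    def test_linear_at_low_density(self):
        assert cp.beverton_holt(1e-3, 2.0, 1000.0) == pytest.approx(2e-3, rel=1e-5)

    def test_rejects_nonpositive_capacity(self):
        with pytest.raises(ValueError):
            cp.beverton_holt(100, 2.0, 0.0)


class TestAllocatePathways:
    def test_published_proportions(self):
        assert cp.allocate_pathways(1000, (0.18, 0.13, 0.69)) == pytest.approx(
            (180, 130, 690)
        )

    def test_degenerate_composition(self):
        assert cp.allocate_pathways(500, (1.0, 0.0, 0.0)) == (500, 0, 0)

    @given(
        fry=st.integers(0, 10_000),
        a=st.floats(0.01, 1), b=st.floats(0.01, 1), c=st.floats(0.01, 1),
        seed=st.integers(0, 2**31 - 1),
    )
    @settings(max_examples=50, deadline=None)
    def test_conservation_stochastic_and_continuous(self, fry, a, b, c, seed):
        props = np.array([a, b, c]) / (a + b + c)
        cont = cp.allocate_pathways(fry, props)
        assert sum(cont) == pytest.approx(fry, abs=1e-9)
        rng = np.random.default_rng(seed)
        stoch = cp.allocate_pathways(fry, props, rng)
        assert sum(stoch) == fry

    def test_rejects_bad_composition(self):
        with pytest.raises(ValidationError):
            cp.allocate_pathways(100, (0.5, 0.5, 0.5))


class TestSurvivalLinks:
    def test_logistic_at_zero(self):
        env = EnvironmentYear()
        coeffs = {"intercept": 0.0, "late_summer_temp": 0.0, "wild_fraction": 0.0}
        assert cp.prespawn_survival(env, coeffs) == pytest.approx(0.5)

    def test_warm_water_reduces_prespawn_survival(self):
        coeffs = cp.default_parameters().prespawn_coefficients
        cool = cp.prespawn_survival(EnvironmentYear(late_summer_temp=14.0), coeffs)
        warm = cp.prespawn_survival(EnvironmentYear(late_summer_temp=19.0), coeffs)
        assert warm < cool

    def test_estuary_baseline_value(self):
        env = EnvironmentYear()  # covariates at average
        coeffs = cp.default_parameters().estuary_coefficients
        assert cp.estuary_ocean_survival(env, coeffs) == pytest.approx(0.1188, abs=5e-4)

    def test_growth_decrement_through_engine(self):
        env = EnvironmentYear()
        coeffs = cp.default_parameters().estuary_coefficients
        drop = 100 * (
            cp.estuary_ocean_survival(env, coeffs)
            - cp.estuary_ocean_survival(env, coeffs, delta_length=-7.02)
        )
        assert drop == pytest.approx(2.21, abs=0.01)

    def test_consistent_with_contaminant_module_link(self):
        # same logistic: engine at average covariates == growth-survival link
        env = EnvironmentYear()
        coeffs = cp.default_parameters().estuary_coefficients
        link = cp.GrowthSurvivalLink(
            intercept=coeffs["intercept"], slope=coeffs["delta_length"]
        )
        for d in (-7.02, -1.04, 0.0, 3.0):
            assert cp.estuary_ocean_survival(env, coeffs, d) == pytest.approx(
                cp.estuary_survival(d, link), rel=1e-12
            )


class TestStepYear:
    def test_hand_computed_single_year(self):
        # spreadsheet-style arithmetic on round numbers, expectation mode
        params = _neutral_params()
        start = PopulationState(
            spawners=1000.0, ocean_abundance=(100.0, 200.0, 0.0, 0.0, 0.0)
        )
        out = cp.step_year(start, params, EnvironmentYear())
        assert out.fry == pytest.approx(2000.0, rel=1e-8)
        assert out.pathway_cohorts == pytest.approx((750 * 0.5, 187.5, 187.5))
        # smolts 337.5, halved entering the ocean
        assert out.ocean_abundance[0] == pytest.approx(168.75)
        assert out.ocean_abundance[1] == pytest.approx(50.0)  # 100 at sea, half survive
        assert out.returning_adults == pytest.approx(100.0)  # 200 * 0.5, all mature
        assert out.spawners == pytest.approx(50.0)

    def test_zero_population_is_absorbing(self):
        params = cp.default_parameters()
        empty = PopulationState()
        det = cp.step_year(empty, params, EnvironmentYear())
        stoch = cp.step_year(
            empty, params, EnvironmentYear(), rng=np.random.default_rng(0)
        )
        for state in (det, stoch):
            assert state.spawners == 0
            assert state.fry == 0
            assert sum(state.ocean_abundance) == 0

    def test_multiplier_monotone_with_common_random_numbers(self):
        params = cp.default_parameters()
        start = cp.initial_state(params)
        env = EnvironmentYear()
        for seed in range(5):
            lo = cp.step_year(start, params, env, cp.ScenarioSpec("b", 1.0),
                              np.random.default_rng(seed))
            hi = cp.step_year(start, params, env, cp.ScenarioSpec("t", 1.54),
                              np.random.default_rng(seed))
            assert hi.pathway_cohorts == lo.pathway_cohorts  # allocation unaffected
            assert hi.ocean_abundance[0] >= lo.ocean_abundance[0]


class TestProject:
    def test_deterministic_mode_is_reproducible(self):
        params = cp.default_parameters().evolve(horizon_years=20)
        a = cp.project(params, stochastic=False)
        b = cp.project(params, stochastic=False)
        np.testing.assert_array_equal(a, b)

    def test_same_seed_same_series(self):
        params = cp.default_parameters().evolve(horizon_years=20)
        env = cp.generate_env_series(years=20, seed=3)[0]
        a = cp.project(params, env_series=env, seed=99)
        b = cp.project(params, env_series=env, seed=99)
        np.testing.assert_array_equal(a, b)

    def test_short_env_series_rejected(self):
        params = cp.default_parameters()
        env = cp.generate_env_series(years=10, seed=3)[0]
        with pytest.raises(ValueError, match="horizon"):
            cp.project(params, env_series=env)

    def test_degenerate_limit_follows_productivity_products(self):
        # all survivals 1, maturation at ocean age 3, no density dependence,
        # empty initial ocean: spawners appear every third year multiplied by
        # the productivity, S_{3k} = prod^k * S0
        params = _neutral_params(
            productivity=3.0,
            fraction_above_dam=0.5,
            fry_survival_below_dam=1.0,
            reservoir_survival=1.0,
            dam_passage_proportion=1.0,
            lower_river_survival=(1.0, 1.0, 1.0),
            estuary_coefficients={
                "intercept": 500.0, "pdo_may": 0.0, "upwelling_may": 0.0,
                "upwelling_sept": 0.0, "delta_length": 0.0,
            },
            prespawn_coefficients={
                "intercept": 500.0, "late_summer_temp": 0.0, "wild_fraction": 0.0,
            },
            ocean_annual_survival=1.0,
            horizon_years=9,
            initial_spawners=10,
        )
        start = PopulationState(spawners=10.0)
        traj = cp.project(params, stochastic=False, start=start)
        np.testing.assert_allclose(
            traj, [0, 0, 30, 0, 0, 90, 0, 0, 270], rtol=1e-9
        )

    def test_density_independent_growth_matches_dominant_eigenvalue(self):
        # independent oracle: the linearized annual projection matrix on
        # (spawners, ocean ages 1..5); its dominant eigenvalue must equal the
        # realized asymptotic growth rate of the expectation-mode engine
        params = cp.default_parameters().evolve(
            capacity_above_dam=1e14, horizon_years=120
        )
        env = EnvironmentYear()
        fresh = (
            params.fraction_above_dam
            * params.dam_passage_proportion
            * params.reservoir_survival
            + (1 - params.fraction_above_dam) * params.fry_survival_below_dam
        )
        lbar = sum(
            p * s
            for p, s in zip(params.pathway_proportions, params.lower_river_survival)
        )
        p_est = cp.estuary_ocean_survival(env, params.estuary_coefficients)
        p_pre = cp.prespawn_survival(env, params.prespawn_coefficients)
        s = params.ocean_annual_survival
        m3, m4, m5 = params.maturation_schedule
        kappa = params.productivity * fresh * lbar * p_est
        A = np.zeros((6, 6))  # order: S, N1..N5
        A[1, 0] = kappa
        A[2, 1] = s
        A[3, 2] = s * (1 - m3)
        A[4, 3] = s * (1 - m4)
        A[5, 4] = s * (1 - m5)
        A[0, 2] = p_pre * s * m3
        A[0, 3] = p_pre * s * m4
        A[0, 4] = p_pre * s * m5
        lam = max(np.abs(np.linalg.eigvals(A)))
        traj = cp.project(params, stochastic=False)
        realized = traj[-1] / traj[-2]
        assert realized == pytest.approx(lam, rel=1e-6)
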