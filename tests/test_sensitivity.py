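"""Design sampling, compositional transform, and influence regression."""

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st
from scipy.stats import kstest

import chinook_pva as cp
from chinook_pva.params import ValidationError
from chinook_pva.sensitivity import (
    DEFAULT_RANGES,
    PATHWAY_PARAMS,
    apply_draw,
    relative_influence,
    sample_design,
)


class TestSampleDesign:
    def test_all_draws_within_ranges(self):
        design = sample_design(n_draws=500, seed=1)
        for name, (low, high) in design.parameter_ranges.items():
            col = design.column(name)
            assert np.all((col >= low) & (col <= high))

    def test_multiplier_range_spans_no_effect_to_full_cleanup(self):
        low, high = DEFAULT_RANGES["subyearling_survival_multiplier"]
        assert (low, high) == (1.00, 1.54)

    def test_uniformity_by_kolmogorov_smirnov(self):
        design = sample_design(n_draws=10_000, seed=2)
        low, high = design.parameter_ranges["capacity_above_dam"]
        stat = kstest(design.column("capacity_above_dam"),
                      "uniform", args=(low, high - low))
        assert stat.pvalue > 0.01

    def test_reproducible(self):
        a = sample_design(n_draws=50, seed=9)
        b = sample_design(n_draws=50, seed=9)
        np.testing.assert_array_equal(a.draws, b.draws)

    def test_degenerate_range_rejected(self):
        with pytest.raises(ValidationError):
            sample_design({"x": (1.0, 1.0)}, n_draws=10, seed=0)

    def test_compositions_sum_to_one(self):
        design = sample_design(n_draws=200, seed=3)
        np.testing.assert_allclose(design.compositions().sum(axis=1), 1.0)


class TestLogRatio:
    def test_equal_composition_maps_to_origin(self):
        assert cp.logratio_transform(1 / 3, 1 / 3, 1 / 3) == pytest.approx((0.0, 0.0))

    def test_study_composition(self):
        x1, x2 = cp.logratio_transform(0.18, 0.13, 0.69)
        assert x1 == pytest.approx(np.log(0.18 / 0.69))
        assert x2 == pytest.approx(np.log(0.13 / 0.69))

    @given(st.floats(0.01, 1), st.floats(0.01, 1), st.floats(0.01, 1))
    @settings(max_examples=100, deadline=None)
    def test_round_trip_identity(self, a, b, c):
        total = a + b + c
        comp = (a / total, b / total, c / total)
        back = cp.inverse_logratio(*cp.logratio_transform(*comp))
        assert back == pytest.approx(comp, abs=1e-12)

    def test_inverse_always_valid_composition(self, rng):
        for x1, x2 in rng.normal(0, 5, size=(50, 2)):
            p = cp.inverse_logratio(x1, x2)
            assert all(v > 0 for v in p)
            assert sum(p) == pytest.approx(1.0)

    def test_zero_component_rejected(self):
        with pytest.raises(ValueError):
            cp.logratio_transform(0.0, 0.5, 0.5)

    def test_bad_sum_rejected(self):
        with pytest.raises(ValueError, match="sum to 1"):
            cp.logratio_transform(0.5, 0.5, 0.5)


class TestApplyDraw:
    def test_draw_materializes_valid_configuration(self):
        design = sample_design(n_draws=20, seed=4)
        base = cp.default_parameters()
        for i in range(20):
            params, scenario = apply_draw(base, design, i)
            assert sum(params.pathway_proportions) == pytest.approx(1.0)
            lo, hi = DEFAULT_RANGES["subyearling_survival_multiplier"]
            assert lo <= scenario.subyearling_survival_multiplier <= hi


class TestRelativeInfluence:
    def test_single_driver_recovers_full_influence(self):
        fixture = cp.make_fixture("linear-sensitivity", seed=0)
        design = sample_design(fixture["ranges"], n_draws=len(fixture["draws"]), seed=0)
        design = design.with_responses(5.0 * design.column("driver"))
        table = relative_influence(design)
        assert table.index[0] == "driver"
        assert table.loc["driver", "relative_influence"] == pytest.approx(1.0)
        others = table.drop("driver")["relative_influence"].abs()
        assert (others < 0.05).all()

    def test_symmetric_drivers_get_equal_influence(self):
        rng = np.random.default_rng(7)
        ranges = {"x1": (0.0, 1.0), "x2": (0.0, 1.0), "x3": (0.0, 1.0)}
        design = sample_design(ranges, n_draws=4000, seed=7)
        y = 3 * design.column("x1") + 3 * design.column("x2") + rng.normal(0, 0.1, 4000)
        table = relative_influence(design.with_responses(y))
        r1 = table.loc["x1", "standardized"]
        r2 = table.loc["x2", "standardized"]
        assert abs(r1) == pytest.approx(abs(r2), rel=0.1)

    def test_ols_against_normal_equations(self):
        # independent linear-algebra oracle on a small noiseless design
        ranges = {"a": (0.0, 2.0), "b": (-1.0, 1.0)}
        design = sample_design(ranges, n_draws=50, seed=11)
        X = np.column_stack(
            [np.ones(50), design.column("a"), design.column("b")]
        )
        y = 2.0 + 1.5 * design.column("a") - 0.75 * design.column("b")
        beta = np.linalg.solve(X.T @ X, X.T @ y)
        table = relative_influence(design.with_responses(y))
        assert table.loc["a", "coefficient"] == pytest.approx(beta[1], rel=1e-8)
        assert table.loc["b", "coefficient"] == pytest.approx(beta[2], rel=1e-8)

    def test_influence_invariant_to_affine_input_rescaling(self):
        rng = np.random.default_rng(3)
        d1 = sample_design({"x": (0.0, 1.0), "z": (0.0, 1.0)}, n_draws=400, seed=3)
        noise = rng.normal(0, 0.05, 400)
        y = 2 * d1.column("x") + 0.5 * d1.column("z") + noise
        t1 = relative_influence(d1.with_responses(y))
        # same design with x rescaled to [0, 100]
        d2 = d1.__class__(
            parameter_ranges={"x": (0.0, 100.0), "z": (0.0, 1.0)},
            n_draws=400, seed=3, parameter_names=("x", "z"),
            draws=np.column_stack([d1.column("x") * 100, d1.column("z")]),
        )
        t2 = relative_influence(d2.with_responses(y))
        assert t1.loc["x", "relative_influence"] == pytest.approx(
            t2.loc["x", "relative_influence"], rel=1e-9
        )

    def test_rank_deficient_design_reports_condition(self):
        design = sample_design({"x": (0.0, 1.0), "z": (0.0, 1.0)}, n_draws=40, seed=5)
        clone = design.__class__(
            parameter_ranges=design.parameter_ranges, n_draws=40, seed=5,
            parameter_names=("x", "z"),
            draws=np.column_stack([design.column("x"), design.column("x")]),
        )
        with pytest.raises(np.linalg.LinAlgError, match="rank"):
            relative_influence(clone.with_responses(np.ones(40)))

    def test_unevaluated_design_rejected(self):
        with pytest.raises(ValueError, match="responses"):
            relative_influence(sample_design(n_draws=50, seed=0))
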