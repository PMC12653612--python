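import math

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from genomestats import (
    GeometricParams,
    MixtureParams,
    PoissonComponent,
    StepParams,
    decompose,
    dominant_component,
    evaluate_mixture,
    geometric_model,
    poisson_component,
    rate_summary,
    step_component,
    step_mean,
)


def _factorial_poisson(k, lam, k0):
    """Direct factorial-series evaluation (independent oracle)."""
    if k < k0:
        return 0.0
    n = k - k0
    return lam**n * math.exp(-lam) / math.factorial(n)


class TestPoissonComponent:
    def test_zero_before_start_class(self):
        assert poisson_component(3, lam=5.0, k0=4) == 0.0

    def test_start_class_mass_is_exp_minus_lambda(self):
        assert poisson_component(7, lam=2.5, k0=7) == pytest.approx(math.exp(-2.5))

    def test_matches_factorial_series_to_twelve_digits(self):
        lam = 6.133813
        value = poisson_component(10, lam=lam, k0=0)
        assert value == pytest.approx(_factorial_poisson(10, lam, 0), rel=1e-12)

    def test_rejects_non_integer_class(self):
        with pytest.raises(TypeError):
            poisson_component(1.5, lam=2.0, k0=0)

    @given(
        lam=st.floats(0.1, 100.0),
        k0=st.integers(0, 50),
    )
    @settings(max_examples=60, deadline=None, derandomize=True)
    def test_mass_sums_to_one_over_support(self, lam, k0):
        ks = np.arange(k0, k0 + 2000)
        total = sum(poisson_component(int(k), lam, k0) for k in ks)
        assert abs(total - 1.0) < 1e-9


class TestStepComponent:
    def test_zero_before_plateau(self, reference_mixture):
        assert step_component(29, reference_mixture.step) == 0.0

    def test_continuous_at_decay_start(self, reference_mixture):
        step = reference_mixture.step
        assert step_component(59, step) == pytest.approx(step.plateau_value)
        assert step_component(58, step) == step.plateau_value

    def test_plateau_value_direct_arithmetic(self):
        step = StepParams(a=1.0, k_start=30, L_s=29, gamma=0.045683)
        assert step.plateau_value == pytest.approx(1.0 / (29 + 1.0 / 0.045683))

    @given(gamma=st.floats(0.02, 0.15), L_s=st.integers(20, 60))
    @settings(max_examples=60, deadline=None, derandomize=True)
    def test_discrete_sum_close_to_one(self, gamma, L_s):
        # the normalizer L_s + 1/gamma is the continuous-profile integral;
        # for slow decay over a long plateau (the regime the model uses)
        # the discrete sum deviates from 1 by less than 2%
        step = StepParams(a=1.0, k_start=5, L_s=L_s, gamma=gamma)
        total = sum(step_component(k, step) for k in range(5, 5 + L_s + 3000))
        assert abs(total - 1.0) < 0.02


class TestStepMean:
    def test_reference_value_direct_arithmetic(self):
        step = StepParams(a=1.0, k_start=30, L_s=29, gamma=0.045683)
        inv = 1.0 / 0.045683
        assert step_mean(step) == pytest.approx((29**2 / 2 + inv) / (29 + inv))

    def test_large_gamma_limit_is_half_plateau(self):
        step = StepParams(a=1.0, k_start=0, L_s=40, gamma=500.0)
        assert step_mean(step) == pytest.approx(20.0, rel=1e-3)

    def test_zero_plateau_reduces_to_printed_formula(self):
        step = StepParams(a=1.0, k_start=0, L_s=0, gamma=0.25)
        inv = 1.0 / 0.25
        assert step_mean(step) == pytest.approx((0.0 + inv) / (0.0 + inv))


class TestMixtureEvaluation:
    def test_all_zero_coefficients_give_zero(self):
        params = MixtureParams(
            a_bg=0.0, L=10,
            poissons=(PoissonComponent(a=0.0, lam=3.0, k0=0),),
            step=StepParams(a=0.0, k_start=2, L_s=3, gamma=0.5),
        )
        assert evaluate_mixture(5, params)["class_mass"] == 0.0

    def test_reference_shares_at_class_ten(self, reference_mixture):
        # genes 5001-5500: three Poisson groups dominate with shares 47/23/30
        parts = decompose(10, reference_mixture)
        total = evaluate_mixture(10, reference_mixture)["class_mass"]
        shares = {name: round(100 * value / total) for name, value in parts.items()}
        assert shares["P1"] == 47
        assert shares["P3"] == 23
        assert shares["P4"] == 30

    def test_density_per_gene_is_mass_over_class_width(self, reference_mixture):
        out = evaluate_mixture(10, reference_mixture)
        assert out["density_per_gene"] == pytest.approx(out["class_mass"] / 500)

    def test_total_mass_matches_coefficient_sum(self, reference_mixture):
        total = sum(
            evaluate_mixture(k, reference_mixture)["class_mass"]
            for k in range(0, 3000)
        )
        # the printed coefficients sum to ~0.9923, not 1; the small surplus
        # is the step component's discrete-vs-continuous normalization
        assert abs(total - reference_mixture.coefficient_sum) < 2e-3
        assert total == pytest.approx(0.9923, abs=2e-3)

    def test_negative_class_rejected(self, reference_mixture):
        with pytest.raises(ValueError):
            evaluate_mixture(-1, reference_mixture)


class TestDecompose:
    def test_contributions_sum_to_mixture_exactly(self, reference_mixture):
        for k in (0, 5, 10, 45, 100, 250):
            parts = decompose(k, reference_mixture)
            assert math.fsum(parts.values()) == evaluate_mixture(
                k, reference_mixture
            )["class_mass"]
            assert all(v >= 0 for v in parts.values())

    def test_class_zero_has_only_background_and_first_poisson(self, reference_mixture):
        parts = decompose(0, reference_mixture)
        nonzero = {name for name, v in parts.items() if v > 0}
        assert nonzero == {"bg", "P1"}

    def test_support_rules_at_class_ten(self, reference_mixture):
        parts = decompose(10, reference_mixture)
        total = evaluate_mixture(10, reference_mixture)["class_mass"]
        assert parts["P5"] == 0.0  # starts at class 44
        assert parts["S"] == 0.0  # starts at class 30
        assert parts["P2"] / total < 0.01  # barely past its start, tiny mass


class TestDominantComponent:
    def test_reference_class_ten_is_first_poisson(self, reference_mixture):
        assert dominant_component(10, reference_mixture) == "P1"

    def test_single_nonzero_component_wins(self):
        params = MixtureParams(
            a_bg=0.0, L=10,
            poissons=(PoissonComponent(a=0.5, lam=3.0, k0=0),),
            step=None,
        )
        assert dominant_component(2, params) == "P1"

    def test_map_matches_brute_force_argmax(self, reference_mixture):
        order = ("bg", "P1", "P2", "P3", "P4", "P5", "S")
        for k in range(200):
            parts = decompose(k, reference_mixture)
            best = max(order, key=lambda name: (parts[name], -order.index(name)))
            assert dominant_component(k, reference_mixture) == best


class TestGeometricModel:
    def test_class_zero_returns_initial_value(self):
        assert geometric_model(0, GeometricParams(f_g0=5.2, q=2.3)) == 5.2

    def test_unit_ratio_is_constant(self):
        params = GeometricParams(f_g0=3.0, q=1.0)
        assert {geometric_model(k, params) for k in range(10)} == {3.0}

    def test_published_fit_explodes_catastrophically(self):
        # the published real-data fit f_g0=5.2, q=2.3 grows without bound —
        # the reason the geometric model was abandoned
        params = GeometricParams(f_g0=5.2, q=2.3)
        assert geometric_model(20, params) / geometric_model(0, params) > 1e6


class TestRateSummary:
    def test_reference_order_and_rates(self, reference_mixture):
        summary = rate_summary(reference_mixture)
        names = [name for name, _ in summary]
        rates = [rate for _, rate in summary]
        assert names == ["P1", "P2", "P3", "P4", "S", "P5"]
        assert rates[:4] == pytest.approx(
            [6.133813, 23.092150, 9.513952, 2.071796]
        )
        assert rates[4] == pytest.approx(step_mean(reference_mixture.step))
        assert rates[5] == pytest.approx(16.900607)

    def test_single_component_summary(self):
        params = MixtureParams(
            a_bg=0.0, L=10,
            poissons=(PoissonComponent(a=1.0, lam=4.0, k0=3),), step=None,
        )
        assert rate_summary(params) == [("P1", 4.0)]

    def test_order_equals_sort_by_start_class(self, reference_mixture):
        starts = {"P1": 0, "P2": 2, "P3": 4, "P4": 6, "P5": 44, "S": 30}
        names = [name for name, _ in rate_summary(reference_mixture)]
        assert names == sorted(starts, key=starts.get)


def test_params_serialize_round_trip(tmp_path, reference_mixture):
    path = tmp_path / "params.txt"
    reference_mixture.to_file(path)
    back = MixtureParams.from_file(path)
    assert back == reference_mixture


def test_step_geometry_constraint(reference_mixture):
    step = reference_mixture.step
    assert step.k_decay == step.k_start + step.L_s == 59
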