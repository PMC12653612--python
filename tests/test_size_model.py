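import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st
from scipy.integrate import solve_ivp

from genomestats import (
    GenomeRecord,
    derive_params,
    dge_fraction,
    fit_size_model,
    le_of_s,
    params_from_bc,
    s_of_g,
    transform_density,
    bin_gene_numbers,
    bin_log_sizes,
)


class TestDerivedParameters:
    def test_reference_derived_values_to_ten_digits(self, reference_size):
        assert reference_size.b == pytest.approx(4_989_883.14035894, rel=1e-10)
        assert reference_size.c == pytest.approx(4.05505505343353e-10, rel=1e-10)
        assert reference_size.le0 == pytest.approx(1009.39930220508, rel=1e-10)
        assert reference_size.lemax == pytest.approx(498_856.770121871, rel=1e-10)

    def test_roundtrip_through_bc_reconstruction(self, reference_size):
        p = reference_size
        back = params_from_bc(p.b, p.c, p.a, p.g0, p.s0)
        assert back.A == pytest.approx(p.A, rel=1e-10)
        assert back.B == pytest.approx(p.B, rel=1e-10)

    def test_degenerate_flat_model_rejected(self):
        with pytest.raises(ValueError):
            derive_params(A=5e6, B=0.0, a=2e-4, g0=149, s0=137_475.0)

    @given(
        A=st.floats(1e4, 1e9),
        B=st.floats(1e-5, 10.0),
        a=st.floats(1e-6, 1e-2),
    )
    @settings(max_examples=60, deadline=None, derandomize=True)
    def test_derive_and_reconstruct_are_mutual_inverses(self, A, B, a):
        p = derive_params(A, B, a, g0=100, s0=1e5)
        assert 0.0 < p.b * p.c < 1.0
        back = params_from_bc(p.b, p.c, a, 100, 1e5)
        assert back.A == pytest.approx(A, rel=1e-9)
        assert back.B == pytest.approx(B, rel=1e-9)


class TestSizeCurve:
    def test_minimal_genome_boundary_condition(self, reference_size):
        assert s_of_g(float(reference_size.g0), reference_size) == pytest.approx(
            137_475.095259792, rel=1e-12
        )

    def test_matches_numerical_integration_of_the_ode(self, reference_size):
        p = reference_size

        def rhs(g, s):
            u = (s[0] - p.s0) + p.b
            return [p.a * u * (1.0 - p.c * u)]

        g_grid = np.linspace(149.0, 60_000.0, 40)
        sol = solve_ivp(
            rhs, (149.0, 60_000.0), [p.s0], t_eval=g_grid,
            rtol=1e-10, atol=1e-4, method="RK45",
        )
        closed = s_of_g(g_grid, p)
        assert np.allclose(sol.y[0], closed, rtol=1e-6)

    def test_strictly_increasing_and_bounded(self, reference_size):
        # up to the range where increments stay resolvable in double
        # precision; far beyond, the curve is numerically flat at s_max
        g = np.linspace(149, 1.5e5, 500)
        s = s_of_g(g, reference_size)
        assert np.all(np.diff(s) > 0)
        assert np.all(s <= reference_size.s_max)
        assert s_of_g(1e7, reference_size) <= reference_size.s_max

    def test_large_gene_number_approaches_saturation(self, reference_size):
        p = reference_size
        limit = p.s0 + p.A / p.B - p.A / (1.0 + p.B)
        assert s_of_g(2e6, p) == pytest.approx(limit, rel=1e-6)
        assert p.s_max == limit

    def test_below_minimal_genome_rejected(self, reference_size):
        with pytest.raises(ValueError):
            s_of_g(100.0, reference_size)

    def test_closed_form_satisfies_the_ode_pointwise(self, reference_size):
        p = reference_size
        g = np.linspace(200, 100_000, 200)
        # h large enough that cancellation noise (s ~ 2.5e9, eps ~ 5e-7)
        # stays far below the 1e-5 relative tolerance
        h = 0.5
        deriv = (s_of_g(g + h, p) - s_of_g(g - h, p)) / (2 * h)
        u = (s_of_g(g, p) - p.s0) + p.b
        rhs = p.a * u * (1.0 - p.c * u)
        assert np.allclose(deriv, rhs, rtol=1e-5)


class TestExtensiveLength:
    def test_at_minimal_size_equals_le0(self, reference_size):
        assert le_of_s(reference_size.s0, reference_size) == pytest.approx(
            reference_size.le0
        )

    def test_published_example_ratio_at_quarter_gigabase(self, reference_size):
        ratio = le_of_s(2.5e8, reference_size, clamp=True) / reference_size.lemax
        assert round(ratio, 1) == 0.1

    def test_clamp_caps_at_lemax(self, reference_size):
        raw = le_of_s(2.5e9, reference_size, clamp=False)
        capped = le_of_s(2.5e9, reference_size, clamp=True)
        assert raw > reference_size.lemax
        assert capped == reference_size.lemax

    def test_below_minimal_size_rejected(self, reference_size):
        with pytest.raises(ValueError):
            le_of_s(reference_size.s0 - 1.0, reference_size)


class TestExtensiveFractionOfNewGenes:
    def test_zero_when_length_saturates(self, reference_size):
        p = reference_size
        s_sat = p.s0 + (p.lemax - p.le0) / p.a
        assert dge_fraction(s_sat * 2, p) == 0.0

    def test_at_minimal_size(self, reference_size):
        p = reference_size
        assert dge_fraction(p.s0, p) == pytest.approx(1.0 - p.le0 / p.lemax)

    def test_published_example_at_quarter_gigabase(self, reference_size):
        assert round(dge_fraction(2.5e8, reference_size), 1) == 0.9

    def test_non_increasing_in_size(self, reference_size):
        s = np.geomspace(reference_size.s0, 1e10, 300)
        frac = dge_fraction(s, reference_size)
        assert np.all(np.diff(frac) <= 1e-15)
        assert np.all((0.0 <= frac) & (frac <= 1.0))


class TestSizeModelFitting:
    def test_noise_free_recovery_within_one_percent(self, reference_size):
        g = np.unique(np.rint(np.geomspace(149, 60_000, 200)).astype(int))
        s = s_of_g(g.astype(float), reference_size)
        records = [
            GenomeRecord.build(f"A{i}", "O", int(gv), 0, 0, int(round(sv)))
            for i, (gv, sv) in enumerate(zip(g, s))
        ]
        fit = fit_size_model(records, seed=1)
        assert fit.params.A == pytest.approx(reference_size.A, rel=0.01)
        assert fit.params.B == pytest.approx(reference_size.B, rel=0.01)
        assert fit.params.a == pytest.approx(reference_size.a, rel=0.01)

    def test_boundary_defaults_to_minimal_record(self, reference_size, small_records):
        fit = fit_size_model(small_records, seed=0)
        assert fit.params.g0 == 149
        assert fit.params.s0 == 140_000

    def test_residual_comparable_to_injected_noise(self, reference_size):
        rng = np.random.default_rng(5)
        g = np.rint(np.geomspace(149, 60_000, 400)).astype(int)
        sigma = 0.05
        s = s_of_g(g.astype(float), reference_size) * 10 ** rng.normal(0, sigma, g.size)
        records = [
            GenomeRecord.build(f"A{i}", "O", int(gv), 0, 0, max(int(round(sv)), 1))
            for i, (gv, sv) in enumerate(zip(g, s))
        ]
        fit = fit_size_model(records, seed=2, loss_scale="log")
        pred = s_of_g(
            np.array([r.total_genes for r in records], dtype=float), fit.params
        )
        log_resid = np.log10([r.size_bp for r in records]) - np.log10(pred)
        assert np.std(log_resid) < 2.0 * sigma

    def test_too_few_distinct_pairs_rejected(self):
        records = [GenomeRecord.build("A", "O", 200, 0, 0, 1_000_000)] * 10
        with pytest.raises(ValueError):
            fit_size_model(records, seed=0)


class TestDensityTransform:
    def test_scaling_leaves_argmax_location_unchanged(
        self, reference_density, reference_mixture
    ):
        log_s1, dens1, _ = transform_density(
            reference_density, reference_mixture, p1=1000.0, p2=1.0
        )
        log_s2, dens2, _ = transform_density(
            reference_density, reference_mixture, p1=1000.0, p2=15.953324
        )
        assert np.argmax(dens1) == np.argmax(dens2)
        assert np.array_equal(log_s1, log_s2)

    def test_max_matching_calibration_recovers_scale(self, reference_mixture):
        # genomes whose sizes follow s = p1*g exactly: the transformed
        # gene-number density must reach the observed log-size peak
        rng = np.random.default_rng(9)
        p1 = 1000.0
        genes = rng.integers(149, 20_000, size=20_000)
        records = [
            GenomeRecord.build(f"A{i}", "O", int(g), 0, 0, int(g * p1))
            for i, g in enumerate(genes)
        ]
        fg = bin_gene_numbers(records, interval=500, max_genes=100_000)
        fs = bin_log_sizes(records, interval=0.1)
        _, dens, tp = transform_density(fg, mixture=None, p1=p1, observed_fs=fs)
        expected_p2 = float(np.max(fs.density)) / float(np.max(fg.density))
        assert tp.p2 == pytest.approx(expected_p2, rel=1e-12)
        assert np.max(dens) == pytest.approx(np.max(fs.density), rel=0.05)
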