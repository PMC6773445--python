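"""Kinetics estimators: shell geometry, windowed derivatives, flux,
product-rule decompositions, asymmetry and the catch-up regression."""
import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

from otomorph import morphodynamics as md
from otomorph import synthetic
from otomorph.synthetic import GeneratorSpec


class TestShellGeometry:
    def test_published_volumes_give_expected_radii(self):
        # cube-root arithmetic: (3*440e3/4pi)^(1/3), (3*807e3/4pi)^(1/3)
        geo = md.shell_from_volumes(440.0, 807.0)
        assert geo.Rl == pytest.approx(47.183, abs=0.01)
        assert geo.Ro == pytest.approx(57.756, abs=0.01)
        assert geo.R == pytest.approx(0.5 * (geo.Rl + geo.Ro))
        assert geo.h == pytest.approx(geo.Ro - geo.Rl)

    def test_empty_lumen(self):
        geo = md.shell_from_volumes(0.0, 100.0)
        assert geo.Rl == 0.0
        assert geo.h == geo.Ro

    @given(vl=st.floats(1.0, 500.0), vo_extra=st.floats(1.0, 500.0))
    @settings(max_examples=50, derandomize=True)
    def test_cube_root_scaling(self, vl, vo_extra):
        base = md.shell_from_volumes(vl, vl + vo_extra)
        scaled = md.shell_from_volumes(8 * vl, 8 * (vl + vo_extra))
        assert scaled.Rl == pytest.approx(2 * base.Rl, rel=1e-9)
        assert scaled.Ro == pytest.approx(2 * base.Ro, rel=1e-9)

    def test_invalid_volumes_rejected(self):
        with pytest.raises(ValueError):
            md.shell_from_volumes(100.0, 50.0)


class TestQuadraticWindowFit:
    def test_exact_on_quadratic(self):
        t = np.arange(0.0, 10.0)
        y = 2 * t ** 2 + 3 * t + 1
        for te in (0.0, 3.5, 9.0):
            val, slope = md.quadratic_window_fit(t, y, te, half_window=3.0)
            assert slope == pytest.approx(4 * te + 3, rel=1e-9)
            assert val == pytest.approx(2 * te ** 2 + 3 * te + 1, rel=1e-9)

    def test_constant_series_zero_slope(self):
        t = np.arange(0.0, 8.0)
        _, slope = md.quadratic_window_fit(t, np.full(8, 5.0), 4.0)
        assert slope == pytest.approx(0.0, abs=1e-12)

    def test_noisy_linear_slope_recovery(self):
        # Monte-Carlo: SNR 10 linear data, derivative within 10% on average
        t = np.arange(0.0, 30.0)
        errs = []
        for seed in range(100):
            rng = np.random.default_rng(seed)
            y = 5.0 * t + 0.5 * rng.standard_normal(t.size) * 5.0
            _, slope = md.quadratic_window_fit(t, y, 15.0, half_window=3.0)
            errs.append(abs(slope / 5.0 - 1.0))
        assert np.mean(errs) < 0.10

    def test_window_shrinks_at_ends_but_requires_three(self):
        t = np.array([0.0, 1.0])
        with pytest.raises(ValueError):
            md.quadratic_window_fit(t, t, 0.0, half_window=0.5)

    def test_half_window_irrelevant_on_noiseless_quadratic(self):
        t = np.arange(0.0, 20.0)
        y = 0.3 * t ** 2 - t + 2
        slopes = [md.quadratic_window_fit(t, y, 10.0, hw)[1]
                  for hw in (2.0, 3.0, 5.0, 8.0)]
        np.testing.assert_allclose(slopes, slopes[0], rtol=1e-9)


class TestFlux:
    def test_constant_volume_zero_flux(self):
        t = np.arange(16.0, 45.0)
        flux = md.compute_flux(t, np.full(t.size, 100.0),
                               np.full(t.size, 1e4))
        np.testing.assert_allclose(flux.Omega, 0.0, atol=1e-10)

    def test_linear_radius_growth_recovers_rate(self):
        # for a sphere growing as R = R0 + c t, flux equals c exactly
        c, r0 = 1.3, 25.0
        t = np.arange(0.0, 25.0)
        R = r0 + c * t
        Vl = 4 * np.pi / 3 * R ** 3 / 1e3
        Sl = 4 * np.pi * R ** 2
        flux = md.compute_flux(t, Vl, Sl)
        interior = (t > 3) & (t < 21)
        np.testing.assert_allclose(flux.Omega[interior], c, rtol=0.01)

    def test_default_cohort_flux_near_one(self, wt_mean):
        flux = md.flux_from_series(wt_mean)
        assert flux.mean_over(21.0, 45.0) == pytest.approx(1.0, rel=0.25)

    def test_nonpositive_surface_rejected(self):
        t = np.arange(0.0, 10.0)
        with pytest.raises(ValueError):
            md.compute_flux(t, t + 1.0, np.zeros(t.size))

    def test_flux_positive_on_growing_lumen(self, noiseless_series):
        flux = md.flux_from_series(noiseless_series)
        assert np.all(flux.Omega[noiseless_series.t >= 17.0] > 0)


class TestTissueGrowthDecomposition:
    def test_early_tissue_growth_offsets(self, wt_mean):
        dec = md.tissue_growth_decomposition(wt_mean.t, wt_mean.N, wt_mean.s)
        early = (wt_mean.t >= 17.0) & (wt_mean.t <= 27.0)
        scale = np.mean(np.abs(dec.division_term[early]))
        assert abs(np.mean(dec.j[early])) < 0.5 * scale
        assert dec.offsetting[early].mean() > 0.5

    def test_constant_cell_size(self):
        t = np.arange(0.0, 20.0)
        N = 400 + 10 * t
        s = np.full(t.size, 0.5)
        dec = md.tissue_growth_decomposition(t, N, s)
        np.testing.assert_allclose(dec.j, 0.5 * 10, rtol=1e-6)

    def test_shrinking_cells_negative_growth(self):
        t = np.arange(0.0, 10.0)
        N = np.full(t.size, 500.0)
        s = 0.5 - 0.025 * t
        dec = md.tissue_growth_decomposition(t, N, s)
        assert np.all(dec.j[1:-1] < 0)
        np.testing.assert_allclose(dec.j, -0.025 * 500, rtol=1e-6)

    def test_closure_on_smooth_noiseless_data(self):
        # product-rule closure: on smooth noise-free curves the two terms
        # sum to the directly fitted derivative of N*s within 1%
        t = np.arange(16.0, 46.0)
        N = 415.0 * np.exp(0.0338 * (t - 16.0))
        s = 0.35 + 0.2 * np.exp(-0.1 * (t - 16.0))
        dec = md.tissue_growth_decomposition(t, N, s)
        _, _, dvt = md.fit_series(t, N * s)
        interior = (t > 19) & (t < 42)
        scale = np.max(np.abs(dvt))
        np.testing.assert_allclose(dec.j[interior], dvt[interior],
                                   atol=0.01 * scale)


class TestSurfaceDecomposition:
    def test_break_even_near_33_hpf(self, wt_mean):
        dec = md.surface_decomposition(wt_mean.t, wt_mean.Sl, wt_mean.N)
        assert dec.break_even_time == pytest.approx(33.0, abs=2.0)

    def test_terms_sum_to_total(self):
        # smooth noise-free curves: stretch + division close the directly
        # fitted dSl/dt within 1%
        t = np.arange(16.0, 46.0)
        N = 415.0 * np.exp(0.0338 * (t - 16.0))
        psi = 26.0 - 18.0 * np.exp(-0.08 * (t - 16.0))
        Sl = psi * N
        dec = md.surface_decomposition(t, Sl, N)
        _, _, dsl = md.fit_series(t, Sl)
        interior = (t > 19) & (t < 42)
        scale = np.max(np.abs(dsl))
        np.testing.assert_allclose(dec.total_rate[interior], dsl[interior],
                                   atol=0.01 * scale)

    def test_constant_cell_number_no_crossing(self):
        t = np.arange(0.0, 20.0)
        N = np.full(t.size, 500.0)
        Sl = 1e4 + 300 * t
        dec = md.surface_decomposition(t, Sl, N)
        assert dec.break_even_time is None
        np.testing.assert_allclose(dec.division_term, 0.0, atol=1e-6)

    def test_constant_apical_area_crosses_at_start(self):
        t = np.arange(0.0, 20.0)
        N = 500 + 20 * t
        Sl = 20.0 * N              # psi constant
        dec = md.surface_decomposition(t, Sl, N)
        assert dec.break_even_time == t[0]


class TestAsymmetry:
    def test_definition_at_puncture(self, puncture_pairs):
        pair = puncture_pairs[0]
        asym = md.asymmetry_metrics(pair)
        i = np.searchsorted(pair.left.t, 30.0)
        expected = (pair.left.Vl[i] - pair.right.Vl[i]) / pair.left.Vl[i]
        assert asym.dVl_rel[i] == pytest.approx(expected)
        assert asym.dh_rel[i] < -0.1     # punctured side thicker

    def test_identical_sides_zero(self, wt_cohort):
        from otomorph.datatypes import PairedExperiment
        pair = PairedExperiment(left=wt_cohort[0], right=wt_cohort[0])
        asym = md.asymmetry_metrics(pair)
        np.testing.assert_allclose(asym.dVl_rel, 0.0, atol=1e-12)

    def test_default_experiment_recovers(self, puncture_pairs):
        for pair in puncture_pairs:
            assert abs(md.asymmetry_metrics(pair).dVl_rel[-1]) < 0.05


class TestFluxDeficitRegression:
    def test_recovers_generator_gain(self, puncture_pairs):
        fit = md.flux_deficit_regression(puncture_pairs)
        assert 3.4 <= fit.kappa_hat <= 4.6
        assert fit.r_squared > 0.5

    def test_default_gain_in_published_range(self, puncture_pairs):
        fit = md.flux_deficit_regression(puncture_pairs)
        assert 3.0 <= fit.kappa_hat <= 5.0

    def test_unpunctured_pairs_flat(self, wt_spec):
        pairs = [synthetic.generate_puncture_experiment(
                    wt_spec, loss_fraction=0.0, kappa=0.0, seed=200 + i)
                 for i in range(10)]
        fit = md.flux_deficit_regression(pairs, t_min=20.0)
        assert abs(fit.kappa_hat) < 3 * fit.kappa_se + 0.5

    def test_degenerate_design_rejected(self, wt_cohort):
        from otomorph.datatypes import PairedExperiment
        pairs = [PairedExperiment(left=wt_cohort[0], right=wt_cohort[0])]
        with pytest.raises(ValueError):
            md.flux_deficit_regression(pairs, t_min=20.0)


def test_flux_equals_radius_rate_for_spherical_lumen(noiseless_series):
    # the conservation identity: dVl/dt / Sl equals dRl/dt for a sphere
    b = noiseless_series
    flux = md.flux_from_series(b)
    Rl = np.array([md.shell_from_volumes(vl, vo).Rl
                   for vl, vo in zip(b.Vl, b.Vo)])
    _, _, drl = md.fit_series(b.t, Rl)
    # the identity is exact where the radius grows smoothly (the early
    # inflation phase has corner-like curvature that windows straddle)
    interior = (b.t > 28) & (b.t < 43)
    np.testing.assert_allclose(flux.Omega[interior], drl[interior], rtol=0.01)
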