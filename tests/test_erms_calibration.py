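import numpy as np
import pytest

from cyclopure import (
    CalibrationStandard,
    DegenerateFitError,
    ErmsSimConfig,
    PredictionError,
    QuadraticModel,
    SYCurve,
    UnivariateModel,
    average_curves,
    build_sy_curve,
    cls_coefficient,
    delta_sy_response,
    effective_linear_fraction,
    fit_quadratic,
    fit_segmented,
    fit_univariate,
    predict_ratio,
    simulate_erms_dataset,
)
from cyclopure.synthetic import MixtureDesign


def curves_from(config, design):
    samples = simulate_erms_dataset(config, design)
    return samples, {s.sample_id: build_sy_curve(s.spectra) for s in samples}


def pure_curves(config):
    grid = np.array(config.voltage_grid)
    lin = SYCurve("lin", grid, config.boltzmann_linear(grid))
    cyc = SYCurve("cyc", grid, config.boltzmann_cyclic(grid))
    return lin, cyc


class TestDeltaSyResponse:
    def test_pure_cyclic_gives_zero(self, noiseless_erms_config):
        _, cyc = pure_curves(noiseless_erms_config)
        assert delta_sy_response(cyc, cyc, 2.2) == 0.0

    def test_convex_combination_identity_without_suppression(self):
        # with r = 1, a mixture at x = 0.3 depresses SY by 0.3 * (SY_cyc - SY_lin)
        cfg = ErmsSimConfig(suppression_r=1.0, noise_sd_rel=0.0)
        lin, cyc = pure_curves(cfg)
        design = MixtureDesign(ratios=(0.3,), replicates=1)
        _, curves = curves_from(cfg, design)
        (mix,) = curves.values()
        expected = 0.3 * (cyc.sy - lin.sy)[np.argmin(np.abs(lin.voltages - 2.2))]
        assert delta_sy_response(mix, cyc, 2.2) == pytest.approx(expected, abs=1e-12)

    def test_monotone_in_ratio(self, noiseless_erms_config):
        _, cyc = pure_curves(noiseless_erms_config)
        design = MixtureDesign(ratios=(0.05, 0.2, 0.5, 0.9), replicates=1)
        _, curves = curves_from(noiseless_erms_config, design)
        responses = [delta_sy_response(c, cyc, 2.2) for c in curves.values()]
        assert all(b > a for a, b in zip(responses, responses[1:]))


class TestClsCoefficient:
    @pytest.mark.parametrize("t", [0.0, 1.0, 0.3, -0.2, 1.2, 0.613])
    def test_affine_equivariance(self, t, noiseless_erms_config):
        # a mixture built as t*l + (1-t)*c returns exactly a = t, never clipped;
        # pure curves with head-room keep the combination inside [0, 1] even
        # for t outside the unit interval
        from cyclopure import BoltzmannParams

        grid = np.array(noiseless_erms_config.voltage_grid)
        lin = SYCurve("lin", grid, BoltzmannParams(0.8, 0.2, 2.05, 0.1)(grid))
        cyc = SYCurve("cyc", grid, BoltzmannParams(0.8, 0.2, 2.55, 0.1)(grid))
        mix = SYCurve("m", lin.voltages, t * lin.sy + (1 - t) * cyc.sy)
        res = cls_coefficient(mix, lin, cyc)
        assert res.a == pytest.approx(t, abs=1e-12)
        if 0.0 <= t <= 1.0:
            assert res.rss == pytest.approx(0.0, abs=1e-20)

    def test_rss_matches_residuals(self, noiseless_erms_config):
        lin, cyc = pure_curves(noiseless_erms_config)
        rng = np.random.default_rng(0)
        mix = SYCurve("m", lin.voltages,
                      np.clip(0.4 * lin.sy + 0.6 * cyc.sy + rng.normal(0, 0.01, lin.sy.size), 0, 1))
        res = cls_coefficient(mix, lin, cyc)
        assert res.rss == pytest.approx(float(res.residuals @ res.residuals), rel=1e-12)

    def test_identical_pure_curves_rejected(self, noiseless_erms_config):
        lin, _ = pure_curves(noiseless_erms_config)
        with pytest.raises(DegenerateFitError):
            cls_coefficient(lin, lin, lin)

    def test_matches_brute_force_scan(self, noiseless_erms_config):
        # 1-D objective scan at 1e-6 resolution as the independent minimiser
        lin, cyc = pure_curves(noiseless_erms_config)
        grid_a = np.arange(-0.2, 1.2 + 1e-9, 1e-6)
        rng = np.random.default_rng(11)
        for true_a in (0.07, 0.35, 0.8):
            sy = np.clip(
                true_a * lin.sy + (1 - true_a) * cyc.sy + rng.normal(0, 0.01, lin.sy.size),
                0, 1,
            )
            mix = SYCurve("m", lin.voltages, sy)
            res = cls_coefficient(mix, lin, cyc)
            q, d = sy - cyc.sy, lin.sy - cyc.sy
            rss = np.zeros_like(grid_a)
            for qj, dj in zip(q, d):
                rss += (qj - grid_a * dj) ** 2
            assert abs(res.a - grid_a[np.argmin(rss)]) < 1e-6


class TestUnivariateFit:
    def test_exact_line(self):
        stds = [CalibrationStandard(x, 1, 2 * x + 0.1) for x in (0.0, 0.1, 0.2, 0.3)]
        m = fit_univariate(stds)
        assert (m.b1, m.b0) == (pytest.approx(2.0), pytest.approx(0.1))
        assert m.se == pytest.approx(0.0, abs=1e-14)
        assert m.r2 == pytest.approx(1.0)

    def test_permutation_invariance(self):
        rng = np.random.default_rng(5)
        stds = [CalibrationStandard(x, 1, 0.5 * x + rng.normal(0, 0.01))
                for x in np.linspace(0, 0.3, 6)]
        m1 = fit_univariate(stds)
        m2 = fit_univariate(stds[::-1])
        for a, b in zip((m1.b0, m1.b1, m1.se, m1.r2), (m2.b0, m2.b1, m2.se, m2.r2)):
            assert a == pytest.approx(b, rel=1e-12, abs=1e-14)

    def test_identical_ratios_rejected(self):
        with pytest.raises(DegenerateFitError):
            fit_univariate([CalibrationStandard(0.1, i, float(i)) for i in range(4)])


class TestSegmentedFit:
    def test_piecewise_exact_recovery(self):
        # two exact lines meeting at 0.3
        def y(x):
            return 0.5 * x if x <= 0.3 else 0.15 + 1.25 * (x - 0.3)

        xs = [0.0, 0.1, 0.2, 0.3, 0.5, 0.7, 1.0]
        seg = fit_segmented([CalibrationStandard(x, 1, y(x)) for x in xs])
        assert seg.low_model.b1 == pytest.approx(0.5, abs=1e-12)
        assert seg.high_model.b1 == pytest.approx(1.25, abs=1e-12)

    def test_suppression_slope_ratio_exceeds_two(self, noiseless_erms_config):
        # noiseless a_eff responses: secant slopes bracket r and 1/r
        xs = np.array([0.0, 0.05, 0.1, 0.15, 0.2, 0.3, 0.4, 0.5, 0.6, 1.0])
        a = effective_linear_fraction(xs, noiseless_erms_config)
        seg = fit_segmented([CalibrationStandard(x, 1, v) for x, v in zip(xs, a)])
        assert seg.high_model.b1 / seg.low_model.b1 > 2.0

    def test_symmetric_data_equal_slopes(self):
        xs = [0.0, 0.2, 0.4, 0.5, 0.6, 0.8, 1.0]
        seg = fit_segmented([CalibrationStandard(x, 1, x) for x in xs], breakpoint=0.5)
        assert seg.low_model.b1 == pytest.approx(seg.high_model.b1, abs=1e-12)

    def test_sparse_side_rejected(self):
        stds = [CalibrationStandard(x, 1, x) for x in (0.0, 0.1, 0.2, 0.3, 0.9)]
        with pytest.raises(DegenerateFitError, match="high"):
            fit_segmented(stds)


class TestQuadraticFit:
    def test_exact_polynomial(self):
        stds = [CalibrationStandard(x, 1, x**2) for x in (0.0, 0.25, 0.5, 0.75, 1.0)]
        q = fit_quadratic(stds)
        assert (q.c0, q.c1, q.c2) == (
            pytest.approx(0.0, abs=1e-12),
            pytest.approx(0.0, abs=1e-12),
            pytest.approx(1.0, abs=1e-12),
        )

    def test_constant_responses_give_zero_curvature(self):
        stds = [CalibrationStandard(x, 1, 0.7) for x in (0.0, 0.3, 0.6, 1.0)]
        q = fit_quadratic(stds)
        assert q.c1 == pytest.approx(0.0, abs=1e-12)
        assert q.c2 == pytest.approx(0.0, abs=1e-12)

    def test_worse_than_low_range_linear_on_suppression_data(self, noiseless_erms_config):
        from cyclopure import rmsec
        from cyclopure.pipeline import _predict_for_standard

        xs = np.array([0.0, 0.05, 0.1, 0.15, 0.2, 0.3, 0.4, 0.5, 0.6, 1.0])
        a = effective_linear_fraction(xs, noiseless_erms_config)
        stds = [CalibrationStandard(x, 1, v) for x, v in zip(xs, a)]
        quad = fit_quadratic(stds)
        low = [s for s in stds if s.ratio <= 0.3]
        lin = fit_univariate(low)
        quad_rmsec = rmsec([_predict_for_standard(quad, s.response, s.ratio) - s.ratio
                            for s in stds])
        lin_rmsec = rmsec([predict_ratio(lin, s.response) - s.ratio for s in low])
        assert quad_rmsec > lin_rmsec


class TestPredictRatio:
    def test_linear_inversion(self):
        m = UnivariateModel(b0=0.0, b1=2.0, se=0.0, r2=1.0, n=4)
        assert predict_ratio(m, 0.4) == pytest.approx(0.2)

    def test_round_trip_identity_on_noiseless_standards(self, noiseless_erms_config):
        # fit on exact piecewise-linear responses and invert at each standard
        cfg = ErmsSimConfig(suppression_mode="piecewise", noise_sd_rel=0.0)
        xs = np.array([0.0, 0.05, 0.1, 0.15, 0.2, 0.3])
        a = effective_linear_fraction(xs, cfg)
        m = fit_univariate([CalibrationStandard(x, 1, v) for x, v in zip(xs, a)])
        for x, v in zip(xs, a):
            assert predict_ratio(m, v) == pytest.approx(x, abs=1e-9)

    def test_segmented_breakpoint_agreement(self):
        def y(x):
            return 0.5 * x if x <= 0.3 else 0.15 + 1.25 * (x - 0.3)

        xs = [0.0, 0.1, 0.2, 0.3, 0.5, 0.7, 1.0]
        seg = fit_segmented([CalibrationStandard(x, 1, y(x)) for x in xs])
        assert predict_ratio(seg, y(0.3)) == pytest.approx(0.3, abs=1e-9)

    def test_segmented_inadmissible_response(self):
        def y(x):
            return 0.5 * x if x <= 0.3 else 0.15 + 1.25 * (x - 0.3)

        xs = [0.0, 0.1, 0.2, 0.3, 0.5, 0.7, 1.0]
        seg = fit_segmented([CalibrationStandard(x, 1, y(x)) for x in xs])
        with pytest.raises(PredictionError):
            predict_ratio(seg, 10.0)

    def test_quadratic_two_roots_is_ambiguous(self):
        q = QuadraticModel(c0=0.16, c1=-1.0, c2=1.0, se=0.0, r2=1.0, n=5)
        with pytest.raises(PredictionError):
            predict_ratio(q, 0.0)  # roots 0.2 and 0.8, both admissible

    def test_near_zero_slope_rejected(self):
        m = UnivariateModel(b0=0.0, b1=1e-15, se=0.0, r2=1.0, n=4)
        with pytest.raises(PredictionError):
            predict_ratio(m, 0.4)


def test_average_curves_pointwise_mean(noiseless_erms_config):
    grid = np.array(noiseless_erms_config.voltage_grid)
    c1 = SYCurve("a", grid, np.full(grid.size, 0.2))
    c2 = SYCurve("a", grid, np.full(grid.size, 0.6))
    avg = average_curves([c1, c2])
    np.testing.assert_array_equal(avg.sy, np.full(grid.size, 0.4))
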