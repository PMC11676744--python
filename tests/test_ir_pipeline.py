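import numpy as np
import pytest
from scipy import sparse
from scipy.sparse.linalg import spsolve

from cyclopure import (
    AslsParams,
    ConfigurationError,
    ExtrapolationError,
    IRSpectrum,
    IrSimConfig,
    asls_baseline,
    band_area,
    fit_pls,
    normalise_mean,
    simulate_ir_dataset,
    tune_asls,
    whittaker_asls,
)
from cyclopure.synthetic import IR_DESIGN, MixtureDesign

GRID = np.linspace(675.0, 4000.0, 800)


def gaussian(grid, centre, sd, amp):
    return amp * np.exp(-0.5 * ((grid - centre) / sd) ** 2)


class TestNormaliseMean:
    def test_constant_spectrum_becomes_unit(self):
        s = normalise_mean(IRSpectrum(GRID, np.full(GRID.size, 3.7)))
        np.testing.assert_allclose(s.absorbance, 1.0)

    def test_idempotent(self):
        rng = np.random.default_rng(0)
        s = IRSpectrum(GRID, 1.0 + 0.1 * rng.normal(size=GRID.size))
        once = normalise_mean(s)
        twice = normalise_mean(once)
        np.testing.assert_allclose(twice.absorbance, once.absorbance, atol=1e-15)

    def test_output_mean_is_one(self):
        rng = np.random.default_rng(1)
        grid = np.linspace(675, 4000, 1725)
        s = normalise_mean(IRSpectrum(grid, 0.5 + rng.random(grid.size)))
        assert s.absorbance.mean() == pytest.approx(1.0, abs=1e-12)

    def test_zero_mean_rejected(self):
        with pytest.raises(ConfigurationError):
            normalise_mean(IRSpectrum(GRID, np.zeros(GRID.size)))


class TestAslsBaseline:
    def test_line_input_fully_removed(self):
        # a smooth peak-free signal is all baseline
        y = 0.5 + 0.3 * (GRID - GRID[0]) / (GRID[-1] - GRID[0])
        _, corrected = asls_baseline(IRSpectrum(GRID, y))
        assert np.max(np.abs(corrected.absorbance)) < 1e-3 * np.ptp(y)

    def test_final_iterate_matches_frozen_weight_solve(self):
        rng = np.random.default_rng(2)
        y = gaussian(GRID, 2105, 18, 0.3) + 0.02 * np.sin(GRID / 400) + rng.normal(0, 1e-3, GRID.size)
        z, w = whittaker_asls(y, 1e4, 0.001)
        n = y.size
        d2 = sparse.diags([1.0, -2.0, 1.0], [0, 1, 2], shape=(n - 2, n), format="csc")
        direct = spsolve((sparse.diags(w) + 1e4 * (d2.T @ d2)).tocsc(), w * y)
        assert np.max(np.abs(z - direct)) < 1e-8

    def test_default_params_recover_peak_area(self):
        # peak + cubic baseline: corrected band area within 5% of the peak-only area
        grid = np.linspace(675, 4000, 1725)
        peak = gaussian(grid, 2105, 18, 0.25)
        u = np.linspace(-1, 1, grid.size)
        baseline = 0.05 * (0.3 - 0.5 * u + 0.8 * u**2 + 0.4 * u**3)
        _, corrected = asls_baseline(IRSpectrum(grid, peak + baseline), AslsParams())
        truth = band_area(IRSpectrum(grid, peak))
        assert band_area(corrected) == pytest.approx(truth, rel=0.05)

    def test_shift_invariance(self):
        # baseline(y + c) = baseline(y) + c up to solver roundoff (which
        # scales with the shift magnitude)
        y = gaussian(GRID, 2105, 18, 0.3) + 0.01 * np.sin(GRID / 300)
        z1, w1 = whittaker_asls(y, 1e4, 0.001)
        for c in (1.0, 5.0):
            z2, w2 = whittaker_asls(y + c, 1e4, 0.001)
            assert np.max(np.abs(z2 - (z1 + c))) < 1e-8 * max(1.0, c)
            np.testing.assert_array_equal(w1, w2)

    def test_non_finite_input_rejected(self):
        y = np.ones(GRID.size)
        y[10] = np.nan
        with pytest.raises(ConfigurationError):
            whittaker_asls(y, 1e4, 0.001)


@pytest.fixture(scope="module")
def normalised_dataset():
    ds = simulate_ir_dataset(
        IrSimConfig(wavenumber_grid=tuple(np.linspace(675, 4000, 600)),
                    raw_spectra_per_replicate=10, seed=7),
        IR_DESIGN,
    )
    return [normalise_mean(s) for s in ds.spectra()], ds.ratios


class TestTuneAsls:
    def test_single_candidate_returned_unchanged(self, normalised_dataset):
        spectra, y = normalised_dataset
        best, table = tune_asls(spectra, [0.001], [1e4], y, max_lv=5)
        assert (best.p, best.lam) == (0.001, 1e4)
        assert len(table) == 1

    def test_gentle_candidate_beats_overcorrecting_one(self, normalised_dataset):
        spectra, y = normalised_dataset
        best, table = tune_asls(
            spectra, None, None, y, max_lv=5, pairs=[(0.001, 1e4), (0.1, 1e6)]
        )
        assert (best.p, best.lam) == (0.001, 1e4)
        # and the winner respects the no-negative-parts screen
        winner = table[(table.p == best.p) & (table.lam == best.lam)].iloc[0]
        assert winner["neg_fraction"] < 0.02

    def test_candidate_order_invariance(self, normalised_dataset):
        spectra, y = normalised_dataset
        b1, _ = tune_asls(spectra, [0.001, 0.01], [1e4, 1e5], y, max_lv=5)
        b2, _ = tune_asls(spectra, [0.01, 0.001], [1e5, 1e4], y, max_lv=5)
        assert (b1.p, b1.lam) == (b2.p, b2.lam)

    def test_all_flagged_raises(self, normalised_dataset):
        spectra, y = normalised_dataset
        with pytest.raises(ConfigurationError, match="negative"):
            tune_asls(spectra, None, None, y, max_lv=5, pairs=[(0.1, 1e6)])


class TestBandArea:
    def test_zero_spectrum(self):
        assert band_area(IRSpectrum(GRID, np.zeros(GRID.size))) == 0.0

    def test_unit_box_over_exact_window(self):
        grid = np.arange(2000.0, 2201.0)  # contains 2040 and 2170 exactly
        y = ((grid >= 2040) & (grid <= 2170)).astype(float)
        assert band_area(IRSpectrum(grid, y)) == pytest.approx(130.0, abs=1e-9)

    def test_gaussian_band_quadrature(self):
        grid = np.linspace(675, 4000, 1725)
        for amp in (0.1, 0.5):
            s = IRSpectrum(grid, gaussian(grid, 2105, 15, amp))
            assert band_area(s) == pytest.approx(amp * 15 * np.sqrt(2 * np.pi), rel=0.01)

    def test_window_outside_grid_rejected(self):
        s = IRSpectrum(np.linspace(2100, 2200, 50), np.ones(50))
        with pytest.raises(ExtrapolationError):
            band_area(s)

    def test_band_maximum_alternative_response(self):
        from cyclopure import band_maximum

        grid = np.linspace(675, 4000, 1725)
        s = IRSpectrum(grid, gaussian(grid, 2105, 15, 0.4))
        assert band_maximum(s) == pytest.approx(0.4, rel=5e-3)  # grid discretisation
        # proportional to the band amplitude, like the area
        s2 = IRSpectrum(grid, gaussian(grid, 2105, 15, 0.8))
        assert band_maximum(s2) == pytest.approx(2 * band_maximum(s), rel=1e-6)


class TestFitPls:
    def test_rank_one_truth_needs_one_lv(self):
        rng = np.random.default_rng(3)
        t = rng.normal(size=12)
        loadings = rng.normal(size=8)
        X = np.outer(t, loadings)
        y = 3.0 * t
        with pytest.warns(UserWarning, match="rank"):
            m = fit_pls(X, y, max_lv=4, n_splits=12)
        assert m.n_lv == 1
        assert m.rmsec < 1e-8

    def test_full_rank_matches_ols(self):
        rng = np.random.default_rng(4)
        X = rng.normal(size=(12, 8))
        y = rng.normal(size=12)
        m = fit_pls(X, y, max_lv=8, n_splits=12)
        Xc = X - X.mean(axis=0)
        beta = np.linalg.lstsq(Xc, y - y.mean(), rcond=None)[0]
        ols_pred = Xc @ beta + y.mean()
        # at full rank the PLS calibration predictions coincide with OLS
        assert m.rmsec_by_lv[-1] == pytest.approx(
            float(np.sqrt(((ols_pred - y) ** 2).mean())), abs=1e-6
        )
        from sklearn.cross_decomposition import PLSRegression

        full_model = PLSRegression(n_components=8, scale=False).fit(X, y)
        np.testing.assert_allclose(full_model.predict(X).ravel(), ols_pred, atol=1e-6)

    def test_contiguous_block_scheme(self, default_ir_dataset):
        ds = default_ir_dataset
        m = fit_pls(ds.absorbance, ds.ratios, max_lv=8, n_splits=11)
        assert m.rmsecv > 0
        with pytest.raises(ConfigurationError):
            fit_pls(ds.absorbance, ds.ratios, max_lv=8, n_splits=5)

    def test_rmsec_non_increasing_in_lv(self, default_ir_dataset):
        ds = default_ir_dataset
        m = fit_pls(ds.absorbance, ds.ratios, max_lv=8, n_splits=11)
        assert np.all(np.diff(m.rmsec_by_lv) <= 1e-12)

    def test_max_lv_capped_at_rank(self):
        rng = np.random.default_rng(5)
        t = rng.normal(size=(9, 2))
        X = t @ rng.normal(size=(2, 6))  # rank 2
        y = t[:, 0]
        with pytest.warns(UserWarning, match="rank"):
            m = fit_pls(X, y, max_lv=6, n_splits=9)
        assert m.n_lv <= 2


class TestNoisePropagation:
    def test_holdout_rmse_within_twice_noise_equivalent(self):
        # baseline-free data so the injected error propagates analytically
        from cyclopure import CalibrationStandard, fit_univariate, predict_ratio, rmsec

        cfg = IrSimConfig(seed=11, baseline_scale=0.0)
        ds = simulate_ir_dataset(cfg, IR_DESIGN)
        grid = ds.wavenumbers
        amp, width = cfg.linear_band[0][2], cfg.linear_band[0][1]
        sensitivity = amp * width * np.sqrt(2 * np.pi)
        window = (grid >= 2040) & (grid <= 2170)
        dx = float(np.diff(grid).mean())
        sigma_area = cfg.noise_sd / np.sqrt(cfg.raw_spectra_per_replicate) * dx * np.sqrt(window.sum())
        sigma_x = sigma_area / sensitivity

        areas = np.array([band_area(s) for s in ds.spectra()])
        y = ds.ratios
        errs = []
        for b in range(11):
            mask = np.ones(y.size, bool)
            mask[3 * b : 3 * b + 3] = False
            m = fit_univariate(
                [CalibrationStandard(r, i, a) for i, (r, a) in enumerate(zip(y[mask], areas[mask]))]
            )
            errs.extend(predict_ratio(m, a) - r for a, r in zip(areas[~mask], y[~mask]))
        assert rmsec(errs) <= 2 * sigma_x

        pls = fit_pls(ds.absorbance, y, max_lv=10, n_splits=11)
        assert pls.rmsecv <= 2 * sigma_x
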