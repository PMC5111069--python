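"""MSD extraction, force-constant conversion and kink detection."""

import numpy as np
import pytest
from scipy.optimize import least_squares

import ribodyn as rd
from ribodyn.constants import FORCE_CONSTANT_PREFACTOR
from ribodyn.elastic import FitError, detect_kink, weighted_line_fit

from conftest import tiny_model


def _series(temps, msd, sigma=None):
    temps = np.asarray(temps, float)
    msd = np.asarray(msd, float)
    sigma = np.full_like(msd, 0.01) if sigma is None else np.asarray(sigma)
    return rd.MSDSeries(
        temperatures=temps, msd=msd, msd_sigma=sigma,
        intercept=np.zeros_like(msd), chi2=np.zeros_like(msd),
        gaussian_ok=np.ones_like(msd, dtype=bool),
        q_window=(0.34, 0.85), convention=6.0,
    )


class TestMSDExtraction:
    def test_noiseless_recovery_is_exact(self, in16):
        m = tiny_model(msd_ref=10.0, slope_above=0.0, slope_below=0.0)
        scan = rd.simulate_elastic_scan(m, in16, [260.0, 280.0, 300.0])
        series = rd.fit_msd(scan, (0.34, 0.85))
        np.testing.assert_allclose(series.msd, 10.0, rtol=1e-10)

    def test_flat_scan_recovers_zero(self, in16):
        m = tiny_model(msd_ref=0.0, slope_above=0.0, slope_below=0.0)
        scan = rd.simulate_elastic_scan(m, in16, [280.0])
        series = rd.fit_msd(scan, (0.34, 0.85))
        assert abs(series.msd[0]) < 1e-10

    def test_noisy_fixture_consistent_with_published_msd(self, catalog, in16):
        """H30S NaCl at 310.15 K recovers 17.9 +/- 0.9 A^2 within combined
        uncertainties after the full reduction chain."""
        sample, empty, van = rd.simulate_elastic_experiment(
            catalog["h30s_nacl"], in16, [310.15],
            rd.NoiseSpec("poisson", 1e5, 42))
        series = rd.fit_msd(rd.reduce_chain(sample, empty, van), (0.34, 0.85))
        tol = np.hypot(series.msd_sigma[0], 0.9)
        assert abs(series.msd[0] - 17.9) < tol

    def test_too_few_q_points_is_an_error(self, in16):
        m = tiny_model()
        scan = rd.simulate_elastic_scan(m, in16, [280.0])
        with pytest.raises(FitError):
            rd.fit_msd(scan, (0.34, 0.40))

    def test_gaussian_validity_flag(self, in16):
        # large MSD: <u^2> q_hi^2 > 4 within a window reaching high Q
        m = tiny_model(msd_ref=20.0, slope_above=0.0, slope_below=0.0)
        scan = rd.simulate_elastic_scan(m, in16, [280.0])
        series = rd.fit_msd(scan, (0.19, 1.89))
        assert not series.gaussian_ok[0]


class TestForceConstant:
    def test_hand_checked_slope_to_force_constant(self):
        # 0.002761 / 0.1726 = 0.016 N/m to printed precision
        temps = np.arange(275.0, 311.0, 5.0)
        series = _series(temps, 5.0 + 0.1726 * (temps - 275.0))
        fc = rd.fit_force_constant(series, 270.0)
        assert fc.k_eff == pytest.approx(0.016, rel=1e-3)

    def test_unit_force_constant_definition(self):
        temps = np.arange(275.0, 311.0, 5.0)
        series = _series(temps, 1.0 + 0.002761 * (temps - 275.0))
        fc = rd.fit_force_constant(series, 270.0)
        assert fc.k_eff == pytest.approx(1.0, rel=1e-3)

    def test_reference_msd_on_fitted_line(self):
        temps = np.arange(275.0, 311.0, 5.0)
        series = _series(temps, 2.0 + 0.05 * temps)
        fc = rd.fit_force_constant(series, 270.0)
        assert fc.msd_at_ref == pytest.approx(2.0 + 0.05 * 310.15, rel=1e-10)

    def test_nonpositive_slope_flagged_nonphysical(self):
        temps = np.arange(275.0, 311.0, 5.0)
        series = _series(temps, 20.0 - 0.05 * temps)
        fc = rd.fit_force_constant(series, 270.0)
        assert not fc.physical and np.isnan(fc.k_eff)

    def test_too_few_points_is_an_error(self):
        series = _series([280.0, 290.0, 300.0], [10.0, 11.0, 12.0])
        with pytest.raises(FitError):
            rd.fit_force_constant(series, 295.0)


class TestEndToEndRecovery:
    def test_noiseless_pipeline_recovers_all_fixtures(self, catalog, in16,
                                                      scan_temperatures):
        """Noiseless simulate -> reduce -> fit returns the configured slope
        and reference MSD to better than 1e-8 relative for every fixture."""
        for m in catalog.values():
            sample, empty, van = rd.simulate_elastic_experiment(
                m, in16, scan_temperatures, None)
            series = rd.fit_msd(rd.reduce_chain(sample, empty, van),
                                (0.34, 0.85))
            fc = rd.fit_force_constant(series, 270.0)
            assert fc.slope == pytest.approx(m.slope_above, rel=1e-8)
            assert fc.msd_at_ref == pytest.approx(m.msd_ref, rel=1e-8)

    def test_force_constant_coverage_under_poisson_noise(self, catalog, in16,
                                                         scan_temperatures):
        """Across 100 noise seeds the recovered <k> lies within 2 sigma of
        the configured truth in at least 90% of runs."""
        m = catalog["h30s_nacl"]
        truth = FORCE_CONSTANT_PREFACTOR / m.slope_above
        hits = 0
        for seed in range(100):
            sample, empty, van = rd.simulate_elastic_experiment(
                m, in16, scan_temperatures,
                rd.NoiseSpec("poisson", 1e5, 1000 + seed))
            series = rd.fit_msd(rd.reduce_chain(sample, empty, van),
                                (0.34, 0.85))
            fc = rd.fit_force_constant(series, 270.0)
            if abs(fc.k_eff - truth) < 2.0 * fc.k_sigma:
                hits += 1
        assert hits >= 90

    def test_softer_slope_means_stiffer_force_constant(self, in16,
                                                       scan_temperatures):
        """Recovered <k> strictly decreases as the configured MSD slope
        increases."""
        ks = []
        for slope in (0.05, 0.1, 0.2):
            m = tiny_model(msd_ref=14.0, slope_above=slope,
                           slope_below=slope / 4.0)
            scan = rd.simulate_elastic_scan(m, in16, scan_temperatures)
            fc = rd.fit_force_constant(rd.fit_msd(scan, (0.34, 0.85)), 270.0)
            ks.append(fc.k_eff)
        assert ks[0] > ks[1] > ks[2]

    def test_gaussian_convention_invariance(self, catalog, in16,
                                            scan_temperatures):
        """Changing the shared Gaussian divisor (6 -> 3) in generator and
        fitter together leaves the recovered force constant unchanged."""
        m = catalog["h50s_nacl"]
        ks = []
        for divisor in (6.0, 3.0):
            scan = rd.simulate_elastic_scan(m, in16, scan_temperatures,
                                            gaussian_divisor=divisor)
            series = rd.fit_msd(scan, (0.34, 0.85), gaussian_divisor=divisor)
            ks.append(rd.fit_force_constant(series, 270.0).k_eff)
        assert ks[0] == pytest.approx(ks[1], rel=1e-10)


def _oracle_kink(series):
    """Exhaustive breakpoint search using an independent nonlinear solver."""
    t = np.asarray(series.temperatures)
    y = np.asarray(series.msd)
    w = 1.0 / np.asarray(series.msd_sigma)
    best, best_sse = None, np.inf
    for tc in t[1:-1]:
        if np.sum(t <= tc) < 3 or np.sum(t > tc) < 3:
            continue

        def resid(p):
            yhat = np.where(t <= tc, p[0] + p[1] * (t - tc),
                            p[0] + p[2] * (t - tc))
            return (yhat - y) * w

        sol = least_squares(resid, x0=[y.mean(), 0.0, 0.0])
        sse = float(sol.fun @ sol.fun)
        if sse < best_sse * (1 - 1e-12):
            best, best_sse = float(tc), sse
    return best


class TestKinkDetection:
    def test_dense_noiseless_scan_recovers_kink_exactly(self, catalog, in16):
        m = catalog["h30s_nacl"]
        temps = np.arange(250.0, 311.0, 1.0)  # includes 273 K
        scan = rd.simulate_elastic_scan(m, in16, temps)
        series = rd.fit_msd(scan, (0.34, 0.85))
        assert detect_kink(series) == 273.0

    def test_agrees_with_exhaustive_oracle(self, catalog, in16):
        m = catalog["h50s_nacl"]
        temps = np.arange(252.0, 311.0, 4.0)
        sample, empty, van = rd.simulate_elastic_experiment(
            m, in16, temps, rd.NoiseSpec("poisson", 1e5, 9))
        series = rd.fit_msd(rd.reduce_chain(sample, empty, van), (0.34, 0.85))
        assert detect_kink(series) == _oracle_kink(series)

    def test_straight_line_ties_break_to_lowest_candidate(self):
        temps = np.arange(250.0, 311.0, 5.0)
        series = _series(temps, 1.0 + 0.1 * temps)
        t = detect_kink(series)
        # first interior candidate with 3 points on each side
        assert t == temps[2]

    def test_noisy_fixture_kink_within_5K(self, catalog, in16,
                                          scan_temperatures):
        sample, empty, van = rd.simulate_elastic_experiment(
            catalog["h30s_nacl"], in16, scan_temperatures,
            rd.NoiseSpec("poisson", 1e5, 42))
        series = rd.fit_msd(rd.reduce_chain(sample, empty, van), (0.34, 0.85))
        assert abs(detect_kink(series) - 273.0) <= 5.0

    def test_too_few_temperatures_is_an_error(self):
        series = _series([250.0, 260.0, 270.0, 280.0, 290.0],
                         [10.0, 10.5, 11.0, 11.5, 12.0])
        with pytest.raises(FitError):
            detect_kink(series)


def test_weighted_line_fit_matches_polyfit():
    rng = np.random.default_rng(0)
    x = np.linspace(0.0, 1.0, 20)
    y = 2.0 + 3.0 * x + rng.normal(0, 0.1, 20)
    a, b, cov, _ = weighted_line_fit(x, y)
    coef = np.polyfit(x, y, 1)
    assert b == pytest.approx(coef[0], rel=1e-10)
    assert a == pytest.approx(coef[1], rel=1e-10)
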