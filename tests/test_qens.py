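"""QENS decomposition: per-Q fits, dispersion, immobile fraction, binning."""

import numpy as np
import pytest

import ribodyn as rd
from ribodyn.constants import HBAR_UEV_PS
from ribodyn.elastic import FitError
from ribodyn.qens import fit_dispersion, immobile_fraction

from conftest import tiny_model


class TestPerQFits:
    def test_pure_elastic_spectrum(self, in5):
        """A fully immobile sample fits with vanishing Lorentzian weights."""
        m = tiny_model(immobile_fraction=1.0, p_hyd=0.0, p_free=0.0)
        spec = rd.simulate_qens(m, in5, 298.0)
        rec = rd.fit_spectrum_q(spec, 1.2, in5.resolution_fwhm)
        assert rec.a0 == pytest.approx(1.0, rel=1e-4)
        assert rec.a1 + rec.a2 < 1e-4

    def test_noiseless_two_population_widths(self, noiseless_qens_fits):
        """At Q = 0.8 both configured Lorentzian widths are recovered to
        better than 1e-4 relative."""
        model, spec, _ = noiseless_qens_fits["h30s_nacl"]
        rec = rd.fit_spectrum_q(spec, 0.8, 75.0)
        q = rec.q
        g_hyd = rd.gamma_jump_diffusion(q, model.d_hyd, model.tau_hyd)
        g_free = rd.gamma_jump_diffusion(q, model.d_free, model.tau_free)
        assert rec.gamma1 == pytest.approx(g_hyd, rel=1e-4)
        assert rec.gamma2 == pytest.approx(g_free, rel=1e-4)

    def test_component_weights_account_for_total_area(self,
                                                      noiseless_qens_fits):
        """a0 + a1 + a2 plus the flat-background area reproduce the omega
        integral of the spectrum (up to finite-window Lorentzian tails)."""
        _, spec, fit = noiseless_qens_fits["h30s_nacl"]
        i = 4  # a mid-grid Q, widths well inside the window
        area = np.trapezoid(spec.intensity[i], spec.omega_grid)
        window = spec.omega_grid[-1] - spec.omega_grid[0]
        total = fit.a0[i] + fit.a1[i] + fit.a2[i] + fit.background[i] * window
        assert total == pytest.approx(area, rel=0.05)


class TestDispersion:
    def test_recovery_within_two_sigma(self):
        rng = np.random.default_rng(12)
        d, tau = 0.23, 1.1
        q = np.linspace(0.4, 1.9, 10)
        g_true = rd.gamma_jump_diffusion(q, d, tau)
        sigma = 0.01 * g_true
        g = g_true + rng.normal(0.0, sigma)
        d_fit, d_sig, tau_fit, tau_sig, _ = fit_dispersion(q, g, sigma)
        assert abs(d_fit - d) < 2.0 * d_sig
        assert abs(tau_fit - tau) < 2.0 * tau_sig

    def test_fickian_limit_reports_zero_tau(self):
        q = np.linspace(0.3, 1.5, 8)
        g = HBAR_UEV_PS * 0.1 * q**2
        d_fit, _, tau_fit, _, flags = fit_dispersion(q, g)
        assert "fickian" in flags
        assert tau_fit == 0.0
        assert d_fit == pytest.approx(0.1, rel=1e-6)

    def test_plateau_asymptote(self):
        """At high Q the jump-diffusion width saturates at hbar/tau."""
        d, tau = 0.4, 2.0
        gammas = rd.gamma_jump_diffusion(np.array([5.0, 20.0, 100.0]), d, tau)
        assert np.all(np.diff(gammas) > 0)
        assert gammas[-1] == pytest.approx(HBAR_UEV_PS / tau, rel=1e-3)

    def test_too_few_points_is_an_error(self):
        with pytest.raises(FitError):
            fit_dispersion([0.3, 0.6, 0.9], [1.0, 2.0, 3.0])


class TestImmobileFraction:
    def test_fully_immobile_noiseless_is_exact(self, in5):
        m = tiny_model(immobile_fraction=1.0, p_hyd=0.0, p_free=0.0)
        spec = rd.simulate_qens(m, in5, 298.0)
        fit = rd.fit_qens(spec, in5.resolution_fwhm)
        assert fit.immobile_fraction == pytest.approx(1.0, abs=1e-4)

    def test_zero_immobile_fraction(self, in5):
        m = tiny_model(immobile_fraction=0.0, p_hyd=1.0 / 3.0,
                       p_free=2.0 / 3.0)
        spec = rd.simulate_qens(m, in5, 298.0)
        fit = rd.fit_qens(spec, in5.resolution_fwhm)
        assert fit.immobile_fraction == pytest.approx(0.0, abs=1e-4)
        # with counting noise the truth sits on the a0 >= 0 boundary, so the
        # constrained estimator is truncated upward by about one per-Q sigma;
        # the estimate must still be small and statistically consistent
        noisy = rd.simulate_qens(m, in5, 298.0,
                                 rd.NoiseSpec("poisson", 1e5, 21))
        fit_n = rd.fit_qens(noisy, in5.resolution_fwhm)
        assert fit_n.immobile_fraction < max(3.0 * fit_n.immobile_sigma, 0.01)
        assert fit_n.immobile_fraction < 0.06

    def test_estimator_unbiased_over_seeds(self, catalog):
        """Mean recovered immobile fraction over 100 noise seeds lies within
        two standard errors of the configured truth, under study-like
        conditions (full Q coverage, 10^5 peak counts)."""
        inst = rd.InstrumentConfig(
            name="in5_like", wavelength=5.1, resolution_fwhm=75.0,
            q_min=0.21, q_max=1.98, n_q=12,
            energy_window=1000.0, n_energy=301,
        )
        m = catalog["h30s_nacl"]
        estimates = []
        for seed in range(100):
            spec = rd.simulate_qens(m, inst, 298.0,
                                    rd.NoiseSpec("poisson", 1e5, 5000 + seed))
            fit = rd.fit_qens(spec, inst.resolution_fwhm)
            estimates.append(fit.immobile_fraction)
        mean = np.mean(estimates)
        se = np.std(estimates, ddof=1) / np.sqrt(len(estimates))
        assert abs(mean - m.immobile_fraction) < 2.0 * se

    def test_requires_three_valid_fits(self):
        with pytest.raises(FitError):
            immobile_fraction([])


class TestBinnedSpectra:
    def test_unit_area(self, noiseless_qens_fits):
        _, spec, _ = noiseless_qens_fits["h30s_nacl"]
        omega, y, _ = rd.binned_normalized_spectrum(spec, 0.2, 2.0)
        assert np.trapezoid(y, omega) == pytest.approx(1.0, abs=1e-12)

    def test_single_q_window_is_normalized_row(self, noiseless_qens_fits):
        _, spec, _ = noiseless_qens_fits["h30s_nacl"]
        q0 = spec.q_grid[3]
        omega, y, _ = rd.binned_normalized_spectrum(spec, q0 - 1e-6, q0 + 1e-6)
        row = spec.intensity[3]
        np.testing.assert_allclose(
            y, row / np.trapezoid(row, spec.omega_grid), rtol=1e-12)

    @staticmethod
    def _fwhm(omega, y):
        half = y.max() / 2.0
        above = omega[y >= half]
        return above[-1] - above[0]

    def test_faster_dynamics_broadens_binned_curve(self, noiseless_qens_fits):
        """The small subunit (fewer immobile H, same water dynamics) shows a
        broader unit-area summed spectrum than the large subunit."""
        _, spec30, _ = noiseless_qens_fits["h30s_nacl"]
        _, spec50, _ = noiseless_qens_fits["h50s_nacl"]
        _, y30, _ = rd.binned_normalized_spectrum(spec30, 0.2, 2.0)
        _, y50, _ = rd.binned_normalized_spectrum(spec50, 0.2, 2.0)
        omega = spec30.omega_grid
        assert self._fwhm(omega, y30) >= self._fwhm(omega, y50)

    def test_broader_configured_dynamics_larger_fwhm(self, in5):
        slow = tiny_model(d_free=0.1)
        fast = tiny_model(d_free=0.4)
        s_slow = rd.simulate_qens(slow, in5, 298.0)
        s_fast = rd.simulate_qens(fast, in5, 298.0)
        _, y_slow, _ = rd.binned_normalized_spectrum(s_slow, 0.2, 2.0)
        _, y_fast, _ = rd.binned_normalized_spectrum(s_fast, 0.2, 2.0)
        omega = s_slow.omega_grid
        assert self._fwhm(omega, y_fast) > self._fwhm(omega, y_slow)

    def test_empty_window_is_an_error(self, noiseless_qens_fits):
        _, spec, _ = noiseless_qens_fits["h30s_nacl"]
        with pytest.raises(rd.ValidationError):
            rd.binned_normalized_spectrum(spec, 5.0, 6.0)
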