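"""Quasi-elastic spectral decomposition.

Each Q is fitted independently with a resolution-shaped elastic line, two
resolution-convolved Lorentzians and a flat background,

    S(Q, w) = a0 R(w) + a1 L(G1) (x) R + a2 L(G2) (x) R + b,

where R is a Gaussian of the instrument FWHM and each Lorentzian (x) Gaussian
is the closed-form Voigt profile. Half-width tables G(Q) per population are
then fitted with the jump-diffusion dispersion to yield a diffusion
coefficient and residence time, and the immobile hydrogen fraction is the
inverse-variance-weighted mean over Q of a0 / (a0 + a1 + a2).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from lmfit import Parameters, minimize
from scipy.optimize import curve_fit, nnls
from scipy.special import voigt_profile
from scipy.stats import norm

from .constants import FWHM_TO_SIGMA, HBAR_UEV_PS
from .datasets import INSTRUMENTS, QENSFitResult, SpectrumSet, ValidationError
from .elastic import FitError

__all__ = [
    "QComponentFit",
    "fit_spectrum_q",
    "fit_dispersion",
    "immobile_fraction",
    "binned_normalized_spectrum",
    "fit_qens",
]


@dataclass
class QComponentFit:
    """Delta + two-Lorentzian decomposition at a single Q.

    ``gamma1 <= gamma2`` by convention (narrow component first); a
    ``single_lorentzian`` flag marks Q values where the two widths were not
    separable and the fit was re-run with one Lorentzian (``gamma2 = nan``).
    """

    q: float
    a0: float
    a0_sigma: float
    a1: float
    a1_sigma: float
    a2: float
    a2_sigma: float
    gamma1: float
    gamma1_sigma: float
    gamma2: float
    gamma2_sigma: float
    background: float
    background_sigma: float
    redchi: float
    flags: list
    #: covariance of (a0, a1, a2) from the linear amplitude subproblem at
    #: the fitted widths; well-defined even when an amplitude sits on its
    #: non-negativity bound (where nonlinear-fit stderr collapses)
    amp_cov: np.ndarray | None = None
    #: covariance of (a0, a1, a2) marginalized over the widths and
    #: background, from the nonlinear fit (None when unavailable)
    amp_cov_nl: np.ndarray | None = None


def _model(omega, sig_res, a0, a1, a2, g1, g2, b):
    out = a0 * norm.pdf(omega, scale=sig_res) + b
    if a1:
        out = out + a1 * voigt_profile(omega, sig_res, g1)
    if a2:
        out = out + a2 * voigt_profile(omega, sig_res, g2)
    return out


def _initial_amplitudes(omega, y, sig_res, g1, g2):
    """Non-negative linear least squares for (a0, a1, a2, b) at fixed widths."""
    A = np.column_stack([
        norm.pdf(omega, scale=sig_res),
        voigt_profile(omega, sig_res, g1),
        voigt_profile(omega, sig_res, g2),
        np.ones_like(omega),
    ])
    coef, _ = nnls(A, y)
    return coef


def _start_grid(omega, y, wgt, sig_res, g_max, n_starts=2):
    """Deterministic multi-start (narrow, broad) HWHM guesses.

    Scans a coarse log grid of width pairs, solving the non-negative linear
    amplitude problem at each, and returns the ``n_starts`` pairs with the
    smallest weighted residuals (seedless and reproducible).
    """
    g1_cands = sig_res * np.array([0.01, 0.03, 0.1, 0.3, 1.0])
    g2_cands = sig_res * np.array([0.1, 0.3, 1.0, 3.0, 8.0, 12.0])
    g1_cands = np.clip(g1_cands, 1e-3 * sig_res, 0.5 * g_max)
    g2_cands = np.clip(g2_cands, 1e-3 * sig_res, 0.9 * g_max)
    elastic = norm.pdf(omega, scale=sig_res)
    ones = np.ones_like(omega)
    profiles = {g: voigt_profile(omega, sig_res, g)
                for g in np.unique(np.concatenate([g1_cands, g2_cands]))}
    scored = []
    for g1 in np.unique(g1_cands):
        for g2 in np.unique(g2_cands):
            if g2 <= 1.5 * g1:
                continue
            A = np.column_stack([elastic, profiles[g1], profiles[g2], ones])
            coef, _ = nnls(A * wgt[:, None], y * wgt)
            resid = (A @ coef - y) * wgt
            scored.append((float(resid @ resid), float(g1), float(g2)))
    scored.sort()
    return [(g1, g2) for _, g1, g2 in scored[:n_starts]]


def _run_fit(omega, y, wgt, sig_res, g_max, starts, two_lorentzians=True):
    def residual(params):
        g2 = params["g2"].value if two_lorentzians else params["g1"].value
        a2 = params["a2"].value if two_lorentzians else 0.0
        m = _model(
            omega, sig_res,
            params["a0"].value, params["a1"].value, a2,
            params["g1"].value, g2, params["b"].value,
        )
        return (m - y) * wgt

    best = None
    for g1_0, g2_0 in starts:
        a0_0, a1_0, a2_0, b_0 = _initial_amplitudes(omega, y, sig_res, g1_0, g2_0)
        params = Parameters()
        total = max(a0_0 + a1_0 + a2_0, 1e-12)
        params.add("a0", value=max(a0_0, 1e-6 * total), min=0.0)
        params.add("a1", value=max(a1_0, 1e-6 * total), min=0.0)
        params.add("g1", value=g1_0, min=1e-6 * sig_res, max=g_max)
        if two_lorentzians:
            params.add("a2", value=max(a2_0, 1e-6 * total), min=0.0)
            params.add("g2", value=g2_0, min=1e-6 * sig_res, max=g_max)
        params.add("b", value=b_0)
        try:
            res = minimize(residual, params, method="leastsq",
                           nan_policy="raise", xtol=1e-11, ftol=1e-11,
                           max_nfev=4000)
            # Polish: restarting from the converged point resets the trust
            # region and escapes premature ftol stops in flat valleys.
            for _ in range(2):
                res2 = minimize(residual, res.params.copy(), method="leastsq",
                                nan_policy="raise", xtol=1e-11, ftol=1e-11,
                                max_nfev=4000)
                if not np.isfinite(res2.chisqr) or res2.chisqr >= res.chisqr * (1 - 1e-6):
                    res = res2 if (np.isfinite(res2.chisqr)
                                   and res2.chisqr < res.chisqr) else res
                    break
                res = res2
        except Exception:
            continue
        # MINPACK reports "tolerance too small" once the minimum is resolved
        # to machine precision; the converged point is still usable.
        if np.isfinite(res.chisqr) and (best is None or res.chisqr < best.chisqr):
            best = res
    return best


def fit_spectrum_q(
    spec: SpectrumSet,
    q: float,
    resolution_fwhm: float | None = None,
) -> QComponentFit:
    """Fit the delta + two-Lorentzian model at the Q point nearest ``q``.

    Uses sigma weights where available (unit weights on noiseless data),
    bounded non-negative amplitudes and Lorentzian HWHMs in (0, window].
    Starting points come from a deterministic coarse grid of width pairs
    scored by non-negative linear amplitude fits; the best-scoring starts
    seed the full nonlinear optimization. If the two widths converge within
    10% of each other the fit is re-run with a single Lorentzian and
    flagged.
    """
    if resolution_fwhm is None:
        name = spec.metadata.get("instrument", "")
        if name not in INSTRUMENTS:
            raise ValidationError(
                "resolution_fwhm not given and instrument preset unknown"
            )
        resolution_fwhm = INSTRUMENTS[name].resolution_fwhm
    sig_res = resolution_fwhm * FWHM_TO_SIGMA
    i = int(np.argmin(np.abs(spec.q_grid - q)))
    omega = spec.omega_grid
    y = spec.intensity[i]
    s = spec.sigma[i]
    wgt = 1.0 / s if np.all(s > 0) else np.ones_like(y)
    g_max = float(omega[-1])

    flags: list = []
    res = _run_fit(omega, y, wgt, sig_res, g_max,
                   _start_grid(omega, y, wgt, sig_res, g_max))
    if res is None:
        raise FitError(
            f"QENS fit failed to converge at Q = {spec.q_grid[i]:g} 1/A "
            f"after multi-start"
        )

    p = res.params
    g1, g2 = p["g1"].value, p["g2"].value
    a1, a2 = p["a1"].value, p["a2"].value
    total = max(p["a0"].value + a1 + a2, 1e-300)
    degenerate = (
        abs(g1 - g2) / max(g1, g2) < 0.10
        and a1 > 1e-3 * total and a2 > 1e-3 * total
    )
    if degenerate:
        flags.append("single_lorentzian")
        res = _run_fit(omega, y, wgt, sig_res, g_max,
                       [(0.2 * sig_res, 0.0), (1.0 * sig_res, 0.0),
                        (4.0 * sig_res, 0.0)],
                       two_lorentzians=False)
        if res is None:
            raise FitError(
                f"single-Lorentzian refit failed at Q = {spec.q_grid[i]:g} 1/A"
            )
        p = res.params

    def err(name):
        e = p[name].stderr if name in p else None
        return float(e) if e is not None else float("nan")

    if degenerate:
        a1v, g1v = p["a1"].value, p["g1"].value
        a2v, g2v = 0.0, float("nan")
        a2e, g2e = 0.0, float("nan")
    else:
        # order components narrow -> broad
        if p["g1"].value <= p["g2"].value:
            a1v, g1v, a2v, g2v = p["a1"].value, p["g1"].value, p["a2"].value, p["g2"].value
            a1e, g1e, a2e, g2e = err("a1"), err("g1"), err("a2"), err("g2")
        else:
            a1v, g1v, a2v, g2v = p["a2"].value, p["g2"].value, p["a1"].value, p["g1"].value
            a1e, g1e, a2e, g2e = err("a2"), err("g2"), err("a1"), err("g1")
    if degenerate:
        a1e, g1e = err("a1"), err("g1")

    # Identifiability vs the resolution function: when the fitted quasi-
    # elastic lines are buried far inside the Gaussian resolution width the
    # elastic/Lorentzian split is unconstrained; flag such Q so estimators
    # can exclude them.
    total = p["a0"].value + a1v + a2v
    narrow_sig = a1v > 1e-3 * total and g1v < 0.05 * sig_res
    broad_sig = a2v > 1e-3 * total and np.isfinite(g2v) and g2v < 0.25 * sig_res
    if narrow_sig or broad_sig:
        flags.append("unresolved")

    # Amplitude covariance from the linear subproblem at the fitted widths:
    # the exact Fisher information for (a0, a1, a2, b), valid on the bounds.
    cols = [norm.pdf(omega, scale=sig_res),
            voigt_profile(omega, sig_res, g1v)]
    if np.isfinite(g2v):
        cols.append(voigt_profile(omega, sig_res, g2v))
    cols.append(np.ones_like(omega))
    Aw = np.column_stack(cols) * wgt[:, None]
    try:
        cov_lin = np.linalg.inv(Aw.T @ Aw)
    except np.linalg.LinAlgError:
        cov_lin = np.full((len(cols), len(cols)), np.nan)
    if not np.all(s > 0):  # unit weights: scale by residual variance
        cov_lin = cov_lin * res.redchi
    amp_cov = np.zeros((3, 3))
    k = 3 if np.isfinite(g2v) else 2
    amp_cov[:k, :k] = cov_lin[:k, :k]

    # nonlinear covariance among the (reordered) amplitudes, widths and
    # background marginalized out
    amp_cov_nl = None
    if res.covar is not None:
        names = list(res.var_names)
        if degenerate:
            order = ["a0", "a1"]
        elif a1v == p["a1"].value:
            order = ["a0", "a1", "a2"]
        else:
            order = ["a0", "a2", "a1"]
        try:
            idx = [names.index(n) for n in order]
            amp_cov_nl = np.zeros((3, 3))
            sub = res.covar[np.ix_(idx, idx)]
            amp_cov_nl[:len(idx), :len(idx)] = sub
        except ValueError:
            amp_cov_nl = None

    return QComponentFit(
        q=float(spec.q_grid[i]),
        a0=p["a0"].value, a0_sigma=err("a0"),
        a1=a1v, a1_sigma=a1e,
        a2=a2v, a2_sigma=a2e,
        gamma1=g1v, gamma1_sigma=g1e,
        gamma2=g2v, gamma2_sigma=g2e,
        background=p["b"].value, background_sigma=err("b"),
        redchi=float(res.redchi),
        flags=flags,
        amp_cov=amp_cov,
        amp_cov_nl=amp_cov_nl,
    )


def fit_dispersion(q, gamma, sigma=None):
    """Fit a Gamma(Q) table with the jump-diffusion dispersion.

    ``Gamma(Q) = hbar D Q^2 / (1 + D Q^2 tau)``; returns
    ``(d, d_sigma, tau, tau_sigma, flags)`` with D in A^2/ps and tau in ps.
    Falls back to the Fickian line through the origin (tau fixed at 0) when
    tau collapses to its lower bound.
    """
    q = np.asarray(q, float)
    gamma = np.asarray(gamma, float)
    if q.size < 4:
        raise FitError("need at least 4 Q points for a dispersion fit")
    use_sigma = sigma is not None and np.all(np.asarray(sigma) > 0)
    sig = np.asarray(sigma, float) if use_sigma else None

    def jump(qq, d, tau):
        return HBAR_UEV_PS * d * qq**2 / (1.0 + d * qq**2 * tau)

    d0 = max(gamma[0] / (HBAR_UEV_PS * q[0] ** 2), 1e-6)
    tau0 = max(HBAR_UEV_PS / (2.0 * gamma.max()), 1e-4)
    popt, pcov = curve_fit(
        jump, q, gamma, p0=[d0, tau0],
        sigma=sig, absolute_sigma=use_sigma,
        bounds=([1e-10, 0.0], [np.inf, np.inf]), maxfev=20000,
    )
    d, tau = popt
    d_sig, tau_sig = np.sqrt(np.diag(pcov))
    flags: list = []
    if tau < 1e-6:  # Fickian limit: weighted line through the origin
        flags.append("fickian")
        x = HBAR_UEV_PS * q**2
        w = 1.0 / sig**2 if use_sigma else np.ones_like(x)
        d = float(np.sum(w * x * gamma) / np.sum(w * x**2))
        var = 1.0 / np.sum(w * x**2)
        if not use_sigma and q.size > 1:
            resid = gamma - d * x
            var *= np.sum(w * resid**2) / (q.size - 1)
        d_sig = float(np.sqrt(var))
        tau, tau_sig = 0.0, 0.0
    return float(d), float(d_sig), float(tau), float(tau_sig), flags


def immobile_fraction(records) -> tuple[float, float]:
    """Inverse-variance-weighted immobile fraction over Q.

    Per Q the estimate is ``a0 / (a0 + a1 + a2)`` with a first-order sigma
    (amplitude covariances neglected). Noiseless fits (zero sigmas) reduce
    to a plain mean. Q values flagged ``unresolved`` (elastic/Lorentzian
    split unconstrained by the resolution) are excluded; at least three
    usable fits are required.
    """
    usable = [r for r in records
              if "failed" not in r.flags and "unresolved" not in r.flags]
    if len(usable) < 3:
        raise FitError("need at least 3 valid per-Q fits")
    f = np.empty(len(usable))
    var = np.empty(len(usable))
    for i, r in enumerate(usable):
        total = r.a0 + r.a1 + r.a2
        f[i] = r.a0 / total
        grad = np.array([(total - r.a0) / total**2,
                         -r.a0 / total**2,
                         -r.a0 / total**2])
        # Two curvature-based variance estimates with complementary failure
        # modes: the nonlinear-fit one includes the width tradeoff but
        # collapses when an amplitude sits on its bound; the fixed-width
        # linear one is immune to bounds but blind to width uncertainty.
        # The larger of the two is the defensible per-Q uncertainty.
        if r.amp_cov_nl is not None and np.all(np.isfinite(r.amp_cov_nl)):
            var_nl = float(grad @ r.amp_cov_nl @ grad)
        else:
            sigs = np.array([
                r.a0_sigma if np.isfinite(r.a0_sigma) else 0.0,
                r.a1_sigma if np.isfinite(r.a1_sigma) else 0.0,
                r.a2_sigma if np.isfinite(r.a2_sigma) else 0.0,
            ])
            var_nl = float(np.sum((grad * sigs) ** 2))
        var_lin = 0.0
        if r.amp_cov is not None and np.all(np.isfinite(r.amp_cov)):
            var_lin = float(grad @ r.amp_cov @ grad)
        var[i] = max(var_nl, var_lin, 0.0)
    if np.all(var > 0):
        w = 1.0 / var
        est = float(np.sum(w * f) / np.sum(w))
        sig = float(np.sqrt(1.0 / np.sum(w)))
        # over-dispersion guard: when the per-Q estimates scatter more than
        # their claimed uncertainties allow, scale the combined sigma by
        # sqrt(chi2/dof) (standard weighted-mean practice)
        if len(f) > 1:
            chi2_dof = float(np.sum(w * (f - est) ** 2)) / (len(f) - 1)
            if chi2_dof > 1.0:
                sig *= np.sqrt(chi2_dof)
    else:
        est = float(np.mean(f))
        sig = float(np.std(f) / np.sqrt(len(f))) if len(f) > 1 else 0.0
    return est, sig


def binned_normalized_spectrum(spec: SpectrumSet, q_lo: float, q_hi: float):
    """Sum spectra over the closed Q window and normalize to unit area.

    Returns ``(omega, intensity, sigma)`` with the trapezoid integral of the
    intensity equal to 1.
    """
    mask = (spec.q_grid >= q_lo) & (spec.q_grid <= q_hi)
    if not mask.any():
        raise ValidationError(
            f"no Q points in [{q_lo}, {q_hi}]; available "
            f"[{spec.q_grid.min():g}, {spec.q_grid.max():g}]"
        )
    summed = spec.intensity[mask].sum(axis=0)
    sig = np.sqrt((spec.sigma[mask] ** 2).sum(axis=0))
    area = np.trapezoid(summed, spec.omega_grid)
    if area <= 0:
        raise ValidationError("binned spectrum has non-positive area")
    return spec.omega_grid.copy(), summed / area, sig / area


def fit_qens(
    spec: SpectrumSet,
    resolution_fwhm: float | None = None,
    *,
    q_subset=None,
) -> QENSFitResult:
    """Full QENS analysis: per-Q fits, dispersion fits, immobile fraction.

    ``q_subset`` optionally restricts which Q values are fitted. Dispersion
    fits use only Q points where the two Lorentzians were separable; at
    least four are required per population for D and tau to be reported
    (otherwise they stay nan).
    """
    qs = spec.q_grid if q_subset is None else np.asarray(q_subset, float)
    records = [fit_spectrum_q(spec, q, resolution_fwhm) for q in qs]

    est, est_sig = immobile_fraction(records)
    result = QENSFitResult(
        q=np.array([r.q for r in records]),
        a0=np.array([r.a0 for r in records]),
        a0_sigma=np.array([r.a0_sigma for r in records]),
        a1=np.array([r.a1 for r in records]),
        a1_sigma=np.array([r.a1_sigma for r in records]),
        a2=np.array([r.a2 for r in records]),
        a2_sigma=np.array([r.a2_sigma for r in records]),
        gamma1=np.array([r.gamma1 for r in records]),
        gamma1_sigma=np.array([r.gamma1_sigma for r in records]),
        gamma2=np.array([r.gamma2 for r in records]),
        gamma2_sigma=np.array([r.gamma2_sigma for r in records]),
        background=np.array([r.background for r in records]),
        redchi=np.array([r.redchi for r in records]),
        flags=[r.flags for r in records],
        immobile_fraction=est,
        immobile_sigma=est_sig,
    )

    clean = [r for r in records if not r.flags and np.isfinite(r.gamma2)]
    if len(clean) >= 4:
        q_arr = np.array([r.q for r in clean])
        g1 = np.array([r.gamma1 for r in clean])
        g1s = np.array([r.gamma1_sigma for r in clean])
        g2 = np.array([r.gamma2 for r in clean])
        g2s = np.array([r.gamma2_sigma for r in clean])
        try:
            d, ds, tau, taus, _ = fit_dispersion(
                q_arr, g1, g1s if np.all(np.isfinite(g1s) & (g1s > 0)) else None
            )
            result.d_hyd, result.d_hyd_sigma = d, ds
            result.tau_hyd, result.tau_hyd_sigma = tau, taus
        except (FitError, RuntimeError):
            pass
        try:
            d, ds, tau, taus, _ = fit_dispersion(
                q_arr, g2, g2s if np.all(np.isfinite(g2s) & (g2s > 0)) else None
            )
            result.d_free, result.d_free_sigma = d, ds
            result.tau_free, result.tau_free_sigma = tau, taus
        except (FitError, RuntimeError):
            pass
    return result
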