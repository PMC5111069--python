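"""Elastic fixed-window scan analysis.

Per temperature, the mean-square displacement is extracted in the Gaussian
approximation from the slope of ln S_el versus Q^2 over a fixed Q window
(weighted least squares, weights from first-order-propagated log
uncertainties). The MSD(T) series is then fitted with a weighted straight
line above a minimum temperature and converted to an effective force
constant ("resilience") via the quasi-harmonic relation
``<k> = 2 k_B / (d<u^2>/dT)`` (0.002761 N/m when the slope is in A^2/K).
A two-segment breakpoint search locates the kink near the freezing of free
water in the sample.
"""

from __future__ import annotations

import warnings

import numpy as np

from .constants import (
    FORCE_CONSTANT_PREFACTOR,
    GAUSSIAN_MSD_DIVISOR,
    GAUSSIAN_VALIDITY_LIMIT,
    T_REF_K,
)
from .datasets import ElasticScan, ForceConstantResult, MSDSeries, ValidationError

__all__ = ["FitError", "weighted_line_fit", "fit_msd", "fit_force_constant",
           "detect_kink"]


class FitError(RuntimeError):
    """A fit could not be performed under its preconditions."""


def weighted_line_fit(x, y, sigma=None):
    """Weighted least-squares straight line y = a + b x.

    Returns ``(a, b, cov)`` with ``cov`` the 2x2 covariance of (a, b). With
    ``sigma`` given (all > 0) the covariance is the exact linear-propagation
    one; otherwise unit weights are used and the covariance is scaled by the
    residual variance (when more than two points are available).
    """
    x = np.asarray(x, float)
    y = np.asarray(y, float)
    if x.size < 2:
        raise FitError("need at least two points for a line fit")
    known_sigma = sigma is not None and np.all(np.asarray(sigma) > 0)
    w = 1.0 / np.asarray(sigma, float) ** 2 if known_sigma else np.ones_like(x)
    X = np.column_stack([np.ones_like(x), x])
    XtW = X.T * w
    cov = np.linalg.inv(XtW @ X)
    beta = cov @ (XtW @ y)
    resid = y - X @ beta
    chi2 = float(np.sum(w * resid**2))
    if not known_sigma and x.size > 2:
        cov = cov * chi2 / (x.size - 2)
    return float(beta[0]), float(beta[1]), cov, chi2


def fit_msd(
    scan: ElasticScan,
    q_window: tuple = (0.34, 0.85),
    *,
    gaussian_divisor: float = GAUSSIAN_MSD_DIVISOR,
) -> MSDSeries:
    """Extract <u^2>(T) from the Q^2 dependence of the elastic intensity.

    For each temperature, fits ln S_el = intercept - <u^2> Q^2 / divisor by
    weighted least squares over the closed Q window. Non-positive
    intensities are dropped with a warning; fewer than three usable Q points
    at any temperature is an error. Temperatures where
    ``<u^2> * q_hi^2`` exceeds the Gaussian-validity limit are flagged
    (``gaussian_ok = False``), not rejected.
    """
    q_lo, q_hi = q_window
    mask_q = (scan.q_grid >= q_lo) & (scan.q_grid <= q_hi)
    if mask_q.sum() < 3:
        raise FitError(
            f"fewer than 3 Q points in window [{q_lo}, {q_hi}]"
        )
    q2 = scan.q_grid[mask_q] ** 2
    n_t = scan.temperatures.size
    msd = np.empty(n_t)
    msd_sig = np.empty(n_t)
    intercept = np.empty(n_t)
    chi2 = np.empty(n_t)
    gaussian_ok = np.empty(n_t, dtype=bool)

    for j, t in enumerate(scan.temperatures):
        inten = scan.intensity[mask_q, j]
        sig = scan.sigma[mask_q, j]
        good = inten > 0
        if not good.all():
            warnings.warn(
                f"dropping {int((~good).sum())} non-positive intensities "
                f"at T = {t:g} K", stacklevel=2,
            )
        if good.sum() < 3:
            raise FitError(
                f"fewer than 3 usable Q points at T = {t:g} K"
            )
        y = np.log(inten[good])
        # first-order propagation: sigma_ln = sigma / I
        s_ln = sig[good] / inten[good] if np.all(sig[good] > 0) else None
        a, b, cov, c2 = weighted_line_fit(q2[good], y, s_ln)
        msd[j] = -gaussian_divisor * b
        msd_sig[j] = gaussian_divisor * np.sqrt(cov[1, 1])
        intercept[j] = a
        chi2[j] = c2
        q_hi_used = np.sqrt(q2[good].max())
        gaussian_ok[j] = msd[j] * q_hi_used**2 <= GAUSSIAN_VALIDITY_LIMIT

    return MSDSeries(
        temperatures=scan.temperatures.copy(),
        msd=msd,
        msd_sigma=msd_sig,
        intercept=intercept,
        chi2=chi2,
        gaussian_ok=gaussian_ok,
        q_window=(float(q_lo), float(q_hi)),
        convention=float(gaussian_divisor),
        sample=scan.metadata.get("sample", ""),
    )


def fit_force_constant(
    series: MSDSeries, t_min: float = 270.0
) -> ForceConstantResult:
    """Fit <u^2> versus T above ``t_min`` and convert to a force constant.

    The fit is a weighted straight line restricted to T > t_min;
    ``<k> = 0.002761 / slope`` N/m with sigma propagated from the slope, and
    the MSD at the 310.15 K (37 C) reference is evaluated on the fitted line
    with full covariance propagation. A non-positive slope yields a
    non-physical result (``k_eff = nan``).
    """
    t = np.asarray(series.temperatures, float)
    sel = t > t_min
    if sel.sum() < 3:
        raise FitError(
            f"need at least 3 temperatures above {t_min:g} K, "
            f"have {int(sel.sum())}"
        )
    x = t[sel]
    y = np.asarray(series.msd, float)[sel]
    s = np.asarray(series.msd_sigma, float)[sel]
    a, b, cov, _ = weighted_line_fit(x, y, s if np.all(s > 0) else None)
    slope_sigma = float(np.sqrt(cov[1, 1]))
    msd_ref = a + b * T_REF_K
    msd_ref_var = cov[0, 0] + T_REF_K**2 * cov[1, 1] + 2 * T_REF_K * cov[0, 1]
    physical = b > 0
    if physical:
        k = FORCE_CONSTANT_PREFACTOR / b
        k_sigma = k * slope_sigma / b
    else:
        k, k_sigma = float("nan"), float("nan")
    return ForceConstantResult(
        slope=float(b),
        slope_sigma=slope_sigma,
        t_min_fit=float(t_min),
        k_eff=float(k),
        k_sigma=float(k_sigma),
        msd_at_ref=float(msd_ref),
        msd_at_ref_sigma=float(np.sqrt(max(msd_ref_var, 0.0))),
        n_points_fit=int(sel.sum()),
        physical=bool(physical),
    )


def _two_segment_sse(t, y, w, t_break):
    """Weighted SSE of the continuous two-segment fit with a hinge at t_break.

    Linear in the parameters (value at the break, left slope, right slope).
    """
    left = np.minimum(t - t_break, 0.0)
    right = np.maximum(t - t_break, 0.0)
    X = np.column_stack([np.ones_like(t), left, right])
    Xw = X * np.sqrt(w)[:, None]
    yw = y * np.sqrt(w)
    beta, *_ = np.linalg.lstsq(Xw, yw, rcond=None)
    resid = yw - Xw @ beta
    return float(resid @ resid)


def detect_kink(series: MSDSeries, min_per_segment: int = 3) -> float:
    """Locate the MSD(T) breakpoint by exhaustive two-segment fitting.

    Candidates are the interior measured temperatures with at least
    ``min_per_segment`` points on each side (a point at the candidate counts
    to the lower segment). Returns the candidate minimizing the weighted
    SSE of a continuous piecewise-linear fit; exact ties break toward the
    lower temperature.
    """
    t = np.asarray(series.temperatures, float)
    y = np.asarray(series.msd, float)
    s = np.asarray(series.msd_sigma, float)
    if t.size < 6:
        raise FitError("need at least 6 temperatures to search for a kink")
    w = 1.0 / s**2 if np.all(s > 0) else np.ones_like(t)
    # tie tolerance: SSE differences below floating-point noise on the data
    # scale count as ties (broken toward lower temperature)
    y_bar = np.average(y, weights=w)
    tol = 1e-9 * float(np.sum(w * (y - y_bar) ** 2)) + 1e-30
    best_t, best_sse = None, np.inf
    for t_c in t[1:-1]:
        n_left = int(np.sum(t <= t_c))
        n_right = int(np.sum(t > t_c))
        if n_left < min_per_segment or n_right < min_per_segment:
            continue
        sse = _two_segment_sse(t, y, w, t_c)
        if sse < best_sse - tol:
            best_t, best_sse = float(t_c), sse
    if best_t is None:
        raise FitError(
            "no candidate breakpoint leaves enough points per segment"
        )
    return best_t
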