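"""Domain containers for incoherent neutron-scattering data.

The three measured-data containers (:class:`SpectrumSet`, :class:`ElasticScan`,
:class:`VanadiumReference`) hold intensities with per-point uncertainties on
regular grids, plus acquisition metadata and reduction-state flags. The
remaining types carry generative ground truth (:class:`SampleModel`) and fit
results. Everything validates eagerly: constructing an inconsistent object
raises :class:`ValidationError`.
"""

from __future__ import annotations

import dataclasses
from dataclasses import dataclass, field
from typing import Optional

import numpy as np

from .constants import DEFAULT_T_KINK, T_REF_K

__all__ = [
    "ValidationError",
    "InstrumentConfig",
    "INSTRUMENTS",
    "SpectrumSet",
    "ElasticScan",
    "VanadiumReference",
    "SampleModel",
    "MSDSeries",
    "ForceConstantResult",
    "QENSFitResult",
    "REDUCTION_FLAGS",
    "restrict_q",
]

#: Reduction-chain flags, in the order the chain applies them.
REDUCTION_FLAGS = (
    "monitor_normalized",
    "empty_cell_subtracted",
    "vanadium_normalized",
)


class ValidationError(ValueError):
    """A dataset or model violates one of its structural invariants."""


def _as_array(x, name: str) -> np.ndarray:
    arr = np.asarray(x, dtype=float)
    if not np.all(np.isfinite(arr)):
        raise ValidationError(f"{name} contains non-finite values")
    return arr


@dataclass
class InstrumentConfig:
    """Geometry and resolution of a spectrometer setting.

    ``energy_window`` is the half-width of the energy-transfer grid (ueV) and
    is required only for quasi-elastic settings; fixed-window elastic scans
    need no energy axis.
    """

    name: str
    wavelength: float  # A
    resolution_fwhm: float  # ueV
    q_min: float  # 1/A
    q_max: float  # 1/A
    n_q: int
    energy_window: Optional[float] = None  # ueV, half-width
    n_energy: Optional[int] = None

    def __post_init__(self):
        if self.wavelength <= 0:
            raise ValidationError("wavelength must be > 0")
        if self.resolution_fwhm <= 0:
            raise ValidationError("resolution_fwhm must be > 0")
        if not (0 < self.q_min < self.q_max):
            raise ValidationError("require 0 < q_min < q_max")
        if self.n_q < 2:
            raise ValidationError("n_q must be >= 2")
        if (self.energy_window is None) != (self.n_energy is None):
            raise ValidationError(
                "energy_window and n_energy must be given together"
            )
        if self.n_energy is not None and self.n_energy < 5:
            raise ValidationError("n_energy must be >= 5")

    @property
    def is_qens(self) -> bool:
        return self.energy_window is not None

    def q_grid(self) -> np.ndarray:
        return np.linspace(self.q_min, self.q_max, self.n_q)

    def omega_grid(self) -> np.ndarray:
        if not self.is_qens:
            raise ValidationError(
                f"instrument {self.name!r} has no energy grid"
            )
        return np.linspace(-self.energy_window, self.energy_window, self.n_energy)


#: Spectrometer presets. IN5 is a disk-chopper time-of-flight instrument used
#: at two incident wavelengths (10-ps-scale water diffusion); IN16 is a cold
#: backscattering spectrometer whose 0.9 ueV resolution defines a ~1 ns
#: elastic window. Q-bin counts are reduction choices, not hardware facts.
INSTRUMENTS = {
    "IN5_5.1A": InstrumentConfig(
        name="IN5_5.1A", wavelength=5.1, resolution_fwhm=75.0,
        q_min=0.21, q_max=1.98, n_q=12, energy_window=1000.0, n_energy=401,
    ),
    "IN5_10A": InstrumentConfig(
        name="IN5_10A", wavelength=10.0, resolution_fwhm=12.0,
        q_min=0.10, q_max=1.01, n_q=10, energy_window=400.0, n_energy=321,
    ),
    "IN16": InstrumentConfig(
        name="IN16", wavelength=6.27, resolution_fwhm=0.9,
        q_min=0.19, q_max=1.89, n_q=20,
    ),
}


def _check_grid(grid: np.ndarray, name: str) -> None:
    if grid.ndim != 1 or grid.size < 1:
        raise ValidationError(f"{name} must be a non-empty 1-D array")
    if grid.size > 1 and not np.all(np.diff(grid) > 0):
        raise ValidationError(f"{name} must be strictly increasing")


def _check_intensity(intensity, sigma, shape, what: str) -> None:
    if intensity.shape != shape:
        raise ValidationError(
            f"{what} intensity shape {intensity.shape} != grid shape {shape}"
        )
    if sigma.shape != shape:
        raise ValidationError(
            f"{what} sigma shape {sigma.shape} != grid shape {shape}"
        )
    if np.any(sigma < 0):
        raise ValidationError(f"{what} has negative sigma values")


def _default_meta() -> dict:
    return {"sample": "", "instrument": "", "reduction_state": []}


@dataclass
class SpectrumSet:
    """Energy-resolved QENS intensities S(Q, omega) with uncertainties."""

    q_grid: np.ndarray  # 1/A, ascending
    omega_grid: np.ndarray  # ueV, ascending, symmetric about 0
    intensity: np.ndarray  # (n_q, n_omega)
    sigma: np.ndarray  # (n_q, n_omega)
    temperature: float  # K
    monitor: float = 1.0  # counts
    transmission: float = 1.0
    metadata: dict = field(default_factory=_default_meta)

    def __post_init__(self):
        self.q_grid = _as_array(self.q_grid, "q_grid")
        self.omega_grid = _as_array(self.omega_grid, "omega_grid")
        self.intensity = _as_array(self.intensity, "intensity")
        self.sigma = _as_array(self.sigma, "sigma")
        _check_grid(self.q_grid, "q_grid")
        _check_grid(self.omega_grid, "omega_grid")
        _check_intensity(
            self.intensity, self.sigma,
            (self.q_grid.size, self.omega_grid.size), "SpectrumSet",
        )
        step = np.median(np.diff(self.omega_grid))
        if abs(self.omega_grid[0] + self.omega_grid[-1]) > step:
            raise ValidationError(
                "omega_grid must be symmetric about 0 within one grid step"
            )
        if not (0 < self.transmission <= 1):
            raise ValidationError("transmission must be in (0, 1]")
        if self.monitor <= 0:
            raise ValidationError("monitor must be > 0")
        self.metadata.setdefault("reduction_state", [])

    @property
    def reduction_state(self) -> list:
        return self.metadata["reduction_state"]


@dataclass
class ElasticScan:
    """Fixed-window elastic intensities S_el(Q, T) with uncertainties."""

    q_grid: np.ndarray  # 1/A, ascending
    temperatures: np.ndarray  # K, strictly increasing
    intensity: np.ndarray  # (n_q, n_T)
    sigma: np.ndarray  # (n_q, n_T)
    monitor: np.ndarray = None  # counts, per temperature
    transmission: float = 1.0
    metadata: dict = field(default_factory=_default_meta)

    def __post_init__(self):
        self.q_grid = _as_array(self.q_grid, "q_grid")
        self.temperatures = _as_array(self.temperatures, "temperatures")
        self.intensity = _as_array(self.intensity, "intensity")
        self.sigma = _as_array(self.sigma, "sigma")
        _check_grid(self.q_grid, "q_grid")
        _check_grid(self.temperatures, "temperatures")
        if self.monitor is None:
            self.monitor = np.ones(self.temperatures.size)
        self.monitor = _as_array(self.monitor, "monitor")
        if self.monitor.shape != self.temperatures.shape:
            raise ValidationError("monitor must have one entry per temperature")
        if np.any(self.monitor <= 0):
            raise ValidationError("monitor values must be > 0")
        _check_intensity(
            self.intensity, self.sigma,
            (self.q_grid.size, self.temperatures.size), "ElasticScan",
        )
        if not (0 < self.transmission <= 1):
            raise ValidationError("transmission must be in (0, 1]")
        self.metadata.setdefault("reduction_state", [])

    @property
    def reduction_state(self) -> list:
        return self.metadata["reduction_state"]


@dataclass
class VanadiumReference:
    """Per-Q elastic intensity of a vanadium calibration run.

    Vanadium is a purely elastic, incoherent scatterer whose signal is
    constant in Q up to detector efficiency, so dividing by it calibrates
    intensities to an absolute scale and removes efficiency differences.
    """

    q_grid: np.ndarray
    intensity: np.ndarray
    sigma: np.ndarray
    metadata: dict = field(default_factory=_default_meta)

    def __post_init__(self):
        self.q_grid = _as_array(self.q_grid, "q_grid")
        self.intensity = _as_array(self.intensity, "intensity")
        self.sigma = _as_array(self.sigma, "sigma")
        _check_grid(self.q_grid, "q_grid")
        _check_intensity(
            self.intensity, self.sigma, (self.q_grid.size,), "VanadiumReference"
        )
        if np.any(self.intensity <= 0):
            raise ValidationError("vanadium intensities must all be > 0")
        self.metadata.setdefault("reduction_state", [])


@dataclass
class SampleModel:
    """Generative ground truth for one synthetic sample.

    The hydrogen population splits into an immobile fraction (motions too slow
    for the quasi-elastic window), hydration water and free water, each water
    population following jump diffusion with coefficient ``d`` (A^2/ps) and
    residence time ``tau`` (ps). The internal mean-square displacement is
    piecewise linear in temperature with a kink at ``t_kink`` where free water
    in the sample freezes, anchored so that msd(310.15 K) = ``msd_ref``.
    """

    name: str
    water_fraction: float
    immobile_fraction: float
    p_free: float
    p_hyd: float
    d_free: float  # A^2/ps
    d_hyd: float  # A^2/ps
    tau_free: float  # ps
    tau_hyd: float  # ps
    msd_ref: float  # A^2 at T_REF_K
    slope_above: float  # A^2/K for T > t_kink
    slope_below: float  # A^2/K for T <= t_kink
    t_kink: float = DEFAULT_T_KINK

    def __post_init__(self):
        fracs = (self.immobile_fraction, self.p_free, self.p_hyd)
        if any(f < 0 or f > 1 for f in fracs):
            raise ValidationError("fractions must lie in [0, 1]")
        if abs(sum(fracs) - 1.0) > 1e-9:
            raise ValidationError(
                "immobile_fraction + p_free + p_hyd must equal 1"
            )
        if not (0 <= self.water_fraction <= 1):
            raise ValidationError("water_fraction must lie in [0, 1]")
        if self.d_free <= 0 or self.d_hyd <= 0:
            raise ValidationError("diffusion coefficients must be > 0")
        if self.tau_free < 0 or self.tau_hyd < 0:
            raise ValidationError("residence times must be >= 0")
        if self.slope_above < 0 or self.slope_below < 0:
            raise ValidationError("MSD slopes must be >= 0")
        # MSD must stay non-negative across the simulated range.
        for t in (200.0, self.t_kink, 350.0):
            if self.msd_at(t) < 0:
                raise ValidationError(
                    f"model {self.name!r} yields negative MSD at {t} K"
                )

    def msd_at(self, temperature) -> np.ndarray | float:
        """Piecewise-linear ground-truth MSD (A^2), continuous at the kink."""
        t = np.asarray(temperature, dtype=float)
        msd_kink = self.msd_ref - self.slope_above * (T_REF_K - self.t_kink)
        out = np.where(
            t > self.t_kink,
            msd_kink + self.slope_above * (t - self.t_kink),
            msd_kink + self.slope_below * (t - self.t_kink),
        )
        return float(out) if np.isscalar(temperature) else out


@dataclass
class MSDSeries:
    """Per-temperature mean-square displacements with fit diagnostics."""

    temperatures: np.ndarray  # K
    msd: np.ndarray  # A^2
    msd_sigma: np.ndarray  # A^2
    intercept: np.ndarray  # ln-intensity intercepts of the per-T fits
    chi2: np.ndarray  # weighted residual sum of squares per T
    gaussian_ok: np.ndarray  # bool; False where <u^2> q_hi^2 exceeds the limit
    q_window: tuple  # (1/A, 1/A)
    convention: float  # Gaussian divisor used (S_el ~ exp(-msd Q^2/convention))
    sample: str = ""

    def __post_init__(self):
        n = np.asarray(self.temperatures).size
        for name in ("msd", "msd_sigma", "intercept", "chi2", "gaussian_ok"):
            if np.asarray(getattr(self, name)).size != n:
                raise ValidationError(f"{name} must have one entry per temperature")

    @property
    def r_g_squared(self) -> np.ndarray:
        """Radius of gyration squared of the motion, R_g^2 = <u^2>/2 (A^2)."""
        return np.asarray(self.msd) / 2.0


@dataclass
class ForceConstantResult:
    """Quasi-harmonic effective force constant from the MSD(T) slope."""

    slope: float  # A^2/K
    slope_sigma: float
    t_min_fit: float  # K; only T > t_min_fit entered the fit
    k_eff: float  # N/m; nan when the slope is non-positive
    k_sigma: float
    msd_at_ref: float  # A^2, fitted line evaluated at T_REF_K
    msd_at_ref_sigma: float
    n_points_fit: int
    physical: bool = True

    def __post_init__(self):
        if self.physical and not (self.k_eff > 0):
            raise ValidationError("physical result requires k_eff > 0")


@dataclass
class QENSFitResult:
    """Per-Q delta + two-Lorentzian decomposition and derived water dynamics."""

    q: np.ndarray
    a0: np.ndarray  # elastic (resolution-shaped) weight
    a0_sigma: np.ndarray
    a1: np.ndarray  # narrow Lorentzian weight (hydration water)
    a1_sigma: np.ndarray
    a2: np.ndarray  # broad Lorentzian weight (free water)
    a2_sigma: np.ndarray
    gamma1: np.ndarray  # ueV HWHM, narrow
    gamma1_sigma: np.ndarray
    gamma2: np.ndarray  # ueV HWHM, broad
    gamma2_sigma: np.ndarray
    background: np.ndarray
    redchi: np.ndarray
    flags: list  # one list of strings per Q
    d_free: float = np.nan  # A^2/ps
    d_free_sigma: float = np.nan
    tau_free: float = np.nan  # ps
    tau_free_sigma: float = np.nan
    d_hyd: float = np.nan
    d_hyd_sigma: float = np.nan
    tau_hyd: float = np.nan
    tau_hyd_sigma: float = np.nan
    immobile_fraction: float = np.nan
    immobile_sigma: float = np.nan


def restrict_q(obj, q_lo: float, q_hi: float):
    """Restrict a dataset to the closed Q interval [q_lo, q_hi].

    Selection is exact membership (never interpolation); the retained window
    is recorded in the metadata. Raises :class:`ValidationError` when no Q
    point falls inside the window, naming the available range.
    """
    if not q_lo < q_hi:
        raise ValidationError("require q_lo < q_hi")
    mask = (obj.q_grid >= q_lo) & (obj.q_grid <= q_hi)
    if not mask.any():
        raise ValidationError(
            f"no Q points in [{q_lo}, {q_hi}]; available range "
            f"[{obj.q_grid.min():g}, {obj.q_grid.max():g}]"
        )
    new = dataclasses.replace(
        obj,
        q_grid=obj.q_grid[mask],
        intensity=obj.intensity[mask],
        sigma=obj.sigma[mask],
        metadata={**obj.metadata, "q_window": (float(q_lo), float(q_hi)),
                  "reduction_state": list(obj.metadata.get("reduction_state", []))},
    )
    return new
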