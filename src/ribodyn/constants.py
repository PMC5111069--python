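"""Physical constants and package-wide analysis conventions.

All energies are in micro-electronvolts (ueV), lengths in Angstrom (A),
times in picoseconds (ps), temperatures in kelvin. Diffusion coefficients
are A^2/ps internally; conversions to cm^2/s appear only in reports.
"""

import math

#: Reduced Planck constant in ueV*ps (6.582119569e-16 eV*s).
HBAR_UEV_PS = 658.2119569

#: Boltzmann constant, J/K (SI, exact).
BOLTZMANN_J_PER_K = 1.380649e-23

#: Quasi-harmonic conversion between the slope of <u^2>(T) and the effective
#: force constant: <k> [N/m] = FORCE_CONSTANT_PREFACTOR / (d<u^2>/dT [A^2/K]).
#: Equals 2*k_B expressed for <u^2> in A^2 and T in K (0.002761 to the
#: precision usually printed).
FORCE_CONSTANT_PREFACTOR = 2.0 * BOLTZMANN_J_PER_K * 1e20

#: Gaussian-approximation convention for the elastic incoherent intensity,
#: S_el(Q) ~ exp(-<u^2> Q^2 / GAUSSIAN_MSD_DIVISOR). Shared by the synthetic
#: generator and the fitters so the two can never disagree. Under this
#: convention <u^2> = 2 R_g^2 for the radius of gyration of the motion.
GAUSSIAN_MSD_DIVISOR = 6.0

#: Reference temperature for reporting MSD (37 C).
T_REF_K = 310.15

#: Gaussian approximation is considered reliable up to <u^2>*Q^2 of about
#: this value; beyond it the per-temperature fit is flagged (not rejected).
GAUSSIAN_VALIDITY_LIMIT = 4.0

#: FWHM -> Gaussian sigma.
FWHM_TO_SIGMA = 1.0 / (2.0 * math.sqrt(2.0 * math.log(2.0)))

#: Default two-segment breakpoint (K) for the piecewise-linear MSD(T) ground
#: truth: free water in the sample freezes near 273 K, stiffening the complex.
DEFAULT_T_KINK = 273.0

#: Conversion A^2/ps -> cm^2/s (1 A^2/ps = 1e-16 cm^2 / 1e-12 s).
A2_PER_PS_TO_CM2_PER_S = 1e-4
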