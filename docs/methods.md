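# Methods

This note records the models, conventions and numerical choices behind
`ribodyn`, and what the synthetic-data tests do and do not demonstrate.

## Physical model

**Elastic fixed-window scans.** The incoherent elastic intensity of a
hydrogen-rich sample in the Gaussian approximation is

    S_el(Q, T) = A exp(−⟨u²⟩(T) Q² / 6),

where ⟨u²⟩ is the hydrogen mean-square displacement resolved within the
instrument's energy window (about 1 ns for a 0.9 μeV FWHM backscattering
setting). The divisor 6 is a convention choice (literature usage varies
between 3 and 6 depending on whether the displacement or its projection is
meant); it is defined once as `GAUSSIAN_MSD_DIVISOR` and shared by the
generator and the fitters, so recovered force constants are invariant under
a consistent change of convention. Under this convention ⟨u²⟩ = 2R_g² for
the radius of gyration of the motion. The approximation degrades beyond
⟨u²⟩Q² ≈ 4; the per-temperature fit flags (but does not reject) windows
exceeding this, since realistic amplitude/Q-range combinations for soft,
hydrated complexes routinely exceed it and the flag is diagnostic.

Per temperature, ⟨u²⟩ = −6 × slope of a weighted least-squares line of
ln S_el versus Q², with log-uncertainties propagated to first order
(σ_ln = σ/I). The default window 0.34–0.85 Å⁻¹ balances Gaussian validity
against leverage; one window is used for all temperatures of a run.

**Quasi-harmonic force constant.** Above the kink where free water in the
sample freezes (~273 K), ⟨u²⟩(T) is fitted with a weighted straight line
restricted to T > 270 K, and the mean effective force constant is

    ⟨k⟩ [N/m] = 2 k_B / (d⟨u²⟩/dT) = 0.002761 / slope[Å²/K].

The implementation uses the exact 2k_B value (0.0027613); σ_k follows from
the slope uncertainty. The reference MSD is the fitted line at 310.15 K
(37 °C), with full covariance propagation. A non-positive slope yields a
flagged non-physical result rather than a negative force constant.

**Kink location.** A continuous two-segment (hinge) model is fitted at
every interior measured temperature with at least three points per side;
the breakpoint minimizing the weighted SSE wins, ties breaking toward
lower temperature. The tie tolerance is an absolute floor scaled to the
weighted data variance, so exactly-linear data (SSE ≈ 0 everywhere at
floating-point noise level) deterministically return the lowest candidate.

**QENS decomposition.** Per Q the model is

    S(Q, ω) = a₀ R(ω) + a₁ L(Γ₁)⊗R + a₂ L(Γ₂)⊗R + b,

with R a Gaussian of the instrument FWHM, L area-normalized Lorentzians and
b a flat background. Lorentzian⊗Gaussian is evaluated as the closed-form
Voigt profile in the fitter. Fits are per-Q and independent (failures stay
localized), followed by weighted jump-diffusion dispersion fits
Γ(Q) = ħDQ²/(1 + DQ²τ) for each population; a Fickian line through the
origin is the fallback when τ collapses to zero. The two-stage design
(per-Q, then dispersion) mirrors standard practice; a global fit across Q
is out of scope.

**Immobile fraction.** The elastic fraction a₀/(a₀+a₁+a₂) per Q is
combined over Q by an inverse-variance-weighted mean. Three details matter:

1. *Per-Q variance.* Two curvature-based estimates are computed and the
   larger used: (i) the delta method over the nonlinear-fit covariance of
   (a₀, a₁, a₂) with widths marginalized, which captures the
   amplitude/width tradeoff but collapses spuriously when an amplitude
   sits on its non-negativity bound; (ii) the covariance of the linear
   amplitude subproblem at the fitted widths (exact Fisher information for
   fixed widths), which is immune to bound pathologies and inflates
   correctly under elastic/Lorentzian collinearity.
2. *Resolution identifiability guard.* Q values whose fitted quasi-elastic
   widths are buried far inside the resolution width (narrow component
   < 5% of the Gaussian sigma, or broad component < 25%) are flagged
   `unresolved` and excluded: there the elastic/Lorentzian split is not
   constrained by the data. Similarly, two Lorentzians converging within
   10% of each other trigger a flagged single-Lorentzian refit.
3. *Over-dispersion.* When the per-Q estimates scatter more than their
   claimed uncertainties allow, the combined sigma is scaled by
   √(χ²/dof) — the standard weighted-mean prescription.

At a configured immobile fraction of exactly zero the non-negativity
constraint truncates the per-Q estimates, so the estimator is biased
upward by roughly one per-Q sigma there; tests at that boundary assert
smallness and statistical consistency rather than symmetric coverage.

## Synthetic generator

The generator emulates two instrument classes: a backscattering elastic
setting (λ 6.27 Å, 0.9 μeV FWHM, Q 0.19–1.89 Å⁻¹, 20 Q bins) and two
time-of-flight QENS settings (5.1 Å/75 μeV over 0.21–1.98 Å⁻¹, 12 Q bins,
±1000 μeV; 10 Å/12 μeV over 0.1–1.01 Å⁻¹, 10 Q bins, ±400 μeV). Q-bin
counts and energy windows are reduction-level choices, not hardware facts.

Three fixture models mirror 30S/50S ribosomal subunit samples in 3 M salt.
Their immobile fractions (6.3/6.3/9.3%), water contents (65/62/67%),
reference MSDs (17.9/16.3/12.1 Å²) and force constants (0.016/0.018/0.034
N/m) are the published values; the KCl immobile fraction reuses the NaCl
number because none was published. The above-kink MSD slope is derived
from the force constant (slope = 2k_B/⟨k⟩); the below-kink slope is a
quarter of it, which reproduces the reported flatter low-temperature
branch with MSD near 10 Å² at the lowest temperatures. Water dynamics
parameters (free: D = 0.23 Å²/ps, τ = 1.1 ps; hydration: D = 0.05 Å²/ps,
τ = 5 ps) are literature-scale stand-ins for bulk-like and surface-slowed
water; no published per-population values were available, so recovery
tests always compare against whatever is configured, never against
absolute water parameters. The mobile hydrogen pool is split
free:hydration = 2:1, a plausible ratio for ~65% hydration; nothing
downstream depends on this choice beyond recovery consistency.

The elastic generator produces exp(−⟨u²⟩Q²/6) with the water populations
contributing nothing inside the narrow elastic window (their quasi-elastic
broadening lies far outside ±0.45 μeV). The QENS generator convolves
area-normalized Lorentzians with the Gaussian resolution *numerically*:
the grid is extended by the full kernel support (8σ), keeping the edge
error below 10⁻⁶ of the peak, and internally refined up to 64× when a
Lorentzian is narrower than the grid step, since sampling a sub-grid-width
Lorentzian directly would alias badly. The refined discrete convolution
agrees with the closed-form Voigt profile to ~10⁻¹⁵ of the peak, so the
generator (numeric) and the fitter (closed form) constitute genuinely
different code paths.

Counting noise is Poisson: expected rates are scaled so the most intense
bin has `counts_scale` expected counts (default 10⁵), draws are returned
in raw counts with √N uncertainties (floored at one count) and the scale
factor recorded as the monitor. Sample, empty-cell and vanadium runs get
independent noise streams derived from one seed. Generation is
bit-reproducible for a fixed seed.

What the generator does *not* emulate: non-Gaussian instrument resolution
functions, detector-geometry and self-shielding effects, multiple
scattering (safe for transmissions above 0.9), anharmonic or
distribution-of-MSD elastic models, and a third Lorentzian for internal
fast motions (absorbed into the elastic fraction on the 10 ps scale).
Passing recovery tests therefore demonstrates the correctness of the
analysis chain under the stated model, not robustness to these real-world
complications.

## Reduction chain

Monitor normalization, empty-cell subtraction scaled by a scalar
transmission (default fixture value 0.93; only a ">0.9" bound is typically
known), and per-Q vanadium division, in that order, each idempotence-
guarded by metadata flags and propagating uncertainties in quadrature.
The energy-resolution half of the vanadium correction is realized
implicitly by fitting resolution-convolved models rather than by
deconvolution, which is numerically safer and standard. On noiseless data
the chain equals its closed-form composition to machine precision.

## Numerical choices

- Per-Q QENS fits: bounded Levenberg–Marquardt (lmfit) with amplitudes
  ≥ 0 and HWHMs in (0, window]. Start points come from a deterministic
  coarse grid of width pairs scored by non-negative linear amplitude fits
  (NNLS); the two best-scoring pairs seed the optimizer. Converged fits
  are polished by restarting from the solution (resetting the trust
  region), which matters in the flat valleys of nearly-degenerate
  components; "tolerance too small" returns from MINPACK are accepted as
  converged. Function evaluations are capped at 4000 per start.
- Elastic fits are weighted linear algebra throughout (closed form, no
  iteration); covariances come from (XᵀWX)⁻¹, scaled by residual variance
  only when point sigmas are unavailable.
- Temperatures are kelvin everywhere (37 °C = 310.15 K); energies μeV;
  lengths Å; diffusion Å²/ps with cm²/s conversions only in reports.
- Problem sizes in the test suite: elastic scans use the full 20 × 13
  (Q × T) grid; QENS recovery uses the full 12 × 401 (Q × ω) grid; the
  100-seed estimator-calibration suites run on reduced grids chosen to
  keep the estimator well inside its validity range.

## Known limitations

- The immobile-fraction estimator carries a small O(σ²) nonlinear bias
  (well below one percent of the value at 10⁵ peak counts) inherent to
  bounded nonlinear fitting; it is negligible against the reported
  uncertainties but measurable with very many seeds.
- Dispersion fits treat per-Q width estimates as independent; width/width
  covariances across populations at the same Q are ignored.
- The file dialect stores complete regular grids only (no masked
  detectors).
- Fickian vs jump-diffusion model selection is by τ-bound collapse, not by
  an information criterion.
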