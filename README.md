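# ribodyn

Analysis of incoherent neutron-scattering measurements of biomolecular
thermal dynamics, built around the two complementary experiments used to
characterize large complexes such as ribosomal subunits in high-salt
solvent:

* **Elastic fixed-window temperature scans** (backscattering, ~1 ns window):
  the elastic intensity obeys the Gaussian approximation
  `S_el(Q, T) ∝ exp(−⟨u²⟩(T) Q²/6)`, so the slope of `ln S_el` versus `Q²`
  yields the hydrogen mean-square displacement ⟨u²⟩ at each temperature.
  Above the free-water freezing kink (~273 K), ⟨u²⟩ grows linearly with T
  and the quasi-harmonic relation `⟨k⟩ = 0.002761 / (d⟨u²⟩/dT)` converts the
  slope (Å²/K) into an effective force constant — the *resilience* — in N/m.

* **Quasi-elastic spectra (QENS)** (time-of-flight, ~10 ps window): each
  spectrum is decomposed per Q into a resolution-shaped elastic line plus
  two Lorentzians convolved with the Gaussian resolution,
  `S(Q, ω) = a₀R(ω) + a₁L(Γ₁)⊗R + a₂L(Γ₂)⊗R + b`.
  The Lorentzian half-widths follow jump diffusion,
  `Γ(Q) = ħDQ²/(1 + DQ²τ)`, giving diffusion coefficients and residence
  times for hydration and free water, and `a₀/(a₀+a₁+a₂)` estimates the
  fraction of hydrogen atoms immobile on the instrument timescale.

Raw data for this kind of measurement are rarely deposited, so `ribodyn`
ships a synthetic generator that emulates an
IN16-style backscattering elastic scan (λ = 6.27 Å, 0.9 μeV FWHM) and
IN5-style time-of-flight QENS (5.1 Å/75 μeV and 10 Å/12 μeV) for three
fixture samples that mirror 30S and 50S ribosomal subunits in 3 M NaCl or
KCl. Every analysis stage is therefore verifiable end to end by parameter
recovery: simulate with known ground truth, reduce, fit, compare.

The standard reduction chain (monitor normalization, transmission-scaled
empty-cell subtraction, vanadium division for detector efficiency and
absolute calibration) is implemented with first-order error propagation and
idempotence guards.

## Worked example

```python
import numpy as np
import ribodyn as rd

model = rd.fixture_catalog()["h30s_nacl"]      # 30S subunit, 3 M NaCl
in16 = rd.INSTRUMENTS["IN16"]

sample, empty, vanadium = rd.simulate_elastic_experiment(
    model, in16, np.arange(250.0, 311.0, 5.0),
    rd.NoiseSpec("poisson", counts_scale=1e5, seed=42),
)
reduced = rd.reduce_chain(sample, empty, vanadium)
series = rd.fit_msd(reduced, q_window=(0.34, 0.85))
fc = rd.fit_force_constant(series, t_min=270.0)
print(f"<k>  = {fc.k_eff:.4f} +/- {fc.k_sigma:.4f} N/m")
print(f"MSD(37C) = {fc.msd_at_ref:.2f} +/- {fc.msd_at_ref_sigma:.2f} A^2")
```

prints

```
<k>  = 0.0162 +/- 0.0003 N/m
MSD(37C) = 17.95 +/- 0.06 A^2
```

i.e. the pipeline recovers the configured ground truth of this fixture
(0.016 N/m, 17.9 Å²) within its statistical uncertainty: the 30S-like
sample is soft, with nanosecond fluctuation amplitudes near 18 Å² at 37 °C.
The same round trip on the 50S-like fixture gives ⟨k⟩ ≈ 0.033 N/m and
MSD ≈ 12.1 Å² — a factor-2 stiffer complex with 1.5-fold smaller
amplitudes.

The same objects can be driven from the shell:

```bash
ribodyn simulate --sample h30s_nacl --out sim/ --seed 42
ribodyn reduce --sample sim/h30s_nacl_elastic.nstsv \
    --empty sim/h30s_nacl_elastic_empty.nstsv \
    --vanadium sim/vanadium_in16.nstsv --out reduced.nstsv
ribodyn fit-elastic --scan reduced.nstsv --qmin 0.34 --qmax 0.85 \
    --tmin 270 --out fit.json
```

Datasets are exchanged in NSTSV, a self-describing tab-separated text
format (`#`-prefixed key/value header plus long-format rows) that keeps
fixtures diff-able.

## Layout

- `src/ribodyn/datasets.py` — domain containers and validation
- `src/ribodyn/nstsv.py` — text dataset format
- `src/ribodyn/simulate.py` — synthetic instrument emulation
- `src/ribodyn/reduction.py` — correction chain
- `src/ribodyn/elastic.py` — MSD extraction, force constants, kink search
- `src/ribodyn/qens.py` — spectral decomposition and water dynamics
- `src/ribodyn/report.py`, `cli.py` — pipeline orchestration and CLI
- `docs/methods.md` — model assumptions, conventions and numerical choices
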