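"""Pipeline orchestration and machine-readable reports.

A :class:`RunConfig` describes which fixtures (or explicit sample models) to
simulate, the instrument settings and analysis windows, and the noise/seed
conditions. :func:`run_pipeline` executes simulate -> reduce -> fit for the
elastic and/or quasi-elastic branch and returns a JSON-serializable report
with a force-constant table (resilience <k> and MSD at 37 C per sample) and
an immobile-fraction block. :func:`compare_samples` forms ratio summaries
between two reports with propagated uncertainties.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import yaml

from . import __version__
from .constants import (
    A2_PER_PS_TO_CM2_PER_S,
    FORCE_CONSTANT_PREFACTOR,
    GAUSSIAN_MSD_DIVISOR,
    T_REF_K,
)
from .datasets import INSTRUMENTS, InstrumentConfig, SampleModel, ValidationError
from .elastic import fit_force_constant, fit_msd
from .qens import fit_qens
from .reduction import reduce_chain
from .simulate import (
    NoiseSpec,
    fixture_catalog,
    simulate_elastic_experiment,
    simulate_qens_experiment,
)

__all__ = ["RunConfig", "run_pipeline", "compare_samples", "write_report"]


def _resolve_instrument(value) -> InstrumentConfig:
    if isinstance(value, InstrumentConfig):
        return value
    if isinstance(value, str):
        if value not in INSTRUMENTS:
            raise ValidationError(
                f"unknown instrument preset {value!r}; "
                f"known: {sorted(INSTRUMENTS)}"
            )
        return INSTRUMENTS[value]
    return InstrumentConfig(**value)


def _resolve_sample(value) -> SampleModel:
    if isinstance(value, SampleModel):
        return value
    if isinstance(value, str):
        catalog = fixture_catalog()
        if value not in catalog:
            raise ValidationError(
                f"unknown fixture {value!r}; known: {sorted(catalog)}"
            )
        return catalog[value]
    return SampleModel(**value)


@dataclass
class RunConfig:
    """Configuration of one simulation + analysis run."""

    samples: list = field(default_factory=lambda: ["h30s_nacl", "h30s_kcl",
                                                   "h50s_nacl"])
    instrument_elastic: object = "IN16"
    instrument_qens: object = "IN5_5.1A"
    temperatures: tuple = (250.0, 310.0, 5.0)  # (start, stop, step), K
    qens_temperature: float = 298.0
    q_window: tuple = (0.34, 0.85)  # 1/A, elastic MSD window
    t_min: float = 270.0  # K, force-constant fit threshold
    noise_mode: str = "poisson"
    counts_scale: float = 1e5
    seed: int = 0
    empty_level: float = 0.05
    transmission: float = 0.93
    do_elastic: bool = True
    do_qens: bool = True

    def __post_init__(self):
        inst = _resolve_instrument(self.instrument_elastic)
        lo, hi = self.q_window
        if not (inst.q_min <= lo < hi <= inst.q_max):
            raise ValidationError(
                f"q_window {self.q_window} outside instrument range "
                f"[{inst.q_min}, {inst.q_max}]"
            )
        for s in self.samples:
            _resolve_sample(s)

    @classmethod
    def from_yaml(cls, path) -> "RunConfig":
        raw = yaml.safe_load(Path(path).read_text()) or {}
        known = {f for f in cls.__dataclass_fields__}
        unknown = set(raw) - known
        if unknown:
            raise ValidationError(f"unknown config keys: {sorted(unknown)}")
        if "temperatures" in raw:
            raw["temperatures"] = tuple(raw["temperatures"])
        if "q_window" in raw:
            raw["q_window"] = tuple(raw["q_window"])
        return cls(**raw)

    def temperature_list(self) -> np.ndarray:
        start, stop, step = self.temperatures
        return np.arange(start, stop + 0.5 * step, step)


def _noise(config: RunConfig, offset: int) -> NoiseSpec:
    return NoiseSpec(config.noise_mode, config.counts_scale,
                     config.seed + offset)


def run_elastic_branch(model, config: RunConfig, noise: NoiseSpec) -> dict:
    instrument = _resolve_instrument(config.instrument_elastic)
    sample, empty, vanadium = simulate_elastic_experiment(
        model, instrument, config.temperature_list(), noise,
        empty_level=config.empty_level, transmission=config.transmission,
    )
    reduced = reduce_chain(sample, empty, vanadium)
    series = fit_msd(reduced, config.q_window)
    fc = fit_force_constant(series, config.t_min)
    return {
        "k_eff_N_per_m": fc.k_eff,
        "k_sigma": fc.k_sigma,
        "msd_at_37C_A2": fc.msd_at_ref,
        "msd_at_37C_sigma": fc.msd_at_ref_sigma,
        "slope_A2_per_K": fc.slope,
        "slope_sigma": fc.slope_sigma,
        "t_min_fit_K": fc.t_min_fit,
        "n_points_fit": fc.n_points_fit,
        "physical": fc.physical,
    }


def run_qens_branch(model, config: RunConfig, noise: NoiseSpec) -> dict:
    instrument = _resolve_instrument(config.instrument_qens)
    sample, empty, vanadium = simulate_qens_experiment(
        model, instrument, config.qens_temperature, noise,
        empty_level=config.empty_level, transmission=config.transmission,
    )
    reduced = reduce_chain(sample, empty, vanadium)
    fit = fit_qens(reduced, instrument.resolution_fwhm)
    return {
        "immobile_fraction": fit.immobile_fraction,
        "immobile_sigma": fit.immobile_sigma,
        "immobile_fraction_percent": 100.0 * fit.immobile_fraction,
        "immobile_sigma_percent": 100.0 * fit.immobile_sigma,
        "d_free_A2_per_ps": fit.d_free,
        "d_free_sigma": fit.d_free_sigma,
        "d_free_cm2_per_s": fit.d_free * A2_PER_PS_TO_CM2_PER_S,
        "tau_free_ps": fit.tau_free,
        "tau_free_sigma": fit.tau_free_sigma,
        "d_hyd_A2_per_ps": fit.d_hyd,
        "d_hyd_sigma": fit.d_hyd_sigma,
        "d_hyd_cm2_per_s": fit.d_hyd * A2_PER_PS_TO_CM2_PER_S,
        "tau_hyd_ps": fit.tau_hyd,
        "tau_hyd_sigma": fit.tau_hyd_sigma,
    }


def run_pipeline(config: RunConfig) -> dict:
    """Execute simulate -> reduce -> fit for every configured sample."""
    report = {
        "version": __version__,
        "seed": config.seed,
        "conventions": {
            "gaussian_msd_divisor": GAUSSIAN_MSD_DIVISOR,
            "force_constant_prefactor": FORCE_CONSTANT_PREFACTOR,
            "t_ref_K": T_REF_K,
        },
        "q_window": list(config.q_window),
        "t_min_K": config.t_min,
        "samples": {},
    }
    for i, entry in enumerate(config.samples):
        model = _resolve_sample(entry)
        block: dict = {}
        if config.do_elastic:
            block["force_constant"] = run_elastic_branch(
                model, config, _noise(config, 10 * i)
            )
        if config.do_qens:
            block["qens"] = run_qens_branch(
                model, config, _noise(config, 10 * i + 5)
            )
        report["samples"][model.name] = block
    return report


def write_report(report: dict, path) -> None:
    """Serialize a report deterministically (sorted keys, no timestamps)."""
    Path(path).write_text(
        json.dumps(report, indent=2, sort_keys=True, allow_nan=True) + "\n"
    )


def _ratio(a, sa, b, sb):
    r = a / b
    sig = abs(r) * np.sqrt((sa / a) ** 2 + (sb / b) ** 2) if a and b else float("nan")
    return float(r), float(sig)


def compare_samples(report_a: dict, report_b: dict,
                    sample_a: str | None = None,
                    sample_b: str | None = None) -> dict:
    """Ratio summary (first over second) of force constants and MSDs.

    ``sample_a`` / ``sample_b`` select samples inside multi-sample reports
    (default: the first). Raises KeyError when a force-constant block is
    missing.
    """
    def pick(report, name):
        samples = report["samples"]
        key = name if name is not None else next(iter(samples))
        block = samples[key]
        if "force_constant" not in block:
            raise KeyError(f"report for {key!r} has no force_constant block")
        return key, block["force_constant"]

    name_a, fc_a = pick(report_a, sample_a)
    name_b, fc_b = pick(report_b, sample_b)
    k_ratio, k_sig = _ratio(
        fc_a["k_eff_N_per_m"], fc_a["k_sigma"],
        fc_b["k_eff_N_per_m"], fc_b["k_sigma"],
    )
    m_ratio, m_sig = _ratio(
        fc_a["msd_at_37C_A2"], fc_a["msd_at_37C_sigma"],
        fc_b["msd_at_37C_A2"], fc_b["msd_at_37C_sigma"],
    )
    return {
        "samples": [name_a, name_b],
        "k_ratio": k_ratio,
        "k_ratio_sigma": k_sig,
        "k_ratio_rounded_int": int(round(k_ratio)),
        "k_ratio_rounded_1dp": round(k_ratio, 1),
        "msd_ratio": m_ratio,
        "msd_ratio_sigma": m_sig,
        "msd_ratio_rounded_int": int(round(m_ratio)),
        "msd_ratio_rounded_1dp": round(m_ratio, 1),
    }
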