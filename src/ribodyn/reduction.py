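"""Correction chain for raw datasets.

Three steps, applied in order by :func:`reduce_chain`:

1. monitor (neutron-flux) normalization,
2. empty-cell subtraction scaled by the sample transmission,
3. vanadium division (detector efficiency + absolute calibration).

Each step is idempotence-guarded through reduction-state flags and
propagates uncertainties to first order. Transmission is a scalar per
sample; multiple scattering is neglected (valid for transmissions above
~0.9). The energy-resolution part of the vanadium correction is realized
implicitly downstream by fitting resolution-convolved models rather than by
deconvolution.
"""

from __future__ import annotations

import dataclasses

import numpy as np

from .datasets import (
    ElasticScan,
    SpectrumSet,
    ValidationError,
    VanadiumReference,
)

__all__ = [
    "ReductionError",
    "normalize_to_monitor",
    "subtract_empty_cell",
    "vanadium_normalize",
    "reduce_chain",
]


class ReductionError(ValueError):
    """A correction step was applied out of contract."""


def _copy_with(obj, **changes):
    meta = {**obj.metadata,
            "reduction_state": list(obj.metadata.get("reduction_state", []))}
    return dataclasses.replace(obj, metadata=meta, **changes)


def _require_unflagged(obj, flag: str):
    if flag in obj.metadata.get("reduction_state", []):
        raise ReductionError(f"step {flag!r} already applied")


def _check_same_grids(a, b):
    bad = []
    if not np.allclose(a.q_grid, b.q_grid, rtol=1e-9, atol=0):
        bad.append("q")
    if isinstance(a, SpectrumSet) and isinstance(b, SpectrumSet):
        if not np.allclose(a.omega_grid, b.omega_grid, rtol=1e-9, atol=0):
            bad.append("omega")
    elif isinstance(a, ElasticScan) and isinstance(b, ElasticScan):
        if (a.temperatures.shape != b.temperatures.shape
                or not np.allclose(a.temperatures, b.temperatures,
                                   rtol=1e-9, atol=0)):
            bad.append("temperature")
    else:
        bad.append("dataset kind")
    if bad:
        raise ReductionError(f"grid mismatch on axes: {', '.join(bad)}")


def normalize_to_monitor(obj):
    """Divide intensities and uncertainties by the recorded monitor counts."""
    _require_unflagged(obj, "monitor_normalized")
    if isinstance(obj, ElasticScan):
        mon = obj.monitor[None, :]
    else:
        mon = obj.monitor
    out = _copy_with(
        obj,
        intensity=obj.intensity / mon,
        sigma=obj.sigma / mon,
    )
    out.metadata["reduction_state"].append("monitor_normalized")
    return out


def subtract_empty_cell(obj, empty, transmission: float):
    """Subtract the transmission-scaled empty-cell signal.

    ``intensity -= transmission * empty.intensity``; uncertainties combine
    in quadrature. Both datasets must share their grids exactly.
    """
    _require_unflagged(obj, "empty_cell_subtracted")
    if not (0 < transmission <= 1):
        raise ValidationError("transmission must be in (0, 1]")
    _check_same_grids(obj, empty)
    out = _copy_with(
        obj,
        intensity=obj.intensity - transmission * empty.intensity,
        sigma=np.sqrt(obj.sigma**2 + (transmission * empty.sigma) ** 2),
    )
    out.metadata["reduction_state"].append("empty_cell_subtracted")
    return out


def vanadium_normalize(obj, vanadium: VanadiumReference):
    """Divide per Q by the vanadium reference (detector efficiency + scale).

    Relative uncertainties combine in quadrature. Raises on any
    non-positive vanadium bin, naming the Q value.
    """
    _require_unflagged(obj, "vanadium_normalized")
    if (obj.q_grid.shape != vanadium.q_grid.shape
            or not np.allclose(obj.q_grid, vanadium.q_grid, rtol=1e-9, atol=0)):
        raise ReductionError("grid mismatch on axes: q")
    bad = np.nonzero(vanadium.intensity <= 0)[0]
    if bad.size:
        raise ReductionError(
            f"vanadium intensity <= 0 at Q = {vanadium.q_grid[bad[0]]:g} 1/A"
        )
    v = vanadium.intensity[:, None]
    vs = vanadium.sigma[:, None]
    out = _copy_with(
        obj,
        intensity=obj.intensity / v,
        sigma=np.sqrt((obj.sigma / v) ** 2 + (obj.intensity * vs / v**2) ** 2),
    )
    out.metadata["reduction_state"].append("vanadium_normalized")
    return out


def reduce_chain(sample, empty, vanadium, transmission: float | None = None):
    """Apply monitor normalization, empty-cell subtraction and vanadium
    division, in that order, recording provenance in the metadata.

    ``transmission`` defaults to the sample's recorded value. The empty-cell
    dataset is monitor-normalized first if it has not been already.
    """
    if transmission is None:
        transmission = sample.transmission
    out = normalize_to_monitor(sample)
    if "monitor_normalized" not in empty.metadata.get("reduction_state", []):
        empty = normalize_to_monitor(empty)
    out = subtract_empty_cell(out, empty, transmission)
    out = vanadium_normalize(out, vanadium)
    out.metadata["provenance"] = [
        {"step": "normalize_to_monitor"},
        {"step": "subtract_empty_cell", "transmission": float(transmission)},
        {"step": "vanadium_normalize"},
    ]
    return out
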