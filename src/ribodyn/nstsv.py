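"""Reader/writer for the NSTSV spectrum/scan dialect.

NSTSV is a self-describing tab-separated text format: a block of
``# key<TAB>value`` header lines, then a column-header row and long-format
data rows. Three kinds exist:

* ``qens``     — columns ``q  omega  intensity  sigma``
* ``elastic``  — columns ``q  temperature  intensity  sigma``
* ``vanadium`` — columns ``q  intensity  sigma``

Files are UTF-8 with LF line endings and '.' decimal separators. Numeric
fields use the shortest decimal representation that reproduces the double
exactly, so a write/load round trip is lossless and a fixed point, and
output is byte-deterministic for identical objects (fixed key order, no
timestamps).
"""

from __future__ import annotations

import io
from pathlib import Path

import numpy as np
import pandas as pd

from .datasets import (
    ElasticScan,
    SpectrumSet,
    ValidationError,
    VanadiumReference,
)

__all__ = ["ParseError", "load_dataset", "write_dataset"]

_REQUIRED_KEYS = (
    "kind", "instrument", "sample", "monitor", "transmission",
    "reduction_state", "q_units", "omega_units",
)

_COLUMNS = {
    "qens": ["q", "omega", "intensity", "sigma"],
    "elastic": ["q", "temperature", "intensity", "sigma"],
    "vanadium": ["q", "intensity", "sigma"],
}


class ParseError(ValueError):
    """Malformed NSTSV content; the message names the offending line."""


def _fmt(x: float) -> str:
    # shortest representation that round-trips the double exactly
    return repr(float(x))


def _header_lines(kind: str, obj) -> list:
    meta = obj.metadata if hasattr(obj, "metadata") else {}
    state = meta.get("reduction_state", [])
    lines = [
        ("kind", kind),
        ("instrument", str(meta.get("instrument", "") or "-")),
        ("sample", str(meta.get("sample", "") or "-")),
    ]
    if kind == "qens":
        lines.append(("temperature_K", _fmt(obj.temperature)))
        lines.append(("monitor", _fmt(obj.monitor)))
        lines.append(("transmission", _fmt(obj.transmission)))
    elif kind == "elastic":
        lines.append(("temperature_column", "temperature"))
        lines.append(("monitor", ",".join(_fmt(m) for m in obj.monitor)))
        lines.append(("transmission", _fmt(obj.transmission)))
    else:  # vanadium
        lines.append(("temperature_K", str(meta.get("temperature_K", "nan"))))
        lines.append(("monitor", "1"))
        lines.append(("transmission", "1"))
    lines.append(("reduction_state", ",".join(state) if state else "-"))
    lines.append(("q_units", "inv_angstrom"))
    lines.append(("omega_units", "ueV"))
    return lines


def write_dataset(obj, path) -> None:
    """Write a dataset to ``path`` in NSTSV; output is byte-deterministic."""
    if isinstance(obj, SpectrumSet):
        kind = "qens"
    elif isinstance(obj, ElasticScan):
        kind = "elastic"
    elif isinstance(obj, VanadiumReference):
        kind = "vanadium"
    else:
        raise TypeError(f"cannot serialize {type(obj).__name__}")

    buf = io.StringIO()
    for key, value in _header_lines(kind, obj):
        buf.write(f"# {key}\t{value}\n")
    buf.write("\t".join(_COLUMNS[kind]) + "\n")

    if kind == "qens":
        for i, q in enumerate(obj.q_grid):
            for j, w in enumerate(obj.omega_grid):
                buf.write(
                    f"{_fmt(q)}\t{_fmt(w)}\t{_fmt(obj.intensity[i, j])}"
                    f"\t{_fmt(obj.sigma[i, j])}\n"
                )
    elif kind == "elastic":
        for i, q in enumerate(obj.q_grid):
            for j, t in enumerate(obj.temperatures):
                buf.write(
                    f"{_fmt(q)}\t{_fmt(t)}\t{_fmt(obj.intensity[i, j])}"
                    f"\t{_fmt(obj.sigma[i, j])}\n"
                )
    else:
        for i, q in enumerate(obj.q_grid):
            buf.write(
                f"{_fmt(q)}\t{_fmt(obj.intensity[i])}\t{_fmt(obj.sigma[i])}\n"
            )

    Path(path).write_bytes(buf.getvalue().encode("utf-8"))


def _parse_header(lines) -> tuple[dict, int]:
    header = {}
    for lineno, line in enumerate(lines, start=1):
        if not line.startswith("#"):
            return header, lineno - 1
        body = line[1:].strip("\n")
        if body.startswith(" "):
            body = body[1:]
        if "\t" not in body:
            raise ParseError(
                f"line {lineno}: header line lacks a tab separator: {line!r}"
            )
        key, value = body.split("\t", 1)
        header[key.strip()] = value.strip()
    raise ParseError("file contains no data section")


def load_dataset(path, kind: str | None = None):
    """Load an NSTSV file, validating grids and metadata.

    ``kind`` (``qens`` | ``elastic`` | ``vanadium``) is checked against the
    file header when given. Returns the matching dataset type.
    """
    text = Path(path).read_text(encoding="utf-8")
    lines = text.splitlines(keepends=True)
    header, n_header = _parse_header(lines)

    for key in _REQUIRED_KEYS:
        if key == "monitor" and "monitor" not in header:
            raise ParseError("missing required header key 'monitor'")
        if key not in header and key != "monitor":
            raise ParseError(f"missing required header key {key!r}")
    if "temperature_K" not in header and "temperature_column" not in header:
        raise ParseError(
            "header must contain temperature_K or temperature_column"
        )
    file_kind = header["kind"]
    if file_kind not in _COLUMNS:
        raise ParseError(f"unknown kind {file_kind!r}")
    if kind is not None and kind != file_kind:
        raise ParseError(f"expected kind {kind!r}, file says {file_kind!r}")
    if header["q_units"] != "inv_angstrom" or header["omega_units"] != "ueV":
        raise ParseError("unsupported units in header")

    body = "".join(lines[n_header:])
    try:
        df = pd.read_csv(io.StringIO(body), sep="\t", dtype=float,
                         float_precision="round_trip")
    except Exception as exc:  # pragma: no cover - pandas message passthrough
        raise ParseError(f"data section unreadable: {exc}") from None
    expected = _COLUMNS[file_kind]
    if list(df.columns) != expected:
        raise ParseError(
            f"line {n_header + 1}: expected columns {expected}, "
            f"got {list(df.columns)}"
        )
    if df.isna().any().any():
        raise ParseError("data section contains missing values")

    state = [] if header["reduction_state"] in ("-", "") else header[
        "reduction_state"].split(",")
    meta = {
        "sample": header["sample"] if header["sample"] != "-" else "",
        "instrument": header["instrument"] if header["instrument"] != "-" else "",
        "reduction_state": state,
    }
    for key, value in header.items():
        if key not in (*_REQUIRED_KEYS, "temperature_K", "temperature_column"):
            meta[key] = value

    q_vals = df["q"].to_numpy()
    q_grid = q_vals[np.sort(np.unique(q_vals, return_index=True)[1])]
    if np.any(np.diff(q_grid) <= 0):
        raise ValidationError("q grid is not strictly increasing")

    if file_kind == "vanadium":
        if "temperature_K" in header:
            meta["temperature_K"] = header["temperature_K"]
        return VanadiumReference(
            q_grid=q_grid,
            intensity=df["intensity"].to_numpy(),
            sigma=df["sigma"].to_numpy(),
            metadata=meta,
        )

    inner_col = "omega" if file_kind == "qens" else "temperature"
    n_q = q_grid.size
    if len(df) % n_q:
        raise ValidationError("data rows do not form a complete (q, axis) grid")
    n_inner = len(df) // n_q
    inner = df[inner_col].to_numpy()[:n_inner]
    if np.any(np.diff(inner) <= 0):
        raise ValidationError(f"{inner_col} grid is not strictly increasing")
    expected_q = np.repeat(q_grid, n_inner)
    expected_inner = np.tile(inner, n_q)
    if not (np.array_equal(q_vals, expected_q)
            and np.array_equal(df[inner_col].to_numpy(), expected_inner)):
        raise ValidationError(
            "data rows are not in canonical q-major long-format order"
        )
    intensity = df["intensity"].to_numpy().reshape(n_q, n_inner)
    sigma = df["sigma"].to_numpy().reshape(n_q, n_inner)

    if file_kind == "qens":
        return SpectrumSet(
            q_grid=q_grid,
            omega_grid=inner,
            intensity=intensity,
            sigma=sigma,
            temperature=float(header["temperature_K"]),
            monitor=float(header["monitor"]),
            transmission=float(header["transmission"]),
            metadata=meta,
        )
    monitor = np.array([float(x) for x in header["monitor"].split(",")])
    if monitor.size == 1:
        monitor = np.full(n_inner, monitor[0])
    return ElasticScan(
        q_grid=q_grid,
        temperatures=inner,
        intensity=intensity,
        sigma=sigma,
        monitor=monitor,
        transmission=float(header["transmission"]),
        metadata=meta,
    )
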