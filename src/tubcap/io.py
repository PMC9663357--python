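"""Delimited-text trace format and JSON serialization.

Trace files are plain CSV with commented metadata header lines::

    # kind=step
    # U_1=-80
    # U_2=-75
    time_ms,current_nA[,voltage_mV,us_mV,ut_mV]
    -5,0.747096,...

Time columns may be ``time_ms`` or ``time_s``; current columns
``current_nA`` or ``current_pA``.  Everything is converted to the canonical
units (ms, nA) on read.
"""

from __future__ import annotations

import json
from pathlib import Path

import numpy as np

from .biexp import BiexpParams
from .extract import ExtractionResult
from .simulate import CurrentTrace

__all__ = [
    "read_trace",
    "write_trace",
    "read_biexp",
    "write_biexp",
    "write_result",
]

_TIME_COLS = {"time_ms": 1.0, "time_s": 1000.0}
_CURRENT_COLS = {"current_nA": 1.0, "current_pA": 1e-3}
_OPTIONAL_COLS = ("voltage_mV", "us_mV", "ut_mV")
_FLOAT_FMT = "%.17g"  # exact float round trip


def _coerce(value: str):
    try:
        return int(value)
    except ValueError:
        pass
    try:
        return float(value)
    except ValueError:
        pass
    if value in ("True", "False"):
        return value == "True"
    if value == "None":
        return None
    return value


def write_trace(trace: CurrentTrace, path) -> None:
    """Write a trace in the package's CSV dialect (lossless to 1e-12)."""
    path = Path(path)
    columns = [("time_ms", trace.t), ("current_nA", trace.J)]
    for name, arr in (("voltage_mV", trace.U), ("us_mV", trace.U_s),
                      ("ut_mV", trace.U_t)):
        if arr is not None:
            columns.append((name, arr))
    with path.open("w") as fh:
        for key, value in trace.meta.items():
            if isinstance(value, (str, int, float, bool)) or value is None:
                fh.write(f"# {key}={value}\n")
        fh.write(",".join(name for name, _ in columns) + "\n")
        data = np.column_stack([arr for _, arr in columns])
        np.savetxt(fh, data, delimiter=",", fmt=_FLOAT_FMT)


def read_trace(path) -> CurrentTrace:
    """Read a trace file, converting units and validating the grid.

    Malformed data rows are rejected with their line numbers; a non-uniform
    time grid (deviation above 0.1% of the sample interval) is an error.
    """
    path = Path(path)
    meta: dict = {}
    header: list[str] | None = None
    rows: list[list[float]] = []
    bad: list[int] = []
    with path.open() as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.strip()
            if not line:
                continue
            if line.startswith("#"):
                body = line.lstrip("#").strip()
                if "=" in body:
                    key, _, value = body.partition("=")
                    meta[key.strip()] = _coerce(value.strip())
                continue
            if header is None:
                header = [c.strip() for c in line.split(",")]
                continue
            parts = line.split(",")
            if len(parts) != len(header):
                bad.append(lineno)
                continue
            try:
                rows.append([float(x) for x in parts])
            except ValueError:
                bad.append(lineno)
    if header is None:
        raise ValueError(f"{path}: no header line found")
    if bad:
        shown = ", ".join(map(str, bad[:10]))
        raise ValueError(f"{path}: malformed data rows at lines {shown}")
    if not rows:
        raise ValueError(f"{path}: no data rows")

    time_cols = [c for c in header if c in _TIME_COLS]
    cur_cols = [c for c in header if c in _CURRENT_COLS]
    if not time_cols or not cur_cols:
        raise ValueError(
            f"{path}: header must name a time column ({list(_TIME_COLS)}) "
            f"and a current column ({list(_CURRENT_COLS)}); got {header}")
    data = np.asarray(rows)
    col = {name: data[:, i] for i, name in enumerate(header)}
    t = col[time_cols[0]] * _TIME_COLS[time_cols[0]]
    J = col[cur_cols[0]] * _CURRENT_COLS[cur_cols[0]]

    steps = np.diff(t)
    dt = float(np.median(steps))
    if dt <= 0 or np.any(np.abs(steps - dt) > 1e-3 * dt):
        raise ValueError(f"{path}: time grid is not uniform (tolerance 0.1% of dt)")

    return CurrentTrace(
        t=t, J=J,
        U=col.get("voltage_mV"),
        U_s=col.get("us_mV"),
        U_t=col.get("ut_mV"),
        meta=meta,
    )


def write_biexp(params: BiexpParams, path) -> None:
    with Path(path).open("w") as fh:
        json.dump(params.to_dict(), fh, indent=2)
        fh.write("\n")


def read_biexp(path) -> BiexpParams:
    with Path(path).open() as fh:
        return BiexpParams.from_dict(json.load(fh))


def write_result(result: ExtractionResult, path) -> None:
    with Path(path).open("w") as fh:
        json.dump(result.to_dict(), fh, indent=2)
        fh.write("\n")
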