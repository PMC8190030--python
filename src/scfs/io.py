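"""Readers and writers for the pipeline's on-disk formats.

Curve files are UTF-8 TSV with ``# key: value`` header lines carrying the
metadata, followed by the columns ``time_s  z_nm  deflection_nm  segment``.
Event tables are plain TSV.  Writing is deterministic: identical inputs
produce byte-identical files.
"""

from __future__ import annotations

import io as _io
from dataclasses import asdict
from pathlib import Path
from typing import Iterable, Sequence

import numpy as np
import pandas as pd

from .constants import DEFAULT_TEMPERATURE_K
from .datamodel import CurveMetadata, ForceCurve, RuptureEvent
from .errors import FormatError, ValidationError

__all__ = [
    "read_curve",
    "write_curve",
    "write_event_table",
    "read_event_table",
    "read_thermal_record",
    "write_thermal_record",
]

# header key <-> CurveMetadata field, with the unit spelled out in the key
_HEADER_FIELDS = [
    ("spring_constant_pN_per_nm", "spring_constant_k", float),
    ("velocity_um_per_s", "velocity_v", float),
    ("max_load_pN", "max_load", float),
    ("dwell_s", "dwell_time", float),
    ("sampling_rate_Hz", "sampling_rate", float),
    ("temperature_K", "temperature", float),
    ("condition", "condition_label", str),
    ("treatment", "treatment_label", str),
    ("curve_id", "curve_id", str),
]

_CURVE_COLUMNS = ["time_s", "z_nm", "deflection_nm", "segment"]

EVENT_COLUMNS = [
    "curve_id",
    "index",
    "separation_nm",
    "step_height_nm",
    "force_pN",
    "class",
    "loading_rate_pN_per_s",
    "pre_slope_pN_per_nm",
]

_FLOAT_FMT = "%.10g"


def _parse_headers(lines: Sequence[str]) -> tuple[CurveMetadata, int]:
    """Parse leading ``# key: value`` lines; returns metadata and the number
    of header lines consumed.  Missing keys fall back to the documented
    CurveMetadata defaults."""
    values: dict[str, object] = {}
    converters = {key: (attr, conv) for key, attr, conv in _HEADER_FIELDS}
    n_header = 0
    for lineno, line in enumerate(lines, start=1):
        if not line.startswith("#"):
            break
        n_header += 1
        body = line[1:].strip()
        if ":" not in body:
            raise FormatError(f"line {lineno}: malformed header {line.strip()!r} (expected '# key: value')")
        key, _, raw = body.partition(":")
        key = key.strip()
        raw = raw.strip()
        if key not in converters:
            raise FormatError(f"line {lineno}: unknown header key {key!r}")
        attr, conv = converters[key]
        try:
            values[attr] = conv(raw)
        except ValueError as exc:
            raise FormatError(f"line {lineno}: cannot parse value {raw!r} for {key!r}") from exc
    return CurveMetadata(**values), n_header


def read_curve(path: str | Path) -> ForceCurve:
    """Read a force curve from the TSV dialect of this package.

    Raises FormatError for malformed headers or columns and ValidationError
    for structurally invalid curves (non-monotone time, empty retract).
    """
    path = Path(path)
    lines = path.read_text(encoding="utf-8").splitlines()
    meta, n_header = _parse_headers(lines)
    body = "\n".join(lines[n_header:])
    try:
        table = pd.read_csv(_io.StringIO(body), sep="\t")
    except Exception as exc:  # pragma: no cover - pandas error text varies
        raise FormatError(f"{path}: cannot parse data table: {exc}") from exc
    missing = [c for c in _CURVE_COLUMNS if c not in table.columns]
    if missing:
        raise FormatError(f"{path}: missing columns {missing}")
    curve = ForceCurve(
        time=table["time_s"].to_numpy(dtype=float),
        z_position=table["z_nm"].to_numpy(dtype=float),
        deflection=table["deflection_nm"].to_numpy(dtype=float),
        segment_labels=table["segment"].to_numpy(dtype=object),
        metadata=meta,
    )
    curve.validate()
    return curve


def write_curve(curve: ForceCurve, path: str | Path) -> None:
    """Write a force curve; deterministic byte layout for identical input."""
    curve.validate()
    path = Path(path)
    meta = asdict(curve.metadata)
    with open(path, "w", encoding="utf-8", newline="\n") as fh:
        for key, attr, conv in _HEADER_FIELDS:
            value = meta[attr]
            if conv is float:
                fh.write(f"# {key}: {_FLOAT_FMT % value}\n")
            else:
                fh.write(f"# {key}: {value}\n")
        fh.write("\t".join(_CURVE_COLUMNS) + "\n")
        for t, z, d, s in zip(curve.time, curve.z_position, curve.deflection, curve.segment_labels):
            fh.write(f"{_FLOAT_FMT % t}\t{_FLOAT_FMT % z}\t{_FLOAT_FMT % d}\t{s}\n")


def write_event_table(events: Iterable[RuptureEvent], path: str | Path) -> None:
    """Write one row per rupture event, ordered by (curve_id, index)."""
    rows = sorted(events, key=lambda e: (e.curve_id, e.index))
    with open(path, "w", encoding="utf-8", newline="\n") as fh:
        fh.write("\t".join(EVENT_COLUMNS) + "\n")
        for e in rows:
            fh.write(
                "\t".join(
                    [
                        e.curve_id,
                        str(int(e.index)),
                        _FLOAT_FMT % e.separation_nm,
                        _FLOAT_FMT % e.step_height_d,
                        _FLOAT_FMT % e.force_F,
                        e.event_class,
                        _FLOAT_FMT % e.loading_rate_r,
                        _FLOAT_FMT % e.pre_slope,
                    ]
                )
                + "\n"
            )


def read_event_table(path: str | Path) -> list[RuptureEvent]:
    """Read an event table written by :func:`write_event_table`."""
    table = pd.read_csv(path, sep="\t")
    missing = [c for c in EVENT_COLUMNS if c not in table.columns]
    if missing:
        raise FormatError(f"{path}: missing columns {missing}")
    return [
        RuptureEvent(
            curve_id=str(row["curve_id"]),
            index=int(row["index"]),
            separation_nm=float(row["separation_nm"]),
            step_height_d=float(row["step_height_nm"]),
            force_F=float(row["force_pN"]),
            event_class=str(row["class"]),
            loading_rate_r=float(row["loading_rate_pN_per_s"]),
            pre_slope=float(row["pre_slope_pN_per_nm"]),
        )
        for row in table.to_dict(orient="records")
    ]


def write_thermal_record(
    deflection: np.ndarray, fs: float, path: str | Path, temperature: float = DEFAULT_TEMPERATURE_K
) -> None:
    """Write a thermal deflection time series as TSV (time_s, deflection_nm)."""
    t = np.arange(len(deflection)) / fs
    with open(path, "w", encoding="utf-8", newline="\n") as fh:
        fh.write(f"# sampling_rate_Hz: {_FLOAT_FMT % fs}\n")
        fh.write(f"# temperature_K: {_FLOAT_FMT % temperature}\n")
        fh.write("time_s\tdeflection_nm\n")
        for ti, di in zip(t, deflection):
            fh.write(f"{_FLOAT_FMT % ti}\t{_FLOAT_FMT % di}\n")


def read_thermal_record(path: str | Path):
    """Read a thermal record TSV; returns (deflection, fs, temperature).

    The sampling rate falls back to the median time spacing when no header
    is present.
    """
    path = Path(path)
    lines = path.read_text(encoding="utf-8").splitlines()
    fs = None
    temperature = DEFAULT_TEMPERATURE_K
    n_header = 0
    for lineno, line in enumerate(lines, start=1):
        if not line.startswith("#"):
            break
        n_header += 1
        body = line[1:].strip()
        if ":" not in body:
            raise FormatError(f"line {lineno}: malformed header {line.strip()!r}")
        key, _, raw = body.partition(":")
        key, raw = key.strip(), raw.strip()
        try:
            if key == "sampling_rate_Hz":
                fs = float(raw)
            elif key == "temperature_K":
                temperature = float(raw)
            else:
                raise FormatError(f"line {lineno}: unknown header key {key!r}")
        except ValueError as exc:
            raise FormatError(f"line {lineno}: cannot parse value {raw!r}") from exc
    table = pd.read_csv(_io.StringIO("\n".join(lines[n_header:])), sep="\t")
    if "deflection_nm" not in table.columns:
        raise FormatError(f"{path}: missing column deflection_nm")
    deflection = table["deflection_nm"].to_numpy(dtype=float)
    if fs is None:
        if "time_s" not in table.columns or len(table) < 2:
            raise FormatError(f"{path}: cannot infer sampling rate")
        dt = np.median(np.diff(table["time_s"].to_numpy(dtype=float)))
        if dt <= 0:
            raise ValidationError(f"{path}: non-monotone time")
        fs = 1.0 / dt
    return deflection, float(fs), float(temperature)
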