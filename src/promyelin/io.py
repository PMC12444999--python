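"""CSV and JSON I/O for traces, binary streams and impedance spectra.

Dialects: '.' decimal, no thousands separators, UTF-8, LF line endings.
Trace files carry a ``time_s`` column plus one mV column per channel
(``chA``..``chH``); spectrum files carry ``freq_hz, z_real_ohm, z_imag_ohm``.
Round-trips are lossless at full float precision (repr-level formatting).
"""

from __future__ import annotations

import json
from pathlib import Path
from typing import Dict, Mapping, Union

import numpy as np
import pandas as pd

from .channel_dynamics import PotentialTrace
from .digitization import BinaryTrace
from .impedance import ImpedanceSpectrum

__all__ = [
    "write_trace_csv",
    "read_trace_csv",
    "write_binary_csv",
    "read_binary_csv",
    "write_spectrum_csv",
    "read_spectrum_csv",
    "write_json_report",
]

PathLike = Union[str, Path]


class ParseError(ValueError):
    """Malformed input file (bad header, non-uniform grid, bad values)."""


def _column(ch: str) -> str:
    return f"ch{ch}"


def write_trace_csv(traces: Mapping[str, PotentialTrace], path: PathLike) -> None:
    """Write an ensemble sharing one time grid as ``time_s,chA,...``."""
    if not traces:
        raise ValueError("no traces to write")
    items = list(traces.items())
    t0 = items[0][1].t
    for ch, tr in items[1:]:
        if len(tr) != t0.size or not np.allclose(tr.t, t0):
            raise ValueError("traces do not share a common time grid")
    df = pd.DataFrame({"time_s": t0})
    for ch, tr in items:
        df[_column(ch)] = tr.v
    df.to_csv(path, index=False, lineterminator="\n", float_format="%.17g")


def read_trace_csv(path: PathLike) -> Dict[str, PotentialTrace]:
    """Read a multichannel trace CSV back into PotentialTrace objects."""
    df = pd.read_csv(path, float_precision="round_trip")
    if "time_s" not in df.columns:
        raise ParseError(f"{path}: missing required column 'time_s'")
    chans = [c for c in df.columns if c.startswith("ch") and len(c) == 3]
    if not chans:
        raise ParseError(f"{path}: no channel columns (chA..chH) found")
    t = df["time_s"].to_numpy(dtype=float)
    if t.size > 1:
        steps = np.diff(t)
        if (steps <= 0).any():
            bad = int(np.argmax(steps <= 0)) + 2  # 1-based, after header
            raise ParseError(f"{path}: time not strictly increasing at line {bad + 1}")
        dt = float(steps[0])
        if not np.allclose(steps, dt, rtol=1e-9):
            bad = int(np.argmax(~np.isclose(steps, dt, rtol=1e-9))) + 2
            raise ParseError(f"{path}: non-uniform sampling interval at line {bad + 1}")
    else:
        dt = 1.0
    out = {}
    for c in chans:
        ch = c[2:]
        out[ch] = PotentialTrace(
            channel_id=ch, t=t, v=df[c].to_numpy(dtype=float), dt=dt
        )
    return out


def write_binary_csv(traces: Mapping[str, BinaryTrace], path: PathLike) -> None:
    """Write binary state streams as ``time_s,chA,...`` with 0/1 entries."""
    if not traces:
        raise ValueError("no binary traces to write")
    items = list(traces.items())
    n = len(items[0][1])
    dt = items[0][1].dt
    for ch, tr in items[1:]:
        if len(tr) != n or tr.dt != dt:
            raise ValueError("binary traces do not share a common grid")
    df = pd.DataFrame({"time_s": np.arange(n) * dt})
    for ch, tr in items:
        df[_column(ch)] = tr.states.astype(int)
    df.to_csv(path, index=False, lineterminator="\n", float_format="%.17g")


def read_binary_csv(path: PathLike) -> Dict[str, BinaryTrace]:
    df = pd.read_csv(path, float_precision="round_trip")
    if "time_s" not in df.columns:
        raise ParseError(f"{path}: missing required column 'time_s'")
    t = df["time_s"].to_numpy(dtype=float)
    dt = float(t[1] - t[0]) if t.size > 1 else 1.0
    out = {}
    for c in df.columns:
        if not (c.startswith("ch") and len(c) == 3):
            continue
        vals = df[c].to_numpy()
        if not np.isin(vals, (0, 1)).all():
            raise ParseError(f"{path}: column {c} contains non-binary values")
        out[c[2:]] = BinaryTrace(
            channel_id=c[2:], states=vals.astype(np.int8),
            threshold_mv=0.0, dt=dt,
        )
    return out


def write_spectrum_csv(spectrum: ImpedanceSpectrum, path: PathLike) -> None:
    df = pd.DataFrame({
        "freq_hz": spectrum.freq,
        "z_real_ohm": spectrum.z.real,
        "z_imag_ohm": spectrum.z.imag,
    })
    df.to_csv(path, index=False, lineterminator="\n", float_format="%.17g")


def read_spectrum_csv(path: PathLike) -> ImpedanceSpectrum:
    df = pd.read_csv(path, float_precision="round_trip")
    required = ("freq_hz", "z_real_ohm", "z_imag_ohm")
    for col in required:
        if col not in df.columns:
            raise ParseError(f"{path}: missing required column '{col}'")
    f = df["freq_hz"].to_numpy(dtype=float)
    if (f <= 0).any():
        bad = int(np.argmax(f <= 0)) + 2
        raise ParseError(f"{path}: non-positive frequency at line {bad}")
    z = df["z_real_ohm"].to_numpy(float) + 1j * df["z_imag_ohm"].to_numpy(float)
    order = np.argsort(f)
    return ImpedanceSpectrum(freq=f[order], z=z[order])


def write_json_report(report: dict, path: PathLike) -> None:
    """Write a machine-readable JSON report (NaN-safe, stable key order)."""

    def default(o):
        if isinstance(o, (np.integer,)):
            return int(o)
        if isinstance(o, (np.floating,)):
            return float(o)
        if isinstance(o, np.ndarray):
            return o.tolist()
        raise TypeError(f"not JSON-serializable: {type(o)}")

    def clean(obj):
        if isinstance(obj, dict):
            return {k: clean(v) for k, v in obj.items()}
        if isinstance(obj, (list, tuple)):
            return [clean(v) for v in obj]
        if isinstance(obj, float) and not np.isfinite(obj):
            return None
        return obj

    Path(path).write_text(
        json.dumps(clean(report), indent=2, sort_keys=True, default=default) + "\n",
        encoding="utf-8",
    )
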