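"""Readers and writers for traces, state paths, idealizations and spectra.

Traces travel as CSV/TSV with a ``time,value`` header, time in seconds at
15 significant digits; state paths as ``time,state``; idealizations as a
per-sample ``time,value`` CSV plus a JSON sidecar of knots and levels;
ECF spectra as ``freq,re,im,magnitude,kept``.
"""

from __future__ import annotations

import json
from pathlib import Path

import numpy as np
import pandas as pd

from .density import ECFSpectrum, ShrinkageResult
from .trace import PiecewiseConstant, StateSequence, TimeSeries

__all__ = [
    "read_trace",
    "write_trace",
    "read_states",
    "write_states",
    "write_pwc",
    "read_pwc",
    "write_spectrum",
]

_REL_TOL = 1e-6  # relative tolerance on uniform sampling


def _sep_for(path) -> str:
    return "\t" if str(path).endswith((".tsv", ".tab")) else ","


def read_trace(path) -> TimeSeries:
    """Read a ``time,value`` CSV/TSV into a TimeSeries.

    The time column must advance by a single uniform interval (within
    1e-6 relative tolerance); the first offending row is named otherwise.
    """
    df = pd.read_csv(path, sep=_sep_for(path))
    cols = [c.strip().lower() for c in df.columns]
    if cols[:2] != ["time", "value"]:
        raise ValueError(f"{path}: expected header 'time,value', got {list(df.columns)}")
    t = df.iloc[:, 0].to_numpy(dtype=float)
    v = df.iloc[:, 1].to_numpy(dtype=float)
    if not np.all(np.isfinite(t)) or not np.all(np.isfinite(v)):
        raise ValueError(f"{path}: non-numeric or non-finite entries")
    if t.size < 2:
        return TimeSeries(v, 1.0)
    dt = np.diff(t)
    dt0 = dt[0]
    if dt0 <= 0:
        raise ValueError(f"{path}: non-increasing time at data row 1")
    bad = np.flatnonzero(np.abs(dt - dt0) > _REL_TOL * abs(dt0))
    if bad.size:
        raise ValueError(
            f"{path}: non-uniform sampling at data row {int(bad[0]) + 1} "
            f"(step {dt[bad[0]]:g}, expected {dt0:g})")
    return TimeSeries(v, float(dt0))


def write_trace(ts: TimeSeries, path) -> None:
    """Write a TimeSeries as ``time,value`` at 15 significant digits."""
    sep = _sep_for(path)
    t = ts.times
    with open(path, "w") as fh:
        fh.write(f"time{sep}value\n")
        for ti, vi in zip(t, ts.values):
            fh.write(f"{ti:.15g}{sep}{vi:.15g}\n")


def read_states(path) -> StateSequence:
    df = pd.read_csv(path, sep=_sep_for(path))
    labels = df["state"].to_numpy(dtype=int)
    return StateSequence(labels, int(labels.max()))


def write_states(seq: StateSequence, path, sample_interval: float = 1.0) -> None:
    sep = _sep_for(path)
    with open(path, "w") as fh:
        fh.write(f"time{sep}state\n")
        for i, s in enumerate(seq.labels):
            fh.write(f"{i * sample_interval:.15g}{sep}{s}\n")


def write_pwc(pwc: PiecewiseConstant, path, sample_interval: float = 1.0
              ) -> None:
    """Per-sample idealization CSV plus a JSON sidecar of knots/levels."""
    write_trace(TimeSeries(pwc.per_sample, sample_interval), path)
    sidecar = Path(str(path)).with_suffix(".json")
    with open(sidecar, "w") as fh:
        json.dump({"knots": [int(k) for k in pwc.knots],
                   "levels": [repr(float(v)) for v in pwc.levels]},
                  fh, indent=1)


def read_pwc(path) -> PiecewiseConstant:
    ts = read_trace(path)
    sidecar = Path(str(path)).with_suffix(".json")
    with open(sidecar) as fh:
        d = json.load(fh)
    return PiecewiseConstant(ts.values, np.array(d["knots"], dtype=int),
                             np.array([float(v) for v in d["levels"]]))


def write_spectrum(spec: ECFSpectrum, path,
                   res: ShrinkageResult | None = None) -> None:
    """Spectrum CSV with columns freq,re,im,magnitude,kept."""
    kept = np.ones(spec.freqs.size, dtype=int)
    if res is not None:
        kept = (np.abs(res.shrunk_coeffs) > 0).astype(int)
    with open(path, "w") as fh:
        fh.write("freq,re,im,magnitude,kept\n")
        for f, c, k in zip(spec.freqs, spec.coeffs, kept):
            fh.write(f"{f},{c.real:.15g},{c.imag:.15g},{abs(c):.15g},{k}\n")
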