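"""Delimited-text I/O for input traces and signal sets.

All tabular exchange uses comma-separated files with a header row whose
first column is ``time_s``.  Unknown columns are rejected by name so a
mis-labelled file fails loudly rather than silently dropping data.
"""

from __future__ import annotations

from pathlib import Path

import numpy as np
import pandas as pd

from .errors import ParseError
from .observables import SIGNAL_NAMES, SignalSet
from .simulate import InputTraces

__all__ = ["read_traces", "write_traces", "read_signals", "write_signals"]

TRACE_COLUMNS = ("time_s", "SaO2", "Pa_mmHg", "k_occ")
_REQUIRED_TRACE = ("time_s", "SaO2", "Pa_mmHg")


def _read_table(path: str | Path) -> pd.DataFrame:
    path = Path(path)
    if not path.exists():
        raise ParseError(f"file not found: {path}")
    try:
        df = pd.read_csv(path)
    except Exception as exc:  # malformed CSV
        raise ParseError(f"could not parse {path}: {exc}") from exc
    if "time_s" not in df.columns:
        raise ParseError(f"{path}: missing required column 'time_s'")
    for col in df.columns:
        if not pd.api.types.is_numeric_dtype(df[col]):
            bad = df[pd.to_numeric(df[col], errors="coerce").isna()]
            line = int(bad.index[0]) + 2 if len(bad) else "?"
            raise ParseError(
                f"{path}: non-numeric value in column {col!r} "
                f"(line {line})")
    t = df["time_s"].to_numpy(dtype=float)
    if np.any(np.diff(t) <= 0):
        i = int(np.where(np.diff(t) <= 0)[0][0]) + 2
        raise ParseError(f"{path}: time_s not strictly increasing "
                         f"(line {i + 1})")
    return df


def read_traces(path: str | Path) -> InputTraces:
    """Read driving-input traces (columns time_s, SaO2, Pa_mmHg and
    optionally k_occ)."""
    df = _read_table(path)
    unknown = [c for c in df.columns if c not in TRACE_COLUMNS]
    if unknown:
        raise ParseError(f"{path}: unknown column(s) {unknown}; expected "
                         f"{list(TRACE_COLUMNS)}")
    missing = [c for c in _REQUIRED_TRACE if c not in df.columns]
    if missing:
        raise ParseError(f"{path}: missing column(s) {missing}")
    return InputTraces(
        time=df["time_s"].to_numpy(dtype=float),
        SaO2=df["SaO2"].to_numpy(dtype=float),
        Pa=df["Pa_mmHg"].to_numpy(dtype=float),
        k_occ=df["k_occ"].to_numpy(dtype=float)
        if "k_occ" in df.columns else None)


def write_traces(traces: InputTraces, path: str | Path) -> None:
    cols = {"time_s": traces.time, "SaO2": traces.SaO2,
            "Pa_mmHg": traces.Pa}
    if traces.k_occ is not None:
        cols["k_occ"] = traces.k_occ
    pd.DataFrame(cols).to_csv(path, index=False,
                              float_format="%.17g")


def read_signals(path: str | Path) -> SignalSet:
    """Read a signal table (time_s plus any subset of the documented
    signal columns)."""
    df = _read_table(path)
    unknown = [c for c in df.columns
               if c != "time_s" and c not in SIGNAL_NAMES]
    if unknown:
        raise ParseError(f"{path}: unknown signal column(s) {unknown}; "
                         f"expected among {list(SIGNAL_NAMES)}")
    return SignalSet.from_frame(df)


def write_signals(signals: SignalSet, path: str | Path) -> None:
    signals.to_frame().to_csv(path, index=False, float_format="%.17g")
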