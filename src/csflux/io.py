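"""Reading and writing peak-integral time courses.

Single CSV dialect: comma-separated, UTF-8, ``.`` decimal separator, header
``time_s,out_integral,in_integral``, optional comment lines starting with
``#``.  Times are always seconds.  A ``# kind: dnp|thermal`` comment records
the acquisition kind and round-trips through :func:`write_timecourse`.
"""

from __future__ import annotations

import math
from pathlib import Path

import numpy as np
import pandas as pd

from .kinetics import TimeCourse

__all__ = ["read_timecourse", "write_timecourse"]

_COLUMNS = ["time_s", "out_integral", "in_integral"]


def read_timecourse(path, kind: str | None = None) -> TimeCourse:
    """Load a validated :class:`TimeCourse` from CSV.

    ``kind`` overrides the ``# kind:`` comment in the file; if neither is
    present, ``"dnp"`` is assumed.  Errors name the offending column or row.
    """
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(f"no such time-course file: {path}")
    file_kind = None
    with open(path) as fh:
        for line in fh:
            if not line.startswith("#"):
                break
            body = line[1:].strip()
            if body.lower().startswith("kind:"):
                file_kind = body.split(":", 1)[1].strip()
    df = pd.read_csv(path, comment="#", float_precision="round_trip")
    missing = [c for c in _COLUMNS if c not in df.columns]
    if missing:
        raise ValueError(f"{path}: missing column(s) {', '.join(missing)}")
    if len(df) == 0:
        raise ValueError(f"{path}: no data rows")
    cols = {}
    for c in _COLUMNS:
        vals = pd.to_numeric(df[c], errors="coerce")
        bad = vals.index[vals.isna() & df[c].notna()]
        if len(bad) > 0:
            raise ValueError(
                f"{path}: non-numeric value {df[c].iloc[bad[0]]!r} in column "
                f"{c!r} at data row {int(bad[0])}"
            )
        if vals.isna().any():
            row = int(vals.index[vals.isna()][0])
            raise ValueError(f"{path}: missing value in column {c!r} at data row {row}")
        cols[c] = vals.to_numpy(dtype=float)
    t = cols["time_s"]
    dt = np.diff(t)
    if np.any(dt <= 0):
        row = int(np.flatnonzero(dt <= 0)[0]) + 1
        raise ValueError(
            f"{path}: time_s must be strictly increasing; violation at data row {row} "
            f"(t={t[row]!r} after t={t[row - 1]!r})"
        )
    return TimeCourse(
        times=t,
        out_signal=cols["out_integral"],
        in_signal=cols["in_integral"],
        kind=kind or file_kind or "dnp",
        meta={"source": str(path)},
    )


def write_timecourse(tc: TimeCourse, path) -> Path:
    """Write a time course as CSV with deterministic formatting.

    Identical inputs yield byte-identical files (17 significant digits, no
    trailing whitespace).  Non-finite signals are refused.
    """
    for name, arr in (("times", tc.times), ("out_signal", tc.out_signal), ("in_signal", tc.in_signal)):
        if not np.all(np.isfinite(arr)):
            raise ValueError(f"refusing to write non-finite values in {name}")
    path = Path(path)
    lines = [f"# kind: {tc.kind}", ",".join(_COLUMNS)]
    for t, o, i in zip(tc.times, tc.out_signal, tc.in_signal):
        lines.append(f"{t:.17g},{o:.17g},{i:.17g}")
    path.write_text("\n".join(lines) + "\n", encoding="utf-8")
    return path
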