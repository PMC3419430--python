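"""Reading and writing the toolkit's file formats.

Signals travel as two-column delimited text (``time_s,value`` with header),
IMF sets as multi-column CSV (``imf1..imfN,residue``) with a JSON sidecar
carrying the decomposition parameters and per-IMF averaged frequencies,
beat tables and phase-shift series as CSV, verification results and
correlation reports as JSON/CSV.
"""

from __future__ import annotations

import json
from pathlib import Path

import numpy as np
import pandas as pd

from .eemd import average_frequency
from .emd import IMFSet
from .signal import Signal


def read_signal(
    path,
    value_column: str | int | None = None,
    time_column: str | int | None = None,
    rate: float | None = None,
    label: str | None = None,
) -> Signal:
    """Load a signal from delimited text.

    Columns can be named or positional.  By default the last column is the
    value and, when the file has at least two columns, the first is time in
    seconds; the sampling rate is inferred from the time column's spacing
    unless ``rate`` is given.  Files with a single column require ``rate``.

    Raises
    ------
    ValueError
        For missing files, non-numeric rows (reported with their row
        numbers), a non-uniform time column, or a missing rate.
    """
    path = Path(path)
    if not path.exists():
        raise ValueError(f"signal file not found: {path}")
    frame = pd.read_csv(path)
    if frame.shape[1] == 0 or frame.shape[0] == 0:
        raise ValueError(f"{path}: no data rows")

    def pick(col, default_idx):
        if col is None:
            return frame.columns[default_idx]
        if isinstance(col, int):
            return frame.columns[col]
        return col

    value_col = pick(value_column, -1)
    values = pd.to_numeric(frame[value_col], errors="coerce").to_numpy(dtype=float)
    bad = np.flatnonzero(~np.isfinite(values))
    if bad.size:
        rows = ", ".join(str(i + 2) for i in bad[:5])  # +2: header and 1-based
        raise ValueError(
            f"{path}: non-numeric or missing values in column {value_col!r} "
            f"at file row(s) {rows}"
        )

    if rate is None:
        if frame.shape[1] < 2:
            raise ValueError(f"{path}: single column; sampling rate required")
        time_col = pick(time_column, 0)
        times = pd.to_numeric(frame[time_col], errors="coerce").to_numpy(dtype=float)
        if not np.all(np.isfinite(times)):
            raise ValueError(f"{path}: non-numeric entries in time column")
        steps = np.diff(times)
        if steps.size == 0 or np.any(steps <= 0):
            raise ValueError(f"{path}: time column must be strictly increasing")
        if np.ptp(steps) > 1e-6 * np.median(steps) + 1e-12:
            raise ValueError(f"{path}: time column is not uniformly spaced")
        rate = 1.0 / float(np.median(steps))
    return Signal(values, float(rate), label or str(value_col))


def write_signal(signal: Signal, path) -> None:
    """Two-column CSV: time_s, value."""
    pd.DataFrame({"time_s": signal.time, signal.label or "value": signal.samples}).to_csv(
        path, index=False
    )


def write_imfset(imfset: IMFSet, path, sidecar: bool = True) -> None:
    """IMFSet as CSV (imf1..imfN, residue) plus a JSON parameter sidecar.

    The sidecar also records each IMF's averaged frequency by both the
    zero-crossing and spectral-centroid definitions.
    """
    path = Path(path)
    cols = {f"imf{i + 1}": imfset.imfs[i] for i in range(imfset.n_imfs)}
    cols["residue"] = imfset.residue
    pd.DataFrame(cols).to_csv(path, index=False)
    if not sidecar:
        return
    freqs = []
    for i in range(imfset.n_imfs):
        row = {}
        for method in ("zero-crossing", "spectral-centroid"):
            try:
                row[method] = average_frequency(imfset.imfs[i], imfset.rate, method)
            except ValueError:
                row[method] = None
        freqs.append(row)
    meta = {
        "method": imfset.method,
        "rate_hz": imfset.rate,
        "n_imfs": imfset.n_imfs,
        "params": imfset.params,
        "averaged_frequency_hz": freqs,
    }
    path.with_suffix(".json").write_text(json.dumps(meta, indent=2))


def read_imfset(path, rate: float, method: str = "plain-emd") -> IMFSet:
    frame = pd.read_csv(path)
    if "residue" not in frame.columns:
        raise ValueError(f"{path}: IMFSet CSV must contain a 'residue' column")
    imf_cols = [c for c in frame.columns if c.startswith("imf")]
    imfs = frame[imf_cols].to_numpy(dtype=float).T
    return IMFSet(
        imfs=imfs, residue=frame["residue"].to_numpy(dtype=float), rate=rate,
        method=method,
    )


def write_table(frame: pd.DataFrame, path) -> None:
    frame.to_csv(path, index=False)


def write_json(payload, path) -> None:
    Path(path).write_text(json.dumps(payload, indent=2, default=_jsonify))


def _jsonify(obj):
    if isinstance(obj, (np.integer,)):
        return int(obj)
    if isinstance(obj, (np.floating,)):
        return float(obj)
    if isinstance(obj, np.ndarray):
        return obj.tolist()
    raise TypeError(f"not JSON serializable: {type(obj)}")
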