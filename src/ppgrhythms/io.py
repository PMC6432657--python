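"""Delimited-text input/output for time series and analysis products.

Native format is delimited text (comma for ``.csv``, tab otherwise) with a
header row.  Time series are two columns (``time_s``, ``value``); matrix
products are written long-format (``time_s``, ``freq_hz``, ``value``).
Floating values are written at 12 significant digits so every read/write
pair is a lossless round-trip at the stated precision.
"""

from __future__ import annotations

import os
from typing import Optional

import numpy as np
import pandas as pd

from .core import TimeSeries

__all__ = ["read_timeseries", "write_timeseries", "write_table", "read_table"]

FLOAT_FMT = "%.12g"

#: relative tolerance on sample-interval uniformity
_SPACING_RTOL = 1e-6


class FormatError(ValueError):
    """Raised for malformed delimited-text input."""


def _sep_for(path) -> str:
    return "," if str(path).lower().endswith(".csv") else "\t"


def read_timeseries(path, column_map: Optional[dict] = None,
                    label: str = "") -> TimeSeries:
    """Read an evenly sampled time series from a delimited-text file.

    Parameters
    ----------
    path : str or Path
        Delimited text with a header; comma-separated for ``.csv``,
        tab-separated otherwise.
    column_map : dict, optional
        ``{"time": <time column>, "value": <value column>}``; defaults to
        ``time_s`` / ``value``.
    label : str
        Channel label for the returned series.

    The sampling rate is inferred from the median time step.  Non-monotone
    time is a :class:`FormatError`; spacing that deviates from the median
    step by more than ``1e-6 * dt`` is an error, never silently resampled.
    """
    cmap = {"time": "time_s", "value": "value"}
    if column_map:
        cmap.update(column_map)
    df = pd.read_csv(path, sep=_sep_for(path))
    for role in ("time", "value"):
        if cmap[role] not in df.columns:
            raise KeyError(
                f"column {cmap[role]!r} (role {role!r}) not found in {path}; "
                f"available: {list(df.columns)}")
    t = df[cmap["time"]].to_numpy(dtype=float)
    v = df[cmap["value"]].to_numpy(dtype=float)
    if t.size < 2:
        raise FormatError("need at least 2 rows to infer a sampling rate")
    dts = np.diff(t)
    if np.any(dts <= 0):
        raise FormatError("time column must be strictly increasing")
    dt = float(np.median(dts))
    if np.max(np.abs(dts - dt)) > _SPACING_RTOL * dt:
        raise FormatError(
            f"uneven sample spacing (max deviation "
            f"{np.max(np.abs(dts - dt)):.3g} s exceeds {_SPACING_RTOL * dt:.3g} s); "
            "resample explicitly instead")
    return TimeSeries(v, rate=1.0 / dt, t0=float(t[0]), label=label)


def write_timeseries(ts: TimeSeries, path) -> None:
    """Write a time series as a two-column delimited-text file."""
    df = pd.DataFrame({"time_s": ts.times, "value": ts.samples})
    df.to_csv(path, sep=_sep_for(path), index=False, float_format=FLOAT_FMT)


def write_table(product, path) -> None:
    """Write any tabular analysis product to delimited text.

    ``product`` is either a DataFrame or an object exposing ``to_frame()``
    (Spectrogram, FrequencyTrack, BoutTable, CoherenceResult, RampAnalysis,
    ...).  Values are written at 12 significant digits and the file is
    re-readable with :func:`read_table`.
    """
    if isinstance(product, pd.DataFrame):
        df = product
    elif hasattr(product, "to_frame"):
        df = product.to_frame()
    else:
        raise TypeError(f"cannot tabulate object of type {type(product).__name__}")
    parent = os.path.dirname(str(path))
    if parent and not os.path.isdir(parent):
        raise FileNotFoundError(f"directory does not exist: {parent}")
    df.to_csv(path, sep=_sep_for(path), index=False, float_format=FLOAT_FMT)


def read_table(path) -> pd.DataFrame:
    """Read back a table written by :func:`write_table`."""
    return pd.read_csv(path, sep=_sep_for(path))
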