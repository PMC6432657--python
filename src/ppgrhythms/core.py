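"""Core containers: evenly sampled time series, multi-channel recordings, run configuration.

A :class:`TimeSeries` is the universal currency of the pipeline: a single
evenly sampled channel (photoplethysmogram voltage or tank temperature) with
a sampling rate in Hz and a start time in seconds from recording onset.
"""

from __future__ import annotations

import dataclasses
from dataclasses import dataclass, field
from typing import Optional

import numpy as np
import yaml

__all__ = ["TimeSeries", "RecordingSet", "RunConfig"]


@dataclass
class TimeSeries:
    """Evenly sampled single-channel signal.

    Parameters
    ----------
    samples : ndarray
        Signal values in arbitrary PPG units (or degrees C for temperature).
    rate : float
        Sampling rate in Hz; must be positive.
    t0 : float
        Time of the first sample, in seconds from recording start.
    label : str
        Channel name, conventionally ``heart``, ``pyloric`` or ``temperature``.
    """

    samples: np.ndarray
    rate: float
    t0: float = 0.0
    label: str = ""

    def __post_init__(self) -> None:
        self.samples = np.asarray(self.samples, dtype=float)
        if self.samples.ndim != 1 or self.samples.size < 1:
            raise ValueError("samples must be a non-empty 1-D array")
        if not np.all(np.isfinite(self.samples)):
            raise ValueError("samples must all be finite")
        if not (self.rate > 0):
            raise ValueError(f"rate must be positive, got {self.rate}")

    @property
    def n(self) -> int:
        return self.samples.size

    @property
    def dt(self) -> float:
        return 1.0 / self.rate

    @property
    def duration(self) -> float:
        """Record duration in seconds (n samples at 1/rate spacing)."""
        return self.n / self.rate

    @property
    def times(self) -> np.ndarray:
        return self.t0 + np.arange(self.n) / self.rate

    def copy_with(self, **kwargs) -> "TimeSeries":
        return dataclasses.replace(self, **kwargs)


@dataclass
class RecordingSet:
    """Aligned multi-channel recording from one animal.

    All present channels share the heart channel's rate and t0 after
    :meth:`align`; the slow temperature channel is linearly interpolated
    onto the heart grid when rates differ.
    """

    heart: TimeSeries
    pyloric: Optional[TimeSeries] = None
    temperature: Optional[TimeSeries] = None
    animal_id: str = ""

    def channels(self) -> dict:
        out = {"heart": self.heart}
        if self.pyloric is not None:
            out["pyloric"] = self.pyloric
        if self.temperature is not None:
            out["temperature"] = self.temperature
        return out

    def align(self) -> "RecordingSet":
        """Interpolate pyloric/temperature channels onto the heart grid.

        Channels whose rate already matches within 1e-6 relative are kept
        as-is (modulo t0 matching); others are linearly interpolated.
        """
        ref = self.heart
        t_ref = ref.times

        def _onto_grid(ts: Optional[TimeSeries]) -> Optional[TimeSeries]:
            if ts is None:
                return None
            same_rate = abs(ts.rate - ref.rate) <= 1e-6 * ref.rate
            if same_rate and abs(ts.t0 - ref.t0) <= 1e-9 and ts.n == ref.n:
                return ts
            vals = np.interp(t_ref, ts.times, ts.samples)
            return TimeSeries(vals, rate=ref.rate, t0=ref.t0, label=ts.label)

        return RecordingSet(
            heart=ref,
            pyloric=_onto_grid(self.pyloric),
            temperature=_onto_grid(self.temperature),
            animal_id=self.animal_id,
        )


@dataclass
class RunConfig:
    """Pipeline parameters shared by the CLI subcommands.

    Defaults follow the analysis protocol: 12.8 s spectral windows with 50%
    overlap at a 10 Hz working rate (128 samples per window), a 6th-order
    5 Hz low-pass, and 2 min multitaper coherence windows stepped by 5 s
    with time-bandwidth 10 and 19 tapers.
    """

    window_s: float = 12.8
    overlap_frac: float = 0.5
    lowpass_hz: float = 5.0
    filter_order: int = 6
    target_rate_hz: float = 10.0
    coh_window_s: float = 120.0
    coh_step_s: float = 5.0
    time_bandwidth: float = 10.0
    n_tapers: int = 19
    alpha: float = 0.05
    band_low_hz: float = 0.2
    band_high_hz: float = 2.5
    seed: int = 0

    def __post_init__(self) -> None:
        if not (0 < self.overlap_frac < 1):
            raise ValueError("overlap_frac must lie in (0, 1)")
        if self.n_tapers > 2 * self.time_bandwidth - 1:
            raise ValueError("n_tapers must be <= 2*time_bandwidth - 1")
        for name in ("window_s", "lowpass_hz", "target_rate_hz",
                     "coh_window_s", "coh_step_s"):
            if getattr(self, name) <= 0:
                raise ValueError(f"{name} must be positive")

    @classmethod
    def from_file(cls, path) -> "RunConfig":
        """Read a key/value YAML file whose keys mirror the field names."""
        with open(path) as fh:
            raw = yaml.safe_load(fh) or {}
        known = {f.name for f in dataclasses.fields(cls)}
        unknown = set(raw) - known
        if unknown:
            raise ValueError(f"unknown config keys: {sorted(unknown)}")
        return cls(**raw)

    def to_dict(self) -> dict:
        return dataclasses.asdict(self)
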