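"""Conditioning of raw 500 Hz PPG traces for spectral analysis.

The protocol is: remove the voltage offset, low-pass filter to 5 Hz with a
6th-order Butterworth applied forward-backward (zero-phase, so the phase
relationship between channels is preserved), then decimate to a 10 Hz
working rate.  At 10 Hz a 12.8 s spectral window holds exactly 128 samples.
"""

from __future__ import annotations

import logging

import numpy as np
from scipy import signal

from .core import RunConfig, TimeSeries

__all__ = ["remove_offset", "lowpass", "downsample", "condition"]

log = logging.getLogger(__name__)


def remove_offset(ts: TimeSeries) -> TimeSeries:
    """Subtract the mean so the output has zero offset.

    Same length and rate; output mean is zero to within 1e-12 of the input
    scale.
    """
    if ts.n < 2:
        raise ValueError("need at least 2 samples")
    return ts.copy_with(samples=ts.samples - ts.samples.mean())


def lowpass(ts: TimeSeries, cutoff: float = 5.0, order: int = 6) -> TimeSeries:
    """Zero-phase Butterworth low-pass filter.

    A digital Butterworth of the given order is applied forward-backward
    (``sosfiltfilt``), squaring the magnitude response: single-pass gain at
    the cutoff is 1/sqrt(2) (-3 dB), two-pass gain is 1/2.  Zero-phase
    filtering keeps rhythm timing intact, which matters downstream for the
    heart-pyloric phase estimates.
    """
    nyq = ts.rate / 2.0
    if not (0 < cutoff < nyq):
        raise ValueError(f"cutoff must lie in (0, Nyquist={nyq} Hz), got {cutoff}")
    sos = signal.butter(order, cutoff, btype="low", fs=ts.rate, output="sos")
    filtered = signal.sosfiltfilt(sos, ts.samples)
    return ts.copy_with(samples=filtered)


def downsample(ts: TimeSeries, target_rate: float = 10.0,
               lowpass_cutoff: float | None = None) -> TimeSeries:
    """Decimate by an integer stride to ``target_rate``.

    The input must already be low-pass filtered at or below the target
    Nyquist; pass ``lowpass_cutoff`` to have an anti-aliasing violation
    logged (not fatal).  ``rate / target_rate`` must be an integer within
    1e-9 relative.
    """
    stride_f = ts.rate / target_rate
    stride = int(round(stride_f))
    if stride < 1 or abs(stride_f - stride) > 1e-9 * stride_f:
        raise ValueError(
            f"rate {ts.rate} Hz is not an integer multiple of target "
            f"{target_rate} Hz")
    if lowpass_cutoff is not None and lowpass_cutoff > target_rate / 2.0:
        log.warning(
            "anti-aliasing violation: low-pass cutoff %.3g Hz exceeds the "
            "target Nyquist %.3g Hz", lowpass_cutoff, target_rate / 2.0)
    if stride == 1:
        return ts
    return ts.copy_with(samples=ts.samples[::stride], rate=target_rate)


def condition(ts: TimeSeries, config: RunConfig | None = None) -> TimeSeries:
    """Full conditioning chain: offset removal, low-pass, decimation."""
    cfg = config or RunConfig()
    log.info("preprocess %s: lowpass %.3g Hz order %d, downsample to %.3g Hz",
             ts.label or "<unnamed>", cfg.lowpass_hz, cfg.filter_order,
             cfg.target_rate_hz)
    out = remove_offset(ts)
    out = lowpass(out, cutoff=cfg.lowpass_hz, order=cfg.filter_order)
    out = downsample(out, target_rate=cfg.target_rate_hz,
                     lowpass_cutoff=cfg.lowpass_hz)
    return out
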