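"""Temperature-response analysis: Q10 regression and critical temperature.

Q10 - the factor by which a rhythm's frequency scales per 10 degC - is
estimated by ordinary least squares of log10(frequency) on temperature
over the rising ramp below the critical temperature:

    log10 F = m T + b,    Q10 = 10**(10 m)

The critical ("crash") temperature is the lowest temperature at which the
rhythm both slows below 90% of its running maximum and loses spectral
peakiness (peak power / band power falls below half its baseline median)
for at least three consecutive windows; when the criteria never co-occur
the critical temperature is undetermined, as happens in vivo for
irregular pyloric signals.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from typing import Optional

import numpy as np
import pandas as pd
from scipy import stats

from .core import TimeSeries
from .spectra import FrequencyTrack, Spectrogram

__all__ = ["RampAnalysis", "q10_fit", "detect_critical_temperature",
           "window_temperatures"]

log = logging.getLogger(__name__)


@dataclass
class RampAnalysis:
    """Per-channel temperature-ramp results.

    ``critical_temperature`` is None when undeterminable.
    """

    q10: float
    slope: float               # log10(Hz) per degC
    intercept: float           # log10(Hz)
    r_squared: float
    critical_temperature: Optional[float]
    fit_range: tuple[float, float]
    n_points: int = 0
    channel: str = ""

    def __post_init__(self):
        if self.q10 <= 0:
            raise ValueError("Q10 must be positive")
        if not (0 <= self.r_squared <= 1 or np.isnan(self.r_squared)):
            raise ValueError("R^2 must lie in [0, 1]")

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame([{
            "channel": self.channel,
            "q10": self.q10,
            "slope_log10hz_per_degc": self.slope,
            "intercept_log10hz": self.intercept,
            "r_squared": self.r_squared,
            "critical_temperature_degc": (
                np.nan if self.critical_temperature is None
                else self.critical_temperature),
            "fit_min_degc": self.fit_range[0],
            "fit_max_degc": self.fit_range[1],
            "n_points": self.n_points,
        }])


def window_temperatures(track: FrequencyTrack, temp: TimeSeries) -> np.ndarray:
    """Temperature at each spectrogram window center (linear interpolation)."""
    return np.interp(track.window_times, temp.times, temp.samples)


def q10_fit(track: FrequencyTrack, temp: TimeSeries,
            fit_range: tuple[float, float],
            critical_temperature: Optional[float] = None,
            channel: str = "", smooth_windows: int = 5) -> RampAnalysis:
    """Log-linear Q10 regression over a temperature range.

    The track is median-smoothed over ``smooth_windows`` windows first.
    Only windows whose interpolated temperature lies inside ``fit_range``
    (and strictly below ``critical_temperature`` when given) enter the
    fit.  The Q10 estimate is invariant to the frequency unit; the unit
    only shifts the intercept.
    """
    lo, hi = fit_range
    if hi <= lo:
        raise ValueError("fit_range must be increasing")
    track = track.median_smoothed(smooth_windows)
    tw = window_temperatures(track, temp)
    mask = (tw >= lo) & (tw <= hi)
    if critical_temperature is not None:
        mask &= tw < critical_temperature
    f = track.peak_freq[mask]
    t = tw[mask]
    if f.size < 5:
        raise ValueError(f"need >= 5 points in fit range, got {f.size}")
    if np.any(f <= 0):
        raise ValueError("non-positive frequency in fit range")
    logf = np.log10(f)
    if np.ptp(logf) == 0.0:
        log.warning("frequency constant over the ramp: Q10 = 1, R^2 "
                    "undefined (reported as 0)")
        return RampAnalysis(q10=1.0, slope=0.0,
                            intercept=float(logf[0]), r_squared=0.0,
                            critical_temperature=critical_temperature,
                            fit_range=fit_range, n_points=int(f.size),
                            channel=channel)
    res = stats.linregress(t, logf)
    q10 = float(10.0 ** (10.0 * res.slope))
    return RampAnalysis(q10=q10, slope=float(res.slope),
                        intercept=float(res.intercept),
                        r_squared=float(res.rvalue ** 2),
                        critical_temperature=critical_temperature,
                        fit_range=fit_range, n_points=int(f.size),
                        channel=channel)


def detect_critical_temperature(track: FrequencyTrack, temp: TimeSeries,
                                spec: Spectrogram,
                                band: tuple[float, float] = (0.2, 2.5),
                                freq_drop_frac: float = 0.9,
                                peakiness_drop_frac: float = 0.5,
                                n_persist: int = 3,
                                baseline_band_degc: float = 1.0,
                                smooth_windows: int = 5) -> Optional[float]:
    """Detect the crash temperature on a rising ramp.

    The track is median-smoothed over ``smooth_windows`` first (isolated
    harmonic-locked windows would otherwise poison the running maximum).
    Per window an irregularity index is computed: power at the tracked
    peak divided by total band power (a sharp rhythm concentrates power at
    its peak; an irregular one spreads it).  The critical temperature is
    the temperature of the first window of the earliest run of
    ``n_persist`` consecutive windows in which the tracked frequency falls
    below ``freq_drop_frac`` of its running maximum AND the irregularity
    index falls below ``peakiness_drop_frac`` of its baseline median.
    Returns None when the criteria never co-occur.
    """
    track = track.median_smoothed(smooth_windows)
    tw = window_temperatures(track, temp)
    i_max = int(np.argmax(tw))
    if i_max < n_persist or tw[i_max] <= tw[0] + 1e-9:
        raise ValueError("no rising temperature segment")
    sl = slice(0, i_max + 1)
    tw_r = tw[sl]
    f_r = track.peak_freq[sl]

    lo, hi = band
    bmask = (spec.freqs >= lo) & (spec.freqs <= hi)
    band_power = spec.power[sl][:, bmask].sum(axis=1)
    peak_ratio = track.peak_power[sl] / np.maximum(band_power,
                                                   np.finfo(float).tiny)

    base = tw_r <= tw_r[0] + baseline_band_degc
    if base.sum() < 5:
        base = np.zeros_like(base)
        base[:min(10, base.size)] = True
    base_ratio = float(np.median(peak_ratio[base]))

    runmax = np.maximum.accumulate(f_r)
    cond = (f_r < freq_drop_frac * runmax) & \
           (peak_ratio < peakiness_drop_frac * base_ratio)
    run = 0
    for i, c in enumerate(cond):
        run = run + 1 if c else 0
        if run >= n_persist:
            start = i - n_persist + 1
            t_crit = float(tw_r[start])
            log.info("critical temperature %.2f degC at window %d", t_crit,
                     start)
            return t_crit
    log.info("critical temperature undetermined (criteria never co-occurred)")
    return None
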