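"""Regression subtraction of the heart artifact from the pyloric channel.

The pyloric PPG sensor frequently picks up the heart (via ophthalmic-artery
pulsation or direct biomechanical coupling), putting a second band at the
heart frequency in the pyloric spectrogram.  To track the pyloric rhythm
unambiguously the heart signal, shifted by the lag that maximizes the
cross-correlation between the channels (the operational "phase
difference"), is regressed onto the pyloric signal by ordinary least
squares and the fitted component subtracted.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
from scipy import signal as sps

from .core import TimeSeries

__all__ = ["SubtractionFit", "estimate_lag", "regress_subtract"]

log = logging.getLogger(__name__)


@dataclass
class SubtractionFit:
    """Fitted lag (samples, signed), gain, intercept, and residual variance.

    Positive lag means the pyloric channel lags the heart.  ``peak_corr``
    is the normalized cross-correlation at the chosen lag; values near 0
    flag an unreliable lag estimate.
    """

    lag: int
    gain: float
    intercept: float
    residual_variance: float
    peak_corr: float = np.nan


def estimate_lag(heart: TimeSeries, pyloric: TimeSeries,
                 max_lag_s: float = 3.0) -> tuple[int, float]:
    """Lag (samples) maximizing |cross-correlation| within +-max_lag_s.

    Returns ``(lag, peak_corr)``.  Positive lag: pyloric delayed relative
    to heart.  Ties are broken toward the smallest |lag|.
    """
    if abs(heart.rate - pyloric.rate) > 1e-9 * heart.rate:
        raise ValueError("channels must share a sampling rate")
    n = min(heart.n, pyloric.n)
    if max_lag_s >= n / heart.rate / 2:
        raise ValueError("max_lag_s must be less than half the record")
    h = heart.samples[:n] - heart.samples[:n].mean()
    p = pyloric.samples[:n] - pyloric.samples[:n].mean()
    sh, sp = np.std(h), np.std(p)
    if sh == 0 or sp == 0:
        raise ValueError("zero-variance channel")
    max_lag = int(round(max_lag_s * heart.rate))
    xc = sps.correlate(p, h, mode="full", method="fft")
    lags = np.arange(-(n - 1), n)
    keep = np.abs(lags) <= max_lag
    xc, lags = xc[keep] / (n * sh * sp), lags[keep]
    best = np.abs(xc).max()
    ties = np.flatnonzero(np.abs(xc) >= best * (1 - 1e-12))
    lag = int(lags[ties[np.argmin(np.abs(lags[ties]))]])
    peak = float(xc[lags == lag][0])
    if abs(peak) < 0.05:
        log.warning("cross-correlation peak |r|=%.3g is weak; lag %d "
                    "samples may be meaningless", abs(peak), lag)
    return lag, peak


def _shift(x: np.ndarray, lag: int) -> np.ndarray:
    """Delay x by ``lag`` samples (zero-padded edges)."""
    out = np.zeros_like(x)
    if lag == 0:
        return x.copy()
    if lag > 0:
        out[lag:] = x[:-lag]
    else:
        out[:lag] = x[-lag:]
    return out


def _ols(regressor: np.ndarray, target: np.ndarray) -> tuple[float, float]:
    var = np.var(regressor)
    if var <= 1e-12 * max(np.var(target), 1e-300):
        return 0.0, 0.0
    gain = float(np.cov(regressor, target, bias=True)[0, 1] / var)
    intercept = float(target.mean() - gain * regressor.mean())
    return gain, intercept


def regress_subtract(heart: TimeSeries, pyloric: TimeSeries,
                     lag: int | None = None, max_lag_s: float = 3.0,
                     per_window_s: float | None = None
                     ) -> tuple[TimeSeries, SubtractionFit]:
    """Subtract the lag-shifted, OLS-scaled heart signal from the pyloric.

    With ``per_window_s`` set, the gain/intercept are refitted in
    consecutive windows of that length (useful on temperature ramps where
    the coupling gain drifts); the lag stays global.  A silent (degenerate)
    heart regressor returns the input unchanged with gain 0, logged.
    """
    if abs(heart.rate - pyloric.rate) > 1e-9 * heart.rate:
        raise ValueError("channels must share a sampling rate")
    n = min(heart.n, pyloric.n)
    h = heart.samples[:n]
    p = pyloric.samples[:n]
    peak = np.nan
    if lag is None:
        try:
            lag, peak = estimate_lag(heart, pyloric, max_lag_s=max_lag_s)
        except ValueError:
            log.warning("lag estimation failed (degenerate channel); "
                        "subtracting nothing")
            fit = SubtractionFit(0, 0.0, 0.0, float(np.var(p)), 0.0)
            return pyloric.copy_with(samples=p.copy()), fit
    hs = _shift(h, lag)

    if per_window_s is None:
        gain, intercept = _ols(hs, p)
        if gain == 0.0 and intercept == 0.0 and np.var(hs) <= 1e-12:
            log.warning("silent heart regressor; returning input unchanged")
            cleaned = p.copy()
        else:
            cleaned = p - (gain * hs + intercept)
    else:
        w = max(int(round(per_window_s * heart.rate)), 2)
        cleaned = np.empty(n)
        gains = []
        for s0 in range(0, n, w):
            s1 = min(s0 + w, n)
            g, c = _ols(hs[s0:s1], p[s0:s1])
            cleaned[s0:s1] = p[s0:s1] - (g * hs[s0:s1] + c)
            gains.append(g)
        gain, intercept = float(np.mean(gains)), 0.0
    resid_var = float(np.var(cleaned))
    log.info("heart subtraction: lag %d samples, gain %.4g, residual "
             "variance %.4g (input %.4g)", lag, gain, resid_var, np.var(p))
    fit = SubtractionFit(lag=lag, gain=gain, intercept=intercept,
                         residual_variance=resid_var, peak_corr=peak)
    return pyloric.copy_with(samples=cleaned), fit
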