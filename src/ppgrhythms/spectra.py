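"""Burg autoregressive spectral estimation and peak-frequency tracking.

The rhythm frequency at each moment is read off a moving-window Burg AR
spectrogram: each 12.8 s window (128 samples at the 10 Hz working rate) is
fitted with an AR model of order ``P = window/4 + 1 = 33`` by the Burg
recursion, the power spectral density is evaluated from the AR
coefficients on a fine frequency grid, and the rhythm frequency is the
frequency at peak spectral power.  Burg spectra resolve sharply on short
windows, which is why they are preferred here over raw FFT periodograms.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
import pandas as pd

from .core import TimeSeries

__all__ = [
    "ARModel", "Spectrogram", "FrequencyTrack",
    "burg_fit", "ar_psd", "spectrogram", "track_peak",
    "ar_line_powers", "mode_track",
    "baseline_median", "population_histogram", "default_order",
]

log = logging.getLogger(__name__)

#: frequency grid used by :func:`spectrogram`: 1024 points on [0, 5] Hz
N_FREQ = 1024
FMAX = 5.0


@dataclass
class ARModel:
    """Autoregressive model  x_t = sum_k phi_k x_{t-k} + e_t.

    ``coeffs`` are the regression coefficients phi_1..phi_P; ``sigma2`` is
    the innovation variance.  Burg estimates are always stable (all
    characteristic roots strictly inside the unit circle); this is asserted
    after the fit.
    """

    coeffs: np.ndarray
    sigma2: float

    @property
    def order(self) -> int:
        return len(self.coeffs)

    def is_stable(self) -> bool:
        if self.order == 0:
            return True
        # roots of z^P - phi_1 z^{P-1} - ... - phi_P
        poly = np.concatenate([[1.0], -np.asarray(self.coeffs)])
        # tolerance reflects np.roots accuracy on high-order polynomials
        # with near-unit-circle roots
        return bool(np.all(np.abs(np.roots(poly)) < 1.0 + 1e-6))


@dataclass
class Spectrogram:
    """Time-frequency power matrix from moving-window Burg fits."""

    window_times: np.ndarray   # window centers, s
    freqs: np.ndarray          # Hz
    power: np.ndarray          # (n_windows, n_freqs), amplitude^2/Hz

    def __post_init__(self):
        self.window_times = np.asarray(self.window_times, float)
        self.freqs = np.asarray(self.freqs, float)
        self.power = np.asarray(self.power, float)
        if self.power.shape != (self.window_times.size, self.freqs.size):
            raise ValueError("power must be (n_windows, n_freqs)")
        if np.any(self.power < 0):
            raise ValueError("power must be non-negative")
        if self.window_times.size > 1 and np.any(np.diff(self.window_times) <= 0):
            raise ValueError("window_times must be strictly increasing")

    def to_frame(self) -> pd.DataFrame:
        """Long-format table (time_s, freq_hz, power)."""
        t = np.repeat(self.window_times, self.freqs.size)
        f = np.tile(self.freqs, self.window_times.size)
        return pd.DataFrame({"time_s": t, "freq_hz": f,
                             "power": self.power.ravel()})

    @classmethod
    def from_frame(cls, df: pd.DataFrame) -> "Spectrogram":
        times = np.unique(df["time_s"].to_numpy())
        freqs = np.unique(df["freq_hz"].to_numpy())
        power = (df.pivot(index="time_s", columns="freq_hz", values="power")
                 .to_numpy())
        return cls(times, freqs, power)


@dataclass
class FrequencyTrack:
    """Per-window peak frequency and power from a spectrogram."""

    window_times: np.ndarray
    peak_freq: np.ndarray
    peak_power: np.ndarray

    def median_smoothed(self, width: int = 5) -> "FrequencyTrack":
        """Running-median copy of the track.

        Isolated windows can lock onto a harmonic of the rhythm; a short
        median filter removes such outliers without lagging genuine
        frequency trends.
        """
        if width <= 1:
            return self
        from scipy.ndimage import median_filter
        return FrequencyTrack(
            self.window_times,
            median_filter(self.peak_freq, size=width, mode="nearest"),
            median_filter(self.peak_power, size=width, mode="nearest"))

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame({"time_s": self.window_times,
                             "peak_freq_hz": self.peak_freq,
                             "peak_power": self.peak_power})


def default_order(n_window: int) -> int:
    """AR order for an n-sample window: P = n/4 + 1 (33 for 128 samples)."""
    return int(n_window // 4 + 1)


def burg_fit(x: Sequence[float], order: int) -> ARModel:
    """Fit an AR model by the Burg recursion.

    Reflection coefficients are chosen to minimize the summed forward plus
    backward prediction error at each stage, which guarantees |k| <= 1 and
    hence a stable model.  Returns regression coefficients (phi convention:
    AR(1) data ``x_t = 0.8 x_{t-1} + e`` yields ``coeffs[0] ~= 0.8``) and
    the final prediction-error variance.
    """
    x = np.asarray(x, dtype=float)
    n = x.size
    if order < 1:
        raise ValueError("order must be >= 1")
    if order >= n:
        raise ValueError(f"order {order} must be < n samples {n}")
    if not np.all(np.isfinite(x)):
        raise ValueError("input must be finite")
    energy = float(np.dot(x, x))
    if energy == 0.0:
        raise ValueError("zero-variance input")

    # a-polynomial with leading 1: A(z) = 1 + a_1 z^-1 + ... + a_P z^-P
    a = np.array([1.0])
    ef = x.copy()   # forward prediction error
    eb = x.copy()   # backward prediction error
    e = energy / n  # prediction-error power
    for _ in range(order):
        efp = ef[1:]
        ebp = eb[:-1]
        den = float(np.dot(efp, efp) + np.dot(ebp, ebp))
        if den <= 0.0 or not np.isfinite(den):
            # perfectly predicted (e.g. noiseless sinusoid at low order);
            # stop early, pad with zero coefficients
            a = np.concatenate([a, np.zeros(order + 1 - a.size)])
            break
        k = -2.0 * float(np.dot(ebp, efp)) / den
        a_pad = np.concatenate([a, [0.0]])
        a = a_pad + k * a_pad[::-1]
        ef = efp + k * ebp
        eb = ebp + k * efp
        e *= (1.0 - k * k)
        e = max(e, 0.0)
        if e <= 1e-12 * energy / n:
            # signal is perfectly predicted (noiseless periodic input);
            # further stages would fit floating-point noise
            a = np.concatenate([a, np.zeros(order + 1 - a.size)])
            break

    model = ARModel(coeffs=-a[1:], sigma2=max(e, np.finfo(float).tiny))
    # Burg guarantees stability in exact arithmetic; numerically a root can
    # brush the unit circle on noiseless inputs.  Pull the poles radially
    # inside by scaling phi_k by rho^-k, with a growing margin because
    # root-finding on high-order near-singular polynomials is inexact.
    margin = 1e-6
    while not model.is_stable() and margin < 1e-2:
        poly = np.concatenate([[1.0], -model.coeffs])
        rho = float(np.max(np.abs(np.roots(poly)))) * (1.0 + margin)
        scale = rho ** -np.arange(1, model.order + 1)
        model = ARModel(coeffs=model.coeffs * scale, sigma2=model.sigma2)
        margin *= 100.0
    return model


def ar_psd(model: ARModel, rate: float, n_freq: int = N_FREQ,
           fmax: float | None = None) -> tuple[np.ndarray, np.ndarray]:
    """Power spectral density of an AR model on an even frequency grid.

    Two-sided density convention: ``P(f) = sigma^2 / rate / |A(e^{-2 pi i
    f/rate})|^2`` with ``A(z) = 1 - sum_k phi_k z^-k``, so the integral over
    [-Nyquist, Nyquist] equals the process variance.
    """
    if not model.is_stable():
        raise ValueError("unstable AR model")
    if fmax is None:
        fmax = rate / 2.0
    freqs = np.linspace(0.0, fmax, n_freq)
    apoly = np.concatenate([[1.0], -np.asarray(model.coeffs)])
    # A(e^{-i omega k}) evaluated on the grid
    k = np.arange(apoly.size)
    phase = np.exp(-2j * np.pi * freqs[:, None] * k[None, :] / rate)
    denom = np.abs(phase @ apoly) ** 2
    power = model.sigma2 / rate / np.maximum(denom, np.finfo(float).tiny)
    return freqs, power


def _floor_linewidth(model: ARModel, rate: float,
                     min_linewidth_hz: float) -> ARModel:
    """Clip AR pole radii so every spectral line has at least the given
    half-width.

    On high-SNR rhythmic signals Burg places poles so close to the unit
    circle that a line's mass falls between grid frequencies, making the
    sampled peak density erratic.  Clipping radii to
    ``r_max = exp(-pi * min_linewidth / rate)`` smooths every line to a
    resolvable width while preserving pole angles (peak frequencies) and
    relative line powers.
    """
    if min_linewidth_hz <= 0 or model.order == 0:
        return model
    r_max = float(np.exp(-np.pi * min_linewidth_hz / rate))
    poly = np.concatenate([[1.0], -model.coeffs])
    roots = np.roots(poly)
    mag = np.abs(roots)
    if not np.any(mag > r_max):
        return model
    roots = np.where(mag > r_max, roots * (r_max / np.maximum(mag, 1e-300)),
                     roots)
    new_poly = np.real(np.poly(roots))
    return ARModel(coeffs=-new_poly[1:], sigma2=model.sigma2)


def spectrogram(ts: TimeSeries, window_s: float = 12.8, overlap: float = 0.5,
                order: int | None = None, n_freq: int = N_FREQ,
                fmax: float = FMAX,
                min_linewidth_hz: float = 0.0) -> Spectrogram:
    """Moving-window Burg spectrogram.

    Windows of ``window_s`` advance by ``window_s * (1 - overlap)``; an
    incomplete trailing window is dropped.  Each window is fitted with
    order ``P = n/4 + 1`` unless overridden.  ``min_linewidth_hz`` floors
    the spectral linewidth (see :func:`_floor_linewidth`); 0.05 Hz is a
    good choice when the track feeds peak-frequency analysis.
    """
    n_win = int(round(window_s * ts.rate))
    if n_win > ts.n:
        raise ValueError(f"record shorter than one window ({window_s} s)")
    if not (0 < overlap < 1):
        raise ValueError("overlap must lie in (0, 1)")
    step = int(round(n_win * (1 - overlap)))
    if step < 1:
        raise ValueError("overlap too large for window size")
    p = default_order(n_win) if order is None else order
    fmax = min(fmax, ts.rate / 2.0)
    log.info("spectrogram: window %.3g s (%d samples), step %d samples, "
             "AR order %d, grid %d pts on [0, %.3g] Hz",
             window_s, n_win, step, p, n_freq, fmax)

    starts = np.arange(0, ts.n - n_win + 1, step)
    freqs = np.linspace(0.0, fmax, n_freq)
    power = np.empty((starts.size, n_freq))
    centers = np.empty(starts.size)
    for i, s0 in enumerate(starts):
        seg = ts.samples[s0:s0 + n_win]
        centers[i] = ts.t0 + (s0 + (n_win - 1) / 2.0) / ts.rate
        seg = seg - seg.mean()
        if float(np.dot(seg, seg)) <= 0.0:
            power[i] = 0.0      # silent window: no power anywhere
            continue
        model = burg_fit(seg, p)
        model = _floor_linewidth(model, ts.rate, min_linewidth_hz)
        _, power[i] = ar_psd(model, ts.rate, n_freq=n_freq, fmax=fmax)
    return Spectrogram(centers, freqs, power)


def _snap_to_fundamental(freqs: np.ndarray, power: np.ndarray,
                         f_star: float, band_lo: float,
                         ratio: float = 0.3, delta: float = 0.05) -> float:
    """Relabel a harmonic-locked peak to its fundamental.

    AR peak *density* between two spectral lines is erratic when both
    lines are narrow, so the argmax occasionally lands on the 2nd or 3rd
    harmonic of a rhythm even though the fundamental carries far more
    power.  Band-*integrated* power is stable: if the integrated power in
    a +-delta Hz neighborhood of f*/k (k = 2, 3) reaches ``ratio`` of that
    around the argmax, the subharmonic is the rhythm fundamental.
    """
    p_star = power[np.abs(freqs - f_star) <= delta].sum()
    best = f_star
    for k in (2, 3):
        fc = f_star / k
        if fc < band_lo:
            continue
        near = np.abs(freqs - fc) <= delta
        if not near.any():
            continue
        fc_ref = freqs[near][np.argmax(power[near])]
        p_sub = power[np.abs(freqs - fc_ref) <= delta].sum()
        if p_sub >= ratio * p_star and fc_ref < best:
            best = fc_ref
    return best


def track_peak(spec: Spectrogram, band: tuple[float, float],
               prefer_fundamental: bool = False) -> FrequencyTrack:
    """Per-window frequency at peak spectral power within a band.

    Ties are broken toward the lower frequency (argmax returns the first
    maximum on an ascending grid), making the track deterministic.  With
    ``prefer_fundamental`` the peak is snapped down to f/2 or f/3 when the
    integrated power there shows the argmax landed on a waveform harmonic
    (see :func:`_snap_to_fundamental`).
    """
    lo, hi = band
    mask = (spec.freqs >= lo) & (spec.freqs <= hi)
    if not np.any(mask):
        raise ValueError(f"band {band} contains no grid frequencies")
    sub = spec.power[:, mask]
    fsub = spec.freqs[mask]
    idx = np.argmax(sub, axis=1)
    peak_f = fsub[idx]
    peak_p = sub[np.arange(sub.shape[0]), idx]
    if prefer_fundamental:
        for i in range(peak_f.size):
            f_new = _snap_to_fundamental(spec.freqs, spec.power[i],
                                         float(peak_f[i]), lo)
            if f_new != peak_f[i]:
                j = int(np.argmin(np.abs(spec.freqs - f_new)))
                peak_f[i] = spec.freqs[j]
                peak_p[i] = spec.power[i, j]
    return FrequencyTrack(spec.window_times, peak_f, peak_p)


def baseline_median(track: FrequencyTrack) -> float:
    """Median of the per-window peak frequencies (baseline summary)."""
    if track.peak_freq.size < 1:
        raise ValueError("empty track")
    return float(np.median(track.peak_freq))


def population_histogram(per_animal: Sequence[Sequence[float]],
                         bin_width: float,
                         freq_range: tuple[float, float] = (0.0, 2.5)
                         ) -> tuple[np.ndarray, np.ndarray]:
    """Cumulative normalized frequency histogram across animals.

    Each animal's histogram is normalized by its total observation count
    (including out-of-range mass), then averaged across animals, so the
    returned bar heights sum to <= 1, with equality when no mass falls
    outside ``freq_range``.

    Returns ``(bin_edges, heights)``.
    """
    if len(per_animal) == 0:
        raise ValueError("need at least one animal")
    lo, hi = freq_range
    edges = np.arange(lo, hi + bin_width / 2, bin_width)
    if edges[-1] < hi:
        edges = np.append(edges, edges[-1] + bin_width)
    acc = np.zeros(edges.size - 1)
    for vals in per_animal:
        vals = np.asarray(vals, float)
        if vals.size == 0:
            raise ValueError("animal with no frequency values")
        counts, _ = np.histogram(vals, bins=edges)
        acc += counts / vals.size
    return edges, acc / len(per_animal)

def ar_line_powers(model: ARModel, rate: float) -> list[tuple[float, float]]:
    """Per-line power of an AR model by exact residue decomposition.

    The process variance of an AR model splits exactly over its poles:
    ``gamma(0) = sigma^2 * sum_k res_k`` with
    ``res_k = p_k^(P-1) / (prod_{j!=k}(p_k - p_j) * prod_j(1 - p_j p_k))``.
    Each complex pole pair is a spectral line at the pole angle carrying
    power ``2 sigma^2 Re(res)``; this is grid-free, so it stays exact even
    when a high-SNR line is far narrower than any display grid's spacing.
    Returns (frequency_hz, power) sorted by frequency, complex pairs only.
    """
    if model.order == 0:
        return []
    poly = np.concatenate([[1.0], -np.asarray(model.coeffs)])
    roots = np.roots(poly)
    p_ord = roots.size
    out = []
    for k, p in enumerate(roots):
        if p.imag <= 1e-12:      # one entry per conjugate pair
            continue
        others = np.delete(roots, k)
        denom = np.prod(p - others) * np.prod(1.0 - roots * p)
        if denom == 0:
            continue
        res = p ** (p_ord - 1) / denom
        f0 = float(np.angle(p) / (2.0 * np.pi) * rate)
        out.append((f0, float(2.0 * model.sigma2 * res.real)))
    return sorted(out)


def mode_track(ts: TimeSeries, window_s: float = 12.8, overlap: float = 0.5,
               order: int | None = None, band: tuple[float, float] = (0.2, 2.5),
               prefer_fundamental: bool = True,
               harmonic_ratio: float = 0.3) -> FrequencyTrack:
    """Track the rhythm frequency via per-window AR line powers.

    Like :func:`spectrogram` + :func:`track_peak` but the per-window
    frequency is the pole angle of the strongest spectral *line* (by
    integrated power) within the band, rather than the argmax of the
    sampled density.  With ``prefer_fundamental`` the strongest line is
    snapped down to a line near half or a third of its frequency whenever
    that line carries at least ``harmonic_ratio`` of its power - waveform
    harmonics never carry more power than the fundamental, so this
    resolves harmonic ambiguity deterministically.
    """
    n_win = int(round(window_s * ts.rate))
    if n_win > ts.n:
        raise ValueError(f"record shorter than one window ({window_s} s)")
    step = int(round(n_win * (1 - overlap)))
    p = default_order(n_win) if order is None else order
    lo, hi = band
    starts = np.arange(0, ts.n - n_win + 1, step)
    centers = np.empty(starts.size)
    freqs = np.empty(starts.size)
    powers = np.empty(starts.size)
    for i, s0 in enumerate(starts):
        seg = ts.samples[s0:s0 + n_win]
        centers[i] = ts.t0 + (s0 + (n_win - 1) / 2.0) / ts.rate
        seg = seg - seg.mean()
        if float(np.dot(seg, seg)) <= 0.0:
            freqs[i] = lo
            powers[i] = 0.0
            continue
        lines = [(f, pw) for f, pw in
                 ar_line_powers(burg_fit(seg, p), ts.rate)
                 if lo <= f <= hi]
        if not lines:
            freqs[i] = lo
            powers[i] = 0.0
            continue
        f_star, p_star = max(lines, key=lambda t: t[1])
        if prefer_fundamental:
            for kdiv in (2, 3):
                cands = [(f, pw) for f, pw in lines
                         if abs(f - f_star / kdiv) < 0.15 * f_star / kdiv
                         and pw >= harmonic_ratio * p_star]
                if cands:
                    f_star, p_star = max(cands, key=lambda t: t[1])
                    break
        freqs[i] = f_star
        powers[i] = p_star
    return FrequencyTrack(centers, freqs, powers)
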