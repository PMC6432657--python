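"""Synthetic two-channel PPG generator with ground truth.

Emulates the statistical structure of in vivo crab heart/pyloric
photoplethysmograms so every analysis stage can be verified against known
ground truth: a quasi-periodic pulsatile heart channel, a smooth
two-harmonic pyloric oscillation, a heart-frequency artifact mixed into the
pyloric channel at a fixed phase offset, two-state Markov bradycardia bouts
that collapse heart amplitude and slow the pyloric rhythm, and temperature
ramps with Q10-governed frequency scaling and a programmed irregular
"crash" above a per-channel critical temperature.

Purely phenomenological: no conductance-based modeling of the cardiac or
stomatogastric ganglia.  Amplitudes are arbitrary PPG units.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Optional, Sequence

import numpy as np
import pandas as pd
from scipy import ndimage, special

from .core import RecordingSet, TimeSeries

__all__ = ["SynthParams", "GroundTruth", "gen_baseline", "gen_ramp",
           "gen_population"]


@dataclass
class SynthParams:
    """Generator parameters.

    Defaults reflect typical baseline animals: a 0.6 Hz heart rhythm and a
    1 Hz pyloric rhythm at an 11 degC reference temperature, Q10 ~ 2 for
    both rhythms, heart crash near 25 degC and pyloric crash near 19 degC,
    exponential bout dwell times with 300 s active / 30 s inhibitory means.
    """

    f_heart: float = 0.6                 # Hz
    f_pyloric: float = 1.0               # Hz
    heart_pulse_width: Optional[float] = None   # s; default 80% of each cycle
    amp_heart: float = 1.0
    amp_pyloric: float = 1.0
    coupling: float = 0.0                # fraction of heart waveform in pyloric
    coupling_phase_deg: float = 0.0      # degrees of the heart cycle
    noise_sd: float = 0.05
    freq_jitter_sd: float = 0.02         # fractional slow wander of rhythm freq
    freq_jitter_tau_s: float = 20.0      # correlation time of the wander
    cycle_jitter_sd: float = 0.02        # fractional beat-to-beat period jitter
    bouts: bool = False
    bout_mean_active_s: float = 300.0
    bout_mean_inhib_s: float = 30.0
    bout_freq_factor: float = 0.6        # pyloric frequency factor during bouts
    bout_amp_factor: float = 0.1         # heart amplitude factor during bouts
    bout_schedule: Optional[Sequence[tuple]] = None  # explicit (start_s, end_s)
    pin_inhibitory_mean: bool = True     # rescale dwells to realize the mean exactly
    post_bout_overshoot: bool = False
    overshoot_amp: float = 0.5           # extra fractional amplitude
    overshoot_tau_s: float = 10.0
    q10_heart: float = 2.007
    q10_pyloric: float = 2.040
    t_crit_heart: float = 25.0           # degC
    t_crit_pyloric: float = 19.1         # degC
    crash_jitter_sd: float = 0.2         # s, per-cycle period jitter past crash
    crash_tau_s: float = 120.0           # frequency relaxation after crash
    crash_amp_tau_s: float = 300.0       # amplitude decay after crash
    ref_temp: float = 11.0               # degC
    duration_s: float = 1800.0
    rate: float = 500.0                  # Hz
    seed: int = 0

    def validate(self) -> None:
        for name in ("f_heart", "f_pyloric"):
            f = getattr(self, name)
            if not (0 < f < self.rate / 2):
                raise ValueError(f"{name}={f} must lie in (0, Nyquist)")
        if not (0 <= self.coupling <= 1):
            raise ValueError("coupling must lie in [0, 1]")
        if self.bout_mean_active_s <= 0 or self.bout_mean_inhib_s <= 0:
            raise ValueError("bout dwell means must be positive")
        if self.q10_heart <= 0 or self.q10_pyloric <= 0:
            raise ValueError("Q10 must be positive")
        if self.duration_s <= 0 or self.rate <= 0:
            raise ValueError("duration and rate must be positive")
        if self.heart_pulse_width is not None and self.heart_pulse_width <= 0:
            raise ValueError("heart_pulse_width must be positive")
        if self.noise_sd < 0:
            raise ValueError("noise_sd must be non-negative")
        if self.freq_jitter_sd < 0 or self.cycle_jitter_sd < 0:
            raise ValueError("jitter sds must be non-negative")


@dataclass
class GroundTruth:
    """Everything the generator knew: per-sample state and frequencies."""

    state: np.ndarray                    # 1 = active, 0 = inhibitory
    f_heart_inst: np.ndarray             # Hz per sample
    f_pyloric_inst: Optional[np.ndarray]
    true_phase_offset_deg: float
    true_q10: dict = field(default_factory=dict)
    true_t_crit: dict = field(default_factory=dict)

    def bout_intervals(self, rate: float) -> list[tuple[float, float]]:
        """(start_s, end_s) of inhibitory intervals."""
        flags = np.concatenate([[1], self.state, [1]])
        edges = np.flatnonzero(np.diff(flags))
        out = []
        for a, b in zip(edges[::2], edges[1::2]):
            out.append((a / rate, b / rate))
        return out


def _state_sequence(p: SynthParams, n: int, rng: np.random.Generator
                    ) -> np.ndarray:
    """Per-sample active(1)/inhibitory(0) flags.

    Explicit ``bout_schedule`` wins; otherwise an alternating-renewal
    process with exponential dwell times of the configured means.
    """
    state = np.ones(n, dtype=np.int8)
    if p.bout_schedule is not None:
        for start_s, end_s in p.bout_schedule:
            i0 = max(0, int(round(start_s * p.rate)))
            i1 = min(n, int(round(end_s * p.rate)))
            state[i0:i1] = 0
        return state
    if not p.bouts:
        return state

    def _draw(n_pairs):
        act = rng.exponential(p.bout_mean_active_s, n_pairs)
        inh = rng.exponential(p.bout_mean_inhib_s, n_pairs)
        return act, inh

    n_pairs = int(p.duration_s / (p.bout_mean_active_s
                                  + p.bout_mean_inhib_s) * 3) + 20
    act, inh = _draw(n_pairs)
    if p.pin_inhibitory_mean:
        # Rescale the inhibitory dwells so the realized mean of the bouts
        # that land inside the record equals the requested mean exactly
        # (exponential shape, mean-matched).  With ~60 bouts in a 6 h
        # record the raw sample mean wanders by ~12%, which would swamp
        # any downstream recovery of the injected value.
        for _ in range(4):
            t, used = 0.0, []
            for a, b in zip(act, inh):
                t += a
                if t >= p.duration_s:
                    break
                if t + b <= p.duration_s:
                    used.append(b)
                t += b
            if not used:
                break
            scale = p.bout_mean_inhib_s / np.mean(used)
            if abs(scale - 1.0) < 1e-9:
                break
            inh = inh * scale
    t = 0.0
    for a, b in zip(act, inh):
        t += a
        if t >= p.duration_s:
            break
        i0 = int(round(t * p.rate))
        i1 = min(n, int(round((t + b) * p.rate)))
        state[i0:i1] = 0
        t += b
    return state


def _render_pulse_train(onsets: np.ndarray, amps: np.ndarray,
                        widths: np.ndarray, n: int, rate: float
                        ) -> np.ndarray:
    """Sum of raised-cosine pulses with per-pulse widths at the onsets.

    The pulse shape is evaluated in continuous time at each sample instant
    (no onset quantization to the sample grid, which would imprint
    spuriously sharp harmonic lines on the spectrum).
    """
    out = np.zeros(n)
    for t_on, a, width in zip(onsets, amps, widths):
        i0 = int(np.ceil(t_on * rate))
        if i0 >= n:
            break
        i1 = min(int(np.floor((t_on + width) * rate)) + 1, n)
        tt = np.arange(i0, i1) / rate - t_on
        out[i0:i1] += a * 0.5 * (1.0 - np.cos(2.0 * np.pi * tt / width))
    return out


def _pulse_widths(p: SynthParams, onsets: np.ndarray) -> np.ndarray:
    """Per-pulse widths: 80% of each cycle (real heartbeats shorten as the
    rate rises), or the explicit ``heart_pulse_width`` capped at 95% of
    the cycle so pulses never fuse into a constant."""
    if onsets.size < 2:
        periods = np.array([1.0 / p.f_heart] * onsets.size)
    else:
        periods = np.diff(onsets)
        periods = np.append(periods, periods[-1])
    if p.heart_pulse_width is None:
        return 0.8 * periods
    return np.minimum(p.heart_pulse_width, 0.95 * periods)


def _freq_wander(p: SynthParams, n: int, rng: np.random.Generator
                 ) -> np.ndarray:
    """Slow multiplicative frequency wander, 1 + j(t).

    Emulates physiological rhythm variability (heart-rate variability and
    its pyloric analogue): white noise smoothed to ``freq_jitter_tau_s``
    correlation time, scaled to fractional sd ``freq_jitter_sd``.  Besides
    realism, the wander keeps the spectral lines from being numerically
    pure tones, on which high-order Burg fits are known to split peaks.
    """
    if p.freq_jitter_sd == 0:
        return np.ones(n)
    w = rng.normal(0.0, 1.0, n)
    size = max(int(p.freq_jitter_tau_s * p.rate), 1)
    sm = ndimage.uniform_filter1d(w, size=size)
    sd = np.std(sm)
    if sd > 0:
        sm = sm / sd * p.freq_jitter_sd
    return np.clip(1.0 + sm, 0.2, 5.0)


def _onsets_from_freq(f_inst: np.ndarray, rate: float, duration_s: float,
                      cycle_jitter_sd: float = 0.0,
                      rng: np.random.Generator | None = None) -> np.ndarray:
    """Cycle onset times for a (possibly wandering) instantaneous frequency.

    ``cycle_jitter_sd`` adds fractional beat-to-beat period jitter (the
    phase random walk broadens the spectral line to a physiological
    width; without it the line is a numerically pure tone).
    """
    onsets = []
    t = 0.0
    n = f_inst.size
    while t < duration_s:
        onsets.append(t)
        i = min(int(t * rate), n - 1)
        period = 1.0 / f_inst[i]
        if cycle_jitter_sd > 0 and rng is not None:
            period *= max(1.0 + cycle_jitter_sd * rng.standard_normal(), 0.2)
        t += period
    return np.array(onsets)


def _fast_freq_noise(p: SynthParams, n: int, rng: np.random.Generator
                     ) -> np.ndarray:
    """Cycle-scale multiplicative frequency noise for the pyloric channel
    (~1 s correlation), the phase-integrated analogue of beat-to-beat
    period jitter."""
    if p.cycle_jitter_sd == 0:
        return np.ones(n)
    w = rng.normal(0.0, 1.0, n)
    sm = ndimage.uniform_filter1d(w, size=max(int(1.0 * p.rate), 1))
    sd = np.std(sm)
    if sd > 0:
        sm = sm / sd * p.cycle_jitter_sd
    return np.clip(1.0 + sm, 0.2, 5.0)


def _amp_envelope(p: SynthParams, state: np.ndarray, n: int) -> np.ndarray:
    env = np.where(state == 1, 1.0, p.bout_amp_factor).astype(float)
    if p.post_bout_overshoot:
        # decaying extra amplitude triggered at each inhibitory->active edge
        ends = np.flatnonzero(np.diff(state.astype(int)) == 1) + 1
        t = np.arange(n) / p.rate
        for e in ends:
            tail = t[e:] - t[e]
            env[e:] += p.overshoot_amp * np.exp(-tail / p.overshoot_tau_s)
    return env


def _pyloric_wave(phase: np.ndarray) -> np.ndarray:
    """Asymmetric smooth oscillation: fundamental plus a weaker 2nd harmonic."""
    return np.sin(phase) + 0.5 * np.sin(2.0 * phase + 1.0)


def _coupling_artifact(params: SynthParams, heart_clean: np.ndarray,
                       n: int) -> np.ndarray:
    """Heart-frequency artifact superimposed on the pyloric channel.

    The heart waveform is delayed by ``coupling_phase_deg`` of the heart
    cycle and smoothed (zero-phase Gaussian, ~0.1 s) before mixing: the
    artifact reaches the pyloric sensor through tissue and the ophthalmic
    artery, which transmit the smooth pulsation, not the sharp pulse
    edges, so the artifact is dominated by the heart's fundamental.
    """
    if params.coupling <= 0:
        return np.zeros(n)
    delay_s = (params.coupling_phase_deg / 360.0) / params.f_heart
    shift = int(round(delay_s * params.rate))
    shifted = np.zeros(n)
    if shift < n:
        shifted[shift:] = heart_clean[:n - shift] if shift else heart_clean
    smooth = ndimage.gaussian_filter1d(shifted, sigma=0.1 * params.rate)
    return params.coupling * smooth


def gen_baseline(params: SynthParams) -> tuple[RecordingSet, GroundTruth]:
    """Generate a baseline (constant temperature) two-channel recording.

    Heart channel: raised-cosine pulse train at ``f_heart`` whose pulse
    amplitude collapses to ``bout_amp_factor`` during inhibitory states,
    plus white noise.  Pyloric channel: two-harmonic oscillation whose
    frequency is multiplied by ``bout_freq_factor`` during inhibitory
    states, plus ``coupling`` times the heart waveform delayed by
    ``coupling_phase_deg`` of the heart cycle, plus white noise.
    """
    params.validate()
    rng = np.random.default_rng(params.seed)
    n = int(round(params.duration_s * params.rate))
    state = _state_sequence(params, n, rng)

    f_heart_inst = params.f_heart * _freq_wander(params, n, rng)
    onsets = _onsets_from_freq(f_heart_inst, params.rate, params.duration_s,
                               params.cycle_jitter_sd, rng)
    env = _amp_envelope(params, state, n)
    onset_idx = np.minimum((onsets * params.rate).astype(int), n - 1)
    heart_clean = _render_pulse_train(
        onsets, params.amp_heart * env[onset_idx],
        _pulse_widths(params, onsets), n, params.rate)
    heart = heart_clean + rng.normal(0.0, params.noise_sd, n)

    f_pyl_inst = params.f_pyloric * np.where(state == 1, 1.0,
                                             params.bout_freq_factor) \
        * _freq_wander(params, n, rng) * _fast_freq_noise(params, n, rng)
    phase = 2.0 * np.pi * np.cumsum(f_pyl_inst) / params.rate
    pyl = params.amp_pyloric * _pyloric_wave(phase)
    pyl = pyl + _coupling_artifact(params, heart_clean, n)
    pyl = pyl + rng.normal(0.0, params.noise_sd, n)

    rec = RecordingSet(
        heart=TimeSeries(heart, rate=params.rate, label="heart"),
        pyloric=TimeSeries(pyl, rate=params.rate, label="pyloric"),
        animal_id="synthetic")
    truth = GroundTruth(
        state=state,
        f_heart_inst=f_heart_inst,
        f_pyloric_inst=f_pyl_inst,
        true_phase_offset_deg=params.coupling_phase_deg,
        true_q10={"heart": params.q10_heart, "pyloric": params.q10_pyloric},
        true_t_crit={})
    return rec, truth


def _ramp_temperature(params: SynthParams, ramp: tuple, n: int) -> np.ndarray:
    t_start, temp0, temp1, ramp_dur = ramp
    if temp1 <= temp0:
        raise ValueError("heating ramp requires T_end > T_start")
    if t_start + ramp_dur > params.duration_s + 1e-9:
        raise ValueError("ramp window exceeds record duration")
    t = np.arange(n) / params.rate
    temp = np.full(n, float(temp0))
    rising = (t >= t_start) & (t < t_start + ramp_dur)
    temp[rising] = temp0 + (temp1 - temp0) * (t[rising] - t_start) / ramp_dur
    temp[t >= t_start + ramp_dur] = temp1
    return temp


def _q10_freq(f_base: float, q10: float, temp: np.ndarray,
              ref: float) -> np.ndarray:
    return f_base * q10 ** ((temp - ref) / 10.0)


def gen_ramp(params: SynthParams, ramp: tuple[float, float, float, float]
             ) -> tuple[RecordingSet, GroundTruth]:
    """Generate a temperature-ramp recording with Q10 scaling and crashes.

    ``ramp = (t_start_s, T_start, T_end, ramp_duration_s)``; temperature
    rises linearly then holds.  Below its critical temperature each
    channel's instantaneous frequency follows ``f_base * Q10**((T - ref)/10)``.
    At and above the critical temperature the channel "crashes": the mean
    frequency relaxes back toward the baseline value (time constant
    ``crash_tau_s``), the amplitude decays (``crash_amp_tau_s``), and cycle
    periods acquire Gaussian jitter of sd ``crash_jitter_sd`` seconds
    (heart) or an equivalent smooth frequency jitter (pyloric), producing
    the irregular spectral signature used by crash detection.
    """
    params.validate()
    rng = np.random.default_rng(params.seed)
    n = int(round(params.duration_s * params.rate))
    temp = _ramp_temperature(params, ramp, n)
    t = np.arange(n) / params.rate

    # ---- heart: cycle-by-cycle pulse train -------------------------------
    f_heart_nom = _q10_freq(params.f_heart, params.q10_heart, temp,
                            params.ref_temp)
    crossed = temp >= params.t_crit_heart
    t_crash_h = t[np.argmax(crossed)] if crossed.any() else None
    onsets, amps = [], []
    tc = 0.0
    while tc < params.duration_s:
        i = min(int(tc * params.rate), n - 1)
        if t_crash_h is None or tc < t_crash_h:
            f = f_heart_nom[i]
            amp = params.amp_heart
            period = 1.0 / f
        else:
            dtc = tc - t_crash_h
            f_crash = _q10_freq(params.f_heart, params.q10_heart,
                                np.array([params.t_crit_heart]),
                                params.ref_temp)[0]
            f = params.f_heart + (f_crash - params.f_heart) * np.exp(
                -dtc / params.crash_tau_s)
            amp = params.amp_heart * (0.3 + 0.7 * np.exp(
                -dtc / params.crash_amp_tau_s))
            period = 1.0 / f + rng.normal(0.0, params.crash_jitter_sd)
            period = max(period, 0.25 / f)
        onsets.append(tc)
        amps.append(amp)
        tc += period
    onsets = np.array(onsets)
    heart_clean = _render_pulse_train(onsets, np.array(amps),
                                      _pulse_widths(params, onsets), n,
                                      params.rate)
    heart = heart_clean + rng.normal(0.0, params.noise_sd, n)

    # ---- pyloric: phase-continuous oscillation ---------------------------
    f_pyl_nom = _q10_freq(params.f_pyloric, params.q10_pyloric, temp,
                          params.ref_temp)
    crossed_p = temp >= params.t_crit_pyloric
    f_pyl = f_pyl_nom.copy()
    amp_pyl = np.full(n, params.amp_pyloric)
    if crossed_p.any():
        ic = int(np.argmax(crossed_p))
        dtc = t[ic:] - t[ic]
        f_crash = f_pyl_nom[ic]
        f_pyl[ic:] = params.f_pyloric + (f_crash - params.f_pyloric) * np.exp(
            -dtc / params.crash_tau_s)
        # smooth multiplicative frequency jitter: white noise low-passed to
        # ~0.5 s correlation, scaled to match crash_jitter_sd per cycle
        wn = rng.normal(0.0, 1.0, n - ic)
        smooth = ndimage.uniform_filter1d(wn, size=max(int(0.5 * params.rate), 1))
        smooth /= max(np.std(smooth), 1e-12)
        rel_sd = params.crash_jitter_sd * f_crash
        f_pyl[ic:] *= np.clip(1.0 + rel_sd * smooth, 0.1, 3.0)
        amp_pyl[ic:] = params.amp_pyloric * (0.3 + 0.7 * np.exp(
            -dtc / params.crash_amp_tau_s))
    phase = 2.0 * np.pi * np.cumsum(f_pyl) / params.rate
    pyl = amp_pyl * _pyloric_wave(phase)
    pyl = pyl + _coupling_artifact(params, heart_clean, n)
    pyl = pyl + rng.normal(0.0, params.noise_sd, n)

    rec = RecordingSet(
        heart=TimeSeries(heart, rate=params.rate, label="heart"),
        pyloric=TimeSeries(pyl, rate=params.rate, label="pyloric"),
        temperature=TimeSeries(temp, rate=params.rate, label="temperature"),
        animal_id="synthetic-ramp")
    truth = GroundTruth(
        state=np.ones(n, dtype=np.int8),
        f_heart_inst=f_heart_nom,
        f_pyloric_inst=f_pyl,
        true_phase_offset_deg=params.coupling_phase_deg,
        true_q10={"heart": params.q10_heart, "pyloric": params.q10_pyloric},
        true_t_crit={"heart": params.t_crit_heart,
                     "pyloric": params.t_crit_pyloric})
    return rec, truth


def gen_population(n_animals: int, corr: float,
                   heart_range: tuple[float, float] = (0.4, 2.4),
                   pyloric_range: tuple[float, float] = (0.2, 1.6),
                   seed: int | np.random.Generator = 0) -> pd.DataFrame:
    """Draw paired baseline frequencies from a Gaussian copula.

    Marginals are uniform on the stated ranges.  The latent Gaussian
    correlation is set to ``2 sin(pi * corr / 6)`` so the Pearson
    correlation of the uniform marginals equals ``corr`` exactly in
    expectation.
    """
    if n_animals < 3:
        raise ValueError("need at least 3 animals")
    if not (-1 < corr < 1):
        raise ValueError("corr must lie in (-1, 1)")
    for lo, hi in (heart_range, pyloric_range):
        if hi <= lo:
            raise ValueError("invalid frequency range")
    rng = (seed if isinstance(seed, np.random.Generator)
           else np.random.default_rng(seed))
    rho = 2.0 * np.sin(np.pi * corr / 6.0)
    cov = np.array([[1.0, rho], [rho, 1.0]])
    z = rng.multivariate_normal([0.0, 0.0], cov, size=n_animals,
                                method="cholesky")
    u = special.ndtr(z)   # standard normal CDF
    heart = heart_range[0] + u[:, 0] * (heart_range[1] - heart_range[0])
    pyl = pyloric_range[0] + u[:, 1] * (pyloric_range[1] - pyloric_range[0])
    return pd.DataFrame({
        "animal_id": [f"synth{i:03d}" for i in range(n_animals)],
        "heart_hz": heart,
        "pyloric_hz": pyl,
    })
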