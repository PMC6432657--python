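# ppgrhythms

Analysis of simultaneously recorded crustacean heart and pyloric rhythms
from photoplethysmogram (PPG) signals — the in vivo dual-rhythm recordings
used to study how the cardiac ganglion (heartbeat) and the stomatogastric
ganglion (pyloric stomach rhythm) of the crab *Cancer borealis* behave at
baseline and under temperature ramps.

The package is for neurophysiologists working with long two-channel PPG
(or comparable rhythmic biosignal) recordings at a few hundred Hz who need
to: track each rhythm's frequency over hours, remove the heartbeat
artifact that the pyloric sensor picks up, segment bradycardia ("inhibitory
bout") episodes, quantify heart–pyloric coupling, and estimate temperature
sensitivity. Because such recordings are rarely shared, a first-class
synthetic generator reproduces their statistical structure with known
ground truth, so every stage of the pipeline is verifiable.

## Methods at a glance

- **Spectral frequency tracking** — moving-window Burg autoregressive
  spectra: windows of 12.8 s (128 samples at the 10 Hz working rate), 50%
  overlap, AR order *P* = window/4 + 1 = 33. The rhythm frequency per
  window is the frequency at peak spectral power; `mode_track` reads it
  directly from the AR pole with the greatest line power (exact residue
  decomposition of the process variance), which stays robust when the
  rhythm line is narrower than any display grid.
- **Preprocessing** — offset removal, zero-phase 6th-order Butterworth
  low-pass at 5 Hz, decimation from 500 Hz to 10 Hz.
- **Heart-artifact subtraction** — the pyloric channel is regressed (OLS,
  with the lag that maximizes the cross-correlation) on the heart channel
  and the fitted component subtracted.
- **Bout segmentation** — a two-state Gaussian hidden Markov model on
  log-RMS amplitude in 2 s windows, trained by Baum–Welch (initial
  transitions P_AI = P_IA = 0.9), decoded by Viterbi; run lengths give the
  bout duration table.
- **Coherence** — multitaper (Slepian) coherence in 2 min windows stepped
  by 5 s, time–bandwidth NW = 10 with K = 19 tapers; theoretical
  confidence level `C = sqrt(1 − α'^(1/(K−1)))` with Bonferroni-corrected
  α′, phase convention: pyloric relative to heart, degrees in [0, 360).
- **Temperature response** — Q10 by log-linear regression
  `log10 F = m·T + b`, `Q10 = 10^(10 m)`; critical ("crash") temperature
  as the first sustained co-occurrence of frequency drop and loss of
  spectral peakiness on a rising ramp.
- **Population statistics** — Pearson correlations, one-way ANOVA, and
  Hartigan's dip test of unimodality with bootstrap p-values.

See `docs/methods.md` for the full model description, parameter defaults,
and known limitations.

## Worked example

Simulate ten minutes of a coupled two-channel recording (heart 1.1 Hz,
pyloric 0.5 Hz, 40% of the heart waveform mixed into the pyloric channel
at a 190° phase offset), condition both channels, track the heart, remove
the heart artifact from the pyloric channel, and measure coherence:

```sh
ppgrhythms simulate --seed 42 --out-prefix crab --duration 600 \
    --f-heart 1.1 --f-pyloric 0.5 --coupling 0.4 --coupling-phase 190 \
    --noise-sd 0.1
ppgrhythms preprocess crab_heart.csv heart10.csv
ppgrhythms preprocess crab_pyloric.csv pyl10.csv
ppgrhythms spectrogram heart10.csv --spec-out spec.csv --track-out track.csv
ppgrhythms subtract-heart heart10.csv pyl10.csv pyl_clean.csv
ppgrhythms spectrogram pyl_clean.csv --spec-out pspec.csv --track-out ptrack.csv
ppgrhythms coherence heart10.csv pyl10.csv --out coh.csv
```

printed output:

```
median peak frequency: 1.1 Hz
lag=5 samples gain=0.3097 residual_var=0.6249
median peak frequency: 0.5034 Hz
threshold C=0.6168; significant fraction 1.000; median phase 191.5 deg
```

Reading it: the heart tracks at its true 1.1 Hz; the artifact regression
finds the pyloric channel lagging the heart by 5 samples (0.5 s ≈ 190° of
a 1.1 Hz cycle) with gain 0.31; after subtraction the pyloric rhythm
tracks at its true 0.5 Hz; the channels are significantly coherent in
every window and the phase at peak coherence recovers the injected 190°
offset (191.5°).

The same stages are available as library functions
(`ppgrhythms.preprocess.condition`, `spectra.mode_track`,
`heartsub.regress_subtract`, `bouts.baum_welch`, `coherence.mt_coherence`,
`thermal.q10_fit`, …) operating on `TimeSeries` objects.

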