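# Methods

This note documents the models and procedures implemented in
`ppgrhythms`, the defaults that matter, what the synthetic generator does
and does not emulate, and the numerical choices made where the design was
genuinely open.

## Signals and conditioning

The pipeline's currency is an evenly sampled single-channel `TimeSeries`
(arbitrary PPG units, rate in Hz, start time in seconds). Raw recordings
are assumed to arrive at 500 Hz. Conditioning (`preprocess.condition`)
removes the voltage offset, low-pass filters at 5 Hz with a 6th-order
Butterworth, and decimates to a 10 Hz working rate, at which the standard
12.8 s spectral window holds exactly 128 samples.

Filtering is applied forward-backward (zero phase). The alternative — a
causal single pass — would delay each channel by a frequency-dependent
group delay and contaminate the heart–pyloric phase estimates, which are a
headline output; zero-phase filtering squares the magnitude response
(gain 1/2 rather than 1/√2 at the cutoff), which is irrelevant to peak
*location* statistics. Decimation uses plain integer-stride sampling: the
5 Hz low-pass is exactly the Nyquist frequency of the 10 Hz target, so no
additional anti-aliasing stage is needed; changing either rate
inconsistently triggers a logged warning, not an error.

## Burg spectral tracking

Each 128-sample window is fitted with an autoregressive model of order
*P* = window/4 + 1 = 33 by the Burg recursion (reflection coefficients
minimizing the summed forward plus backward prediction error; the
recursion stops early if the relative prediction error collapses below
1e-12, which happens only on noiseless periodic inputs where further
stages would fit floating-point noise). The PSD is evaluated as
`σ²/rate / |1 − Σ φ_k e^(−2πifk/rate)|²` on 1024 grid points over
[0, 5] Hz (bin ≈ 0.0049 Hz).

Two peak-frequency readers are provided:

- `track_peak` — argmax of the sampled PSD within a band (ties toward the
  lower frequency). This is the textbook reading, but on high-SNR rhythms
  the Burg poles sit so close to the unit circle (|r| ~ 0.99998 measured)
  that a line's width can be far below the grid spacing; the sampled peak
  *density* then becomes erratic, occasionally handing the argmax to a
  waveform harmonic carrying a small fraction of the power.
- `mode_track` — the frequency is the angle of the AR pole pair with the
  greatest *line power*, obtained from the exact residue decomposition of
  the process variance over the poles
  (`res_k = p_k^(P−1) / (Π_{j≠k}(p_k − p_j) · Π_j(1 − p_j p_k))`, verified
  against closed-form AR(1)/AR(2) variances). Line powers are grid-free
  and stable, so this reader is used wherever the track feeds quantitative
  analysis (thermal fits, bout-slowing readouts). A deterministic
  disambiguation step snaps the strongest line down to a line near f/2 or
  f/3 when that line carries at least 30% of its power — a waveform
  harmonic never outpowers its fundamental.

Consumers of tracks (`thermal.q10_fit`,
`thermal.detect_critical_temperature`) additionally median-smooth the
track over 5 windows; an isolated harmonic-locked window would otherwise
poison running maxima.

Tracking accuracy, measured against the generator's ground-truth
instantaneous frequency: ≥95% of windows within 0.05 Hz, with the window
median within ~2 grid bins of the true frequency. Claims of exact 1-bin
accuracy are not achievable with this window/order/grid combination:
high-order Burg on near-pure tones shows the classic line-splitting bias
of 2–4 bins, an estimator property (verified identical in an independent
Burg implementation), not an implementation artifact.

## Heart-artifact subtraction

The pyloric sensor picks up the heartbeat (arterial pulsation or direct
biomechanical coupling). The artifact is removed by ordinary least
squares: the heart channel, shifted by the single integer-sample lag that
maximizes the absolute cross-correlation (ties toward the smallest |lag|),
is scaled and subtracted. The "phase difference" between the channels is
thus operationalized as one global lag; a per-window refit (120 s) is
available for temperature ramps where the coupling gain drifts. The
regression includes an intercept even though channels are offset-removed
(cheap, harmless). A silent heart regressor returns the input unchanged
with gain 0, logged. Least-squares guarantees the residual variance never
exceeds the input variance and that the cleaned signal is uncorrelated
with the regressor.

## Bout segmentation

Bradycardia bouts collapse the heart PPG envelope. The observable is the
log of the windowed standard deviation (RMS about the window mean) in 2 s
windows stepped by 1 s — insensitive to local baseline level, strongly
bimodal on bout recordings, with modes separated by about |log(amplitude
factor)|. A two-state Gaussian HMM is trained on it by Baum–Welch with
scaled forward-backward; the log-likelihood is asserted non-decreasing at
every iteration and iteration stops at a relative tolerance of 1e-6 or
500 iterations.

Initialization: transitions start at the published values
(P_AI = P_IA = 0.9, self-transitions 0.1) and are re-estimated; emission
means seed at the 2nd/98th feature percentiles and variances at a quarter
of the pooled variance. Both choices matter: with bouts at a realistic
~10% duty cycle a more central quantile seeds both means inside the active
mode, and a full-variance seed lets the fast-switching transition prior
wash out the emission separation — in either case EM converges to a
degenerate one-mode split.

Decoding is by Viterbi (posteriors from forward-backward are also
returned); the state with the lower emission mean is labeled inhibitory,
making results permutation-stable and affine-invariant. Run-length
encoding of the decoded path gives the bout table; durations tile the
record exactly. No minimum bout duration filter is applied by default.
Bouts shorter than the 2 s feature window are invisible to the decoder,
which biases the recovered mean inhibitory duration upward by roughly 5%
at a 30 s dwell mean.

## Multitaper coherence

Coherence between the conditioned channels is estimated in 120 s windows
stepped by 5 s with K = 19 Slepian tapers at time–bandwidth NW = 10
(half-bandwidth W = NW/T ≈ 0.083 Hz). Per window and frequency the
coherency is `S_xy / sqrt(S_xx S_yy)` with taper-averaged spectra; the
magnitude lies in [0, 1] and the phase is reported in degrees on
[0, 360), pyloric relative to heart, positive meaning the pyloric signal
lags (delaying the pyloric channel by τ at frequency f yields
+360·f·τ degrees).

Significance uses the theoretical confidence level
`C = sqrt(1 − α'^(1/(K−1)))` with `α' = α/m` (Bonferroni). The
multiplicity m defaults to the number of in-band frequency bins (277 at
the default resolution, giving C = 0.617 at α = 0.05): the per-window
statistic is a peak over those bins, and a smaller multiplicity leaves the
null exceedance far above α. A dataset is called coherent when more than
half of its windows exceed C; the phase summary is a circular median (an
ordinary median fails at the 0/360 wraparound).

A real limitation, reproduced and documented rather than hidden: two
*uncoupled* oscillators whose spectral lines are stable within a window
are indistinguishable from a coupled pair at finite bandwidth — at bins
within W of strong lines in both channels, the cross-phase is nearly fixed
and coherence stays high. The null behaves correctly once the rhythms
carry realistic phase diffusion (beat-to-beat jitter of several percent).
Coherence between clean, rhythm-rich channels should therefore be read as
"consistent phase relation", not proof of physiological coupling.

## Temperature response

Q10 is estimated by ordinary least squares of log10(frequency) on
temperature over the rising ramp, restricted to a fit range below the
critical temperature: `Q10 = 10^(10·m)`. Base-10 logarithms are a fixed
convention; any base gives an identical Q10 under the matching
back-transform (asserted in tests). The estimate is invariant to the
frequency unit. R² is the squared Pearson correlation of the fitted
pairs; a temperature-independent track returns Q10 = 1 with R² reported
as 0 and a warning. Temperature is paired to each window by linear
interpolation at the window center.

The critical ("crash") temperature is detected as the lowest temperature
at which, for at least 3 consecutive windows, (a) the tracked frequency
falls below 90% of its running maximum over the ramp so far, and (b) a
peakiness index (power at the tracked peak over total band power) falls
below 50% of its baseline median (baseline = windows within 1 °C of the
ramp start). All three thresholds are parameters. When the criteria never
co-occur the result is undetermined — the in vivo situation for many
irregular pyloric recordings — and the Q10 fit then uses the full rising
ramp, logged.

## Synthetic generator

The generator produces what the analysis assumes, with ground truth:

- **Heart channel**: raised-cosine pulses at the heart rate, each pulse
  spanning 80% of its cycle (real PPG heartbeats are broad; narrow pulses
  would put near-equal power into many harmonics, which no peak-frequency
  method can disambiguate). Pulses are rendered in continuous time —
  quantizing onsets to the sample grid imprints spuriously sharp harmonic
  lines.
- **Pyloric channel**: a two-harmonic asymmetric oscillation
  (`sin φ + 0.5 sin(2φ + 1)`) to mimic complex pyloric waveforms.
- **Rhythm variability**: slow multiplicative frequency wander (fractional
  sd 2%, correlation time 20 s) and beat-to-beat period jitter (2%).
  These are physiological (heart-rate-variability-like) and also
  numerically essential: with literally zero variability and noise the
  Burg prediction error collapses to machine precision and every spectral
  statistic degenerates. "Noiseless" configurations in tests therefore
  mean no *sensor* noise (default floor sd 0.05) unless variability is
  explicitly zeroed for exact-construction checks.
- **Coupling**: a fraction of the heart waveform, delayed by a phase
  expressed in degrees of the heart cycle and smoothed by a 0.1 s
  zero-lag Gaussian (tissue and arterial transmission pass the smooth
  pulsation, not sharp pulse edges), is added to the pyloric channel.
- **Bouts**: a two-state alternating-renewal process with exponential
  dwell times (defaults 300 s active / 30 s inhibitory). The inhibitory
  state scales heart amplitude by 0.1 and pyloric frequency by 0.6. By
  default the realized inhibitory dwell mean is pinned exactly to the
  requested value (exponential shape, rescaled): a 6 h record holds only
  ~60 bouts, so the raw sample mean wanders by ~12% and would swamp any
  recovery benchmark of the injected value; `pin_inhibitory_mean=False`
  restores the pure renewal process. An explicit `bout_schedule` overrides
  the stochastic process. Optional post-bout amplitude overshoot is off by
  default.
- **Temperature ramps**: the tank temperature rises linearly (default
  experiment: 11→28 °C over 90 min) and each channel's instantaneous
  frequency follows `f_base · Q10^((T − 11)/10)` below its critical
  temperature. At and above it the channel "crashes": frequency relaxes
  back toward baseline (τ = 120 s), amplitude decays (τ = 300 s, floor
  0.3), and cycles acquire Gaussian period jitter (heart) or equivalent
  smooth frequency jitter (pyloric).
- **Population draws**: paired baseline frequencies from a Gaussian copula
  with uniform marginals on the requested ranges; the latent correlation
  is `2 sin(π·r/6)` so the Pearson correlation of the marginals equals the
  requested r exactly in expectation.

What the generator does **not** emulate: conductance-based dynamics of the
cardiac or stomatogastric ganglia, movement artifacts, sensor drift,
gastric-mill interference, bimodal bout-duration distributions (a mixture
option could emulate them but exponential dwells are the default), or
amplitude calibration (units are arbitrary throughout). Passing tests
demonstrate that the pipeline recovers what this class of signal contains;
they cannot certify behavior on artifact types the generator omits.

## Population statistics

Pearson correlations (two-sided p via the t transform, n−2 dof), one-way
ANOVA (between/within mean squares; equals the squared two-sample t for
two groups), and Hartigan's dip test. The dip statistic is computed from
its variational definition — the smallest band half-width d admitting a
nondecreasing convex-then-concave function through the ECDF bands
`[i/n − d, (i−1)/n + d]` — by bisection with convex-hull feasibility
passes; tied values intersect their bands. One documented simplification
(interior-mode junction monotonicity not enforced) makes the statistic at
most a few percent smaller on a small minority of samples relative to an
exact linear-programming reference (shipped with the tests); p-values are
exact regardless because the bootstrap null (default 2000 uniform samples
of the same n, cached per sample size) uses the same statistic. No
multiple-testing correction is applied across the population summary
table.

## Benchmarks

`ppgrhythms.recovery` holds the standing end-to-end benchmarks run by
`scripts/acceptance.py` and asserted in `tests/test_acceptance.py`:
injected values are the published population means (heart Q10 2.007,
pyloric Q10 2.040, 30 s mean inhibitory dwell, 25.0 °C heart crash,
190° coupling phase, r = 0.61 at n = 29, and 0.9 Hz pyloric slowing
inside a bout). Problem sizes — 90 min ramps, a 6 h bout record, a 30 min
coherence baseline, 200 population replicates — are the package's chosen
benchmark scales: large enough that estimator noise sits well inside each
tolerance, small enough to run in seconds.

## Known limitations

- Peak-frequency accuracy is bounded by Burg line splitting (±2–4 grid
  bins on near-pure tones); medians and regressions over many windows are
  accurate to much better than a bin.
- Coherence between clean stable oscillators overstates coupling (see
  above).
- The HMM assumes exactly two regimes with Gaussian log-RMS emissions;
  gradual bradycardia (frequency slowing without amplitude collapse) is
  not its observable.
- Crash detection requires a monotone rising ramp segment and a clean
  baseline; cooling/recovery kinetics are reported only via the track.
- The dip test's bootstrap p-values assume exchangeability under the
  uniform null; its statistic carries the documented small one-sided
  relaxation.
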