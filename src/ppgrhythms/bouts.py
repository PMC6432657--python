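"""Two-state hidden Markov segmentation of heart inhibitory bouts.

Periods of bradycardia (inhibitory bouts) collapse the heart PPG envelope.
The observable is the log root-mean-square amplitude in short moving
windows; a two-state Gaussian HMM is trained on it by Baum-Welch
(expectation-maximization with log-space forward-backward), the most
probable state path is decoded by Viterbi, and run lengths of the decoded
path give the bout duration table.  State labels are assigned by emission
mean - the low-amplitude state is "inhibitory" - so results are stable
under state permutation.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .core import TimeSeries

__all__ = ["HMMParams", "StateSequence", "BoutTable", "bout_feature",
           "baum_welch", "decode_states", "bout_durations"]

log = logging.getLogger(__name__)

LOG2PI = math.log(2.0 * math.pi)


@dataclass
class HMMParams:
    """Two-state Gaussian HMM parameters.

    ``transmat[i, j]`` is P(state j at t+1 | state i at t); rows sum to 1.
    ``means``/``variances`` parameterize the per-state Gaussian emissions
    on the bout feature.  The default initial transition values (0.1
    self-transition, 0.9 switch) follow the published initialization;
    Baum-Welch re-estimates them.
    """

    transmat: np.ndarray
    means: np.ndarray
    variances: np.ndarray
    startprob: np.ndarray
    log_likelihoods: list = field(default_factory=list)
    n_iter: int = 0
    converged: bool = False

    def __post_init__(self):
        self.transmat = np.asarray(self.transmat, float)
        self.means = np.asarray(self.means, float)
        self.variances = np.asarray(self.variances, float)
        self.startprob = np.asarray(self.startprob, float)
        if self.transmat.shape != (2, 2):
            raise ValueError("transmat must be 2x2")
        if not np.allclose(self.transmat.sum(axis=1), 1.0, atol=1e-8):
            raise ValueError("transition rows must sum to 1")
        if np.any(self.variances <= 0):
            raise ValueError("variances must be positive")
        if not np.isclose(self.startprob.sum(), 1.0, atol=1e-8):
            raise ValueError("startprob must sum to 1")

    @classmethod
    def default_init(cls, features: np.ndarray) -> "HMMParams":
        """Published initial transitions; emission means at the 2nd/98th
        feature percentiles (state 0 low = inhibitory-leaning).

        Extreme quantiles keep the low-state seed inside the bout mode even
        when bouts occupy only a few percent of the record; a more central
        quantile can start both means in the active mode, from which EM
        converges to a degenerate split.
        """
        f = np.asarray(features, float)
        lo, hi = np.percentile(f, [2, 98])
        # a quarter of the pooled variance per state: seeding with the
        # full variance lets the fast-switching transition prior wash out
        # the emission separation and EM collapses to a one-mode optimum
        var = max(float(np.var(f)) / 4.0, 1e-12)
        return cls(transmat=np.array([[0.1, 0.9], [0.9, 0.1]]),
                   means=np.array([lo, hi]),
                   variances=np.array([var, var]),
                   startprob=np.array([0.5, 0.5]))


@dataclass
class StateSequence:
    """Decoded state path with per-step inhibitory posterior."""

    window_times: np.ndarray
    state: np.ndarray              # 1 = active, 0 = inhibitory
    posterior_inhib: np.ndarray    # P(inhibitory | data) per step
    step_s: float

    def __post_init__(self):
        s = np.asarray(self.state)
        if not np.all((s == 0) | (s == 1)):
            raise ValueError("states must be binary")
        p = np.asarray(self.posterior_inhib, float)
        if np.any((p < -1e-9) | (p > 1 + 1e-9)):
            raise ValueError("posteriors must lie in [0, 1]")

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame({"time_s": self.window_times,
                             "state": self.state,
                             "posterior_inhib": self.posterior_inhib})


@dataclass
class BoutTable:
    """Alternating (state, start_s, duration_s) rows tiling the record."""

    table: pd.DataFrame
    summaries: dict = field(default_factory=dict)

    def to_frame(self) -> pd.DataFrame:
        return self.table

    def durations(self, state: int) -> np.ndarray:
        return self.table.loc[self.table["state"] == state,
                              "duration_s"].to_numpy()


def bout_feature(ts: TimeSeries, window_s: float = 2.0,
                 step_s: float = 1.0) -> TimeSeries:
    """Log RMS amplitude in moving windows: the bout observable.

    The heart envelope collapses during inhibitory bouts, so log-RMS is
    strongly bimodal on bout recordings, with modes separated by
    |log bout amplitude factor|.
    """
    n_win = int(round(window_s * ts.rate))
    step = int(round(step_s * ts.rate))
    if n_win > ts.n:
        raise ValueError("feature window longer than record")
    if n_win < 1 or step < 1:
        raise ValueError("window and step must be positive")
    starts = np.arange(0, ts.n - n_win + 1, step)
    sw = np.lib.stride_tricks.sliding_window_view(ts.samples, n_win)[starts]
    # RMS about the window mean: insensitive to local baseline offset, so
    # only the oscillation envelope (which collapses during bouts) counts
    rms = np.std(sw, axis=1)
    if np.any(rms <= 0):
        raise ValueError("zero-amplitude window: log-RMS undefined")
    centers = ts.t0 + (starts + (n_win - 1) / 2.0) / ts.rate
    return TimeSeries(np.log(rms), rate=1.0 / step_s, t0=float(centers[0]),
                      label="log_rms")


def _emission_loglik(f: np.ndarray, means: np.ndarray,
                     variances: np.ndarray) -> np.ndarray:
    """(n, 2) per-step Gaussian log densities."""
    out = np.empty((f.size, 2))
    for j in range(2):
        out[:, j] = -0.5 * (LOG2PI + np.log(variances[j])
                            + (f - means[j]) ** 2 / variances[j])
    return out


def _forward_backward(logb: np.ndarray, transmat: np.ndarray,
                      startprob: np.ndarray
                      ) -> tuple[np.ndarray, np.ndarray, float]:
    """Scaled forward-backward for 2 states.

    Scalar Python arithmetic on the two states: markedly faster than
    per-step tiny-array numpy for records of ~1e4 steps.  Returns
    (gamma, xi_sums, log-likelihood) where xi_sums[i, j] accumulates the
    expected i->j transition counts.
    """
    n = logb.shape[0]
    b = np.exp(logb - logb.max(axis=1, keepdims=True))
    bmax = logb.max(axis=1)
    t00, t01 = float(transmat[0, 0]), float(transmat[0, 1])
    t10, t11 = float(transmat[1, 0]), float(transmat[1, 1])
    b0, b1 = b[:, 0], b[:, 1]

    alpha = np.empty((n, 2))
    c = np.empty(n)          # per-step scale factors
    a0 = float(startprob[0]) * float(b0[0])
    a1 = float(startprob[1]) * float(b1[0])
    s = a0 + a1
    alpha[0] = (a0 / s, a1 / s)
    c[0] = s
    pa0, pa1 = a0 / s, a1 / s
    for t in range(1, n):
        a0 = (pa0 * t00 + pa1 * t10) * float(b0[t])
        a1 = (pa0 * t01 + pa1 * t11) * float(b1[t])
        s = a0 + a1
        if s <= 0:
            raise FloatingPointError("forward pass underflow")
        pa0, pa1 = a0 / s, a1 / s
        alpha[t, 0], alpha[t, 1] = pa0, pa1
        c[t] = s

    beta = np.empty((n, 2))
    beta[n - 1] = 1.0
    pb0 = pb1 = 1.0
    xi = np.zeros((2, 2))
    for t in range(n - 2, -1, -1):
        nb0, nb1 = float(b0[t + 1]), float(b1[t + 1])
        s = c[t + 1]
        v0 = nb0 * pb0
        v1 = nb1 * pb1
        nb_beta0 = (t00 * v0 + t01 * v1) / s
        nb_beta1 = (t10 * v0 + t11 * v1) / s
        # expected transition counts (unnormalized by P(O) cancels via scaling)
        a_t0, a_t1 = alpha[t, 0], alpha[t, 1]
        xi[0, 0] += a_t0 * t00 * v0 / s
        xi[0, 1] += a_t0 * t01 * v1 / s
        xi[1, 0] += a_t1 * t10 * v0 / s
        xi[1, 1] += a_t1 * t11 * v1 / s
        beta[t, 0], beta[t, 1] = nb_beta0, nb_beta1
        pb0, pb1 = nb_beta0, nb_beta1

    gamma = alpha * beta
    gamma /= gamma.sum(axis=1, keepdims=True)
    loglik = float(np.sum(np.log(c) + bmax))
    return gamma, xi, loglik


def baum_welch(features: np.ndarray | TimeSeries,
               init: HMMParams | None = None, max_iter: int = 500,
               tol: float = 1e-6) -> HMMParams:
    """Fit the two-state Gaussian HMM by expectation-maximization.

    The log-likelihood is non-decreasing at every iteration (EM guarantee,
    asserted); iteration stops when the relative improvement drops below
    ``tol`` or at ``max_iter``.
    """
    f = features.samples if isinstance(features, TimeSeries) else \
        np.asarray(features, float)
    if f.size < 10:
        raise ValueError("need at least 10 feature steps")
    if not np.all(np.isfinite(f)):
        raise ValueError("non-finite features")
    if np.var(f) <= 0:
        raise ValueError("degenerate (zero-variance) feature")
    params = init if init is not None else HMMParams.default_init(f)

    transmat = params.transmat.copy()
    means = params.means.copy()
    variances = params.variances.copy()
    startprob = params.startprob.copy()
    var_floor = max(1e-10 * float(np.var(f)), 1e-300)

    logliks: list[float] = []
    converged = False
    for it in range(max_iter):
        logb = _emission_loglik(f, means, variances)
        gamma, xi, ll = _forward_backward(logb, transmat, startprob)
        if logliks and ll < logliks[-1] - 1e-8 * abs(logliks[-1]):
            raise AssertionError(
                f"EM log-likelihood decreased at iter {it}: "
                f"{logliks[-1]} -> {ll}")
        if logliks:
            denom = max(abs(logliks[-1]), 1.0)
            if (ll - logliks[-1]) / denom < tol:
                logliks.append(ll)
                converged = True
                break
        logliks.append(ll)
        # M-step
        startprob = gamma[0] / gamma[0].sum()
        row = xi.sum(axis=1, keepdims=True)
        transmat = np.where(row > 0, xi / np.maximum(row, 1e-300), transmat)
        transmat /= transmat.sum(axis=1, keepdims=True)
        w = gamma.sum(axis=0)
        for j in range(2):
            if w[j] <= 0:
                continue   # state lost all mass (single-regime data)
            means[j] = float(gamma[:, j] @ f) / w[j]
            variances[j] = max(
                float(gamma[:, j] @ (f - means[j]) ** 2) / w[j], var_floor)
    log.info("baum_welch: %d iterations, loglik %.6g, converged=%s",
             len(logliks), logliks[-1], converged)
    return HMMParams(transmat=transmat, means=means, variances=variances,
                     startprob=startprob, log_likelihoods=logliks,
                     n_iter=len(logliks), converged=converged)


def _viterbi(logb: np.ndarray, transmat: np.ndarray,
             startprob: np.ndarray) -> np.ndarray:
    n = logb.shape[0]
    with np.errstate(divide="ignore"):
        lt = np.log(np.maximum(transmat, 1e-300))
        lp = np.log(np.maximum(startprob, 1e-300))
    delta = np.empty((n, 2))
    psi = np.empty((n, 2), dtype=np.int8)
    delta[0] = lp + logb[0]
    for t in range(1, n):
        for j in range(2):
            cand0 = delta[t - 1, 0] + lt[0, j]
            cand1 = delta[t - 1, 1] + lt[1, j]
            if cand0 >= cand1:
                delta[t, j] = cand0 + logb[t, j]
                psi[t, j] = 0
            else:
                delta[t, j] = cand1 + logb[t, j]
                psi[t, j] = 1
    path = np.empty(n, dtype=np.int8)
    path[n - 1] = int(np.argmax(delta[n - 1]))
    for t in range(n - 2, -1, -1):
        path[t] = psi[t + 1, path[t + 1]]
    return path


def decode_states(model: HMMParams, features: np.ndarray | TimeSeries,
                  window_times: np.ndarray | None = None,
                  step_s: float | None = None) -> StateSequence:
    """Viterbi decoding plus forward-backward posteriors.

    The internal state with the lower emission mean is labeled inhibitory
    (0); the other active (1), independent of state index.
    """
    if isinstance(features, TimeSeries):
        if window_times is None:
            window_times = features.times
        if step_s is None:
            step_s = features.dt
        f = features.samples
    else:
        f = np.asarray(features, float)
        if window_times is None:
            window_times = np.arange(f.size, dtype=float)
        if step_s is None:
            step_s = 1.0
    logb = _emission_loglik(f, model.means, model.variances)
    path = _viterbi(logb, model.transmat, model.startprob)
    gamma, _, _ = _forward_backward(logb, model.transmat, model.startprob)
    inhib_idx = int(np.argmin(model.means))
    state = np.where(path == inhib_idx, 0, 1).astype(np.int8)
    return StateSequence(window_times=np.asarray(window_times, float),
                         state=state,
                         posterior_inhib=gamma[:, inhib_idx],
                         step_s=float(step_s))


def bout_durations(states: StateSequence) -> BoutTable:
    """Run-length encode the state path into a bout table with summaries.

    Durations are run length times the feature step; rows tile the record
    without overlap and adjacent rows alternate state, so the durations sum
    exactly to ``n_steps * step_s``.
    """
    s = np.asarray(states.state)
    if s.size < 1:
        raise ValueError("empty state sequence")
    edges = np.flatnonzero(np.diff(s)) + 1
    bounds = np.concatenate([[0], edges, [s.size]])
    rows = []
    for a, b in zip(bounds[:-1], bounds[1:]):
        rows.append({"state": int(s[a]),
                     "start_s": states.window_times[0] + a * states.step_s,
                     "duration_s": (b - a) * states.step_s})
    table = pd.DataFrame(rows)
    summaries = {}
    for st, name in ((1, "active"), (0, "inhibitory")):
        d = table.loc[table["state"] == st, "duration_s"].to_numpy()
        summaries[name] = {
            "n": int(d.size),
            "mean_s": float(d.mean()) if d.size else np.nan,
            "median_s": float(np.median(d)) if d.size else np.nan,
            "total_s": float(d.sum()),
        }
    return BoutTable(table=table, summaries=summaries)
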