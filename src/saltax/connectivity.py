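"""Jitter-corrected cross-correlogram detection of L5->POm pairs.

For simultaneously recorded unit pairs the spike-time cross-correlogram
is computed over all spike pairs within ±20 ms.  A surrogate (null)
distribution is built by independently displacing every spike of both
units by a uniform random offset from a 20 ms wide window centered on
zero, which destroys millisecond timing while preserving slow rate
covariations.  A pair counts as putatively connected when the observed
CCG peak reaches the maximum of the jittered mean plus four times the
maximum jittered SD, and is at least four spikes high.  The
transmission delay is read from the causal (positive-lag) peak.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .spike_metrics import SpikeTrain


class ConnectivityError(ValueError):
    pass


@dataclass
class CCG:
    """Cross-correlogram: pair counts of (t_b - t_a) per lag bin."""

    lags: np.ndarray        # bin centers, symmetric around 0
    counts: np.ndarray
    bin_width: float

    @property
    def peak(self) -> float:
        return float(self.counts.max()) if len(self.counts) else 0.0


@dataclass
class PairResult:
    connected: bool
    peak_lag: float         # ms, lag of the global CCG maximum
    peak_height: float
    delay: float            # ms, causal (positive-lag) peak; nan if no causal mass
    null_mean: np.ndarray
    null_sd: np.ndarray
    n_jitters: int


def _times(x) -> np.ndarray:
    return x.spike_times if isinstance(x, SpikeTrain) else np.asarray(x, dtype=float)


def _edges(max_lag: float, bin_width: float) -> np.ndarray:
    # symmetric bin edges; guarantees a bin centered layout over ±max_lag
    n = int(np.ceil(max_lag / bin_width))
    return np.arange(-n, n + 1) * bin_width


def cross_correlogram(a, b, max_lag: float = 20.0,
                      bin_width: float = 0.5) -> CCG:
    """Exact pair-count cross-correlogram of two spike trains.

    Every pair ``(t_a, t_b)`` with ``|t_b - t_a| <= max_lag`` is counted
    once into the bin containing ``t_b - t_a``.
    """
    ta, tb = np.sort(_times(a)), np.sort(_times(b))
    if len(ta) == 0 or len(tb) == 0:
        raise ConnectivityError("both trains must be non-empty")
    edges = _edges(max_lag, bin_width)
    counts = np.zeros(len(edges) - 1)
    lo = 0
    for t in ta:
        while lo < len(tb) and tb[lo] < t - max_lag:
            lo += 1
        j = lo
        while j < len(tb) and tb[j] <= t + max_lag:
            k = int(np.searchsorted(edges, tb[j] - t, side="right")) - 1
            if 0 <= k < len(counts):
                counts[k] += 1
            j += 1
    lags = 0.5 * (edges[:-1] + edges[1:])
    return CCG(lags=lags, counts=counts, bin_width=bin_width)


def jitter_null(a, b, n_jitters: int = 100, jitter_width: float = 20.0,
                seed: int = 0, max_lag: float = 20.0,
                bin_width: float = 0.5):
    """Jittered-surrogate mean and SD of the CCG, per lag bin.

    Every spike of both trains is displaced independently by
    U(-jitter_width/2, +jitter_width/2) per repetition; deterministic
    for a fixed seed.  ``jitter_width = 0`` degenerates to the observed
    CCG with zero SD.
    """
    if n_jitters < 2:
        raise ConnectivityError("n_jitters must be >= 2")
    ta, tb = _times(a), _times(b)
    rng = np.random.default_rng(seed)
    acc = None
    half = jitter_width / 2.0
    for rep in range(n_jitters):
        ja = ta + rng.uniform(-half, half, size=len(ta))
        jb = tb + rng.uniform(-half, half, size=len(tb))
        ccg = cross_correlogram(np.sort(ja), np.sort(jb), max_lag, bin_width)
        if acc is None:
            acc = np.zeros((n_jitters, len(ccg.counts)))
        acc[rep] = ccg.counts
    mean = acc.mean(axis=0)
    sd = acc.std(axis=0, ddof=0)
    return mean, sd


def detect_pair(ccg: CCG, null_mean: np.ndarray, null_sd: np.ndarray,
                min_spikes: int = 4, n_jitters: int = 100) -> PairResult:
    """Connectivity decision for one unit pair.

    Connected iff ``peak(ccg) >= max(null_mean) + 4 max(null_sd)`` and
    the peak is at least ``min_spikes`` high.  The reported delay is the
    lag of the maximum strictly-causal bin (upstream spike precedes
    downstream spike).
    """
    if len(null_mean) != len(ccg.counts):
        raise ConnectivityError("ccg and null must share binning")
    peak_i = int(np.argmax(ccg.counts))
    threshold = float(null_mean.max()) + 4.0 * float(null_sd.max())
    connected = (ccg.counts[peak_i] >= threshold
                 and ccg.counts[peak_i] >= min_spikes)
    causal = ccg.lags > 0
    if causal.any() and ccg.counts[causal].max() > 0:
        ci = np.nonzero(causal)[0]
        delay = float(ccg.lags[ci[np.argmax(ccg.counts[ci])]])
    else:
        delay = float("nan")
    return PairResult(
        connected=bool(connected),
        peak_lag=float(ccg.lags[peak_i]),
        peak_height=float(ccg.counts[peak_i]),
        delay=delay,
        null_mean=null_mean,
        null_sd=null_sd,
        n_jitters=n_jitters,
    )


def evaluate_pair(a, b, max_lag: float = 20.0, bin_width: float = 0.5,
                  n_jitters: int = 100, jitter_width: float = 20.0,
                  seed: int = 0, min_spikes: int = 4) -> PairResult:
    """CCG + jitter null + decision for one (upstream, downstream) pair."""
    ccg = cross_correlogram(a, b, max_lag, bin_width)
    mean, sd = jitter_null(a, b, n_jitters, jitter_width, seed, max_lag, bin_width)
    return detect_pair(ccg, mean, sd, min_spikes, n_jitters)


def connection_probability(results) -> float:
    """Connected pairs / all simultaneously recorded pairs."""
    results = list(results)
    if not results:
        raise ConnectivityError("need at least one evaluated pair")
    return sum(1 for r in results if r.connected) / len(results)
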