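"""Spike-train and voltage-trace analysis for evoked-response sessions.

Implements the unit-level measures used for optogenetically evoked
L5/POm recordings and for simulated sessions: evoked first-spike
latency/variance/probability, burst detection by instantaneous-rate
chaining, burst-transfer failure between an upstream and a downstream
site, temporal clustering of burst spikes, EPSP time-course binning,
Gaussian(-mixture) fits to latency histograms, and the paired
opto/whisker coincidence integration-window analysis.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import optimize, stats

from .cable_engine import match_spikes


class AnalysisError(ValueError):
    pass


@dataclass
class SpikeTrain:
    """Timestamps of one unit (ms, strictly increasing)."""

    unit_id: str
    spike_times: np.ndarray
    region: str = "other"   # L5 | POm | other

    def __post_init__(self) -> None:
        self.spike_times = np.asarray(self.spike_times, dtype=float)
        if len(self.spike_times) > 1 and not (np.diff(self.spike_times) > 0).all():
            raise AnalysisError(f"unit {self.unit_id}: spike times must be strictly increasing")

    def __len__(self) -> int:
        return len(self.spike_times)


@dataclass
class StimEvents:
    """Stimulus triggers: onset (ms), kind (opto|whisker), parameters."""

    onsets: np.ndarray
    kinds: list = field(default_factory=list)
    params: list = field(default_factory=list)   # power / amplitude
    delays: list = field(default_factory=list)   # opto-to-whisker delay for paired trials

    def __post_init__(self) -> None:
        self.onsets = np.asarray(self.onsets, dtype=float)
        if len(self.onsets) > 1 and not (np.diff(self.onsets) >= 0).all():
            raise AnalysisError("stimulus onsets must be sorted")
        if not self.kinds:
            self.kinds = ["opto"] * len(self.onsets)

    def __len__(self) -> int:
        return len(self.onsets)


@dataclass
class EvokedMetrics:
    """Per-unit evoked-response summary over stimuli."""

    delay: float          # ms, mean first-spike latency (nan if no spikes)
    variance: float       # ms², sample variance of first-spike latency
    probability: float    # fraction of stimuli with >=1 evoked spike
    n_spikes: float       # mean spike count in the evoked window
    burst_frequency: float  # Hz, mean within-window rate of >=50 Hz events
    n_trials: int
    defined: bool         # False when no trial had an evoked spike


def evoked_metrics(t: SpikeTrain, s: StimEvents,
                   window: tuple = (5.0, 40.0)) -> EvokedMetrics:
    """Evoked first-spike statistics in a post-stimulus window.

    The window (ms after onset) defaults to the POm convention (5-40);
    use (2, 30) for L5 units.  Variance is the sample variance (n-1
    denominator) of first-spike latencies over responsive trials;
    ``burst_frequency`` averages the instantaneous frequency of
    within-window spike pairs at 50 Hz or faster.
    """
    if len(s) == 0:
        raise AnalysisError("no stimuli")
    w0, w1 = window
    if not w0 < w1:
        raise AnalysisError("window start must precede end")
    latencies, counts, burst_freqs = [], [], []
    for onset in s.onsets:
        sel = t.spike_times[(t.spike_times >= onset + w0) & (t.spike_times <= onset + w1)]
        counts.append(len(sel))
        if len(sel):
            latencies.append(sel[0] - onset)
        if len(sel) > 1:
            isi = np.diff(sel)
            fast = 1000.0 / isi[isi <= 1000.0 / 50.0]
            if len(fast):
                burst_freqs.append(float(np.mean(fast)))
    n = len(s.onsets)
    prob = len(latencies) / n
    if latencies:
        delay = float(np.mean(latencies))
        var = float(np.var(latencies, ddof=1)) if len(latencies) > 1 else 0.0
        defined = True
    else:
        delay, var, defined = float("nan"), float("nan"), False
    return EvokedMetrics(
        delay=delay, variance=var, probability=prob,
        n_spikes=float(np.mean(counts)),
        burst_frequency=float(np.mean(burst_freqs)) if burst_freqs else float("nan"),
        n_trials=n, defined=defined,
    )


@dataclass
class BurstStats:
    """Bursts of one unit: chained spikes above a rate threshold."""

    bursts: list            # (start ms, spike count, instantaneous Hz)
    n_isolated: int
    is_bursting_unit: bool
    exclude: bool           # mean burst frequency above the exclusion cap
    burst_event_fraction: float
    mean_burst_frequency: float


def burst_detect(t: SpikeTrain, freq_threshold: float = 100.0,
                 min_bursts: int = 10, max_mean_freq: float = 500.0) -> BurstStats:
    """Chain consecutive ISIs above ``freq_threshold`` into bursts.

    A run of spikes whose successive ISIs are all shorter than
    ``1000/freq_threshold`` ms forms one burst; its instantaneous
    frequency is ``(n_spikes - 1) / duration``.  A unit is a bursting
    unit iff it fires at least ``min_bursts`` bursts; units whose mean
    burst frequency exceeds ``max_mean_freq`` are flagged for exclusion.
    ``burst_event_fraction`` counts bursts against all firing events
    (bursts + isolated spikes).
    """
    times = t.spike_times
    max_isi = 1000.0 / freq_threshold
    bursts = []
    isolated = 0
    i = 0
    while i < len(times):
        j = i
        while j + 1 < len(times) and times[j + 1] - times[j] < max_isi:
            j += 1
        if j > i:
            dur = times[j] - times[i]
            bursts.append((float(times[i]), j - i + 1, (j - i) / dur * 1000.0))
        else:
            isolated += 1
        i = j + 1
    mean_freq = float(np.mean([b[2] for b in bursts])) if bursts else float("nan")
    n_events = len(bursts) + isolated
    return BurstStats(
        bursts=bursts,
        n_isolated=isolated,
        is_bursting_unit=len(bursts) >= min_bursts,
        exclude=bool(bursts) and mean_freq > max_mean_freq,
        burst_event_fraction=len(bursts) / n_events if n_events else float("nan"),
        mean_burst_frequency=mean_freq,
    )


@dataclass
class TransferResult:
    failure_fraction: float
    n_upstream: int
    n_matched: int
    transfer_map: np.ndarray   # (k, 2): upstream Hz, downstream Hz per interval


def transfer_failure(upstream: SpikeTrain | np.ndarray,
                     downstream: SpikeTrain | np.ndarray,
                     window: tuple = (0.2, 15.0)) -> TransferResult:
    """Propagation failure between causally related spike trains.

    Upstream spikes are matched to downstream spikes by the
    order-preserving greedy matcher within the causal ``window``;
    failure fraction is the unmatched share.  ``transfer_map`` pairs the
    instantaneous frequency of consecutive upstream spikes with the
    downstream frequency of their matched counterparts (only intervals
    whose two endpoints both transmitted).
    """
    up = upstream.spike_times if isinstance(upstream, SpikeTrain) else np.asarray(upstream, float)
    down = downstream.spike_times if isinstance(downstream, SpikeTrain) else np.asarray(downstream, float)
    m = match_spikes(up, down, window)
    n_matched = int((m >= 0).sum())
    pairs = []
    for i in range(len(up) - 1):
        if m[i] >= 0 and m[i + 1] >= 0:
            fu = 1000.0 / (up[i + 1] - up[i])
            fd = 1000.0 / (down[m[i + 1]] - down[m[i]])
            pairs.append((fu, fd))
    failure = 1.0 - n_matched / len(up) if len(up) else float("nan")
    return TransferResult(
        failure_fraction=failure, n_upstream=len(up), n_matched=n_matched,
        transfer_map=np.asarray(pairs) if pairs else np.empty((0, 2)),
    )


def first_window_fraction(l5: SpikeTrain | np.ndarray,
                          pom: SpikeTrain | np.ndarray,
                          first_ms: float = 10.0, total_ms: float = 20.0):
    """Fraction of POm spikes in the first 10 ms of the 20 ms after an
    L5 spike.

    Returns ``(fraction, n_considered)``; the fraction is ``nan`` (and
    n 0) when no POm spike falls in any window.
    """
    a = l5.spike_times if isinstance(l5, SpikeTrain) else np.asarray(l5, float)
    b = pom.spike_times if isinstance(pom, SpikeTrain) else np.asarray(pom, float)
    early = total = 0
    for t0 in a:
        k = np.searchsorted(b, t0, side="right")
        while k < len(b) and b[k] - t0 <= total_ms:
            total += 1
            if b[k] - t0 <= first_ms:
                early += 1
            k += 1
    if total == 0:
        return float("nan"), 0
    return early / total, total


def temporal_cluster_probability(t: SpikeTrain, s: StimEvents,
                                 boundaries) -> np.ndarray:
    """Per-cluster spike probability over stimuli.

    ``boundaries`` is an ordered sequence of non-overlapping
    ``(start, end)`` windows (ms after onset), one per within-burst
    spike position; each stimulus contributes presence/absence per
    cluster.
    """
    if len(s) == 0:
        raise AnalysisError("no stimuli")
    bounds = [tuple(b) for b in boundaries]
    for (a0, a1), (b0, b1) in zip(bounds, bounds[1:]):
        if b0 < a1:
            raise AnalysisError("cluster boundaries overlap or are unordered")
    hits = np.zeros(len(bounds))
    for onset in s.onsets:
        rel = t.spike_times - onset
        for k, (w0, w1) in enumerate(bounds):
            if ((rel >= w0) & (rel < w1)).any():
                hits[k] += 1
    return hits / len(s.onsets)


def epsp_bin_average(traces, dt: float, bin_ms: float = 5.0):
    """Average subthreshold voltage transients in fixed bins from onset.

    ``traces`` is an iterable of equal-dt voltage segments aligned to
    EPSP onset (mV, baseline-subtracted or raw -- the caller decides).
    Returns ``(bin_means, normalized)`` where the second series divides
    by the first bin's mean.
    """
    traces = [np.asarray(tr, dtype=float) for tr in traces]
    if not traces:
        raise AnalysisError("no traces")
    n_min = min(len(tr) for tr in traces)
    per_bin = int(round(bin_ms / dt))
    n_bins = n_min // per_bin
    if n_bins < 1:
        raise AnalysisError("traces shorter than one bin")
    means = np.zeros(n_bins)
    for tr in traces:
        trimmed = tr[: n_bins * per_bin].reshape(n_bins, per_bin)
        means += trimmed.mean(axis=1)
    means /= len(traces)
    if means[0] == 0:
        raise AnalysisError("first bin mean is zero; cannot normalize")
    return means, means / means[0]


@dataclass
class MixtureFit:
    components: int
    means: np.ndarray
    sds: np.ndarray
    weights: np.ndarray
    r2: float
    sse: float
    bin_centers: np.ndarray
    density: np.ndarray
    fitted: np.ndarray


def _gauss(x, mu, sd, w):
    return w / (sd * math.sqrt(2 * math.pi)) * np.exp(-0.5 * ((x - mu) / sd) ** 2)


def fit_latency_mixture(latencies, components: int = 2,
                        bin_width: float = 1.0) -> MixtureFit:
    """Least-squares 1- or 2-Gaussian fit to a latency histogram.

    The histogram is density-normalized; ``r2`` is computed against the
    binned density, and the residual sum of squares is returned so 1-
    vs 2-component fits can be compared side by side.
    """
    lat = np.asarray(list(latencies), dtype=float)
    if len(lat) < 10:
        raise AnalysisError("need at least 10 latencies")
    if components not in (1, 2):
        raise AnalysisError("components must be 1 or 2")
    lo = math.floor(lat.min()) - bin_width
    hi = math.ceil(lat.max()) + bin_width
    edges = np.arange(lo, hi + bin_width, bin_width)
    dens, edges = np.histogram(lat, bins=edges, density=True)
    x = 0.5 * (edges[:-1] + edges[1:])

    mu0, sd0 = float(np.mean(lat)), max(float(np.std(lat)), bin_width / 2)
    try:
        if components == 1:
            p0 = [mu0, sd0, 1.0]
            popt, _ = optimize.curve_fit(
                lambda x, m, s, w: _gauss(x, m, abs(s), w), x, dens, p0=p0,
                maxfev=20000,
            )
            means = np.array([popt[0]]); sds = np.array([abs(popt[1])])
            weights = np.array([popt[2]])
            fitted = _gauss(x, *means, *sds, *weights)
        else:
            q1, q3 = np.percentile(lat, [25, 75])
            p0 = [q1, sd0 / 2, 0.5, q3, sd0 / 2, 0.5]

            def two(xv, m1, s1, w1, m2, s2, w2):
                return _gauss(xv, m1, abs(s1), w1) + _gauss(xv, m2, abs(s2), w2)

            popt, _ = optimize.curve_fit(two, x, dens, p0=p0, maxfev=40000)
            order = np.argsort([popt[0], popt[3]])
            means = np.array([popt[0], popt[3]])[order]
            sds = np.abs(np.array([popt[1], popt[4]]))[order]
            weights = np.array([popt[2], popt[5]])[order]
            fitted = two(x, *popt)
    except RuntimeError as exc:
        raise AnalysisError(f"mixture fit did not converge: {exc}") from None

    resid = dens - fitted
    sse = float(np.sum(resid ** 2))
    sst = float(np.sum((dens - dens.mean()) ** 2))
    r2 = 1.0 - sse / sst if sst > 0 else 1.0
    return MixtureFit(components, means, sds, weights, r2, sse, x, dens, fitted)


@dataclass
class IntegrationWindow:
    delays: np.ndarray
    p_values: np.ndarray
    significant: np.ndarray
    fold_change: np.ndarray
    peak_delay: float
    width_ms: float


def integration_window(trials: pd.DataFrame, alpha: float = 0.05,
                       grid_step: float | None = None,
                       mode: str = "trials") -> IntegrationWindow:
    """Coincidence integration window from a paired-stimulation table.

    ``trials`` must have one row per tested opto-to-whisker delay with
    columns ``delay_ms, n_trials_paired, n_resp_paired, n_trials_opto,
    n_resp_opto, n_trials_whisker, n_resp_whisker`` (plus ``n_spikes_*``
    for ``mode='spikes'``).  Per delay a two-sided Fisher exact test
    compares paired responsiveness against the pooled single-modality
    trials; the window width is the number of significant delays times
    the grid step, and the peak delay maximizes the fold change
    (paired probability / pooled single-modality probability).
    """
    req = ["delay_ms", "n_trials_paired", "n_resp_paired",
           "n_trials_opto", "n_resp_opto", "n_trials_whisker", "n_resp_whisker"]
    for c in req:
        if c not in trials.columns:
            raise AnalysisError(f"missing column {c!r}")
    df = trials.sort_values("delay_ms").reset_index(drop=True)
    if (df[["n_resp_paired", "n_resp_opto", "n_resp_whisker"]].to_numpy() == 0).all():
        raise AnalysisError("no responsive trials in any condition")
    delays = df["delay_ms"].to_numpy(dtype=float)
    if grid_step is None:
        grid_step = float(np.min(np.diff(delays))) if len(delays) > 1 else 10.0

    pvals, folds = [], []
    for _, row in df.iterrows():
        n_p = int(row["n_trials_paired"])
        n_s = int(row["n_trials_opto"]) + int(row["n_trials_whisker"])
        if n_p == 0 or n_s == 0:
            raise AnalysisError(f"zero trials at delay {row['delay_ms']}")
        if mode == "trials":
            k_p = int(row["n_resp_paired"])
            k_s = int(row["n_resp_opto"]) + int(row["n_resp_whisker"])
        elif mode == "spikes":
            k_p = int(row["n_spikes_paired"])
            k_s = int(row["n_spikes_opto"]) + int(row["n_spikes_whisker"])
            n_p = max(n_p, k_p)
            n_s = max(n_s, k_s)
        else:
            raise AnalysisError("mode must be 'trials' or 'spikes'")
        table = [[k_p, n_p - k_p], [k_s, n_s - k_s]]
        _, p = stats.fisher_exact(table, alternative="two-sided")
        pvals.append(p)
        p_paired = k_p / n_p
        p_sum = k_s / n_s
        folds.append(p_paired / p_sum if p_sum > 0 else np.inf)

    pvals = np.asarray(pvals)
    folds = np.asarray(folds)
    sig = pvals < alpha
    finite = np.where(np.isfinite(folds), folds, -np.inf)
    peak = float(delays[int(np.argmax(finite))])
    return IntegrationWindow(
        delays=delays, p_values=pvals, significant=sig, fold_change=folds,
        peak_delay=peak, width_ms=float(sig.sum() * grid_step),
    )


# ---------------------------------------------------------------------------
# delimited-text I/O
# ---------------------------------------------------------------------------


def read_spike_table(path) -> dict:
    """Read a spike table (TSV/CSV: unit_id, time_ms[, region]) into
    SpikeTrains keyed by unit id."""
    df = pd.read_csv(path, sep=None, engine="python")
    cols = {c.lower(): c for c in df.columns}
    if "unit_id" not in cols or "time_ms" not in cols:
        raise AnalysisError("spike table needs unit_id and time_ms columns")
    out = {}
    for uid, grp in df.groupby(cols["unit_id"]):
        region = str(grp[cols["region"]].iloc[0]) if "region" in cols else "other"
        out[str(uid)] = SpikeTrain(str(uid), np.sort(grp[cols["time_ms"]].to_numpy()),
                                   region=region)
    return out


def write_spike_table(trains: dict, path) -> None:
    rows = []
    for uid, tr in trains.items():
        for t in tr.spike_times:
            rows.append((uid, t, tr.region))
    pd.DataFrame(rows, columns=["unit_id", "time_ms", "region"]).to_csv(
        path, sep="\t", index=False
    )


def read_stim_table(path) -> StimEvents:
    df = pd.read_csv(path, sep=None, engine="python")
    kinds = df["kind"].tolist() if "kind" in df.columns else []
    delays = df["delay_ms"].tolist() if "delay_ms" in df.columns else []
    params = df["param"].tolist() if "param" in df.columns else []
    return StimEvents(onsets=df["onset_ms"].to_numpy(), kinds=kinds,
                      params=params, delays=delays)


def write_stim_table(s: StimEvents, path) -> None:
    df = pd.DataFrame({"onset_ms": s.onsets})
    df["kind"] = s.kinds if s.kinds else "opto"
    if s.params:
        df["param"] = s.params
    if s.delays:
        df["delay_ms"] = s.delays
    df.to_csv(path, sep="\t", index=False)
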