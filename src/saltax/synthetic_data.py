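"""Synthetic spike-train sessions with known ground truth.

Emulates the in vivo experiment designs so every analysis operation can
be validated against planted parameters rather than recorded data:

- juxtacellular/Neuropixels-like units: L5 pyramidal cells with low
  spontaneous rates (~0.5 Hz) that answer optogenetic pulses with
  3-4-spike bursts near 200 Hz at short latency; POm relay cells
  (~0.6 Hz spontaneous) receiving planted monosynaptic connections with
  a transmission delay, first-spike failure probability and jitter;
- paired opto+whisker coincidence trials on a grid of relative delays
  with a configurable supralinear boost window.

The ``cpz`` condition preset shifts the transmission parameters in the
directions measured after cuprizone demyelination (delay +4 ms,
first-spike failure 0.1 -> 0.3, latency variance x3); these deltas
parameterize tests, not biological claims.  Every generator is
deterministic for a fixed seed and returns a machine-readable
ground-truth record alongside the data.
"""

from __future__ import annotations

from dataclasses import dataclass, field, asdict

import numpy as np
import pandas as pd

from .spike_metrics import SpikeTrain, StimEvents


@dataclass
class BurstModel:
    """Optogenetically evoked L5 burst parameters."""

    n_spikes_choices: tuple = (3, 4)
    intra_burst_hz: float = 200.0
    intra_burst_sd_hz: float = 20.0
    onset_latency_ms: float = 4.0
    onset_latency_sd_ms: float = 0.5


@dataclass
class TransmissionModel:
    """Monosynaptic L5->POm transfer for one planted pair."""

    synaptic_delay_ms: float = 1.5
    conduction_delay_ms: float = 1.5
    first_spike_failure_p: float = 0.1
    jitter_sd_ms: float = 0.5
    later_spike_p: float = 0.25  # giant-synapse depression for later burst spikes

    @property
    def total_delay_ms(self) -> float:
        return self.synaptic_delay_ms + self.conduction_delay_ms


#: condition presets: the cpz deltas follow the measured effect
#: directions (delay +4 ms, failure 0.1 -> 0.3, variance x3)
CONDITION_PRESETS = {
    "control": TransmissionModel(),
    "cpz": TransmissionModel(
        conduction_delay_ms=5.5,
        first_spike_failure_p=0.3,
        jitter_sd_ms=0.5 * np.sqrt(3.0),
    ),
}


@dataclass
class SessionSpec:
    """Design of one synthetic recording session."""

    duration_min: float = 15.0
    n_l5: int = 4
    n_pom: int = 4
    l5_rate_hz: float = 0.5
    pom_rate_hz: float = 0.6
    n_stimuli: int = 0
    stim_interval_ms: float = 1000.0
    stim_start_ms: float = 1000.0
    burst: BurstModel = field(default_factory=BurstModel)
    pairs: list = field(default_factory=list)   # (l5 idx, pom idx)
    condition: str = "control"
    transmission: TransmissionModel | None = None
    dead_time_ms: float = 1.0
    seed: int = 0

    def __post_init__(self) -> None:
        if self.l5_rate_hz < 0 or self.pom_rate_hz < 0:
            raise ValueError("rates must be >= 0")
        tm = self.transmission or CONDITION_PRESETS[self.condition]
        if not (0.0 <= tm.first_spike_failure_p <= 1.0):
            raise ValueError("failure probability must be in [0, 1]")
        self.transmission = tm


def _poisson_train(rng, rate_hz: float, duration_ms: float) -> np.ndarray:
    if rate_hz <= 0:
        return np.empty(0)
    n = rng.poisson(rate_hz * duration_ms / 1000.0)
    return np.sort(rng.uniform(0.0, duration_ms, size=n))


def _dedupe(times: np.ndarray, dead_ms: float) -> np.ndarray:
    """Sort and enforce a minimal inter-spike interval."""
    if len(times) == 0:
        return times
    out = []
    for t in np.sort(times):
        if not out or t - out[-1] >= dead_ms:
            out.append(t)
    return np.asarray(out)


def gen_session(spec: SessionSpec):
    """Generate one session: spike trains, stimuli, and ground truth.

    Returns ``(trains, stims, truth)`` where ``trains`` maps unit ids to
    :class:`SpikeTrain` (L5 units ``L5_0..``, POm units ``POm_0..``),
    ``stims`` are the opto events, and ``truth`` records the planted
    pairs, delays, failure and latency parameters plus the seed.
    """
    rng = np.random.default_rng(spec.seed)
    duration_ms = spec.duration_min * 60e3
    onsets = spec.stim_start_ms + spec.stim_interval_ms * np.arange(spec.n_stimuli)
    onsets = onsets[onsets < duration_ms - 100.0]
    bm = spec.burst
    tm = spec.transmission

    trains: dict[str, SpikeTrain] = {}
    l5_spikes: list[np.ndarray] = []
    for i in range(spec.n_l5):
        t = list(_poisson_train(rng, spec.l5_rate_hz, duration_ms))
        for onset in onsets:
            lat = -1.0
            while lat <= 0:
                lat = rng.normal(bm.onset_latency_ms, bm.onset_latency_sd_ms)
            n_sp = int(rng.choice(spec.burst.n_spikes_choices))
            cur = onset + lat
            t.append(cur)
            for _ in range(n_sp - 1):
                f = max(rng.normal(bm.intra_burst_hz, bm.intra_burst_sd_hz), 50.0)
                cur += 1000.0 / f
                t.append(cur)
        arr = _dedupe(np.asarray(t), spec.dead_time_ms)
        l5_spikes.append(arr)
        trains[f"L5_{i}"] = SpikeTrain(f"L5_{i}", arr, region="L5")

    pom_evoked: dict[int, list] = {j: [] for j in range(spec.n_pom)}
    truth_pairs = []
    for (i, j) in spec.pairs:
        src = l5_spikes[i]
        ev = []
        prev = -np.inf
        for t in src:
            first = (t - prev) > 20.0  # first spike of a burst
            prev = t
            p = (1.0 - tm.first_spike_failure_p) if first else tm.later_spike_p
            if rng.uniform() < p:
                ev.append(t + tm.total_delay_ms + rng.normal(0.0, tm.jitter_sd_ms))
        pom_evoked[j].extend(ev)
        truth_pairs.append({
            "l5": f"L5_{i}", "pom": f"POm_{j}",
            "delay_ms": tm.total_delay_ms,
            "first_spike_failure_p": tm.first_spike_failure_p,
            "jitter_sd_ms": tm.jitter_sd_ms,
        })

    for j in range(spec.n_pom):
        t = np.concatenate([
            _poisson_train(rng, spec.pom_rate_hz, duration_ms),
            np.asarray(pom_evoked[j]),
        ])
        t = t[(t >= 0) & (t < duration_ms)]
        arr = _dedupe(t, spec.dead_time_ms)
        trains[f"POm_{j}"] = SpikeTrain(f"POm_{j}", arr, region="POm")

    stims = StimEvents(onsets=onsets, kinds=["opto"] * len(onsets))
    truth = {
        "seed": spec.seed,
        "condition": spec.condition,
        "duration_ms": duration_ms,
        "l5_rate_hz": spec.l5_rate_hz,
        "pom_rate_hz": spec.pom_rate_hz,
        "burst": asdict(bm),
        "transmission": asdict(tm),
        "expected_pom_latency_ms": bm.onset_latency_ms + tm.total_delay_ms,
        "pairs": truth_pairs,
    }
    return trains, stims, truth


@dataclass
class CoincidenceSpec:
    """Design of a paired opto/whisker coincidence experiment."""

    delays_ms: tuple = tuple(range(-50, 60, 10))
    n_trials: int = 30          # paired trials per delay
    n_single_trials: int = 90   # session-level opto-alone / whisker-alone trials
    p_opto: float = 0.02
    p_whisker: float = 0.02
    boost: float = 0.45
    window_ms: tuple = (0.0, 20.0)  # true supralinear window (inclusive)
    seed: int = 0

    def __post_init__(self) -> None:
        for p in (self.p_opto, self.p_whisker, self.boost):
            if p < 0 or p > 1:
                raise ValueError("probabilities must be in [0, 1]")
        if self.n_trials < 1:
            raise ValueError("need at least one trial per delay")


def gen_coincidence_trials(spec: CoincidenceSpec):
    """Per-delay responsive-trial counts with a planted boost window.

    Outside the true window the paired response probability equals the
    pooled single-modality rate (the exact null of the Fisher
    comparison used downstream, so a zero boost yields a calibrated
    test); inside the window the probability is raised by ``boost``.
    Returns ``(DataFrame, truth)``; the frame has the column layout
    consumed by :func:`saltax.spike_metrics.integration_window`.
    """
    rng = np.random.default_rng(spec.seed)
    p_base = 0.5 * (spec.p_opto + spec.p_whisker)
    # single-modality trials are interleaved across the session and do
    # not depend on the tested delay: draw them once and reuse per row
    ns = spec.n_single_trials
    k_o = int(rng.binomial(ns, spec.p_opto))
    k_w = int(rng.binomial(ns, spec.p_whisker))
    rows = []
    for d in spec.delays_ms:
        inside = spec.window_ms[0] <= d <= spec.window_ms[1]
        p_paired = min(1.0, p_base + (spec.boost if inside else 0.0))
        n = spec.n_trials
        k_p = int(rng.binomial(n, p_paired))
        rows.append({
            "delay_ms": float(d),
            "n_trials_paired": n, "n_resp_paired": k_p,
            "n_spikes_paired": k_p,
            "n_trials_opto": ns, "n_resp_opto": k_o, "n_spikes_opto": k_o,
            "n_trials_whisker": ns, "n_resp_whisker": k_w, "n_spikes_whisker": k_w,
        })
    df = pd.DataFrame(rows)
    inside = [d for d in spec.delays_ms
              if spec.window_ms[0] <= d <= spec.window_ms[1]]
    step = float(np.min(np.diff(sorted(spec.delays_ms)))) if len(spec.delays_ms) > 1 else 10.0
    truth = {
        "seed": spec.seed,
        "p_base": p_base,
        "boost": spec.boost,
        "true_window_ms": list(spec.window_ms),
        "true_width_ms": len(inside) * step,
        "boosted_delays": inside,
    }
    return df, truth
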