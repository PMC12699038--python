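"""High-level simulation protocols of the L5->POm myelination study.

These functions bundle the standard experiments run on the model:
single evoked APs for conduction-velocity measurements, repeated
fluctuating-input burst trials for transfer statistics, passive probes
(input resistance, resting potential), the AP-waveform protocol, and
the myelin-thickness sweep.  They are used by the test suite and the
reproduction script and are convenient entry points for interactive
work.
"""

from __future__ import annotations

import numpy as np

from .cable_engine import (
    CableSystem,
    FluctuatingInput,
    SimConfig,
    StimulusProtocol,
    build_default_model,
    conduction_velocity,
    measure_ap_waveform,
    run_simulation,
    settle,
    spike_to_spike_delay,
    threshold_step_current,
)
from .demyelination import Scenario, apply_scenario, preset_scenario
from .spike_metrics import SpikeTrain, burst_detect, transfer_failure

#: burst protocol of the study: 20 ms somatic step on top of the
#: point-conductance background, trials of 150 ms
BURST_STEP_NA = 1.7
BURST_STEP_ONSET_MS = 20.0
BURST_STEP_DUR_MS = 20.0
TRIAL_MS = 150.0
SYNAPTIC_DELAY_MS = 1.5


def control_system(n_lamellae: int = 9, **kwargs) -> CableSystem:
    return CableSystem(build_default_model(n_lamellae, **kwargs))


def scenario_system(preset: str, n_lamellae: int = 9, **kwargs) -> CableSystem:
    model = build_default_model(n_lamellae, **kwargs)
    if preset == "demyel_all":
        scen = Scenario(regions=("Ctx", "WM", "Thal"), remove_myelin=True)
    else:
        scen = preset_scenario(preset)
    return CableSystem(apply_scenario(model, scen))


def single_ap_metrics(sys: CableSystem, state=None, dt: float = 0.01) -> dict:
    """Threshold 3 ms somatic step; CV, propagation and spike-to-spike delay."""
    if state is None:
        state = settle(sys, dt=dt)
    amp = threshold_step_current(sys, state, dt=dt)
    cfg = SimConfig(duration=40.0, dt=dt,
                    record_sites=("soma", "ais_end", "bouton"),
                    temperature=sys.temperature)
    res = run_simulation(
        sys, StimulusProtocol(step_currents=[("soma", 1.0, 3.0, amp)]),
        cfg, init_state=state)
    path_um = sys.path_length_between("ais_end", "bouton")
    cv = conduction_velocity(res, "ais_end", "bouton", path_um)
    prop = float(res.spikes["bouton"][0] - res.spikes["ais_end"][0])
    return {
        "threshold_na": amp,
        "cv_m_per_s": float(cv[0]),
        "propagation_ms": prop,
        "spike_to_spike_ms": spike_to_spike_delay(prop, SYNAPTIC_DELAY_MS),
        "path_um": path_um,
        "result": res,
    }


def burst_trials(sys: CableSystem, state, n_trials: int, seed: int,
                 amp_na: float = BURST_STEP_NA) -> list:
    """Repeated fluctuating-input burst trials; AIS + terminal spikes."""
    child_seeds = np.random.default_rng(seed).integers(2 ** 31, size=n_trials)
    out = []
    for s in child_seeds:
        cfg = SimConfig(duration=TRIAL_MS, seed=int(s),
                        record_sites=("ais_end", "bouton"),
                        temperature=sys.temperature)
        proto = StimulusProtocol(
            step_currents=[("soma", BURST_STEP_ONSET_MS, BURST_STEP_DUR_MS, amp_na)],
            fluctuating=FluctuatingInput(),
        )
        res = run_simulation(sys, proto, cfg, init_state=state)
        out.append((res.spikes["ais_end"], res.spikes["bouton"]))
    return out


def burst_summary(trials, burst_threshold_hz: float = 100.0,
                  window=(BURST_STEP_ONSET_MS,
                          BURST_STEP_ONSET_MS + BURST_STEP_DUR_MS + 8.0)) -> dict:
    """Evoked-burst statistics over fluctuating-input trials.

    Statistics are restricted to the evoked window around the somatic
    step (the fluctuating background also fires the cell outside it).
    Intra-burst frequency averages the instantaneous frequency of AIS
    bursts (ISI chaining above ``burst_threshold_hz``) per trial.  The
    failure fraction counts evoked AIS burst spikes without a matched
    terminal spike (order-preserving causal matching), i.e. APs within
    the burst that do not reach the presynaptic terminal.  Matched
    AIS/terminal spike pairs also yield L5->POm delays whose variance
    quantifies temporal dispersion.
    """
    from .cable_engine import match_spikes

    freqs, spike_counts = [], []
    n_burst_spikes = 0
    n_failed = 0
    delays = []
    maps = []
    for (up_all, down) in trials:
        sel = (up_all >= window[0]) & (up_all <= window[1])
        up = up_all[sel]
        st = SpikeTrain("ais", up)
        stats = burst_detect(st, freq_threshold=burst_threshold_hz, min_bursts=1)
        if stats.bursts:
            freqs.append(stats.mean_burst_frequency)
        # burst spikes only: members of chained events
        burst_mask = np.zeros(len(up), dtype=bool)
        for (start, count, _f) in stats.bursts:
            i0 = int(np.searchsorted(up, start))
            burst_mask[i0:i0 + count] = True
        spike_counts.append(int(burst_mask.sum()))
        matched = match_spikes(up, down)
        n_burst_spikes += int(burst_mask.sum())
        n_failed += int((matched[burst_mask] < 0).sum())
        for i in np.nonzero(matched >= 0)[0]:
            delays.append(down[matched[i]] - up[i])
        tr = transfer_failure(up, down)
        if len(tr.transfer_map):
            maps.append(tr.transfer_map)
    freqs = np.asarray(freqs)
    return {
        "freq_mean_hz": float(freqs.mean()) if len(freqs) else float("nan"),
        "freq_sem_hz": float(freqs.std(ddof=1) / np.sqrt(len(freqs)))
        if len(freqs) > 1 else float("nan"),
        "mean_burst_spikes": float(np.mean(spike_counts)),
        "failure_fraction": n_failed / n_burst_spikes if n_burst_spikes else float("nan"),
        "n_burst_spikes": n_burst_spikes,
        "delay_variance_ms2": float(np.var(delays, ddof=1)) if len(delays) > 1 else float("nan"),
        "transfer_map": np.concatenate(maps) if maps else np.empty((0, 2)),
        "n_trials": len(trials),
    }


def first_ap_waveform(sys: CableSystem, state, seed: int = 0) -> dict:
    """Amplitude/halfwidth of the first somatic AP in the evoked burst."""
    child = int(np.random.default_rng(seed).integers(2 ** 31))
    cfg = SimConfig(duration=60.0, seed=child,
                    record_sites=("soma", "ais_end"),
                    temperature=sys.temperature)
    proto = StimulusProtocol(
        step_currents=[("soma", BURST_STEP_ONSET_MS, BURST_STEP_DUR_MS, BURST_STEP_NA)],
        fluctuating=FluctuatingInput(),
    )
    res = run_simulation(sys, proto, cfg, init_state=state)
    soma_spikes = res.spikes["soma"]
    soma_spikes = soma_spikes[soma_spikes >= BURST_STEP_ONSET_MS]
    if len(soma_spikes) == 0:
        raise RuntimeError("burst protocol evoked no somatic AP")
    amp, hw = measure_ap_waveform(res.v_m["soma"], res.dt, soma_spikes[0])
    return {"amplitude_mv": amp, "halfwidth_us": hw,
            "n_ais_spikes": len(res.spikes["ais_end"])}


def lamella_cv_sweep(counts=(0, 1, 3, 5, 9, 15, 21), dt: float = 0.01) -> dict:
    """CV of a single evoked AP for each myelin thickness.

    Zero lamellae means the fully demyelinated axon (bare membrane with
    the 200 pS/µm² NaV floor), matching the demyelination transform.
    """
    out = {}
    for n in counts:
        sys = (scenario_system("demyel_all") if n == 0
               else control_system(n_lamellae=n))
        state = settle(sys, duration=400.0, dt=dt)
        out[int(n)] = single_ap_metrics(sys, state, dt=dt)["cv_m_per_s"]
    return out
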