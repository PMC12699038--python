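import math

import numpy as np
import pytest

from saltax.biophysics import DensityTable, PassiveSpec, myelin_params_from_lamellae
from saltax.cable_engine import (
    CableSystem,
    FluctuatingInput,
    SimConfig,
    SimulationError,
    StimulusProtocol,
    build_default_model,
    build_system,
    conduction_velocity,
    detect_spikes,
    measure_ap_waveform,
    ou_conductance_step,
    run_simulation,
    settle,
    spike_to_spike_delay,
    threshold_step_current,
)
from saltax.demyelination import Scenario, apply_scenario
from saltax.morphology import (
    DOMAIN_CODE,
    Morphology,
    Section,
    SegmentationRule,
    segmentize,
)


def _passive_zero_table():
    return DensityTable(table={dom: {} for dom in DOMAIN_CODE})


def _dense_dc_solution(sys, stim_seg, amp_na):
    """Direct dense solve of the two-layer DC circuit (oracle)."""
    n = sys.n
    G = np.zeros((2 * n, 2 * n))
    b = np.zeros(2 * n)
    for i in range(n):
        vi, ve = 2 * i, 2 * i + 1
        g = sys.gpas[i]
        G[vi, vi] += g
        G[vi, ve] -= g
        b[vi] += g * sys.epas
        if sys.grounded[i]:
            G[ve, ve] = 1.0
        else:
            G[ve, vi] -= g
            G[ve, ve] += g + sys.gmy[i] + sys.gp_ground[i]
            b[ve] -= g * sys.epas
    for i in range(1, n):
        p = sys.parent[i]
        ga = sys.ga[i]
        G[2 * i, 2 * i] += ga
        G[2 * p, 2 * p] += ga
        G[2 * i, 2 * p] -= ga
        G[2 * p, 2 * i] -= ga
        gp = sys.gp[i]
        if gp > 0:
            G[2 * i + 1, 2 * i + 1] += gp
            G[2 * p + 1, 2 * p + 1] += gp
            G[2 * i + 1, 2 * p + 1] -= gp
            G[2 * p + 1, 2 * i + 1] -= gp
    b[2 * stim_seg] += amp_na
    x = np.linalg.solve(G, b)
    return x[0::2], x[1::2]


class TestBuildSystem:
    def test_dc_steady_state_matches_dense_solve(self, mini_config):
        """Passive double-cable steady state equals the direct solution."""
        model = build_default_model(9, morph_config=mini_config,
                                    density_table=_passive_zero_table())
        sys = CableSystem(model)
        soma = sys.sites["soma"]
        vi_ref, ve_ref = _dense_dc_solution(sys, soma, -0.1)
        # long relaxation to DC with the step held on
        internode = int(np.nonzero(model.disc.domain_code == DOMAIN_CODE["internode"])[0][3])
        cfg = SimConfig(duration=120.0, record_sites=("soma", "bouton", internode),
                        theta=1.0)
        res, state = run_simulation(
            sys, StimulusProtocol(step_currents=[("soma", 0.0, 120.0, -0.1)]),
            cfg, return_state=True,
        )
        assert np.allclose(state.vi, vi_ref, atol=1e-3)
        assert np.allclose(state.ve, ve_ref, atol=1e-3)

    def test_bare_axon_periaxonal_collapse(self, mini_config):
        """Fully demyelinated: periaxonal potential stays at ground."""
        model = apply_scenario(
            build_default_model(9, morph_config=mini_config),
            Scenario(regions=("Ctx", "WM", "Thal"), remove_myelin=True),
        )
        sys = CableSystem(model)
        state = settle(sys, duration=300.0)
        inter = int(np.nonzero(model.disc.domain_code == DOMAIN_CODE["internode"])[0][2])
        cfg = SimConfig(duration=30.0, record_sites=("ais_end", inter, "bouton"))
        res = run_simulation(
            sys, StimulusProtocol(step_currents=[("soma", 2.0, 3.0, 3.0)]),
            cfg, init_state=state,
        )
        assert len(res.spikes["ais_end"]) >= 1
        assert np.abs(res.v_mym[str(inter)]).max() < 0.1

    def test_myelinated_axon_has_transmyelin_transients(self, mini_system, mini_rest, mini_model):
        inter = int(np.nonzero(
            mini_model.disc.domain_code == DOMAIN_CODE["internode"])[0][2])
        cfg = SimConfig(duration=30.0, record_sites=("ais_end", inter, "bouton"))
        res = run_simulation(
            mini_system, StimulusProtocol(step_currents=[("soma", 2.0, 3.0, 3.0)]),
            cfg, init_state=mini_rest,
        )
        assert len(res.spikes["bouton"]) >= 1
        assert np.abs(res.v_mym[str(inter)]).max() > 1.0


class TestRunSimulation:
    def test_rest_is_a_fixed_point(self, mini_system, mini_rest):
        cfg = SimConfig(duration=150.0, record_sites=("soma", "ais_end", "bouton"))
        res = run_simulation(mini_system, StimulusProtocol(), cfg, init_state=mini_rest)
        for site, v in res.v_m.items():
            assert np.abs(v - v[0]).max() < 0.5

    def test_passive_rc_relaxation(self):
        """Single passive compartment follows V = V_inf (1 - e^{-t/tau})."""
        soma = Morphology([Section("soma", None, "soma", "Ctx", 25.0, 25.0)], [])
        passive = PassiveSpec()
        disc = segmentize(soma, SegmentationRule(), passive)
        from saltax.biophysics import assign_densities
        cond = assign_densities(disc, _passive_zero_table())
        sys = build_system(disc, cond, myelin_params_from_lamellae(9), passive)
        cfg = SimConfig(duration=12.0, record_sites=("soma",), theta=0.5)
        res = run_simulation(
            sys, StimulusProtocol(step_currents=[("soma", 1.0, 11.0, 0.05)]), cfg)
        t = res.time
        v = res.v_m["soma"] - passive.e_pas
        area_cm2 = disc.area.sum() * 1e-8
        r_mohm = passive.r_m * 1e3 / area_cm2 / 1e6
        tau = passive.r_m * 1e3 * passive.c_m * 1e-6 * 1e3  # ms
        v_inf = 0.05 * r_mohm
        sel = (t > 1.0) & (t <= 11.0)
        expected = v_inf * (1.0 - np.exp(-(t[sel] - 1.0) / tau))
        err = np.abs(v[sel] - expected).max() / v_inf
        assert err < 0.01

    def test_ap_initiates_in_ais_then_soma_and_reaches_terminal(
            self, mini_system, mini_rest):
        amp = threshold_step_current(mini_system, mini_rest)
        cfg = SimConfig(duration=25.0, record_sites=("soma", "ais_end", "bouton"))
        res = run_simulation(
            mini_system, StimulusProtocol(step_currents=[("soma", 1.0, 3.0, amp)]),
            cfg, init_state=mini_rest,
        )
        assert len(res.spikes["ais_end"]) == 1
        assert len(res.spikes["soma"]) == 1
        assert len(res.spikes["bouton"]) == 1
        assert res.spikes["ais_end"][0] < res.spikes["soma"][0]

    def test_seed_determinism_bitwise(self, mini_system, mini_rest):
        cfg = SimConfig(duration=60.0, seed=7, record_sites=("ais_end", "bouton"))
        proto = StimulusProtocol(step_currents=[("soma", 10.0, 20.0, 1.7)],
                                 fluctuating=FluctuatingInput())
        r1 = run_simulation(mini_system, proto, cfg, init_state=mini_rest)
        r2 = run_simulation(mini_system, proto, cfg, init_state=mini_rest)
        assert np.array_equal(r1.v_m["bouton"], r2.v_m["bouton"])
        assert np.array_equal(r1.spikes["ais_end"], r2.spikes["ais_end"])
        r3 = run_simulation(
            mini_system, proto,
            SimConfig(duration=60.0, seed=8, record_sites=("ais_end", "bouton")),
            init_state=mini_rest)
        assert not np.array_equal(r1.v_m["bouton"], r3.v_m["bouton"])

    @pytest.mark.parametrize("dt", [0.005, 0.025])
    def test_bounded_voltages_across_stable_dt_range(self, mini_system, mini_rest, dt):
        cfg = SimConfig(duration=20.0, dt=dt, record_sites=("soma", "bouton"))
        res = run_simulation(
            mini_system, StimulusProtocol(step_currents=[("soma", 2.0, 3.0, 2.0)]),
            cfg, init_state=mini_rest,
        )
        for v in res.v_m.values():
            assert np.isfinite(v).all()
            assert np.abs(v).max() < 150.0

    def test_stimulus_outside_duration_rejected(self, mini_system):
        cfg = SimConfig(duration=10.0)
        with pytest.raises(SimulationError):
            run_simulation(mini_system,
                           StimulusProtocol(step_currents=[("soma", 50.0, 3.0, 1.0)]),
                           cfg)


class TestOUProcess:
    def test_noiseless_relaxation(self):
        g = 0.05
        for _ in range(600):
            g = ou_conductance_step(g, 0.012, 0.012, 2.72, 0.1, 0.0)
        assert g == pytest.approx(0.012, abs=1e-6)

    def test_stationary_moments_match_printed_values(self):
        rng = np.random.default_rng(42)
        dt, tau, g0, sd = 0.05, 2.72, 0.012, 0.012
        n = 10 ** 6
        f = math.exp(-dt / tau)
        amp = sd * math.sqrt(1 - f * f)
        noise = rng.standard_normal(n)
        # exact-update recursion (same formula as ou_conductance_step)
        from scipy.signal import lfilter
        g = g0 + lfilter([amp], [1.0, -f], noise)
        # spot-check equivalence with the scalar step
        gs = g0
        for k in range(5):
            gs = ou_conductance_step(gs, g0, sd, tau, dt, noise[k])
        assert gs == pytest.approx(g[4], rel=1e-12)
        burn = int(20 * tau / dt)
        assert np.mean(g[burn:]) == pytest.approx(g0, abs=3 * sd / math.sqrt(n * dt / (2 * tau)))
        assert np.std(g[burn:]) == pytest.approx(sd, rel=0.02)

    def test_autocorrelation_time_matches_tau(self):
        rng = np.random.default_rng(3)
        dt, tau, g0, sd = 0.05, 2.72, 0.0, 1.0
        n = 10 ** 6
        f = math.exp(-dt / tau)
        amp = sd * math.sqrt(1 - f * f)
        from scipy.signal import lfilter
        g = lfilter([amp], [1.0, -f], rng.standard_normal(n))
        g = g[10000:]
        lags = np.arange(1, int(3 * tau / dt))
        ac = np.array([np.corrcoef(g[:-k], g[k:])[0, 1] for k in lags])
        slope = np.polyfit(lags * dt, np.log(ac), 1)[0]
        assert -1.0 / slope == pytest.approx(tau, rel=0.05)


class TestSpikeMeasures:
    def test_flat_trace_no_spikes(self):
        times, thr = detect_spikes(np.full(2000, -80.0), 0.01)
        assert len(times) == 0

    def test_gaussian_bump_single_spike_at_peak(self):
        dt = 0.01
        t = np.arange(0, 20, dt)
        v = -80.0 + 110.0 * np.exp(-0.5 * ((t - 10.0) / 0.2) ** 2)
        assert np.max(np.diff(v) / dt) > 50.0
        times, thr = detect_spikes(v, dt)
        assert len(times) == 1
        assert times[0] == pytest.approx(10.0, abs=dt)

    def test_triangular_pulse_halfwidth_geometry(self):
        """Isoceles triangle, height 100 mV, base 1 ms -> halfwidth 500 µs."""
        dt = 0.001
        t = np.arange(0, 3, dt)
        v = np.full_like(t, -80.0)
        rise = (t >= 1.0) & (t <= 1.5)
        fall = (t > 1.5) & (t <= 2.0)
        v[rise] = -80.0 + 200.0 * (t[rise] - 1.0)
        v[fall] = 20.0 - 200.0 * (t[fall] - 1.5)
        amp, hw = measure_ap_waveform(v, dt, 1.5)
        assert amp == pytest.approx(100.0, rel=0.01)
        assert hw == pytest.approx(500.0, rel=0.01)

    def test_halfwidth_resampling_invariance(self):
        """Halfwidth changes < 2% when the trace is sampled twice as fine."""
        def make(dt):
            t = np.arange(0, 20, dt)
            v = -80.0 + 105.0 * np.exp(-0.5 * ((t - 10.0) / 0.18) ** 2)
            return v, dt

        v1, d1 = make(0.01)
        v2, d2 = make(0.005)
        t1, _ = detect_spikes(v1, d1)
        t2, _ = detect_spikes(v2, d2)
        _, hw1 = measure_ap_waveform(v1, d1, t1[0])
        _, hw2 = measure_ap_waveform(v2, d2, t2[0])
        assert abs(hw1 - hw2) / hw1 < 0.02

    def test_truncated_spike_raises(self):
        dt = 0.01
        t = np.arange(0, 10, dt)
        v = -80.0 + 110.0 * np.exp(-0.5 * ((t - 9.95) / 0.2) ** 2)
        with pytest.raises(SimulationError):
            measure_ap_waveform(v, dt, 9.95)


class TestConductionVelocity:
    def test_arithmetic(self):
        res = type("R", (), {})()
        res.spikes = {"a": np.array([1.0]), "b": np.array([3.1])}
        cv = conduction_velocity(res, "a", "b", 4200.0)
        assert cv[0] == pytest.approx(2.0)

    def test_negative_delay_raises(self):
        res = type("R", (), {})()
        res.spikes = {"a": np.array([5.0]), "b": np.array([2.0])}
        with pytest.raises(SimulationError):
            conduction_velocity(res, "a", "b", 4200.0)

    def test_spike_to_spike_delay_sums(self):
        assert spike_to_spike_delay(2.24) == pytest.approx(3.74)
        assert spike_to_spike_delay(0.0) == pytest.approx(1.5)
        with pytest.raises(ValueError):
            spike_to_spike_delay(-1.0)
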