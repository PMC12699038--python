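"""Numba kernels for the double-cable backward-Euler integrator.

The spatial system has two potentials per segment: the intracellular
potential ``vi`` and the periaxonal (submyelin) potential ``ve``; the
transmembrane potential is ``vi - ve`` and the transmyelin potential is
``ve`` (the outermost layer is grounded).  Bare segments (soma,
dendrites, AIS, nodes, bouton, demyelinated stretches) have their
periaxonal layer collapsed to ground (``ve = 0``).

Each time step:

1. exact Ornstein-Uhlenbeck update of the fluctuating synaptic
   conductances,
2. analytic exponential update of all gating states using lookup tables
   of steady states and step factors (staggered with the voltage solve),
3. assembly of per-segment total conductance/driving terms,
4. one implicit solve of the coupled two-layer cable system by
   block-Hines elimination with 2x2 blocks (children are eliminated into
   parents; the segment ordering guarantees parent index < child index);
   conductive terms are theta-weighted between the old and new time
   levels (theta = 1: backward Euler; theta = 0.5: Crank-Nicolson with
   staggered gating),
5. submembrane calcium update.

Voltage-dependent rates are tabulated on a uniform grid (built from the
same Python rate functions exposed by :mod:`saltax.biophysics`) and
linearly interpolated, which keeps the per-step cost at a few
operations per gate instance.
"""

import numpy as np
from numba import njit


@njit(cache=True)
def _lerp(tab, gate, v, v0, dv, nv):
    x = (v - v0) / dv
    if x <= 0.0:
        return tab[gate, 0]
    if x >= nv - 1:
        return tab[gate, nv - 1]
    i = int(x)
    f = x - i
    return tab[gate, i] * (1.0 - f) + tab[gate, i + 1] * f


@njit(cache=True)
def integrate(
    nsteps,
    dt,
    theta,
    # geometry / passive
    parent,      # (n,) int64, parent segment (-1 root), parent[i] < i
    ga,          # (n,) µS intracellular axial conductance to parent
    gp,          # (n,) µS periaxonal axial conductance to parent (0 if either side grounded)
    grounded,    # (n,) uint8, 1 if periaxonal layer collapses to ground
    cm,          # (n,) nF membrane capacitance
    cmy,         # (n,) nF myelin capacitance
    gmy,         # (n,) µS myelin (radial) conductance
    gp_ground,   # (n,) µS periaxonal conductance to ground via grounded neighbours
    gpas,        # (n,) µS leak conductance
    epas,        # mV leak reversal
    # channels
    chan_ptr,    # (n_chan+1,) int64 instance ranges per channel
    chan_seg,    # (n_inst,) int64 segment per instance
    gbar,        # (n_inst,) µS maximal conductance per instance
    erev,        # (n_chan,) mV
    is_ca,       # (n_chan,) uint8 channel carries Ca current
    # gates
    gate_chan,       # (n_gate,) int64 channel of each gate
    gate_exp,        # (n_gate,) int64 exponent
    gate_is_kca,     # (n_gate,) uint8 calcium-dependent forward rate
    gate_kca_a,      # (n_gate,) 1/ms/mM (already Q10-scaled)
    gate_kca_b,      # (n_gate,) 1/ms (already Q10-scaled)
    gate_state_ptr,  # (n_gate+1,) int64 state ranges
    states,          # (sum of instance counts over gates,) gating states
    xinf_tab,        # (n_gate, nv) steady states on the v grid
    xfac_tab,        # (n_gate, nv) 1 - exp(-dt/tau) on the v grid
    v0, dv,
    # calcium
    ca,          # (n,) mM
    ca_scale,    # (n,) mM per nA·ms
    tau_ca, ca0,
    # fluctuating input (exact OU, conductances clipped at evaluation)
    ou_seg,      # int64 segment index or -1
    ou_par,      # (8,) ge0, sde, taue, Ee, gi0, sdi, taui, Ei
    ou_state,    # (2,) current ge, gi (µS)
    noise,       # (nsteps, 2) standard normal draws
    # stimulus steps
    stim_seg, stim_on, stim_off, stim_amp,   # per step-current arrays
    # state (updated in place)
    vi, ve,
    # recording
    rec_idx,     # (nrec,) int64
    vm_out,      # (nsteps+1, nrec)
    ve_out,      # (nsteps+1, nrec)
):
    n = vi.shape[0]
    nv = xinf_tab.shape[1]
    n_chan = chan_ptr.shape[0] - 1
    n_gate = gate_chan.shape[0]
    nrec = rec_idx.shape[0]

    gsum = np.empty(n)
    gesum = np.empty(n)
    istim = np.empty(n)
    icasum = np.empty(n)
    vm = np.empty(n)
    for i in range(n):
        vm[i] = vi[i] - ve[i]

    # scratch: open conductance per instance for Ca-carrying channels
    gopen = np.empty(chan_seg.shape[0])

    # per-segment 2x2 blocks and rhs
    d11 = np.empty(n); d12 = np.empty(n); d21 = np.empty(n); d22 = np.empty(n)
    b1 = np.empty(n); b2 = np.empty(n)

    for k in range(nrec):
        vm_out[0, k] = vm[rec_idx[k]]
        ve_out[0, k] = ve[rec_idx[k]]

    ge0 = ou_par[0]; sde = ou_par[1]; taue = ou_par[2]; Ee = ou_par[3]
    gi0 = ou_par[4]; sdi = ou_par[5]; taui = ou_par[6]; Ei = ou_par[7]
    if ou_seg >= 0:
        fe = np.exp(-dt / taue)
        ae = sde * np.sqrt(1.0 - fe * fe)
        fi = np.exp(-dt / taui)
        ai = sdi * np.sqrt(1.0 - fi * fi)
    else:
        fe = ae = fi = ai = 0.0

    for step in range(nsteps):
        t_new = (step + 1) * dt

        # --- fluctuating conductances (exact OU update) ---
        if ou_seg >= 0:
            ou_state[0] = ge0 + (ou_state[0] - ge0) * fe + ae * noise[step, 0]
            ou_state[1] = gi0 + (ou_state[1] - gi0) * fi + ai * noise[step, 1]

        # --- gating update (analytic exponential, tabulated rates) ---
        for g in range(n_gate):
            c = gate_chan[g]
            i0 = chan_ptr[c]
            s0 = gate_state_ptr[g]
            cnt = chan_ptr[c + 1] - i0
            if gate_is_kca[g] == 1:
                a_coef = gate_kca_a[g]
                b_coef = gate_kca_b[g]
                for k in range(cnt):
                    seg = chan_seg[i0 + k]
                    a = a_coef * ca[seg]
                    r = a + b_coef
                    inf = a / r
                    fac = 1.0 - np.exp(-dt * r)
                    states[s0 + k] += (inf - states[s0 + k]) * fac
            else:
                for k in range(cnt):
                    seg = chan_seg[i0 + k]
                    v = vm[seg]
                    inf = _lerp(xinf_tab, g, v, v0, dv, nv)
                    fac = _lerp(xfac_tab, g, v, v0, dv, nv)
                    states[s0 + k] += (inf - states[s0 + k]) * fac

        # --- assemble per-segment conductances ---
        for i in range(n):
            gsum[i] = gpas[i]
            gesum[i] = gpas[i] * epas
            istim[i] = 0.0
            icasum[i] = 0.0

        for c in range(n_chan):
            i0 = chan_ptr[c]
            cnt = chan_ptr[c + 1] - i0
            for k in range(cnt):
                gopen[i0 + k] = gbar[i0 + k]
            for g in range(n_gate):
                if gate_chan[g] != c:
                    continue
                s0 = gate_state_ptr[g]
                e = gate_exp[g]
                for k in range(cnt):
                    x = states[s0 + k]
                    p = x
                    for _ in range(e - 1):
                        p *= x
                    gopen[i0 + k] *= p
            E = erev[c]
            for k in range(cnt):
                seg = chan_seg[i0 + k]
                gsum[seg] += gopen[i0 + k]
                gesum[seg] += gopen[i0 + k] * E

        if ou_seg >= 0:
            g_e = ou_state[0] if ou_state[0] > 0.0 else 0.0
            g_i = ou_state[1] if ou_state[1] > 0.0 else 0.0
            gsum[ou_seg] += g_e + g_i
            gesum[ou_seg] += g_e * Ee + g_i * Ei

        for s in range(stim_seg.shape[0]):
            if stim_on[s] < t_new <= stim_off[s] + 1e-12:
                istim[stim_seg[s]] += stim_amp[s]

        # --- build 2x2 blocks (theta-weighted conductive terms) ---
        omt = 1.0 - theta
        for i in range(n):
            alpha = cm[i] / dt + theta * gsum[i]
            # explicit part of the membrane current (zero for theta = 1)
            imem_old = omt * gsum[i] * vm[i]
            rhs_m = cm[i] / dt * vm[i] - imem_old + gesum[i] + istim[i]
            d11[i] = alpha
            d12[i] = -alpha
            b1[i] = rhs_m
            if grounded[i] == 1:
                d21[i] = 0.0
                d22[i] = 1.0
                b2[i] = 0.0
            else:
                beta = cmy[i] / dt + theta * (gmy[i] + gp_ground[i])
                d21[i] = -alpha
                d22[i] = alpha + beta
                b2[i] = (
                    -rhs_m + istim[i] + cmy[i] / dt * ve[i]
                    - omt * (gmy[i] + gp_ground[i]) * ve[i]
                )
                # note: istim enters the intracellular node only; the
                # stimulus term cancels from row B (rhs_m includes it)
        # axial contributions: theta-weighted implicit part on the
        # diagonal, explicit remainder on the rhs
        for i in range(n):
            p = parent[i]
            if p >= 0:
                d11[i] += theta * ga[i]
                d11[p] += theta * ga[i]
                if omt > 0.0:
                    f = omt * ga[i] * (vi[i] - vi[p])
                    b1[i] -= f
                    b1[p] += f
                if gp[i] > 0.0:
                    d22[i] += theta * gp[i]
                    d22[p] += theta * gp[i]
                    if omt > 0.0:
                        f = omt * gp[i] * (ve[i] - ve[p])
                        b2[i] -= f
                        b2[p] += f

        # --- block-Hines elimination (children into parents) ---
        for i in range(n - 1, 0, -1):
            p = parent[i]
            det = d11[i] * d22[i] - d12[i] * d21[i]
            inv11 = d22[i] / det
            inv12 = -d12[i] / det
            inv21 = -d21[i] / det
            inv22 = d11[i] / det
            # off-diagonal blocks are diag(-ga, -gp) in both directions
            u1 = -theta * ga[i]
            u2 = -theta * gp[i]
            # M = L * D^-1  where L = diag(u1, u2)
            m11 = u1 * inv11
            m12 = u1 * inv12
            m21 = u2 * inv21
            m22 = u2 * inv22
            d11[p] -= m11 * u1
            d12[p] -= m12 * u2
            d21[p] -= m21 * u1
            d22[p] -= m22 * u2
            b1[p] -= m11 * b1[i] + m12 * b2[i]
            b2[p] -= m21 * b1[i] + m22 * b2[i]

        det = d11[0] * d22[0] - d12[0] * d21[0]
        vi[0] = (b1[0] * d22[0] - d12[0] * b2[0]) / det
        ve[0] = (d11[0] * b2[0] - b1[0] * d21[0]) / det
        for i in range(1, n):
            p = parent[i]
            r1 = b1[i] + theta * ga[i] * vi[p]
            r2 = b2[i] + theta * gp[i] * ve[p]
            det = d11[i] * d22[i] - d12[i] * d21[i]
            vi[i] = (r1 * d22[i] - d12[i] * r2) / det
            ve[i] = (d11[i] * r2 - r1 * d21[i]) / det

        for i in range(n):
            vm[i] = vi[i] - ve[i]

        # --- calcium update (backward Euler on the shell ODE) ---
        for c in range(n_chan):
            if is_ca[c] == 0:
                continue
            i0 = chan_ptr[c]
            cnt = chan_ptr[c + 1] - i0
            E = erev[c]
            for k in range(cnt):
                seg = chan_seg[i0 + k]
                icasum[seg] += gopen[i0 + k] * (vm[seg] - E)
        for i in range(n):
            if ca_scale[i] > 0.0:
                influx = -icasum[i] * ca_scale[i]
                if influx < 0.0:
                    influx = 0.0
                ca[i] = (ca[i] + dt * influx + dt * ca0 / tau_ca) / (1.0 + dt / tau_ca)

        for k in range(nrec):
            vm_out[step + 1, k] = vm[rec_idx[k]]
            ve_out[step + 1, k] = ve[rec_idx[k]]

        if (step & 255) == 0:
            bad = False
            for i in range(n):
                if not np.isfinite(vi[i]):
                    bad = True
                    break
            if bad:
                return step
    for i in range(n):
        if not np.isfinite(vi[i]) or not np.isfinite(ve[i]):
            return nsteps - 1
    return -1
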