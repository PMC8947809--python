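"""Numba-compiled integration kernels.

All kernels work in a single consistent unit system: mV, pA, nS, pF, ms,
kHz (rates are events per ms).  Conversions from user-facing units (nA for
currents and current-based weights) happen at the API boundary in
:mod:`spiketempering.lif_core`.

Conventions shared by all kernels:

* synaptic state variables jump by the synaptic weight at (delayed) spike
  arrival, at the beginning of a step, and decay exponentially;
* the membrane is advanced with an exact exponential update (current-based)
  or exponential Euler (conductance-based);
* a spike is stamped when the membrane is at or above threshold at the end
  of a step; the membrane is then clamped to the reset potential for the
  refractory period while synaptic variables keep integrating;
* each kernel call seeds numba's own RNG, so identical arguments produce
  bit-identical output.
"""

import numpy as np
from numba import njit

#: status codes returned by kernels
OK = 0
NONFINITE = 1


@njit(cache=True)
def _poisson(lam):
    if lam <= 0.0:
        return 0
    return np.random.poisson(lam)


@njit(cache=True)
def cuba_net(
    n_steps,
    dt,
    # per-neuron parameters
    tau_m,
    tau_s,
    g_l,
    E_l,
    v_th,
    v_reset,
    ref_steps,
    I_in,  # pA, constant injected current
    # background: shared rate schedule (kHz per step), per-neuron weights (pA)
    nu_exc_t,
    nu_inh_t,
    w_bg_exc,
    w_bg_inh,  # signed; inhibitory weights are negative
    # recurrent synapses in CSR-like layout by presynaptic neuron
    syn_ptr,
    syn_post,
    syn_w,  # pA increments (signed)
    syn_delay,  # steps, >= 0 (0 means arrival at the next step)
    u0,
    record_u,
    seed,
    max_spikes,
):
    """Current-based LIF network with exponential synaptic currents."""
    np.random.seed(seed)
    n = tau_m.shape[0]

    d_m = np.empty(n)
    d_s = np.empty(n)
    k_syn = np.empty(n)
    for i in range(n):
        d_m[i] = np.exp(-dt / tau_m[i])
        d_s[i] = np.exp(-dt / tau_s[i])
        if abs(tau_s[i] - tau_m[i]) > 1e-9 * tau_s[i]:
            k_syn[i] = tau_s[i] / (g_l[i] * (tau_s[i] - tau_m[i]))
        else:
            # degenerate tau_s == tau_m limit handled separately below
            k_syn[i] = np.nan

    max_delay = 0
    for s in range(syn_delay.shape[0]):
        if syn_delay[s] > max_delay:
            max_delay = syn_delay[s]
    L = max_delay + 2
    buf = np.zeros((L, n))

    u = u0.copy()
    I_syn = np.zeros(n)
    refrac = np.zeros(n, dtype=np.int64)

    spike_steps = np.empty(max_spikes, dtype=np.int64)
    spike_ids = np.empty(max_spikes, dtype=np.int64)
    n_spikes = 0

    if record_u:
        u_out = np.empty((n_steps, n))
    else:
        u_out = np.empty((0, n))

    status = OK
    for t in range(n_steps):
        slot = t % L
        for i in range(n):
            # delayed recurrent input, then background jumps
            I_syn[i] += buf[slot, i]
            buf[slot, i] = 0.0
            lam_e = nu_exc_t[t] * dt
            lam_i = nu_inh_t[t] * dt
            I_syn[i] += w_bg_exc[i] * _poisson(lam_e) + w_bg_inh[i] * _poisson(lam_i)

            if refrac[i] > 0:
                u[i] = v_reset[i]
                refrac[i] -= 1
            else:
                u_inf = E_l[i] + I_in[i] / g_l[i]
                a = I_syn[i]
                if np.isnan(k_syn[i]):
                    # tau_s == tau_m: particular solution (a*t/(g_l*tau)) e^{-t/tau}
                    u[i] = (
                        u_inf
                        + (u[i] - u_inf) * d_m[i]
                        + (a / g_l[i]) * (dt / tau_m[i]) * d_m[i]
                    )
                else:
                    u[i] = (
                        u_inf
                        + (u[i] - u_inf - k_syn[i] * a) * d_m[i]
                        + k_syn[i] * a * d_s[i]
                    )
                if u[i] > v_th[i]:
                    if n_spikes < max_spikes:
                        spike_steps[n_spikes] = t
                        spike_ids[n_spikes] = i
                        n_spikes += 1
                    u[i] = v_reset[i]
                    refrac[i] = ref_steps[i]
                    for s in range(syn_ptr[i], syn_ptr[i + 1]):
                        d = syn_delay[s]
                        if d < 1:
                            d = 1
                        buf[(t + d) % L, syn_post[s]] += syn_w[s]
            I_syn[i] *= d_s[i]
            if record_u:
                u_out[t, i] = u[i]
        if (t & 4095) == 0:
            for i in range(n):
                if not np.isfinite(u[i]):
                    status = NONFINITE
        if status != OK:
            break

    return status, spike_steps[:n_spikes], spike_ids[:n_spikes], u_out


@njit(cache=True)
def coba_net(
    n_steps,
    dt,
    # per-neuron parameters
    C_m,
    g_l,
    E_l,
    E_exc,
    E_inh,
    tau_exc,
    tau_inh,
    v_th,
    v_reset,
    ref_steps,
    I_in,  # pA
    g_bias_exc,  # nS, constant excitatory conductance offset
    # background
    nu_exc_t,
    nu_inh_t,
    w_bg_exc,
    w_bg_inh,  # nS, both positive
    # per-neuron constant-rate Poisson drive on the excitatory channel;
    # with share_extra=1 one spike train (rate nu_extra[0]) drives everyone
    nu_extra,
    w_extra,
    share_extra,
    # recurrent synapses (CSR by presynaptic neuron)
    syn_ptr,
    syn_post,
    syn_w,  # nS, positive
    syn_is_inh,
    syn_delay,
    u0,
    record_u,
    record_g,
    seed,
    max_spikes,
):
    """Conductance-based LIF network with exponential conductances."""
    np.random.seed(seed)
    n = C_m.shape[0]

    d_e = np.empty(n)
    d_i = np.empty(n)
    for i in range(n):
        d_e[i] = np.exp(-dt / tau_exc[i])
        d_i[i] = np.exp(-dt / tau_inh[i])

    max_delay = 0
    for s in range(syn_delay.shape[0]):
        if syn_delay[s] > max_delay:
            max_delay = syn_delay[s]
    L = max_delay + 2
    buf_e = np.zeros((L, n))
    buf_i = np.zeros((L, n))

    u = u0.copy()
    g_e = np.zeros(n)
    g_i = np.zeros(n)
    refrac = np.zeros(n, dtype=np.int64)

    spike_steps = np.empty(max_spikes, dtype=np.int64)
    spike_ids = np.empty(max_spikes, dtype=np.int64)
    n_spikes = 0

    if record_u:
        u_out = np.empty((n_steps, n))
    else:
        u_out = np.empty((0, n))
    if record_g:
        ge_out = np.empty((n_steps, n))
        gi_out = np.empty((n_steps, n))
    else:
        ge_out = np.empty((0, n))
        gi_out = np.empty((0, n))

    status = OK
    for t in range(n_steps):
        slot = t % L
        shared_cnt = 0
        if share_extra == 1 and nu_extra[0] > 0.0:
            shared_cnt = _poisson(nu_extra[0] * dt)
        for i in range(n):
            g_e[i] += buf_e[slot, i]
            g_i[i] += buf_i[slot, i]
            buf_e[slot, i] = 0.0
            buf_i[slot, i] = 0.0
            g_e[i] += w_bg_exc[i] * _poisson(nu_exc_t[t] * dt)
            g_i[i] += w_bg_inh[i] * _poisson(nu_inh_t[t] * dt)
            if share_extra == 1:
                g_e[i] += w_extra[i] * shared_cnt
            elif nu_extra[i] > 0.0:
                g_e[i] += w_extra[i] * _poisson(nu_extra[i] * dt)

            if refrac[i] > 0:
                u[i] = v_reset[i]
                refrac[i] -= 1
            else:
                ge_tot = g_e[i] + g_bias_exc[i]
                g_tot = g_l[i] + ge_tot + g_i[i]
                u_inf = (
                    g_l[i] * E_l[i]
                    + ge_tot * E_exc[i]
                    + g_i[i] * E_inh[i]
                    + I_in[i]
                ) / g_tot
                u[i] = u_inf + (u[i] - u_inf) * np.exp(-dt * g_tot / C_m[i])
                if u[i] > v_th[i]:
                    if n_spikes < max_spikes:
                        spike_steps[n_spikes] = t
                        spike_ids[n_spikes] = i
                        n_spikes += 1
                    u[i] = v_reset[i]
                    refrac[i] = ref_steps[i]
                    for s in range(syn_ptr[i], syn_ptr[i + 1]):
                        d = syn_delay[s]
                        if d < 1:
                            d = 1
                        if syn_is_inh[s]:
                            buf_i[(t + d) % L, syn_post[s]] += syn_w[s]
                        else:
                            buf_e[(t + d) % L, syn_post[s]] += syn_w[s]
            g_e[i] *= d_e[i]
            g_i[i] *= d_i[i]
            if record_u:
                u_out[t, i] = u[i]
            if record_g:
                ge_out[t, i] = g_e[i]
                gi_out[t, i] = g_i[i]
        if (t & 4095) == 0:
            for i in range(n):
                if not np.isfinite(u[i]):
                    status = NONFINITE
        if status != OK:
            break

    return status, spike_steps[:n_spikes], spike_ids[:n_spikes], u_out, ge_out, gi_out


@njit(cache=True)
def coba_single_twin(
    n_steps,
    dt,
    C_m,
    g_l,
    E_l,
    E_exc,
    E_inh,
    tau_exc,
    tau_inh,
    v_th,
    v_reset,
    ref_steps,
    I_in,
    nu_bg_exc,
    nu_bg_inh,
    w_bg_exc,
    w_bg_inh,
    ge_jump,  # nS conductance increments per step from the replayed stimulus
    gi_jump,
    stochastic,  # 0: deterministic threshold; 1: exponential escape rate
    T_esc,  # mV
    u_T,  # mV
    record_twin,
    seed,
    max_spikes,
):
    """One conductance-based neuron plus its passive (threshold-free) twin.

    The spiking neuron integrates the replayed stimulus (``ge_jump``,
    ``gi_jump``) plus its own Poisson background realization.  The twin is
    the stimulus-filtered free membrane potential: it receives the stimulus
    only — the background is exactly the variability the escape rate is
    fitted to describe — and is reset to ``v_reset`` at every spike of the
    spiking neuron and held there for the refractory period, mirroring the
    spiking neuron's reset dynamics.  With ``stochastic=1`` the spike
    criterion is the exponential escape rate ``rho = exp((u - u_T)/T)/dt``
    applied to the spiking neuron's membrane; otherwise the deterministic
    threshold.
    """
    np.random.seed(seed)
    d_e = np.exp(-dt / tau_exc)
    d_i = np.exp(-dt / tau_inh)

    u = E_l
    u_twin = E_l
    g_e = 0.0  # spiking neuron: stimulus + background
    g_i = 0.0
    g_e_s = 0.0  # twin: stimulus only
    g_i_s = 0.0
    refrac = 0

    spike_steps = np.empty(max_spikes, dtype=np.int64)
    n_spikes = 0
    if record_twin:
        twin_out = np.empty(n_steps)
    else:
        twin_out = np.empty(0)

    for t in range(n_steps):
        g_e += ge_jump[t] + w_bg_exc * _poisson(nu_bg_exc[t] * dt)
        g_i += gi_jump[t] + w_bg_inh * _poisson(nu_bg_inh[t] * dt)
        g_e_s += ge_jump[t]
        g_i_s += gi_jump[t]

        g_tot = g_l + g_e + g_i
        u_inf = (g_l * E_l + g_e * E_exc + g_i * E_inh + I_in) / g_tot
        decay = np.exp(-dt * g_tot / C_m)

        g_tot_s = g_l + g_e_s + g_i_s
        u_inf_s = (g_l * E_l + g_e_s * E_exc + g_i_s * E_inh + I_in) / g_tot_s
        if refrac > 0:
            u_twin = v_reset
        else:
            u_twin = u_inf_s + (u_twin - u_inf_s) * np.exp(-dt * g_tot_s / C_m)
        if record_twin:
            # pre-reset value: at spike steps this is the potential the
            # histogram fit conditions on
            twin_out[t] = u_twin

        spiked = False
        if refrac > 0:
            u = v_reset
            refrac -= 1
        else:
            u = u_inf + (u - u_inf) * decay
            if stochastic == 1:
                rho_dt = np.exp((u - u_T) / T_esc)  # rho * dt
                if rho_dt > 30.0:
                    p = 1.0
                else:
                    p = 1.0 - np.exp(-rho_dt)
                spiked = np.random.random() < p
            else:
                spiked = u > v_th
            if spiked:
                if n_spikes < max_spikes:
                    spike_steps[n_spikes] = t
                    n_spikes += 1
                u = v_reset
                u_twin = v_reset
                refrac = ref_steps

        g_e *= d_e
        g_i *= d_i
        g_e_s *= d_e
        g_i_s *= d_i

    return spike_steps[:n_spikes], twin_out
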