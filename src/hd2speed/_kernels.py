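"""Numba inner loops for spike sampling and synapse recursion.

These are sequential recursions (dead-time thinning, per-spike synaptic
state updates) that do not vectorise; everything around them is numpy.
"""

from __future__ import annotations

import numba
import numpy as np


@numba.njit(cache=True)
def thin_with_dead_time(cand_t, cand_rate, uniforms, lam_max, refractory):
    """Accept candidate Poisson events by thinning with an absolute dead time.

    Candidates within ``refractory`` ms of the last accepted event are
    rejected outright (intensity is zero during the dead time); otherwise a
    candidate at time t is accepted with probability rate(t)/lam_max.
    Returns the accepted times.
    """
    n = cand_t.shape[0]
    out = np.empty(n, dtype=np.float64)
    m = 0
    t_last = -1e18
    for i in range(n):
        if cand_t[i] - t_last < refractory:
            continue
        if uniforms[i] * lam_max < cand_rate[i]:
            out[m] = cand_t[i]
            m += 1
            t_last = cand_t[i]
    return out[:m]


@numba.njit(cache=True)
def tm_release_train(spike_times, tau_d, tau_f, U):
    """Per-spike release fractions u⁺x⁻ of a Tsodyks–Markram synapse.

    Event-driven exact recursion from rest (x=1, u=0): between spikes
    x relaxes toward 1 with tau_d and u decays with tau_f; on a spike
    u⁺ = u⁻ + U(1−u⁻), release = u⁺x⁻, x⁺ = x⁻(1−u⁺).
    """
    n = spike_times.shape[0]
    rel = np.empty(n, dtype=np.float64)
    x = 1.0
    u = 0.0
    t_prev = -1e18
    for i in range(n):
        dt = spike_times[i] - t_prev
        if dt < 1e17:  # skip relaxation before the first spike
            x = 1.0 - (1.0 - x) * np.exp(-dt / tau_d)
            u = u * np.exp(-dt / tau_f)
        u = u + U * (1.0 - u)
        rel[i] = u * x
        x = x * (1.0 - u)
        t_prev = spike_times[i]
    return rel


@numba.njit(cache=True)
def exp_filter(impulses, decay):
    """Leaky accumulator: g[k] = g[k-1]*decay + impulses[k]."""
    n = impulses.shape[0]
    out = np.empty(n, dtype=np.float64)
    g = 0.0
    for k in range(n):
        g = g * decay + impulses[k]
        out[k] = g
    return out


@numba.njit(cache=True)
def hh_step_loop(gsyn, dt, c_m, g_l, e_l, g_na, e_na, g_k, e_k, g_ks, tau_ks, e_syn,
                 v0, thresh, reset_level):
    """Integrate a single-compartment spiking neuron driven by a conductance.

    Wang–Buzsáki-style fast sodium (instantaneous m) and delayed-rectifier
    kinetics plus a slow non-inactivating potassium conductance standing in
    for the Kv1.1-mediated current.  Spike times are upward crossings of
    ``thresh`` with hysteresis (V must fall below ``reset_level`` before the
    next spike is counted).  Returns (spike_times, V trace).
    """
    n = gsyn.shape[0]
    v = v0
    # steady-state gates at v0
    h = 0.6
    ng = 0.3
    p = 0.0
    phi = 5.0
    vtr = np.empty(n, dtype=np.float64)
    spikes = np.empty(n, dtype=np.float64)
    nsp = 0
    armed = True
    for k in range(n):
        vm = v
        # alpha/beta rate functions (Wang & Buzsaki 1996 conventions)
        am = -0.1 * (vm + 35.0) / (np.exp(-0.1 * (vm + 35.0)) - 1.0) if vm != -35.0 else 1.0
        bm = 4.0 * np.exp(-(vm + 60.0) / 18.0)
        minf = am / (am + bm)
        ah = 0.07 * np.exp(-(vm + 58.0) / 20.0)
        bh = 1.0 / (np.exp(-0.1 * (vm + 28.0)) + 1.0)
        an = -0.01 * (vm + 34.0) / (np.exp(-0.1 * (vm + 34.0)) - 1.0) if vm != -34.0 else 0.1
        bn = 0.125 * np.exp(-(vm + 44.0) / 80.0)
        pinf = 1.0 / (1.0 + np.exp(-(vm + 35.0) / 10.0))
        i_na = g_na * minf ** 3 * h * (vm - e_na)
        i_k = g_k * ng ** 4 * (vm - e_k)
        i_ks = g_ks * p * (vm - e_k)
        i_l = g_l * (vm - e_l)
        i_syn = gsyn[k] * (vm - e_syn)
        dv = (-i_na - i_k - i_ks - i_l - i_syn) / c_m
        v = vm + dt * dv
        h = h + dt * phi * (ah * (1.0 - h) - bh * h)
        ng = ng + dt * phi * (an * (1.0 - ng) - bn * ng)
        p = p + dt * (pinf - p) / tau_ks
        vtr[k] = v
        if armed and v >= thresh and vm < thresh:
            spikes[nsp] = k * dt
            nsp += 1
            armed = False
        if not armed and v < reset_level:
            armed = True
    return spikes[:nsp], vtr


@numba.njit(cache=True)
def tm_ode_rk4(spike_times, duration, dt, tau_d, tau_f, tau_g, U, weight):
    """Brute-force fixed-step RK4 integration of the TM system.

    Jumps are applied at spike times (assumed aligned to the step grid);
    the smooth part is integrated with classical RK4.  Returns the (x, u, g)
    trajectories sampled at every step — an independent oracle for the
    event-driven implementation.
    """
    n = int(round(duration / dt)) + 1
    xs = np.empty(n)
    us = np.empty(n)
    gs = np.empty(n)
    x = 1.0
    u = 0.0
    g = 0.0
    isp = 0
    nsp = spike_times.shape[0]
    for k in range(n):
        t = k * dt
        # apply any spike scheduled at this instant (before recording)
        while isp < nsp and spike_times[isp] <= t + 1e-12:
            up = u + U * (1.0 - u)
            g = g + weight * up * x
            x = x * (1.0 - up)
            u = up
            isp += 1
        xs[k] = x
        us[k] = u
        gs[k] = g
        # RK4 on the linear decays (independent equations)
        # dx/dt = (1-x)/tau_d ; du/dt = -u/tau_f ; dg/dt = -g/tau_g
        k1 = (1.0 - x) / tau_d
        k2 = (1.0 - (x + 0.5 * dt * k1)) / tau_d
        k3 = (1.0 - (x + 0.5 * dt * k2)) / tau_d
        k4 = (1.0 - (x + dt * k3)) / tau_d
        x = x + dt / 6.0 * (k1 + 2 * k2 + 2 * k3 + k4)
        k1 = -u / tau_f
        k2 = -(u + 0.5 * dt * k1) / tau_f
        k3 = -(u + 0.5 * dt * k2) / tau_f
        k4 = -(u + dt * k3) / tau_f
        u = u + dt / 6.0 * (k1 + 2 * k2 + 2 * k3 + k4)
        k1 = -g / tau_g
        k2 = -(g + 0.5 * dt * k1) / tau_g
        k3 = -(g + 0.5 * dt * k2) / tau_g
        k4 = -(g + dt * k3) / tau_g
        g = g + dt / 6.0 * (k1 + 2 * k2 + 2 * k3 + k4)
    return xs, us, gs
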