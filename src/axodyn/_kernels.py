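"""Numba kernels for the implicit cable integrator.

The spatially discretized cell is a chain (tridiagonal conductance matrix).
One backward-Euler step solves

    (C/dt + G + g_Na(t) e_na e_na^T) V_{k+1} = C/dt V_k + b_k

where G collects leak and axial conductances and the sodium point conductance
g_Na(t) = gbar * m enters only on the diagonal of the sodium node.  Because G
is constant within a trial, the tridiagonal LU factorization of
A0 = C/dt + G is precomputed once; the rank-one sodium term is folded in per
step with the Sherman-Morrison identity using the precomputed column
z = A0^{-1} e_na.  Gating uses exact exponential relaxation toward
m_inf(V_na) evaluated at the pre-step voltage (staggered update).

Units: mV, ms, nA, uS, nF (currents g*V in uS*mV = nA).
"""

import numpy as np
from numba import njit

__all__ = [
    "thomas_factor",
    "thomas_solve",
    "run_trial_kernel",
    "relax_clamped_kernel",
]


@njit(cache=True)
def thomas_factor(lower, diag, upper):
    """LU factorization of a tridiagonal matrix (Thomas algorithm).

    Returns (w, dp): elimination multipliers and modified diagonal such that
    a solve is one forward and one backward sweep.
    """
    n = diag.shape[0]
    w = np.zeros(n)
    dp = np.zeros(n)
    dp[0] = diag[0]
    for i in range(1, n):
        w[i] = lower[i] / dp[i - 1]
        dp[i] = diag[i] - w[i] * upper[i - 1]
    return w, dp


@njit(cache=True)
def thomas_solve(w, dp, upper, rhs, out):
    """Solve A x = rhs given the factorization from thomas_factor."""
    n = rhs.shape[0]
    out[0] = rhs[0]
    for i in range(1, n):
        out[i] = rhs[i] - w[i] * out[i - 1]
    out[n - 1] = out[n - 1] / dp[n - 1]
    for i in range(n - 2, -1, -1):
        out[i] = (out[i] - upper[i] * out[i + 1]) / dp[i]


@njit(cache=True, fastmath=True)
def run_trial_kernel(
    cap,            # per-node capacitance (nF)
    g_leak,         # per-node leak conductance (uS)
    g_ax,           # axial edge conductances, length n-1 (uS)
    e_leak,         # leak reversal (mV)
    na_node,        # int index of sodium point conductance
    gbar_na,        # peak sodium conductance (uS)
    e_na,           # sodium reversal (mV)
    v_half,         # activation midpoint (mV)
    k_a,            # activation slope (mV)
    tau_m,          # activation time constant (ms)
    inj_node,       # int injection node
    stim,           # injected current per step (nA), length n_steps
    dt,             # time step (ms)
    v0,             # initial voltages, modified in place semantics: copied
    m0,             # initial gating value
    detect_thr,     # detection threshold on V[na_node] (mV); np.inf disables
    reset_thr,      # reset threshold on V[na_node] (mV); np.inf disables
    reset_v,        # voltage all nodes are reset to (mV)
    m_reset,        # gating value after reset
    record_idx,     # int array of node indices to record (may be empty)
    record_stride,  # record every k-th step
):
    """Integrate one trial; returns (spike_times, reset_times, records, v_end, m_end).

    Spike times are detection-threshold upward crossings of the sodium-node
    voltage, linearly interpolated between samples.  On crossing reset_thr the
    whole cell is reset (forced AP termination).
    """
    n = cap.shape[0]
    n_steps = stim.shape[0]

    # constant backward-Euler matrix A0 = C/dt + G (leak + axial)
    lower = np.zeros(n)
    upper = np.zeros(n)
    diag = np.zeros(n)
    for i in range(n):
        diag[i] = cap[i] / dt + g_leak[i]
    for i in range(n - 1):
        diag[i] += g_ax[i]
        diag[i + 1] += g_ax[i]
        upper[i] = -g_ax[i]
        lower[i + 1] = -g_ax[i]
    w, dp = thomas_factor(lower, diag, upper)
    inv_dp = 1.0 / dp

    # Sherman-Morrison column for the sodium node
    e_vec = np.zeros(n)
    e_vec[na_node] = 1.0
    z = np.zeros(n)
    thomas_solve(w, dp, upper, e_vec, z)

    em = np.exp(-dt / tau_m)
    cdt = cap / dt
    gle = g_leak * e_leak

    v = v0.copy()
    m = m0
    f = np.empty(n)
    y = np.empty(n)

    max_spikes = int(n_steps * dt / 2.0) + 16
    spike_times = np.empty(max_spikes)
    reset_times = np.empty(max_spikes)
    n_spikes = 0
    n_resets = 0
    armed = v[na_node] < detect_thr

    n_rec = record_idx.shape[0]
    n_rec_steps = 0
    if n_rec > 0:
        n_rec_steps = n_steps // record_stride + 1
    records = np.zeros((n_rec, n_rec_steps))
    if n_rec > 0:
        for j in range(n_rec):
            records[j, 0] = v[record_idx[j]]

    for k in range(n_steps):
        v_na_old = v[na_node]
        # staggered gating update at pre-step voltage
        m_inf = 1.0 / (1.0 + np.exp((v_half - v_na_old) / k_a))
        m = m_inf + (m - m_inf) * em
        g_na = gbar_na * m

        # fused rhs construction + Thomas forward sweep
        fprev = cdt[0] * v[0] + gle[0]
        if inj_node == 0:
            fprev += stim[k]
        if na_node == 0:
            fprev += g_na * e_na
        f[0] = fprev
        for i in range(1, n):
            r = cdt[i] * v[i] + gle[i]
            if i == inj_node:
                r += stim[k]
            if i == na_node:
                r += g_na * e_na
            fprev = r - w[i] * fprev
            f[i] = fprev
        # backward sweep
        ylast = f[n - 1] * inv_dp[n - 1]
        y[n - 1] = ylast
        for i in range(n - 2, -1, -1):
            ylast = (f[i] - upper[i] * ylast) * inv_dp[i]
            y[i] = ylast
        # Sherman-Morrison correction for the sodium conductance
        corr = g_na * y[na_node] / (1.0 + g_na * z[na_node])
        for i in range(n):
            v[i] = y[i] - corr * z[i]

        t_new = (k + 1) * dt
        v_na_new = v[na_node]

        if armed and v_na_new >= detect_thr and v_na_old < detect_thr:
            frac = (detect_thr - v_na_old) / (v_na_new - v_na_old)
            if n_spikes < max_spikes:
                spike_times[n_spikes] = t_new - dt + frac * dt
                n_spikes += 1
            armed = False
        elif (not armed) and v_na_new < detect_thr:
            armed = True

        if v_na_new >= reset_thr:
            if n_resets < max_spikes:
                reset_times[n_resets] = t_new
                n_resets += 1
            for i in range(n):
                v[i] = reset_v
            m = m_reset
            armed = True

        if n_rec > 0 and (k + 1) % record_stride == 0:
            r = (k + 1) // record_stride
            if r < n_rec_steps:
                for j in range(n_rec):
                    records[j, r] = v[record_idx[j]]

    return spike_times[:n_spikes], reset_times[:n_resets], records, v, m


@njit(cache=True)
def relax_clamped_kernel(
    cap, g_leak, g_ax, e_leak,
    na_node, gbar_na, e_na, v_half, k_a, tau_m,
    clamp_node, clamp_v,
    dt, v0, m0, max_time, dv_tol,
):
    """Relax the cell with one node voltage-clamped until |dV/dt| < dv_tol everywhere.

    Returns (v, m, converged).  The clamp is imposed as a Dirichlet row in the
    implicit matrix.  Used for quasi-static voltage-clamp sweeps.
    """
    n = cap.shape[0]
    lower = np.zeros(n)
    upper = np.zeros(n)
    diag = np.zeros(n)
    for i in range(n):
        diag[i] = cap[i] / dt + g_leak[i]
    for i in range(n - 1):
        diag[i] += g_ax[i]
        diag[i + 1] += g_ax[i]
        upper[i] = -g_ax[i]
        lower[i + 1] = -g_ax[i]
    # Dirichlet row for the clamped node
    diag[clamp_node] = 1.0
    if clamp_node > 0:
        lower[clamp_node] = 0.0
    if clamp_node < n - 1:
        upper[clamp_node] = 0.0
    w, dp = thomas_factor(lower, diag, upper)

    e_vec = np.zeros(n)
    e_vec[na_node] = 1.0
    z = np.zeros(n)
    thomas_solve(w, dp, upper, e_vec, z)

    em = np.exp(-dt / tau_m)
    v = v0.copy()
    v[clamp_node] = clamp_v
    m = m0
    rhs = np.zeros(n)
    y = np.zeros(n)

    n_steps = int(max_time / dt)
    converged = False
    for k in range(n_steps):
        v_na_old = v[na_node]
        m_inf = 1.0 / (1.0 + np.exp((v_half - v_na_old) / k_a))
        m = m_inf + (m - m_inf) * em
        g_na = gbar_na * m

        for i in range(n):
            rhs[i] = cap[i] / dt * v[i] + g_leak[i] * e_leak
        rhs[na_node] += g_na * e_na
        rhs[clamp_node] = clamp_v

        thomas_solve(w, dp, upper, rhs, y)
        corr = g_na * y[na_node] / (1.0 + g_na * z[na_node])
        max_dv = 0.0
        for i in range(n):
            v_new = y[i] - corr * z[i]
            dv = abs(v_new - v[i])
            if dv > max_dv:
                max_dv = dv
            v[i] = v_new
        if max_dv / dt < dv_tol:
            converged = True
            break

    return v, m, converged


@njit(cache=True)
def sta_group_sums(dec, spike_times, trial_ids, group_of_trial, n_groups,
                   dt_sta, half):
    """Sum mean-subtracted current windows around spikes, per trial group.

    dec: (n_trials, n_samples) float32, already mean-subtracted per trial.
    Spikes whose +-half window leaves the trace are excluded.  Returns
    (sums (n_groups, 2*half), counts (n_groups,)); lag 0 sits at index half.
    """
    n_win = 2 * half
    n_samples = dec.shape[1]
    sums = np.zeros((n_groups, n_win))
    counts = np.zeros(n_groups, dtype=np.int64)
    for s in range(spike_times.shape[0]):
        tr = trial_ids[s]
        idx = int(np.floor(spike_times[s] / dt_sta - 0.5 + 0.5))
        if idx - half >= 0 and idx + half <= n_samples:
            g = group_of_trial[tr]
            row = dec[tr]
            for j in range(n_win):
                sums[g, j] += row[idx - half + j]
            counts[g] += 1
    return sums, counts


@njit(cache=True)
def surrogate_stas(dec, spike_times, trial_ids, shifts, burn_in, duration,
                   dt_sta, half):
    """Spike-triggered sums under per-trial cyclic time shifts of the spikes.

    shifts: (n_surrogates, n_trials) in ms; each spike time t becomes
    burn_in + (t - burn_in + shift) mod duration, breaking any input-output
    relation while preserving the spike count and the within-trial structure.
    Returns (stas (n_surrogates, 2*half) sums, counts (n_surrogates,)).
    """
    n_surr = shifts.shape[0]
    n_win = 2 * half
    n_samples = dec.shape[1]
    stas = np.zeros((n_surr, n_win))
    counts = np.zeros(n_surr, dtype=np.int64)
    for q in range(n_surr):
        for s in range(spike_times.shape[0]):
            tr = trial_ids[s]
            t = burn_in + ((spike_times[s] - burn_in + shifts[q, tr]) % duration)
            idx = int(np.floor(t / dt_sta - 0.5 + 0.5))
            if idx - half >= 0 and idx + half <= n_samples:
                row = dec[tr]
                for j in range(n_win):
                    stas[q, j] += row[idx - half + j]
                counts[q] += 1
    return stas, counts
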