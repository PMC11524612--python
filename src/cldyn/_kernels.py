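"""Compiled fixed-step RK4 integration kernel.

The right-hand side is re-stated here in scalar form for numba; it must agree
with :func:`cldyn.model.rhs` exactly (covered by a dedicated test).  The
kernel integrates with a fixed step, detects spikes on the full-resolution
voltage stream (upward threshold crossing with a refractory period), stores a
decimated trace, and aborts with the offending time and state if the state
leaves the model's validity region.
"""

from __future__ import annotations

import numpy as np
from numba import njit

# packed-parameter indices (see ModelParams.pack)
_C, _GNA, _GK, _GNAL, _GKL, _GCLL, _GAMMA, _RHO, _UKCC2, _UNKCC1, _EPSK, \
    _KBATH, _BETA, _EHCO3, _RHCO3, _NERNST, _TAUION, _KTOT, _NAOREF, \
    _NAIREF, _CLOREF, _CLIREF, _GSIGN, _KOSCALE = range(24)

STATUS_OK = 0
STATUS_DOMAIN = 1


@njit(cache=True)
def g_gaba_at(t, stim):
    kind = stim[0]
    if kind == 0.0:
        return 0.0
    if kind == 1.0:  # step
        if stim[2] <= t <= stim[3]:
            return stim[1]
        return 0.0
    # spike train
    A0, tau1, tau2, period, onset, offset, form = (
        stim[4], stim[5], stim[6], stim[7], stim[8], stim[9], stim[10])
    last = t if t < offset else offset
    if last < onset:
        return 0.0
    k_last = int(np.floor((last - onset) / period))
    horizon = 46.0 * max(tau1, tau2)
    k_first = int(np.ceil((t - onset - horizon) / period))
    if k_first < 0:
        k_first = 0
    sign = 1.0 if form == 0.0 else -1.0
    total = 0.0
    for k in range(k_first, k_last + 1):
        dt = t - (onset + k * period)
        if dt < 0.0:
            continue
        total += np.exp(-dt / tau1) + sign * np.exp(-dt / tau2)
    return A0 * total


@njit(cache=True)
def _ratefun(x, scale, width):
    if abs(x) < 1e-6:
        return scale * width * (1.0 + x / (2.0 * width))
    return scale * x / (1.0 - np.exp(-x / width))


@njit(cache=True)
def rhs_packed(t, y, p, stim, out):
    """Scalar restatement of cldyn.model.rhs on packed arrays (7 derivatives, per ms)."""
    V = y[0]
    m = y[1]
    n = y[2]
    h = y[3]
    K_o = y[4]
    Na_i = y[5]
    Cl_i = y[6]

    K_i = p[_KTOT] - Na_i + Cl_i
    Na_o = p[_NAOREF] - p[_BETA] * (Na_i - p[_NAIREF])
    Cl_o = p[_CLOREF] - p[_BETA] * (Cl_i - p[_CLIREF])

    c = p[_NERNST]
    E_Na = c * np.log(Na_o / Na_i)
    E_K = c * np.log(K_o / K_i)
    E_Cl = c * np.log(Cl_i / Cl_o)

    am = _ratefun(V + 54.0, 0.32, 4.0)
    bm = _ratefun(-(V + 27.0), 0.28, 5.0)
    ah = 0.128 * np.exp(-(V + 50.0) / 18.0)
    bh = 4.0 / (1.0 + np.exp(-(V + 27.0) / 5.0))
    an = _ratefun(V + 52.0, 0.032, 5.0)
    bn = 0.5 * np.exp(-(V + 57.0) / 40.0)

    rho_p = p[_RHO] / (1.0 + np.exp((25.0 - Na_i) / 3.0)) / (1.0 + np.exp(3.5 - K_o))
    rho_kcc2 = p[_UKCC2] * np.log((K_i * Cl_i) / (K_o * Cl_o))
    f_Ko = 1.0 / (1.0 + np.exp(16.0 - K_o))
    rho_nkcc1 = p[_UNKCC1] * f_Ko * (
        np.log((K_o * Cl_o) / (K_i * Cl_i)) + np.log((Na_o * Cl_o) / (Na_i * Cl_i)))

    g = g_gaba_at(t, stim)
    I_Na = (p[_GNA] * m ** 3 * h + p[_GNAL]) * (V - E_Na)
    I_K = (p[_GK] * n ** 4 + p[_GKL]) * (V - E_K)
    I_ClL = p[_GCLL] * (V - E_Cl)
    I_gcl = g * (V - E_Cl)
    I_ghco3 = p[_RHCO3] * g * (V - p[_EHCO3])
    I_pump = rho_p / p[_GAMMA]

    I_total = I_Na + I_K + I_ClL + I_pump - p[_GSIGN] * (I_gcl + I_ghco3)
    out[0] = -I_total / p[_C]
    out[1] = am * (1.0 - m) - bm * m
    out[2] = an * (1.0 - n) - bn * n
    out[3] = ah * (1.0 - h) - bh * h
    gam = p[_GAMMA]
    tau = p[_TAUION]
    out[4] = (p[_KOSCALE] * (gam * I_K - 2.0 * rho_p - rho_nkcc1 + rho_kcc2)
              - p[_EPSK] * (K_o - p[_KBATH])) / tau
    out[5] = (-gam * I_Na - 3.0 * rho_p + rho_nkcc1) / tau
    out[6] = (gam * (I_ClL + I_gcl) + 2.0 * rho_nkcc1 - rho_kcc2) / tau


@njit(cache=True)
def _valid(y, p):
    K_o = y[4]
    Na_i = y[5]
    Cl_i = y[6]
    if not (np.isfinite(y[0]) and np.isfinite(K_o) and np.isfinite(Na_i) and np.isfinite(Cl_i)):
        return False
    if K_o <= 0.0 or Na_i <= 0.0 or Cl_i <= 0.0:
        return False
    if p[_KTOT] - Na_i + Cl_i <= 0.0:
        return False
    if p[_NAOREF] - p[_BETA] * (Na_i - p[_NAIREF]) <= 0.0:
        return False
    if p[_CLOREF] - p[_BETA] * (Cl_i - p[_CLIREF]) <= 0.0:
        return False
    return True


@njit(cache=True)
def rk4_integrate(y0, p, stim, t0, t_end, dt, stride, spike_thresh, refractory):
    """Fixed-step RK4 from t0 to t_end.

    Returns (status, t_fail, ts, ys, spike_times) where ts/ys are decimated by
    ``stride`` steps (first and last accepted samples always included) and
    spike_times are full-resolution upward crossings of ``spike_thresh``.
    """
    n_steps = int(np.rint((t_end - t0) / dt))
    n_samples = n_steps // stride + 1
    ts = np.empty(n_samples + 1)
    ys = np.empty((n_samples + 1, 7))
    max_spikes = int((t_end - t0) / refractory) + 2
    spikes = np.empty(max_spikes)
    n_spikes = 0

    y = y0.copy()
    k1 = np.empty(7)
    k2 = np.empty(7)
    k3 = np.empty(7)
    k4 = np.empty(7)
    ytmp = np.empty(7)

    ts[0] = t0
    ys[0] = y
    n_stored = 1
    last_spike = t0 - 2.0 * refractory
    t = t0

    for i in range(n_steps):
        if not _valid(y, p):
            return STATUS_DOMAIN, t, ts[:n_stored], ys[:n_stored], spikes[:n_spikes]
        v_prev = y[0]
        rhs_packed(t, y, p, stim, k1)
        for j in range(7):
            ytmp[j] = y[j] + 0.5 * dt * k1[j]
        rhs_packed(t + 0.5 * dt, ytmp, p, stim, k2)
        for j in range(7):
            ytmp[j] = y[j] + 0.5 * dt * k2[j]
        rhs_packed(t + 0.5 * dt, ytmp, p, stim, k3)
        for j in range(7):
            ytmp[j] = y[j] + dt * k3[j]
        rhs_packed(t + dt, ytmp, p, stim, k4)
        for j in range(7):
            y[j] = y[j] + dt / 6.0 * (k1[j] + 2.0 * k2[j] + 2.0 * k3[j] + k4[j])
        t = t0 + (i + 1) * dt

        if v_prev < spike_thresh <= y[0] and t - last_spike >= refractory:
            if n_spikes < max_spikes:
                spikes[n_spikes] = t
                n_spikes += 1
            last_spike = t

        if (i + 1) % stride == 0 or i == n_steps - 1:
            ts[n_stored] = t
            ys[n_stored] = y
            n_stored += 1

    if not _valid(y, p):
        return STATUS_DOMAIN, t, ts[:n_stored], ys[:n_stored], spikes[:n_spikes]
    return STATUS_OK, t, ts[:n_stored], ys[:n_stored], spikes[:n_spikes]
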