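"""Time integration of the coupled voltage/ion system and trace recording.

The reference integrator is fixed-step RK4 (default dt = 0.02 ms), compiled
with numba; spike detection runs on the undecimated voltage stream inside the
kernel while the stored trace is decimated (default 1 sample/ms).  An adaptive
stiff method (scipy LSODA, rtol 1e-8) is available for cross-checking; the two
must agree (covered by tests).
"""

from __future__ import annotations

import json
import math
from dataclasses import dataclass, field
from typing import Optional

import numpy as np
import pandas as pd

from . import _kernels, model, stimulus as stim_mod
from .model import DomainViolationError, ModelParams, NeuronState, STATE_NAMES
from .stimulus import BathProtocol, Protocol

__all__ = ["Trace", "integrate", "steady_state_of", "SPIKE_THRESHOLD", "REFRACTORY_MS"]

#: Upward crossing of this voltage (mV) counts as a spike; action potentials
#: in this model overshoot 0 mV, so −20 mV is unambiguous.
SPIKE_THRESHOLD = -20.0
#: Minimum separation between detected spikes (ms).
REFRACTORY_MS = 2.0


@dataclass
class Trace:
    """Time-indexed record of an integration.

    ``t`` (ms) and ``states`` (len(t) × 7, columns ordered as
    :data:`cldyn.model.STATE_NAMES`) are decimated; ``spike_times`` were
    detected at full integration resolution.
    """

    t: np.ndarray
    states: np.ndarray
    spike_times: np.ndarray
    params: ModelParams
    protocol: Protocol = None
    metadata: dict = field(default_factory=dict)

    def __post_init__(self):
        if np.any(np.diff(self.t) <= 0):
            raise ValueError("trace times must be strictly increasing")

    def __len__(self) -> int:
        return len(self.t)

    @property
    def V(self) -> np.ndarray:
        return self.states[:, 0]

    def column(self, name: str) -> np.ndarray:
        return self.states[:, STATE_NAMES.index(name)]

    def final_state(self) -> NeuronState:
        return NeuronState.from_array(self.states[-1])

    def g_gaba(self) -> np.ndarray:
        """GABA conductance at each stored sample time."""
        return np.array([stim_mod.conductance(t, self.protocol) for t in self.t])

    def derived_frame(self) -> pd.DataFrame:
        """Reversal potentials and fluxes at each stored sample."""
        g = self.g_gaba()
        rows = [
            model.derived_quantities(NeuronState.from_array(y), self.params, gi)
            for y, gi in zip(self.states, g)
        ]
        return pd.DataFrame([r.__dict__ for r in rows], index=self.t)

    def to_frame(self) -> pd.DataFrame:
        """Tidy per-sample record: state plus reversal potentials."""
        df = pd.DataFrame(self.states, columns=[
            "V_mV", "m", "n", "h", "K_o_mM", "Na_i_mM", "Cl_i_mM"])
        df.insert(0, "t_ms", self.t)
        der = self.derived_frame()
        for col in ("E_Na", "E_K", "E_Cl", "E_GABA"):
            df[col] = der[col].to_numpy()
        return df

    def to_csv(self, path) -> None:
        """Write the tidy trace plus a JSON metadata sidecar header comment."""
        meta = dict(self.metadata)
        meta["params"] = self.params.to_mapping()
        with open(path, "w") as fh:
            fh.write("# " + json.dumps(meta, sort_keys=True) + "\n")
            self.to_frame().to_csv(fh, index=False, float_format="%.17g")

    def window(self, t_from: float, t_to: float = math.inf) -> "Trace":
        """Sub-trace restricted to t ∈ [t_from, t_to]."""
        sel = (self.t >= t_from) & (self.t <= t_to)
        spk = self.spike_times[(self.spike_times >= t_from) & (self.spike_times <= t_to)]
        return Trace(self.t[sel], self.states[sel], spk, self.params,
                     self.protocol, dict(self.metadata))


def _merge_bath(params: ModelParams, bath: Optional[BathProtocol]) -> ModelParams:
    if bath is None:
        return params
    return params.replace(K_bath=bath.K_bath, eps_k=bath.eps_k)


def integrate(initial: NeuronState, params: ModelParams, protocol: Protocol = None,
              bath: Optional[BathProtocol] = None, *, t_end: float, dt: float = 0.02,
              t_start: float = 0.0, method: str = "rk4", sample_dt: float = 1.0,
              spike_threshold: float = SPIKE_THRESHOLD,
              refractory: float = REFRACTORY_MS) -> Trace:
    """Integrate the 7-dimensional system from ``initial`` over [t_start, t_end] ms.

    ``method`` is ``"rk4"`` (fixed-step reference) or ``"adaptive"`` (scipy
    LSODA, rtol 1e-8; spikes are then detected on the dense output at ``dt``
    resolution).  ``sample_dt`` controls trace decimation.  A domain violation
    mid-run raises :class:`DomainViolationError` with the offending time and
    state attached.
    """
    if dt <= 0:
        raise ValueError("dt must be positive")
    if t_end <= t_start:
        raise ValueError("t_end must exceed t_start")
    initial.validate(params)
    params = _merge_bath(params, bath)
    if method == "rk4":
        stride = max(1, int(round(sample_dt / dt)))
        status, t_last, ts, ys, spikes = _kernels.rk4_integrate(
            initial.as_array(), params.pack(), stim_mod.pack_protocol(protocol),
            float(t_start), float(t_end), float(dt), stride,
            float(spike_threshold), float(refractory))
        if status == _kernels.STATUS_DOMAIN:
            raise DomainViolationError(
                f"state left the validity region at t = {t_last:.3f} ms; "
                f"last stored state: {ys[-1].tolist()}")
        meta = {"method": "rk4", "dt_ms": dt, "t_start_ms": t_start, "t_end_ms": t_end}
        return Trace(ts, ys, spikes, params, protocol, meta)
    if method == "adaptive":
        return _integrate_adaptive(initial, params, protocol, t_start, t_end,
                                   dt, sample_dt, spike_threshold, refractory)
    raise ValueError(f"unknown method {method!r}")


def _integrate_adaptive(initial, params, protocol, t_start, t_end, dt,
                        sample_dt, spike_threshold, refractory) -> Trace:
    from scipy.integrate import solve_ivp

    def fun(t, y):
        g = stim_mod.conductance(t, protocol)
        return model.rhs(t, y, params, g)

    t_eval = np.arange(t_start, t_end + 0.5 * dt, dt)
    sol = solve_ivp(fun, (t_start, t_end), initial.as_array(), method="LSODA",
                    rtol=1e-8, atol=[1e-8, 1e-12, 1e-12, 1e-12, 1e-10, 1e-10, 1e-10],
                    t_eval=t_eval, max_step=5.0)
    if not sol.success:
        raise DomainViolationError(f"adaptive integration failed: {sol.message}")
    V = sol.y[0]
    spikes = []
    last = t_start - 2 * refractory
    for i in range(1, len(t_eval)):
        if V[i - 1] < spike_threshold <= V[i] and t_eval[i] - last >= refractory:
            spikes.append(t_eval[i])
            last = t_eval[i]
    stride = max(1, int(round(sample_dt / dt)))
    keep = np.unique(np.r_[np.arange(0, len(t_eval), stride), len(t_eval) - 1])
    meta = {"method": "adaptive", "dt_ms": dt, "t_start_ms": t_start, "t_end_ms": t_end}
    return Trace(t_eval[keep], sol.y.T[keep], np.array(spikes), params, protocol, meta)


def steady_state_of(initial: NeuronState, params: ModelParams, protocol: Protocol = None,
                    bath: Optional[BathProtocol] = None, *,
                    convergence_window: float = 10_000.0, tol: float = 1e-4,
                    t_max: float = 600_000.0, dt: float = 0.02):
    """Integrate until every state variable varies less than ``tol`` over
    ``convergence_window`` ms, or return ``None`` ("non-stationary") at ``t_max``.

    Variation is measured on the stored (1 ms) samples of each successive
    window; a window containing a spike is never accepted as stationary.
    """
    params = _merge_bath(params, bath)
    state = initial
    t = 0.0
    while t < t_max:
        tr = integrate(state, params, protocol, t_start=t,
                       t_end=t + convergence_window, dt=dt)
        span = tr.states.max(axis=0) - tr.states.min(axis=0)
        if len(tr.spike_times) == 0 and np.all(span < tol):
            return tr.final_state()
        state = tr.final_state()
        t += convergence_window
    return None
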