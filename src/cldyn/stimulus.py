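"""GABA conductance protocols and bath-coupling settings, as pure functions of time.

Two protocol shapes are supported: a constant conductance step over a time
window, and a periodic presynaptic spike train where every spike launches a
biexponential conductance kernel.  Spike times are regular (interval
1000/frequency ms) within [onset, offset]; there is no randomness anywhere.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Union

import numpy as np

__all__ = [
    "StepProtocol",
    "SpikeTrainProtocol",
    "BathProtocol",
    "Protocol",
    "step_conductance",
    "spike_train_conductance",
    "conductance",
]

#: Default kernel time constants (ms) and amplitude (mS·cm⁻²).  The amplitude
#: is chosen so a 10 Hz train has a time-averaged conductance of
#: 0.1 mS·cm⁻² with the ``sum`` kernel: A0·(tau1+tau2)/100 ms = 0.1.
DEFAULT_TAU1 = 5.0
DEFAULT_TAU2 = 1.0
DEFAULT_A0 = 5.0 / 3.0


@dataclass(frozen=True)
class StepProtocol:
    """Constant GABA conductance ``G_gaba`` on the window [t0, tn] (ms)."""

    G_gaba: float                 # mS·cm⁻²
    t0: float = 0.0               # ms
    tn: float = math.inf          # ms

    def __post_init__(self):
        if self.G_gaba < 0:
            raise ValueError("G_gaba must be non-negative")
        if self.t0 > self.tn:
            raise ValueError("window start must not exceed window end")


@dataclass(frozen=True)
class SpikeTrainProtocol:
    """Periodic presynaptic spike train; each spike gates on a biexponential kernel.

    ``kernel_form="sum"`` uses A0·[exp(−(t−tᵢ)/τ1) + exp(−(t−tᵢ)/τ2)] for
    t ≥ tᵢ (value 2·A0 at the spike time); ``"difference"`` uses the
    conventional rise–decay synapse A0·[exp(−(t−tᵢ)/τ1) − exp(−(t−tᵢ)/τ2)]
    with τ1 ≥ τ2 (zero at the spike time).  The kernel onset is gated by the
    spike time; contributions from successive spikes add.
    """

    frequency: float              # Hz
    A0: float = DEFAULT_A0        # mS·cm⁻²
    tau1: float = DEFAULT_TAU1    # ms
    tau2: float = DEFAULT_TAU2    # ms
    onset: float = 0.0            # ms
    offset: float = math.inf      # ms
    kernel_form: str = "sum"      # "sum" | "difference"

    def __post_init__(self):
        if self.frequency <= 0:
            raise ValueError("frequency must be positive")
        if self.tau1 <= 0 or self.tau2 <= 0:
            raise ValueError("time constants must be positive")
        if self.A0 < 0:
            raise ValueError("A0 must be non-negative")
        if self.kernel_form not in ("sum", "difference"):
            raise ValueError("kernel_form must be 'sum' or 'difference'")
        if self.kernel_form == "difference" and self.tau1 < self.tau2:
            raise ValueError("difference kernel requires tau1 >= tau2")

    @property
    def period(self) -> float:
        """Inter-spike interval in ms."""
        return 1000.0 / self.frequency

    def spike_times(self, t_end: float) -> np.ndarray:
        """Deterministic spike times within [onset, min(offset, t_end)]."""
        stop = min(self.offset, t_end)
        if stop < self.onset:
            return np.empty(0)
        k = int(math.floor((stop - self.onset) / self.period)) + 1
        return self.onset + self.period * np.arange(k)


@dataclass(frozen=True)
class BathProtocol:
    """Extracellular-potassium coupling to a fixed bath reservoir."""

    K_bath: float = 3.0           # mM
    eps_k: float = 0.25           # s⁻¹

    def __post_init__(self):
        if self.K_bath < 0 or self.eps_k < 0:
            raise ValueError("K_bath and eps_k must be non-negative")


Protocol = Union[StepProtocol, SpikeTrainProtocol, None]


def step_conductance(t: float, protocol: StepProtocol) -> float:
    """g_GABA(t) for a step protocol: G_gaba inside [t0, tn], zero outside."""
    return protocol.G_gaba if protocol.t0 <= t <= protocol.tn else 0.0


def spike_train_conductance(t: float, protocol: SpikeTrainProtocol) -> float:
    """g_GABA(t) for a spike-train protocol (causal, additive over spikes)."""
    p = protocol
    last = min(t, p.offset)
    if last < p.onset:
        return 0.0
    k_last = int(math.floor((last - p.onset) / p.period))
    # Kernels older than ~46 decay constants are numerically zero.
    horizon = 46.0 * max(p.tau1, p.tau2)
    k_first = max(0, int(math.ceil((t - p.onset - horizon) / p.period)))
    total = 0.0
    sign = 1.0 if p.kernel_form == "sum" else -1.0
    for k in range(k_first, k_last + 1):
        dt = t - (p.onset + k * p.period)
        if dt < 0.0:
            continue
        total += math.exp(-dt / p.tau1) + sign * math.exp(-dt / p.tau2)
    return p.A0 * total


def conductance(t: float, protocol: Protocol) -> float:
    """Evaluate any protocol (or None) at time t (ms)."""
    if protocol is None:
        return 0.0
    if isinstance(protocol, StepProtocol):
        return step_conductance(t, protocol)
    if isinstance(protocol, SpikeTrainProtocol):
        return spike_train_conductance(t, protocol)
    raise TypeError(f"unknown protocol type: {type(protocol)!r}")


def pack_protocol(protocol: Protocol) -> np.ndarray:
    """Encode a protocol as a flat float vector for the compiled kernels.

    Layout: [kind, G, t0, tn, A0, tau1, tau2, period, onset, offset, form]
    with kind 0 = none, 1 = step, 2 = train and form 0 = sum, 1 = difference.
    """
    v = np.zeros(11)
    if protocol is None:
        return v
    if isinstance(protocol, StepProtocol):
        v[0] = 1.0
        v[1] = protocol.G_gaba
        v[2] = protocol.t0
        v[3] = protocol.tn
        return v
    if isinstance(protocol, SpikeTrainProtocol):
        v[0] = 2.0
        v[4] = protocol.A0
        v[5] = protocol.tau1
        v[6] = protocol.tau2
        v[7] = protocol.period
        v[8] = protocol.onset
        v[9] = protocol.offset
        v[10] = 0.0 if protocol.kernel_form == "sum" else 1.0
        return v
    raise TypeError(f"unknown protocol type: {type(protocol)!r}")
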