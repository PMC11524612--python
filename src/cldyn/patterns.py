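"""Spike detection, firing-pattern classification and transition searches.

The vocabulary follows the model's phenomenology along rising [Cl⁻]ᵢ:
resting → periodic bursting → tonic ("intensive") firing → bursting
interrupted by depolarization block (DB) → stable DB.  Classification is
rule-based and deterministic:

* spike: upward crossing of −20 mV with a 2 ms refractory period;
* DB window: 2 s of mean V above −50 mV containing no spikes;
* stable DB: the DB criterion holds over the final 20 s;
* burst segmentation: inter-spike intervals exceeding 5× the within-burst
  median ISI split bursts; tonic firing has no DB windows and ISI
  coefficient of variation below 0.5;
* subthreshold oscillation: no spikes but peak-to-peak V above 1 mV.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from typing import Callable, Optional, Sequence

import numpy as np

from .simulate import Trace

__all__ = [
    "FiringPattern", "detect_spikes", "classify", "find_transition",
    "SPIKE_THRESHOLD", "DB_MEAN_V", "DB_WINDOW_MS", "STABLE_DB_TAIL_MS",
]

SPIKE_THRESHOLD = -20.0       # mV, upward crossing
REFRACTORY_MS = 2.0
DB_MEAN_V = -50.0             # mV, depolarized-plateau criterion
DB_WINDOW_MS = 2000.0
STABLE_DB_TAIL_MS = 20_000.0
ISI_CV_TONIC = 0.5
ISI_BURST_FACTOR = 5.0
SUBTHRESHOLD_P2P_MV = 1.0
MIN_BURST_WINDOW_MS = 60_000.0

LABELS = ("resting", "subthreshold_oscillation", "tonic_firing",
          "periodic_bursting", "bursting_with_DB", "stable_DB")


@dataclass
class FiringPattern:
    """Classification result for one analysis window."""

    label: str
    spike_times: np.ndarray
    burst_boundaries: list[tuple[float, float]] = field(default_factory=list)
    db_intervals: list[tuple[float, float]] = field(default_factory=list)
    low_confidence: bool = False

    @property
    def n_spikes(self) -> int:
        return len(self.spike_times)

    @property
    def n_bursts(self) -> int:
        return len(self.burst_boundaries)

    def db_occupancy(self, window: tuple[float, float]) -> float:
        total = window[1] - window[0]
        if total <= 0:
            return 0.0
        return sum(b - a for a, b in self.db_intervals) / total

    def report(self, window: tuple[float, float]) -> dict:
        return {
            "label": self.label,
            "spike_count": int(self.n_spikes),
            "burst_count": int(self.n_bursts),
            "db_occupancy": self.db_occupancy(window),
            "low_confidence": bool(self.low_confidence),
        }

    def report_json(self, window: tuple[float, float]) -> str:
        return json.dumps(self.report(window), indent=2)


def detect_spikes(trace: Trace, threshold: float = SPIKE_THRESHOLD,
                  refractory: float = REFRACTORY_MS) -> np.ndarray:
    """Spike times (ms): upward threshold crossings with refractory separation.

    Integrations record spikes at full step resolution inside the solver;
    those are used directly when the trace's threshold settings match the
    defaults.  Otherwise crossings are recomputed from the stored samples.
    """
    if (threshold == SPIKE_THRESHOLD and refractory == REFRACTORY_MS
            and trace.spike_times is not None and len(trace.spike_times) >= 0
            and trace.metadata.get("method") in ("rk4", "adaptive")):
        return np.asarray(trace.spike_times)
    V = trace.V
    t = trace.t
    up = np.flatnonzero((V[:-1] < threshold) & (V[1:] >= threshold)) + 1
    out = []
    last = -np.inf
    for i in up:
        if t[i] - last >= refractory:
            out.append(t[i])
            last = t[i]
    return np.array(out)


def _db_intervals(trace: Trace, spikes: np.ndarray) -> list[tuple[float, float]]:
    """Maximal intervals where every 2 s window has mean V > −50 and no spikes."""
    t = trace.t
    V = trace.V
    if t[-1] - t[0] < DB_WINDOW_MS:
        return []
    step = DB_WINDOW_MS / 4.0
    starts = np.arange(t[0], t[-1] - DB_WINDOW_MS + 1e-9, step)
    flags = []
    for s in starts:
        sel = (t >= s) & (t <= s + DB_WINDOW_MS)
        in_db = (V[sel].mean() > DB_MEAN_V
                 and not np.any((spikes >= s) & (spikes <= s + DB_WINDOW_MS)))
        flags.append(in_db)
    intervals = []
    cur = None
    for s, f in zip(starts, flags):
        if f and cur is None:
            cur = s
        elif not f and cur is not None:
            intervals.append((cur, s + DB_WINDOW_MS - step))
            cur = None
    if cur is not None:
        intervals.append((cur, t[-1]))
    return intervals


def _burst_boundaries(spikes: np.ndarray) -> tuple[list[tuple[float, float]], float]:
    """Split spikes into bursts by the ISI rule; returns (bursts, isi_cv)."""
    if len(spikes) < 2:
        return ([(spikes[0], spikes[0])] if len(spikes) else []), 0.0
    isi = np.diff(spikes)
    cv = float(isi.std() / isi.mean()) if isi.mean() > 0 else 0.0
    base = np.median(isi)
    within = isi[isi <= ISI_BURST_FACTOR * base]
    thr = ISI_BURST_FACTOR * (np.median(within) if len(within) else base)
    bursts = []
    start = spikes[0]
    for k, gap in enumerate(isi):
        if gap > thr:
            bursts.append((start, spikes[k]))
            start = spikes[k + 1]
    bursts.append((start, spikes[-1]))
    return bursts, cv


def classify(trace: Trace, window: Optional[tuple[float, float]] = None) -> FiringPattern:
    """Assign a firing-pattern label to the trace over ``window`` (ms).

    Burst-class labels are only confident on windows of at least 60 s
    (long-period bursting near the DB boundary); shorter windows set the
    ``low_confidence`` flag rather than failing.
    """
    if window is None:
        window = (float(trace.t[0]), float(trace.t[-1]))
    sub = trace.window(*window)
    spikes = detect_spikes(sub)
    span = window[1] - window[0]

    tail = sub.window(max(window[0], window[1] - STABLE_DB_TAIL_MS))
    tail_spikes = spikes[spikes >= tail.t[0]]
    tail_db = (len(tail_spikes) == 0 and tail.V.mean() > DB_MEAN_V
               and tail.t[-1] - tail.t[0] >= STABLE_DB_TAIL_MS - 1.0)

    db = _db_intervals(sub, spikes)
    low_conf = span < MIN_BURST_WINDOW_MS

    if len(spikes) == 0:
        if tail_db:
            return FiringPattern("stable_DB", spikes, [], db, low_conf)
        half = sub.window(window[0] + span / 2.0)
        p2p = float(half.V.max() - half.V.min())
        if p2p > SUBTHRESHOLD_P2P_MV:
            return FiringPattern("subthreshold_oscillation", spikes, [], db, low_conf)
        return FiringPattern("resting", spikes, [], db, False)

    bursts, cv = _burst_boundaries(spikes)
    if tail_db:
        return FiringPattern("stable_DB", spikes, bursts, db, low_conf)
    if db:
        return FiringPattern("bursting_with_DB", spikes, bursts, db, low_conf)
    if cv < ISI_CV_TONIC and len(spikes) >= 10:
        return FiringPattern("tonic_firing", spikes, bursts, [], low_conf)
    return FiringPattern("periodic_bursting", spikes, bursts, [], low_conf)


def find_transition(predicate: Callable[[float], bool],
                    bracket: tuple[float, float], tol: float, *,
                    max_expand: int = 8) -> float:
    """Bisect for the boundary of a monotone predicate over a scalar.

    ``predicate`` must differ between the two bracket endpoints; if it does
    not, the bracket is expanded geometrically outward (up to ``max_expand``
    times) before raising.  Returns the midpoint of the final bracket of
    width < ``tol``.
    """
    lo, hi = float(bracket[0]), float(bracket[1])
    if lo >= hi:
        raise ValueError("bracket must satisfy lo < hi")
    p_lo, p_hi = predicate(lo), predicate(hi)
    width = hi - lo
    n = 0
    while p_lo == p_hi and n < max_expand:
        n += 1
        if not p_hi:
            hi += width
            p_hi = predicate(hi)
        else:
            lo = max(1e-9, lo - width)
            p_lo = predicate(lo)
    if p_lo == p_hi:
        raise ValueError("predicate equal at both bracket endpoints")
    while hi - lo > tol:
        mid = 0.5 * (lo + hi)
        if predicate(mid) == p_hi:
            hi = mid
        else:
            lo = mid
    return 0.5 * (lo + hi)
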