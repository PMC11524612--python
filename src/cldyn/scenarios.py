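"""Scenario presets, YAML (de)serialization, and result bundles.

A :class:`Scenario` is a complete, declarative description of one numerical
experiment: initial state (gating auto-completed, or a stationary point
computed on the fly), parameter overrides, stimulation and bath protocols,
duration, and which analyses to run.  The bundled presets encode the
stimulation protocols of the study's figure panels; spike-train presets
carry an ``amplitude_unpublished`` annotation because the source reports
neither the kernel amplitude nor its time constants.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, asdict
from typing import Optional

import numpy as np
import yaml

from . import bifurcation, patterns, simulate
from .model import ModelParams, NeuronState
from .stimulus import BathProtocol, SpikeTrainProtocol, StepProtocol

__all__ = ["Scenario", "ScenarioError", "run_scenario", "grid_scan",
           "PRESETS", "get_preset"]

SCHEMA_VERSION = 1


class ScenarioError(ValueError):
    """Scenario failed schema validation; message carries the field path."""


@dataclass
class Scenario:
    name: str
    initial: dict                       # explicit state or fixed-point request
    t_end_ms: float
    params: dict = field(default_factory=dict)
    stimulus: Optional[dict] = None     # {"type": "step"|"train", ...}
    bath: Optional[dict] = None         # {"K_bath": .., "eps_k": ..}
    dt_ms: float = 0.02
    analyses: tuple = ("classify",)
    branch: Optional[dict] = None       # {"parameter", "lo", "hi", ...}
    notes: dict = field(default_factory=dict)
    schema_version: int = SCHEMA_VERSION

    # -- validation / construction -----------------------------------------

    def validate(self) -> None:
        if self.t_end_ms <= 0:
            raise ScenarioError("t_end_ms: must be positive")
        if self.dt_ms <= 0:
            raise ScenarioError("dt_ms: must be positive")
        mode = self.initial.get("type", "explicit")
        if mode == "explicit":
            missing = {"V", "K_o", "Na_i", "Cl_i"} - set(self.initial)
            if missing:
                raise ScenarioError(f"initial: missing fields {sorted(missing)}")
        elif mode == "fixed_point":
            pass
        else:
            raise ScenarioError(f"initial.type: unknown mode {mode!r}")
        if self.stimulus is not None:
            kind = self.stimulus.get("type")
            if kind not in ("step", "train"):
                raise ScenarioError(f"stimulus.type: must be 'step' or 'train', got {kind!r}")
            if kind == "train":
                for key in ("frequency", "A0", "tau1", "tau2"):
                    if key not in self.stimulus:
                        raise ScenarioError(f"stimulus.{key}: required for spike trains")
        for a in self.analyses:
            if a not in ("classify", "branch", "none"):
                raise ScenarioError(f"analyses: unknown analysis {a!r}")
        if "branch" in self.analyses and not self.branch:
            raise ScenarioError("branch: analysis requested but no branch block given")

    def build_params(self) -> ModelParams:
        p = ModelParams.from_mapping(self.params) if self.params else ModelParams()
        if self.bath is not None:
            p = p.replace(K_bath=self.bath.get("K_bath", p.K_bath),
                          eps_k=self.bath.get("eps_k", p.eps_k))
        return p

    def build_initial(self, params: ModelParams) -> NeuronState:
        mode = self.initial.get("type", "explicit")
        if mode == "fixed_point":
            clamp = self.initial.get("clamp")
            guess = self.initial.get(
                "guess", {"V": -65.0, "K_o": 3.5, "Na_i": 19.0, "Cl_i": 7.0})
            gs = NeuronState.with_steady_gating(**guess)
            p0 = params if self.initial.get("with_bath", True) else params.replace(eps_k=0.0)
            fp = bifurcation.find_fixed_point(
                gs, p0, clamp=None if clamp is None else (clamp["name"], clamp["value"]),
                g_gaba=self.initial.get("g_gaba", 0.0))
            return fp.state
        init = {k: self.initial[k] for k in ("V", "K_o", "Na_i", "Cl_i")}
        if all(k in self.initial for k in ("m", "n", "h")):
            return NeuronState(V=init["V"], m=self.initial["m"], n=self.initial["n"],
                               h=self.initial["h"], K_o=init["K_o"],
                               Na_i=init["Na_i"], Cl_i=init["Cl_i"])
        return NeuronState.with_steady_gating(**init)

    def build_protocol(self):
        if self.stimulus is None:
            return None
        s = dict(self.stimulus)
        kind = s.pop("type")
        if kind == "step":
            return StepProtocol(G_gaba=s["G_gaba"], t0=s.get("t0", 0.0),
                                tn=s.get("tn", math.inf))
        return SpikeTrainProtocol(
            frequency=s["frequency"], A0=s["A0"], tau1=s["tau1"], tau2=s["tau2"],
            onset=s.get("onset", 0.0), offset=s.get("offset", math.inf),
            kernel_form=s.get("kernel_form", "sum"))

    # -- serialization ------------------------------------------------------

    def to_mapping(self) -> dict:
        d = asdict(self)
        d["analyses"] = list(self.analyses)
        return d

    @classmethod
    def from_mapping(cls, d: dict) -> "Scenario":
        d = dict(d)
        d["analyses"] = tuple(d.get("analyses", ("classify",)))
        sc = cls(**d)
        sc.validate()
        return sc

    def to_yaml(self) -> str:
        return yaml.safe_dump(self.to_mapping(), sort_keys=True)

    @classmethod
    def from_yaml(cls, text: str) -> "Scenario":
        return cls.from_mapping(yaml.safe_load(text))


def run_scenario(scenario: Scenario, *, sample_dt: float = 1.0) -> dict:
    """Execute a scenario: integrate, classify, and/or continue a branch.

    Returns a bundle dict with keys among ``trace``, ``pattern``, ``branch``,
    ``summary``; fully deterministic (the model has no randomness).
    """
    scenario.validate()
    params = scenario.build_params()
    bundle: dict = {"name": scenario.name, "summary": {}}

    if "branch" in scenario.analyses:
        b = scenario.branch
        guess_map = b.get("guess", {"V": -76.0, "K_o": 2.4, "Na_i": 21.7, "Cl_i": b["lo"]})
        guess = NeuronState.with_steady_gating(**guess_map)
        br = bifurcation.continue_branch(
            b["parameter"], (b["lo"], b["hi"]), guess, params,
            g_gaba=b.get("g_gaba", 0.0), step0=b.get("step0", 0.1),
            direction=b.get("direction", 1.0))
        bundle["branch"] = br
        bundle["summary"].update(bifurcation.export_summary_json(br))

    if scenario.analyses != ("branch",):
        initial = scenario.build_initial(params)
        protocol = scenario.build_protocol()
        trace = simulate.integrate(initial, params, protocol,
                                   t_end=scenario.t_end_ms, dt=scenario.dt_ms,
                                   sample_dt=sample_dt)
        bundle["trace"] = trace
        if "classify" in scenario.analyses:
            pat = patterns.classify(trace)
            bundle["pattern"] = pat
            bundle["summary"].update(pat.report((trace.t[0], trace.t[-1])))
            bundle["summary"]["final_Cl_i"] = float(trace.column("Cl_i")[-1])
            bundle["summary"]["final_V"] = float(trace.V[-1])
    return bundle


def _set_path(d: dict, path: str, value) -> None:
    keys = path.split(".")
    cur = d
    for k in keys[:-1]:
        if cur.get(k) is None:
            cur[k] = {}
        cur = cur[k]
    cur[keys[-1]] = value


def grid_scan(template: Scenario, axis1: tuple[str, list], axis2: tuple[str, list],
              *, sample_dt: float = 1.0):
    """Run the scenario over a 2-axis grid; returns a tidy DataFrame.

    Axis names are dotted paths into the scenario mapping, e.g.
    ``"stimulus.frequency"`` or ``"bath.eps_k"``.  A 1×1 grid is identical to
    a single :func:`run_scenario` call.
    """
    import pandas as pd

    rows = []
    for v1 in axis1[1]:
        for v2 in axis2[1]:
            d = template.to_mapping()
            _set_path(d, axis1[0], v1)
            _set_path(d, axis2[0], v2)
            d["name"] = f"{template.name}[{axis1[0]}={v1},{axis2[0]}={v2}]"
            sc = Scenario.from_mapping(d)
            bundle = run_scenario(sc, sample_dt=sample_dt)
            row = {axis1[0]: v1, axis2[0]: v2}
            row.update(bundle["summary"])
            rows.append(row)
    return pd.DataFrame(rows)


# ---------------------------------------------------------------------------
# Figure-panel presets
# ---------------------------------------------------------------------------

#: Initial conditions of the intrinsic-dynamics sweep: start from the resting
#: voltage with [Na⁺]ᵢ = 20.06 and [K⁺]ₒ = 2.99 held, varying only [Cl⁻]ᵢ.
_SWEEP_INITIAL = {"V": -70.74, "K_o": 2.99, "Na_i": 20.06}
_SWEEP_CL = {"fig1d": 5.97, "fig1e": 9.88, "fig1f": 10.23,
             "fig1g": 10.93, "fig1h": 11.99, "fig1i": 12.5}

_TRAIN_DEFAULTS = {"A0": 5.0 / 3.0, "tau1": 5.0, "tau2": 1.0}
_UNPUBLISHED = {"amplitude_unpublished": True,
                "note": "spike-train kernel amplitude/time constants are not "
                        "reported in the source; package defaults are used, so "
                        "event timings are qualitative"}


def _conservative(cl0: float, name: str, t_end: float = 300_000.0) -> Scenario:
    return Scenario(
        name=name,
        initial={**_SWEEP_INITIAL, "Cl_i": cl0},
        params={"eps_k": 0.0},
        t_end_ms=t_end,
    )


def _build_presets() -> dict:
    presets: dict[str, Scenario] = {}
    # Fig 1B: fixed-point branch in [Cl-]i, no diffusion, no GABA
    presets["fig1b"] = Scenario(
        name="fig1b", initial={**_SWEEP_INITIAL, "Cl_i": 5.0},
        params={"eps_k": 0.0}, t_end_ms=1.0, analyses=("branch",),
        branch={"parameter": "Cl_i", "lo": 5.0, "hi": 20.0},
    )
    for name, cl0 in _SWEEP_CL.items():
        presets[name] = _conservative(cl0, name)
    # Fig 2A/B: pure-chloride GABA (no HCO3) fixed-point branches
    for g in (0.0, 0.1, 0.4):
        presets[f"fig2a_g{g:g}"] = Scenario(
            name=f"fig2a_g{g:g}", initial={**_SWEEP_INITIAL, "Cl_i": 5.0},
            params={"eps_k": 0.0, "r_hco3": 0.0}, t_end_ms=1.0,
            analyses=("branch",),
            branch={"parameter": "Cl_i", "lo": 5.0, "hi": 20.0, "g_gaba": g},
        )
    # Fig 2D/F: pure-chloride GABA spike trains hyperpolarize a resting neuron
    for name, freq in (("fig2d", 25.0), ("fig2f", 80.0)):
        presets[name] = Scenario(
            name=name, initial={**_SWEEP_INITIAL, "Cl_i": 5.97},
            params={"eps_k": 0.0, "r_hco3": 0.0},
            stimulus={"type": "train", "frequency": freq, **_TRAIN_DEFAULTS,
                      "onset": 500.0},
            t_end_ms=120_000.0, notes=dict(_UNPUBLISHED),
        )
    # Fig 3: 10 Hz train with HCO3 efflux drives rest -> SLE -> stable DB
    presets["fig3"] = Scenario(
        name="fig3", initial={**_SWEEP_INITIAL, "Cl_i": 5.97},
        params={"eps_k": 0.0, "r_hco3": 0.2},
        stimulus={"type": "train", "frequency": 10.0, **_TRAIN_DEFAULTS,
                  "onset": 100_000.0},
        t_end_ms=700_000.0, notes=dict(_UNPUBLISHED),
    )
    # Fig 4: DB neuron connected to a low-K bath relaxes to rest
    for name, eps in (("fig4a", 0.0025), ("fig4f1", 0.025), ("fig4f2", 0.25)):
        presets[name] = Scenario(
            name=name,
            initial={"type": "fixed_point", "with_bath": False,
                     "clamp": {"name": "Cl_i", "value": 18.75},
                     "guess": {"V": -35.0, "K_o": 16.5, "Na_i": 27.6, "Cl_i": 18.75}},
            params={"eps_k": eps, "K_bath": 3.0},
            t_end_ms=200_000.0,
        )
    # Fig 6: GABA trains with HCO3 under bath coupling (frequency x eps grid)
    presets["fig6"] = Scenario(
        name="fig6",
        initial={"type": "fixed_point",
                 "guess": {"V": -71.0, "K_o": 3.0, "Na_i": 20.0, "Cl_i": 5.9}},
        params={"r_hco3": 0.2}, bath={"K_bath": 3.0, "eps_k": 0.25},
        stimulus={"type": "train", "frequency": 10.0, **_TRAIN_DEFAULTS},
        t_end_ms=300_000.0, notes=dict(_UNPUBLISHED),
    )
    # Fig 8: steady states vs GABA step conductance under bath coupling
    for name, eps in (("fig8_eps0.25", 0.25), ("fig8_eps0.025", 0.025),
                      ("fig8_eps0.0025", 0.0025)):
        presets[name] = Scenario(
            name=name,
            initial={"type": "fixed_point",
                     "guess": {"V": -71.0, "K_o": 3.0, "Na_i": 20.0, "Cl_i": 5.9}},
            params={"r_hco3": 0.2}, bath={"K_bath": 3.0, "eps_k": eps},
            t_end_ms=1.0, analyses=("branch",),
            branch={"parameter": "g_gaba", "lo": 0.0, "hi": 4.0, "step0": 0.05,
                    "guess": {"V": -71.0, "K_o": 3.0, "Na_i": 20.0, "Cl_i": 5.9}},
        )
    # Fig 8 D/G/H/I: firing patterns at selected step conductances
    for g in (0.24, 0.33, 2.07):
        presets[f"fig8_step{g:g}"] = Scenario(
            name=f"fig8_step{g:g}",
            initial={"type": "fixed_point",
                     "guess": {"V": -71.0, "K_o": 3.0, "Na_i": 20.0, "Cl_i": 5.9}},
            params={"r_hco3": 0.2}, bath={"K_bath": 3.0, "eps_k": 0.25},
            stimulus={"type": "step", "G_gaba": g, "t0": 10_000.0},
            t_end_ms=300_000.0,
        )
    # Fig 9: rebound after train offset, K_bath=3, eps=0.025
    for freq in (10.0, 40.0, 80.0):
        presets[f"fig9_{freq:g}hz"] = Scenario(
            name=f"fig9_{freq:g}hz",
            initial={"type": "fixed_point",
                     "guess": {"V": -71.0, "K_o": 3.0, "Na_i": 20.0, "Cl_i": 5.9}},
            params={"r_hco3": 0.2}, bath={"K_bath": 3.0, "eps_k": 0.025},
            stimulus={"type": "train", "frequency": freq, **_TRAIN_DEFAULTS,
                      "onset": 100_000.0, "offset": 600_000.0},
            t_end_ms=800_000.0, notes=dict(_UNPUBLISHED),
        )
    for sc in presets.values():
        sc.validate()
    return presets


PRESETS = _build_presets()


def get_preset(name: str) -> Scenario:
    try:
        return Scenario.from_mapping(PRESETS[name].to_mapping())
    except KeyError:
        raise KeyError(f"unknown preset {name!r}; available: {sorted(PRESETS)}") from None
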