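"""Single-compartment neuron model with coupled voltage and ion-concentration dynamics.

The membrane potential follows Hodgkin–Huxley-style kinetics (transient Na⁺,
delayed-rectifier K⁺, three leak currents, an electrogenic Na⁺/K⁺ pump and a
GABA_A conductance carrying both Cl⁻ and HCO₃⁻), while the extracellular
potassium [K⁺]ₒ, intracellular sodium [Na⁺]ᵢ and intracellular chloride [Cl⁻]ᵢ
evolve in response to the transmembrane currents, the pump, the KCC2 and NKCC1
cotransporters, and first-order exchange of [K⁺]ₒ with a bath reservoir.
Reversal potentials are recomputed from the instantaneous concentrations via
the Nernst equation; the remaining concentrations ([K⁺]ᵢ, [Na⁺]ₒ, [Cl⁻]ₒ) are
closed algebraically by electroneutrality.

Units contract: V in mV, t in ms, concentrations in mM, conductances in
mS·cm⁻², currents in µA·cm⁻², transport fluxes in mM·s⁻¹.  Ion equations are
scaled by ``tau_ion`` (default 1000) so that concentrations evolve on a
seconds timescale while the voltage evolves on milliseconds.

Everything here is a pure, stateless evaluation; integration lives in
:mod:`cldyn.simulate` and stationary analysis in :mod:`cldyn.bifurcation`.
"""

from __future__ import annotations

import dataclasses
import math
from dataclasses import dataclass
from typing import Mapping

import numpy as np

__all__ = [
    "DomainViolationError",
    "NeuronState",
    "ModelParams",
    "DerivedQuantities",
    "gating_rates",
    "steady_gating",
    "closures",
    "reversal_potentials",
    "gaba_reversal",
    "pump_rate",
    "cotransporter_fluxes",
    "derived_quantities",
    "rhs",
    "flux_charge_residual",
    "STATE_NAMES",
]

#: Order of the dynamical state vector used throughout the package.
STATE_NAMES = ("V", "m", "n", "h", "K_o", "Na_i", "Cl_i")


class DomainViolationError(ValueError):
    """The state left the model's validity region (a concentration became ≤ 0)."""


@dataclass(frozen=True)
class NeuronState:
    """The 7-dimensional dynamical state (V, m, n, h, [K⁺]ₒ, [Na⁺]ᵢ, [Cl⁻]ᵢ)."""

    V: float        # membrane potential, mV
    m: float        # Na⁺ activation gate
    n: float        # K⁺ activation gate
    h: float        # Na⁺ inactivation gate
    K_o: float      # extracellular potassium, mM
    Na_i: float     # intracellular sodium, mM
    Cl_i: float     # intracellular chloride, mM

    def as_array(self) -> np.ndarray:
        return np.array([self.V, self.m, self.n, self.h, self.K_o, self.Na_i, self.Cl_i])

    @classmethod
    def from_array(cls, y: np.ndarray) -> "NeuronState":
        return cls(*(float(v) for v in y))

    @classmethod
    def with_steady_gating(cls, V: float, K_o: float, Na_i: float, Cl_i: float) -> "NeuronState":
        """State with m, n, h set to their voltage steady-state values at ``V``."""
        m, n, h = steady_gating(V)
        return cls(V=V, m=m, n=n, h=h, K_o=K_o, Na_i=Na_i, Cl_i=Cl_i)

    def validate(self, params: "ModelParams") -> None:
        for g in (self.m, self.n, self.h):
            if not -1e-9 <= g <= 1 + 1e-9:
                raise DomainViolationError(f"gating variable outside [0, 1]: {g!r}")
        closures(self.Na_i, self.Cl_i, params)
        if self.K_o <= 0:
            raise DomainViolationError(f"K_o must be positive, got {self.K_o!r}")


@dataclass(frozen=True)
class ModelParams:
    """Constant parameters of the single-compartment model.

    Defaults are the reference parameter set of the model (bundled as
    ``data/table1.yaml``) plus the GABA_A bicarbonate settings and the
    electroneutrality closure constants.
    """

    C: float = 1.0            # membrane capacitance, µF·cm⁻²
    gNa: float = 30.0         # maximal Na⁺ conductance, mS·cm⁻²
    gK: float = 20.0          # maximal K⁺ conductance, mS·cm⁻²
    gNaL: float = 0.04        # Na⁺ leak conductance, mS·cm⁻²
    gKL: float = 0.1          # K⁺ leak conductance, mS·cm⁻²
    gClL: float = 0.1         # Cl⁻ leak conductance, mS·cm⁻²
    gamma: float = 0.03       # current→flux conversion S/(F·vᵢ), mM·cm²·s⁻¹·µA⁻¹
    rho: float = 0.8          # maximal Na⁺/K⁺ pump rate, mM·s⁻¹
    U_kcc2: float = 0.3       # KCC2 cotransporter strength, mM·s⁻¹
    U_nkcc1: float = 0.1      # NKCC1 cotransporter strength, mM·s⁻¹
    eps_k: float = 0.25       # bath potassium exchange rate, s⁻¹
    K_bath: float = 3.0       # bath potassium concentration, mM
    beta: float = 7.0         # intra-/extracellular volume ratio
    E_hco3: float = -13.0     # bicarbonate reversal potential, mV (held fixed)
    r_hco3: float = 0.2       # HCO₃⁻/Cl⁻ conductance ratio of the GABA_A receptor
    nernst_coef: float = 26.64  # RT/F at 310 K, mV
    tau_ion: float = 1000.0   # slow-timescale factor for the ion equations (ms per s)
    # Electroneutrality closure constants (mM):
    k_total: float = 100.0    # [K⁺]ᵢ = k_total − [Na⁺]ᵢ + [Cl⁻]ᵢ
    na_o_ref: float = 135.0   # [Na⁺]ₒ = na_o_ref − β([Na⁺]ᵢ − na_i_ref)
    na_i_ref: float = 20.0
    cl_o_ref: float = 145.0   # [Cl⁻]ₒ = cl_o_ref − β([Cl⁻]ᵢ − cl_i_ref)
    cl_i_ref: float = 6.0
    #: Restore the literal printed sign convention of the GABA terms in the
    #: voltage equation (+g(V−E) instead of −g(V−E)).  Off by default; the
    #: negative convention matches every other current and makes GABA
    #: inhibitory below the crossover voltage.
    literal_gaba_sign: bool = False
    #: Scale the transmembrane flux terms of d[K⁺]ₒ/dt by β.  The extracellular
    #: space holds 1/β of the intracellular volume, so a membrane flux that
    #: changes an intracellular concentration at rate r changes [K⁺]ₒ at rate
    #: β·r.  On by default; set False for the unscaled variant.  The scaling
    #: leaves every equilibrium with eps_k = 0 unchanged (it multiplies a flux
    #: that vanishes there) but matters for dynamics and for bath-coupled
    #: steady states.
    ko_beta_scaling: bool = True

    def __post_init__(self) -> None:
        for name in ("C", "gNa", "gK", "gNaL", "gKL", "gClL", "gamma", "rho",
                     "U_kcc2", "U_nkcc1", "eps_k", "K_bath", "tau_ion"):
            if getattr(self, name) < 0:
                raise ValueError(f"{name} must be non-negative")
        if not 0.0 <= self.r_hco3 <= 1.0:
            raise ValueError("r_hco3 must lie in [0, 1]")
        if self.beta <= 0:
            raise ValueError("beta must be positive")

    # -- serialization ------------------------------------------------------

    def to_mapping(self) -> dict:
        d = dataclasses.asdict(self)
        d["literal_gaba_sign"] = bool(self.literal_gaba_sign)
        return d

    @classmethod
    def from_mapping(cls, mapping: Mapping) -> "ModelParams":
        unknown = set(mapping) - {f.name for f in dataclasses.fields(cls)}
        if unknown:
            raise ValueError(f"unknown parameter names: {sorted(unknown)}")
        return cls(**dict(mapping))

    @classmethod
    def from_table(cls, path=None, **overrides) -> "ModelParams":
        """Parameters from a flat YAML mapping (default: the bundled
        reference table), with optional keyword overrides."""
        import yaml

        if path is None:
            from importlib.resources import files
            text = files("cldyn").joinpath("data/table1.yaml").read_text()
        else:
            with open(path) as fh:
                text = fh.read()
        mapping = dict(yaml.safe_load(text))
        mapping.update(overrides)
        return cls.from_mapping(mapping)

    def replace(self, **kwargs) -> "ModelParams":
        return dataclasses.replace(self, **kwargs)

    @property
    def gaba_sign(self) -> float:
        return 1.0 if self.literal_gaba_sign else -1.0

    @property
    def ko_flux_scale(self) -> float:
        """Multiplier applied to the transmembrane flux terms of d[K⁺]ₒ/dt."""
        return self.beta if self.ko_beta_scaling else 1.0

    def pack(self) -> np.ndarray:
        """Flat float64 vector consumed by the compiled integration kernels."""
        return np.array([
            self.C, self.gNa, self.gK, self.gNaL, self.gKL, self.gClL,
            self.gamma, self.rho, self.U_kcc2, self.U_nkcc1, self.eps_k,
            self.K_bath, self.beta, self.E_hco3, self.r_hco3,
            self.nernst_coef, self.tau_ion, self.k_total, self.na_o_ref,
            self.na_i_ref, self.cl_o_ref, self.cl_i_ref, self.gaba_sign,
            self.ko_flux_scale,
        ])


@dataclass(frozen=True)
class DerivedQuantities:
    """Algebraic quantities evaluated at one state (reversal potentials, fluxes, currents)."""

    E_Na: float
    E_K: float
    E_Cl: float
    E_GABA: float
    K_i: float
    Na_o: float
    Cl_o: float
    rho_pump: float
    rho_kcc2: float
    rho_nkcc1: float
    f_Ko: float
    alpha_m: float
    beta_m: float
    alpha_h: float
    beta_h: float
    alpha_n: float
    beta_n: float
    I_Na: float
    I_K: float
    I_Cl_leak: float
    I_gaba_cl: float
    I_gaba_hco3: float
    I_pump: float


# ---------------------------------------------------------------------------
# Gating kinetics
# ---------------------------------------------------------------------------

def _ratefun(x: float, scale: float, width: float) -> float:
    """scale·x / (1 − exp(−x/width)), with the removable singularity at x = 0
    replaced by its analytic limit (first-order Taylor branch for |x| small)."""
    if abs(x) < 1e-6:
        return scale * width * (1.0 + x / (2.0 * width))
    return scale * x / (1.0 - math.exp(-x / width))


def gating_rates(V: float):
    """Voltage-dependent opening/closing rates (α_m, β_m, α_h, β_h, α_n, β_n) in ms⁻¹.

    Hippocampal-neuron rate functions; the removable singularities of α_m
    (V = −54), β_m (V = −27) and α_n (V = −52) are evaluated by their limits.
    """
    if not math.isfinite(V):
        raise ValueError(f"membrane potential must be finite, got {V!r}")
    alpha_m = _ratefun(V + 54.0, 0.32, 4.0)
    beta_m = _ratefun(-(V + 27.0), 0.28, 5.0)
    alpha_h = 0.128 * math.exp(-(V + 50.0) / 18.0)
    beta_h = 4.0 / (1.0 + math.exp(-(V + 27.0) / 5.0))
    alpha_n = _ratefun(V + 52.0, 0.032, 5.0)
    beta_n = 0.5 * math.exp(-(V + 57.0) / 40.0)
    return alpha_m, beta_m, alpha_h, beta_h, alpha_n, beta_n


def steady_gating(V: float):
    """Voltage steady-state gating values m∞(V), n∞(V), h∞(V)."""
    am, bm, ah, bh, an, bn = gating_rates(V)
    return am / (am + bm), an / (an + bn), ah / (ah + bh)


# ---------------------------------------------------------------------------
# Algebraic closures, reversal potentials, pump and cotransporters
# ---------------------------------------------------------------------------

def closures(Na_i: float, Cl_i: float, params: ModelParams):
    """Electroneutrality closures: ([K⁺]ᵢ, [Na⁺]ₒ, [Cl⁻]ₒ) from ([Na⁺]ᵢ, [Cl⁻]ᵢ)."""
    K_i = params.k_total - Na_i + Cl_i
    Na_o = params.na_o_ref - params.beta * (Na_i - params.na_i_ref)
    Cl_o = params.cl_o_ref - params.beta * (Cl_i - params.cl_i_ref)
    if K_i <= 0 or Na_o <= 0 or Cl_o <= 0 or Na_i <= 0 or Cl_i <= 0:
        raise DomainViolationError(
            f"closure produced a non-positive concentration: "
            f"Na_i={Na_i:.6g}, Cl_i={Cl_i:.6g} -> K_i={K_i:.6g}, Na_o={Na_o:.6g}, Cl_o={Cl_o:.6g}"
        )
    return K_i, Na_o, Cl_o


def reversal_potentials(state: NeuronState, params: ModelParams):
    """Nernst reversal potentials (E_Na, E_K, E_Cl) in mV.

    E = nernst_coef·ln([out]/[in]) for the cations; chloride, being an anion,
    uses the inverted ratio ln([in]/[out]).
    """
    K_i, Na_o, Cl_o = closures(state.Na_i, state.Cl_i, params)
    if state.K_o <= 0:
        raise DomainViolationError(f"K_o must be positive, got {state.K_o!r}")
    c = params.nernst_coef
    E_Na = c * math.log(Na_o / state.Na_i)
    E_K = c * math.log(state.K_o / K_i)
    E_Cl = c * math.log(state.Cl_i / Cl_o)
    return E_Na, E_K, E_Cl


def gaba_reversal(E_Cl: float, params: ModelParams) -> float:
    """Mixed GABA_A reversal potential: conductance-weighted average of E_Cl and E_HCO3.

    E_GABA = (E_Cl + r·E_HCO3) / (1 + r) with r the HCO₃⁻/Cl⁻ conductance ratio.
    """
    r = params.r_hco3
    return (E_Cl + r * params.E_hco3) / (1.0 + r)


def pump_rate(Na_i: float, K_o: float, params: ModelParams) -> float:
    """Na⁺/K⁺ pump rate (mM·s⁻¹): product of two logistic activations.

    ρ_pump = ρ / (1 + exp((25 − [Na⁺]ᵢ)/3)) · 1 / (1 + exp(3.5 − [K⁺]ₒ)).
    """
    return (params.rho
            / (1.0 + math.exp((25.0 - Na_i) / 3.0))
            / (1.0 + math.exp(3.5 - K_o)))


def cotransporter_fluxes(state: NeuronState, params: ModelParams):
    """KCC2 and NKCC1 cotransporter fluxes (mM·s⁻¹) and the NKCC1 activation f([K⁺]ₒ).

    Both cotransporters are modelled thermodynamically, as strengths times the
    log of the relevant concentration-product ratios; NKCC1 is additionally
    gated by a logistic function of [K⁺]ₒ.
    """
    K_i, Na_o, Cl_o = closures(state.Na_i, state.Cl_i, params)
    K_o = state.K_o
    if K_o <= 0:
        raise DomainViolationError(f"K_o must be positive, got {K_o!r}")
    rho_kcc2 = params.U_kcc2 * math.log((K_i * state.Cl_i) / (K_o * Cl_o))
    f_Ko = 1.0 / (1.0 + math.exp(16.0 - K_o))
    rho_nkcc1 = params.U_nkcc1 * f_Ko * (
        math.log((K_o * Cl_o) / (K_i * state.Cl_i))
        + math.log((Na_o * Cl_o) / (state.Na_i * state.Cl_i))
    )
    return rho_kcc2, rho_nkcc1, f_Ko


def derived_quantities(state: NeuronState, params: ModelParams,
                       g_gaba: float = 0.0) -> DerivedQuantities:
    """All algebraic quantities of the model at one state."""
    K_i, Na_o, Cl_o = closures(state.Na_i, state.Cl_i, params)
    E_Na, E_K, E_Cl = reversal_potentials(state, params)
    am, bm, ah, bh, an, bn = gating_rates(state.V)
    rho_kcc2, rho_nkcc1, f_Ko = cotransporter_fluxes(state, params)
    rho_p = pump_rate(state.Na_i, state.K_o, params)
    V = state.V
    I_Na = (params.gNa * state.m ** 3 * state.h + params.gNaL) * (V - E_Na)
    I_K = (params.gK * state.n ** 4 + params.gKL) * (V - E_K)
    I_Cl_leak = params.gClL * (V - E_Cl)
    I_gaba_cl = g_gaba * (V - E_Cl)
    I_gaba_hco3 = params.r_hco3 * g_gaba * (V - params.E_hco3)
    I_pump = rho_p / params.gamma
    return DerivedQuantities(
        E_Na=E_Na, E_K=E_K, E_Cl=E_Cl, E_GABA=gaba_reversal(E_Cl, params),
        K_i=K_i, Na_o=Na_o, Cl_o=Cl_o,
        rho_pump=rho_p, rho_kcc2=rho_kcc2, rho_nkcc1=rho_nkcc1, f_Ko=f_Ko,
        alpha_m=am, beta_m=bm, alpha_h=ah, beta_h=bh, alpha_n=an, beta_n=bn,
        I_Na=I_Na, I_K=I_K, I_Cl_leak=I_Cl_leak,
        I_gaba_cl=I_gaba_cl, I_gaba_hco3=I_gaba_hco3, I_pump=I_pump,
    )


# ---------------------------------------------------------------------------
# Right-hand side of the coupled system
# ---------------------------------------------------------------------------

def rhs(t: float, y: np.ndarray, params: ModelParams, g_gaba: float = 0.0) -> np.ndarray:
    """Time derivative of the 7-dimensional state (per ms).

    ``y`` is ordered as :data:`STATE_NAMES`.  ``g_gaba`` is the instantaneous
    GABA_A chloride conductance (mS·cm⁻²); callers evaluating a time-dependent
    protocol pass g_gaba = g(t).  The GABA contribution to dV/dt is
    sign·[g(V−E_Cl) + r·g(V−E_HCO3)] with sign = −1 by default, and the GABA
    chloride current additionally feeds d[Cl⁻]ᵢ/dt.  Ion derivatives are the
    mM·s⁻¹ fluxes divided by ``tau_ion``.
    """
    V, m, n, h, K_o, Na_i, Cl_i = (float(v) for v in y)
    state = NeuronState(V, m, n, h, K_o, Na_i, Cl_i)
    q = derived_quantities(state, params, g_gaba)

    sign = params.gaba_sign
    I_total = q.I_Na + q.I_K + q.I_Cl_leak + q.I_pump - sign * (q.I_gaba_cl + q.I_gaba_hco3)
    dV = -I_total / params.C

    am, bm, ah, bh, an, bn = q.alpha_m, q.beta_m, q.alpha_h, q.beta_h, q.alpha_n, q.beta_n
    dm = am * (1.0 - m) - bm * m
    dn = an * (1.0 - n) - bn * n
    dh = ah * (1.0 - h) - bh * h

    g = params.gamma
    tau = params.tau_ion
    dK_o = (params.ko_flux_scale
            * (g * q.I_K - 2.0 * q.rho_pump - q.rho_nkcc1 + q.rho_kcc2)
            - params.eps_k * (K_o - params.K_bath)) / tau
    dNa_i = (-g * q.I_Na - 3.0 * q.rho_pump + q.rho_nkcc1) / tau
    dCl_i = (g * (q.I_Cl_leak + q.I_gaba_cl) + 2.0 * q.rho_nkcc1 - q.rho_kcc2) / tau

    return np.array([dV, dm, dn, dh, dK_o, dNa_i, dCl_i])


def flux_charge_residual(state: NeuronState, params: ModelParams,
                         g_gaba: float = 0.0) -> float:
    """Residual of the flux–charge consistency identity (mM·s⁻¹).

    The net rate of intracellular charge accumulation implied by the ion flux
    equations (counting the untracked HCO₃⁻ efflux like the chloride flux and
    the cotransporters as electroneutral, without the bath diffusion term)
    must equal γ·C·dV/dt, i.e. γ times the total membrane current of the
    voltage equation.  This redundancy is what makes the stationary set a
    one-parameter family when bath diffusion and GABA input are absent.
    """
    q = derived_quantities(state, params, g_gaba)
    # flux side (mM/s): d/dt (Na_i + K_i - Cl_i - HCO3_i) from the membrane fluxes
    d_na = -params.gamma * q.I_Na - 3.0 * q.rho_pump + q.rho_nkcc1
    d_k_i = -(params.gamma * q.I_K - 2.0 * q.rho_pump - q.rho_nkcc1 + q.rho_kcc2)
    d_cl = params.gamma * (q.I_Cl_leak + q.I_gaba_cl) + 2.0 * q.rho_nkcc1 - q.rho_kcc2
    d_hco3 = params.gamma * q.I_gaba_hco3
    charge_flux = d_na + d_k_i - d_cl - d_hco3
    # voltage side: gamma * C * dV/dt with the default (physical) sign convention
    I_total = (q.I_Na + q.I_K + q.I_Cl_leak + q.I_pump + q.I_gaba_cl + q.I_gaba_hco3)
    return charge_flux - params.gamma * (-I_total)
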