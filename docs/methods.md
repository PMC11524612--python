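# Methods

## Model

`cldyn` implements a single-compartment, Hodgkin–Huxley-style neuron in
which three ion concentrations are dynamical variables.  The membrane
carries transient Na⁺ and delayed-rectifier K⁺ currents with
hippocampal-type rate functions, three ohmic leaks (Na⁺, K⁺, Cl⁻), an
electrogenic 3:2 Na⁺/K⁺ pump, and a GABA_A conductance that is permeable to
both Cl⁻ and HCO₃⁻.  Extracellular potassium [K⁺]ₒ, intracellular sodium
[Na⁺]ᵢ and intracellular chloride [Cl⁻]ᵢ evolve with the membrane fluxes,
the pump, the KCC2 and NKCC1 cotransporters (thermodynamic, log-ratio
driven), and — for [K⁺]ₒ — first-order exchange with a bath reservoir.
The remaining concentrations are closed algebraically by electroneutrality:

    [K⁺]ᵢ  = 100 − [Na⁺]ᵢ + [Cl⁻]ᵢ
    [Na⁺]ₒ = 135 − β([Na⁺]ᵢ − 20)
    [Cl⁻]ₒ = 145 − β([Cl⁻]ᵢ − 6)           (all mM, β = 7)

Reversal potentials follow the Nernst equation with prefactor 26.64 mV
(310 K); chloride, an anion, uses the inverted concentration ratio.  The
mixed GABA_A reversal is the conductance-weighted average
E_GABA = (E_Cl + r·E_HCO3)/(1 + r).

Assumptions inherited from the model family: fixed cell volume (β
constant), fixed E_HCO3 = −13 mV (bicarbonate is replenished fast enough by
carbonic anhydrase that its gradient is effectively clamped), no pH
dynamics, no glial compartment beyond the lumped bath term, a single
isopotential compartment, and deterministic channels.

### Units and timescales

V in mV, time in ms, concentrations in mM, conductances in mS·cm⁻²,
currents in µA·cm⁻², transport fluxes in mM·s⁻¹.  The conversion factor
γ = 0.03 mM·cm²·s⁻¹·µA⁻¹ (surface-to-volume over Faraday constant) turns
current densities into concentration rates per second, so the three ion
equations are divided by τ = 10³ to express them per millisecond.  τ is
exposed as `tau_ion` but is a unit bridge, not a tunable biological
parameter.

### Two deliberate deviations from naive readings

* **Sign of the GABA terms.**  The voltage equation uses the same
  −g·(V−E) convention for the GABA chloride and bicarbonate currents as
  for every other current.  Written with the opposite sign, GABA input
  would be depolarizing whenever V > E_Cl, contradicting the behaviour of
  every simulated protocol here (a pure-chloride train hyperpolarizes a
  resting neuron).  `ModelParams(literal_gaba_sign=True)` restores the
  alternative convention for inspection.

* **Volume scaling of the [K⁺]ₒ balance.**  The extracellular space holds
  1/β of the intracellular volume, so a membrane flux that changes an
  intracellular concentration at rate r changes [K⁺]ₒ at rate β·r.  The
  package therefore multiplies the transmembrane flux terms of d[K⁺]ₒ/dt
  by β (`ko_beta_scaling=True`, default); the bath-exchange term acts on
  [K⁺]ₒ directly and is not scaled.  The scaling leaves every equilibrium
  of the isolated (ε_K = 0) system unchanged — it multiplies a flux that
  vanishes there — but it controls the slow dynamics and the bath-coupled
  steady states.  It is decisive quantitatively: with it, the step-GABA
  firing-onset conductance computed by continuation (≈0.203 mS·cm⁻² at
  ε_K = 0.25, [K⁺]bath = 3) agrees with simulation and with the expected
  order of magnitude, whereas the unscaled variant (`ko_beta_scaling=False`)
  places it three-fold higher and shifts the spiking-onset chloride load by
  +1.4 mM.  Both variants are available; all defaults, tests and the
  acceptance script use the scaled form.

### Flux–charge consistency and the conserved quantity

Counting the untracked HCO₃⁻ efflux like the chloride flux, the net rate of
intracellular charge accumulation implied by the ion equations equals
γ·C·dV/dt exactly (`flux_charge_residual`; the residual is a pure
floating-point error, asserted < 10⁻⁹ at random states).  Two consequences
structure the whole analysis:

* With ε_K = 0 and no bicarbonate-carrying GABA input,
  Q = [Na⁺]ᵢ − [K⁺]ₒ/β − [Cl⁻]ᵢ − (γC/τ)·V is a constant of motion.
  Trajectories live on Q-level sets, the stationary set is a one-parameter
  family, and **the asymptotic state depends on the initial condition**:
  a trajectory started from rest with a given chloride load relaxes to the
  family member on its own level set, not to a universal resting point.
  The spiking-onset load is, to three digits, the level set through the
  subcritical Hopf that destabilizes the resting branch; the
  depolarization-block onset is the level set through the upper Hopf.
* The redundancy makes a 7-equation Newton solve rank-deficient.  Fixed
  points are therefore computed with one coordinate clamped (normally
  [Cl⁻]ᵢ; V near folds) and the clamped coordinate's own balance is
  *verified* afterwards (residual < 10⁻⁶) rather than assumed.

The GABA bicarbonate current breaks the redundancy (HCO₃⁻ is not a state
variable), as does bath exchange; in those regimes fixed points are
isolated and all seven equations are active.

## Parameters

| name | default | units | role |
|---|---|---|---|
| C | 1.0 | µF·cm⁻² | membrane capacitance |
| gNa, gK | 30, 20 | mS·cm⁻² | maximal voltage-gated conductances |
| gNaL, gKL, gClL | 0.04, 0.1, 0.1 | mS·cm⁻² | leaks |
| γ (`gamma`) | 0.03 | mM·cm²·s⁻¹·µA⁻¹ | current→flux conversion |
| ρ (`rho`) | 0.8 | mM·s⁻¹ | maximal pump rate |
| U_kcc2, U_nkcc1 | 0.3, 0.1 | mM·s⁻¹ | cotransporter strengths |
| ε_K (`eps_k`) | 0.25 | s⁻¹ | bath exchange rate (0 isolates the neuron) |
| [K⁺]bath (`K_bath`) | 3.0 | mM | bath potassium |
| β (`beta`) | 7 | — | intra-/extracellular volume ratio |
| E_HCO3 (`E_hco3`) | −13 | mV | fixed bicarbonate reversal |
| r (`r_hco3`) | 0.2 | — | HCO₃⁻/Cl⁻ conductance ratio of GABA_A |
| `tau_ion` | 1000 | — | ms↔s bridge for the ion equations |

The reference set ships as `data/table1.yaml`
(`ModelParams.from_table()` reproduces it bit-exactly).  NKCC1's logistic
activation is centred at [K⁺]ₒ = 16 mM, so at physiological [K⁺]ₒ its flux
is ~10⁻⁶ mM·s⁻¹ — effectively a spectator in every scenario here.

### Stimulus protocols

Step protocol: a constant conductance on a closed window.  Spike-train
protocol: regular presynaptic spikes (interval 1000/f ms) each gating on a
biexponential kernel; the default "sum" form contributes
A0·[e^(−t/τ1) + e^(−t/τ2)] from the spike time (value 2·A0 at the spike),
the conventional "difference" form is also available.  The kernel constants
are not constrained by any published value; the package fixes τ1 = 5 ms,
τ2 = 1 ms and A0 = 5/3 mS·cm⁻² so that a 10 Hz train carries a
time-averaged conductance of 0.1 mS·cm⁻² — the order of the step
conductances at which interesting transitions occur.  Consequently the
*timings* of spike-train-driven events (when firing starts, when block is
reached) are meaningful only qualitatively; thresholds expressed as
conductances or chloride levels do not depend on this choice.  Protocols
requiring the unknown amplitude carry an `amplitude_unpublished` annotation
in their scenario metadata.

## Numerics

* **Integration.**  Reference method: fixed-step classical RK4 with
  dt = 0.02 ms, compiled with numba; spike detection (upward crossing of
  −20 mV, 2 ms refractory) runs at full step resolution inside the kernel
  while the stored trace is decimated to 1 ms.  Cross-check method: scipy
  LSODA at rtol 10⁻⁸.  Agreement on a smooth 5 s segment (max |ΔV| <
  0.1 mV, |ΔCl| < 10⁻³ mM) and spike-count invariance under dt halving are
  asserted in the suite.  The conserved quantity drifts by < 10⁻⁶ mM over
  30 s of bursting at the reference step.
* **Validity region.**  A state with any non-positive concentration (direct
  or closed) raises a domain violation carrying the offending time and
  state; integration never clamps, so failures stay diagnosable.
* **Removable singularities** of the gating rate functions (V = −54, −27,
  −52 mV) are evaluated by a first-order Taylor branch for |x| < 10⁻⁶.
* **Fixed points.**  scipy's hybrid-Powell solver on scaled residuals
  (gating ×10, ion equations ×10³ so all rows are O(1)); acceptance
  requires max scaled residual < 10⁻⁸ and, for clamped conservative solves,
  a verified omitted-equation residual < 10⁻⁶.
* **Jacobians** by central differences, step 10⁻⁶ scaled per coordinate
  (checked against an independent step choice to 10⁻⁴ relative on the
  spectrum).  Stability classes: stable, saddle, unstable_focus, marginal
  (|Re λ| < 10⁻⁶); on the conservative family the structural zero mode is
  excluded before classification.
* **Continuation.**  Pseudo-arclength predictor–corrector with the tangent
  from an SVD null space, per-coordinate scales (V 25 mV, concentrations
  5 mM, conductance 0.25 mS·cm⁻²), step adaptation ×1.3 on success and ×0.5
  on failure, and exact landing on range boundaries.  Folds (SN) are
  detected as sign changes of the parameter increment and refined by
  bracketing dP/dξ = 0 in the locally fastest coordinate ξ; Hopf points as
  sign changes of the leading complex-pair real part, refined by bisection
  with fresh warm-started solves.  SN/HB locations are invariant to ±0.02 mM
  under step halving.  On the chloride branch the relevant spectrum is the
  [Cl⁻]ᵢ-clamped 6×6 reduced Jacobian; on the conductance branch the full
  7×7.
* **Pattern classification** is rule-based: DB window = 2 s with mean V >
  −50 mV and no spikes; stable DB = DB over the final 20 s; burst
  segmentation at inter-spike intervals exceeding 5× the within-burst
  median; tonic vs bursting at ISI CV 0.5; subthreshold oscillation at
  > 1 mV peak-to-peak without spikes.  The CV rule and the −50 mV plateau
  criterion are this package's operationalization of a visual
  classification; windows shorter than 60 s set a low-confidence flag.  One
  known edge: a depolarized *subthreshold oscillation* whose tail is
  spike-free also meets the stable-DB tail criterion; where the distinction
  matters (the DB-onset conductance) the acceptance script additionally
  requires tail stationarity (peak-to-peak < 0.5 mV).
* **Transition searches** bisect a monotone predicate over initial [Cl⁻]ᵢ
  or conductance with 300 s probes (long transients near boundaries), with
  geometric bracket expansion when the supplied bracket does not straddle
  the boundary.

## Problem sizes

The default suite and the acceptance script use: continuation branches of
~30–130 points; 300 s probe integrations (1.5×10⁷ RK4 steps each) for the
sweep bisections to 0.005–0.01 mM; a 700 s run for the bicarbonate-switch
scenario; 800 s for the rebound scenario.  The full acceptance script
completes in a few minutes on one CPU.

## What the scenarios emulate — and what they do not

Scenario presets encode idealized protocols: instantaneous chloride loading
with all other coordinates at their resting values, perfectly regular
presynaptic trains, a step conductance with no kinetics or desensitization,
and a bath that lumps glial and vascular potassium clearance into one
first-order rate.  Real recordings differ in ways the model deliberately
ignores: stochastic synaptic timing, receptor desensitization and
short-term plasticity, activity-dependent volume changes (which move the
closure constants and hence every reversal potential), HCO₃⁻/pH dynamics,
and network feedback.  Passing tests therefore demonstrate internal
consistency of this idealized single-cell mechanism — the chloride-load
bifurcation skeleton, the bicarbonate-driven inhibition→excitation switch,
the chloride–potassium competition — not quantitative agreement with any
particular experimental preparation.

## Known limitations

* The spiking- and DB-onset chloride loads are basin boundaries of a
  conservative system; they are exquisitely sensitive to the conserved
  quantity of the initial state (a 0.1 mM change in initial [Na⁺]ᵢ shifts
  both by 0.1 mM).  Published values for such boundaries can differ between
  implementations by more than the continuation-level quantities do.
* Near the subcritical Hopf that ends the resting branch, transients are
  minutes long; probe durations shorter than ~300 s bias onset estimates
  downward.
* The upper Hopf of the chloride branch sits where the reduced spectrum's
  complex pair crosses slowly (|Re λ| ~ 10⁻⁴ ms⁻¹); its location is robust
  to solver settings here but moves visibly with any change to the slow
  equations.
* No limit-cycle continuation: oscillation boundaries are characterized by
  simulation, not Floquet analysis.
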