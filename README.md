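# cldyn — chloride–potassium ion dynamics in a single-compartment neuron

`cldyn` is a simulation and bifurcation toolkit for a conductance-based
neuron whose ion concentrations are dynamical variables.  It is aimed at
computational neuroscientists studying how chloride homeostasis shapes
excitability — in particular how sustained GABA_A input, which carries both
a Cl⁻ influx and an HCO₃⁻ efflux, can switch from inhibitory to
seizure-promoting, and how extracellular potassium exchange with a bath
counteracts that switch.

## The model

A Hodgkin–Huxley-style membrane equation is coupled to three slow ion
balances.  The state is (V, m, n, h, [K⁺]ₒ, [Na⁺]ᵢ, [Cl⁻]ᵢ):

```
C dV/dt  = −g_Na m³h (V−E_Na) − g_K n⁴ (V−E_K) − g_NaL (V−E_Na)
           − g_KL (V−E_K) − g_ClL (V−E_Cl) − ρ_pump/γ
           − g_GABA (V−E_Cl) − r·g_GABA (V−E_HCO3)

τ d[K⁺]ₒ/dt  = β·(γ I_K − 2ρ_pump − ρ_NKCC1 + ρ_KCC2) − ε_K([K⁺]ₒ − [K⁺]bath)
τ d[Na⁺]ᵢ/dt = −γ I_Na − 3ρ_pump + ρ_NKCC1
τ d[Cl⁻]ᵢ/dt = γ (I_ClL + I_GABA,Cl) + 2ρ_NKCC1 − ρ_KCC2
```

Reversal potentials follow the instantaneous concentrations through the
Nernst equation; [K⁺]ᵢ, [Na⁺]ₒ and [Cl⁻]ₒ are closed by electroneutrality
with a fixed intra-/extracellular volume ratio β = 7 (the β factor converts
membrane fluxes to extracellular concentration changes in the [K⁺]ₒ
equation).  The Na⁺/K⁺ pump and the KCC2/NKCC1 cotransporters are modelled
thermodynamically; the GABA_A receptor carries an HCO₃⁻ current at a fixed
fraction r = 0.2 of its chloride conductance with E_HCO3 = −13 mV.  Units:
mV, ms, mM, mS·cm⁻², µA·cm⁻², mM·s⁻¹ (τ = 10³ bridges ms and s).

A structural feature does a lot of work here: with ε_K = 0 and no
bicarbonate flux, the total membrane current is an exact linear combination
of the ion fluxes (flux–charge consistency), so Q = [Na⁺]ᵢ − [K⁺]ₒ/β −
[Cl⁻]ᵢ − (γC/τ)V is conserved and the stationary states form a
one-parameter family.  `cldyn` traces that family by clamping [Cl⁻]ᵢ,
classifies stability from Jacobian eigenvalues, and refines the saddle-node
(SN) and Hopf (HB) points that bound the resting and depolarization-block
(DB) branches.  With bath coupling on, fixed points are isolated and the
natural continuation parameter is the GABA step conductance.

## Worked example

```python
from cldyn import ModelParams, NeuronState, continue_branch, gaba_crossover

params = ModelParams(eps_k=0.0)               # isolated neuron, no bath
guess = NeuronState.with_steady_gating(V=-76.5, K_o=2.4, Na_i=21.7, Cl_i=5.0)
branch = continue_branch("Cl_i", (5.0, 20.0), guess, params, step0=0.1)
print(max(b.value for b in branch.sn_points))   # 7.884899140765471
print(max(b.value for b in branch.hb_points))   # 18.918381927132806
print(gaba_crossover(branch)[0])                # -36.3826617596183
```

The three numbers are, in order: the [Cl⁻]ᵢ (mM) of the saddle-node where
the stable resting branch ends — chloride loads below it relax back to
rest; the [Cl⁻]ᵢ of the Hopf where the stable depolarization-block branch
begins — loads beyond it are captured by a silent, strongly depolarized
state; and the voltage (mV) at which the fixed-point branch crosses E_Cl —
below it a pure-chloride GABA conductance is inhibitory, above it
depolarizing.  The `examples/` scripts walk through the other capabilities
(firing-pattern classification along the initial-chloride sweep, the
bicarbonate inhibition→excitation switch, step-GABA thresholds under bath
coupling), and the `cldyn` command line exposes the same scenarios
(`cldyn list`, `cldyn reproduce fig1b`, `cldyn simulate --config …`).

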