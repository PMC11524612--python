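# Reference constant-parameter set of the single-compartment model,
# keyed by symbol name. Units: conductances mS/cm^2, C uF/cm^2,
# gamma mM*cm^2/(s*uA), rates mM/s, eps_k 1/s, concentrations mM.
C: 1.0
gNa: 30.0
gK: 20.0
gNaL: 0.04
gKL: 0.1
gClL: 0.1
gamma: 0.03
rho: 0.8
U_nkcc1: 0.1
U_kcc2: 0.3
eps_k: 0.25
K_bath: 3.0
beta: 7.0
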