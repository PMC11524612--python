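"""Trace the fixed-point branch in intracellular chloride and locate its
saddle-node and Hopf points.

With potassium diffusion off and no GABA input, the stationary states form a
one-parameter family in [Cl-]i.  Below the saddle-node the neuron has a
stable resting state; between the SN and the Hopf the fixed points are
unstable (the neuron bursts or fires); above the Hopf a stable
depolarization-block state exists.
"""

from cldyn import ModelParams, NeuronState, continue_branch, gaba_crossover

params = ModelParams(eps_k=0.0)
guess = NeuronState.with_steady_gating(V=-76.5, K_o=2.4, Na_i=21.7, Cl_i=5.0)
branch = continue_branch("Cl_i", (5.0, 20.0), guess, params, step0=0.1)

sn = max(b.value for b in branch.sn_points)
hb = max(b.value for b in branch.hb_points)
v_star, cl_star = gaba_crossover(branch)

print(f"branch points computed : {len(branch)}")
print(f"saddle-node (SN)       : [Cl-]i = {sn:.3f} mM  "
      "(end of the stable resting branch)")
print(f"Hopf (HB)              : [Cl-]i = {hb:.3f} mM  "
      "(onset of the stable depolarization-block branch)")
print(f"V = E_Cl crossover     : {v_star:.2f} mV at [Cl-]i = {cl_star:.2f} mM")
print("Below the crossover voltage a pure-chloride GABA conductance is "
      "inhibitory; above it, depolarizing.")
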