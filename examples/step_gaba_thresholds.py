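"""Step-GABA thresholds under bath potassium coupling.

With the extracellular potassium exchanging with a 3 mM bath at
eps_k = 0.25 /s, the steady state is continued in the held GABA step
conductance.  The stable resting state is lost at a small conductance
(firing onset); a stable depolarization-block state appears at a much larger
one.  Between the two the neuron oscillates or fires.
"""

from cldyn import ModelParams, NeuronState, continue_branch
from cldyn.bifurcation import find_fixed_point

params = ModelParams(eps_k=0.25, K_bath=3.0, r_hco3=0.2)

rest = find_fixed_point(
    NeuronState.with_steady_gating(-70.0, 3.0, 20.0, 6.0), params, g_gaba=0.0)
print(f"resting state at G=0   : V = {rest.state.V:.2f} mV, "
      f"K_o pinned to the bath ({rest.state.K_o:.2f} mM)")

lower = continue_branch("g_gaba", (0.0, 4.0), rest.state, params,
                        g_gaba=0.0, step0=0.05)
onset = min(b.value for b in lower.hb_points + lower.sn_points if b.value > 0.05)
print(f"firing onset           : G_GABA = {onset:.3f} mS/cm^2 "
      "(stable low-voltage state lost)")

db_seed = find_fixed_point(
    NeuronState.with_steady_gating(-35.0, 15.0, 28.0, 16.0), params, g_gaba=3.0)
upper = continue_branch("g_gaba", (0.5, 3.5), db_seed.state, params,
                        g_gaba=3.0, step0=0.05, direction=-1.0)
g_db = max(b.value for b in upper.hb_points)
print(f"depolarization block   : G_GABA = {g_db:.3f} mS/cm^2 "
      "(stable DB fixed point appears)")
print("\nStronger bath coupling shifts both thresholds upward; the DB "
      "threshold is the more sensitive of the two.")
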