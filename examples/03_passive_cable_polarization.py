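"""Field-induced polarization of a passive cable vs cable theory.

A sealed straight cable of length ℓ in a linear extracellular gradient E
polarizes at its ends by ±E·λ·tanh(ℓ/2λ) with λ = √(d·R_m/4R_a).  This is
the analytic anchor for the solver: the simulated end polarization should
match to better than 1%.
"""
import math

import fieldmorph as fm
from fieldmorph.cablesim import SimConfig, Stimulus, assemble, run
from fieldmorph.protocol import field_offsets

E = 10.0  # mV/mm
cable = fm.straight_cable_neuron(1000.0, 1.0, soma_radius=0.5,
                                 max_compartment_length=10.0)
state = assemble(cable.model, cable.biophys)
cfg = SimConfig(duration=200.0, record_targets=("dendrite_end",))
off = field_offsets(cable.model, E, mode="linear_potential")
trace = run(state, cfg, Stimulus(efield=off))

v_end = trace.voltages["dendrite_end"][-1] + 70.0
lam = math.sqrt(1e-4 * 2e4 / 400.0) * 1e4  # µm
# the recorded compartment's midpoint sits half a compartment in from x = ℓ
import numpy as np
dend = np.flatnonzero(cable.model.type_mask("basal_dendrite"))
x = cable.model.midpoints[dend, 2].max()
pred = abs(E * 1e-3 * lam * math.sinh((x - 500.0) / lam) / math.cosh(500.0 / lam))
print(f"space constant λ = {lam:.0f} µm")
print(f"saturation bound E·λ·tanh(ℓ/2λ) = {E*1e-3*lam*math.tanh(500.0/lam):.4f} mV")
print(f"simulated |polarization| at x = {x:.0f} µm : {abs(v_end):.4f} mV")
print(f"analytic  |V(x)|                         : {pred:.4f} mV")
print(f"relative error = {abs(abs(v_end) - pred) / pred:.2%}")
print("\nThe end of the cable facing the field gradient polarizes; the"
      "\nmagnitude grows with cable length until saturating at E·λ.")
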