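"""Write a cell to SWC, read it back, and inspect it section by section.

Demonstrates the SWC dialect (7 columns, radii in µm, soma recentred at the
origin on load) and the per-class compartment statistics.
"""
import tempfile
from pathlib import Path

import fieldmorph as fm
from fieldmorph.metrics import compartment_stats

neuron = fm.generate_neuron(fm.default_class_spec("PC", "L5"),
                            fm.default_biophysics(), seed=4)
with tempfile.TemporaryDirectory() as d:
    path = Path(d) / "pc_l5.swc"
    fm.write_swc(neuron.morphology, path)
    print(f"wrote {sum(1 for l in path.read_text().splitlines() if not l.startswith('#'))} "
          f"SWC points")
    back = fm.read_swc(path)

model = fm.discretize(back, 20.0)
print(f"{len(back.sections)} sections -> {model.n} compartments at <=20 µm")
for cls in ("dendritic", "axonal"):
    st = compartment_stats(model, cls)
    print(f"  {cls:9s}: mean length {st.mean_length:6.2f} µm, "
          f"mean diameter {st.mean_diameter:5.2f} µm, {st.n_branches} branch points")
print(f"z-length {fm.z_length(model):.1f} µm, "
      f"vector magnitude {fm.vector_magnitude(model):.1f} µm")
print("\nThe round trip conserves topology and geometry; metrics are computed"
      "\non the soma-centered model.")
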