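"""Does any morphology trait predict field susceptibility?

Runs the end-to-end experiment on a reduced synthetic population: trait
table, trial loop, per-cell susceptibility, Pearson/partial correlations per
trait and Mann–Whitney group tests, plus the fixed-conductance control in
which PC L2/3 cells are re-simulated with channel densities averaged over
the subset (removing biophysical variability).
"""
import fieldmorph as fm
from fieldmorph.cablesim import SimConfig
from fieldmorph.protocol import FieldProtocol

population = fm.generate_population(
    [("PC", "L23", 4), ("PC", "L5", 4), ("PV", "L23", 4), ("PV", "L5", 4)],
    seed=1)
protocol = FieldProtocol(e_levels=(-50.0, 0.0, 50.0), n_trials=3, seed=1)
cfg = SimConfig(duration=200.0, analysis_start=100.0)

result = fm.run_experiment(population, protocol, cfg)

print("trait vs susceptibility (Pearson R, Wald-t p):")
for trait, st in result.stats["traits"].items():
    star = " *" if st["significant"] else ""
    partial = (f"   r_partial={st['r_partial']:+.2f} (p={st['p_partial']:.3f})"
               if "r_partial" in st else "")
    print(f"  {trait:20s} R={st['R']:+.2f}  p={st['p']:.3f}{star}{partial}")

print("\ngroup tests (Mann–Whitney U):")
for name, st in result.stats["group_tests"].items():
    print(f"  {name:45s} U={st['U']:5.1f}  p={st['p']:.3f}")

ctrl = fm.fixed_conductance_control(population, protocol, cfg)
print("\nfixed-conductance control (PC L2/3, densities averaged and uniform):")
print(ctrl[["id", "S"]].to_string(index=False))
print("\nA '*' marks p < 0.05.  In this synthetic population the generator"
      "\nbuilds in strong class differences, so size-related traits can reach"
      "\nsignificance; with realistic within-class variability such single-trait"
      "\neffects wash out.  The control shows the susceptibility spread that"
      "\nremains when channel-density variability is removed.")
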