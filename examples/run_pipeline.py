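"""End-to-end simulation: synthetic cohort -> screw grid -> injury tabulation.

Generates 100 synthetic ankles from the packaged calibrated configuration,
simulates all 90 screw placement options per ankle (10 levels x 3 trajectory
rules x 3 diameters), and prints the per-level injury-potential marginal.
"""

import dataclasses

from synfix import (
    cell_table,
    generate_cohort,
    load_default_config,
    make_screw_grid,
    marginals,
    run_cohort,
)

config = dataclasses.replace(load_default_config(), n_ankles=100, seed=42)
cohort = generate_cohort(config)
grid = make_screw_grid(config.level_heights)
records = run_cohort(cohort, grid)
print(f"{len(cohort)} ankles x {len(grid)} screw options = {len(records)} simulated screws")

cells = cell_table(records)
flagged = int(cells["n_flagged"].sum())
print(f"overall injury potential: {flagged} ({100 * flagged / len(records):.1f}%)\n")

print("level (cm)  flagged/total   pct")
for _, row in marginals(cells, "level").iterrows():
    print(f"  {row['category']:>5}     {row['n_flagged']:>4}/{row['n_total']}    "
          f"{row['pct']:5.1f}%")
print("\nEach row pools the 9 (rule, diameter) options at that level; a flag "
      "means the artery lies within the screw's outer shaft radius of the axis. "
      "Risk rises with placement height; the two most distal levels are safe "
      "by construction of the calibrated anatomy.")
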