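"""Per-tree spatial-structure indices on a simulated mixed stand.

Builds a 1-ha, ~600-tree mixture, then computes for every live tree its
mingling M (species segregation), uniform angle index W (spacing
regularity), dominance U (size suppression), and the composite FSS over
the 4 nearest neighbours, excluding reference trees within 5 m of the
plot boundary from the summary.
"""

import numpy as np

from standthin.simulate import StandConfig, assign_attributes, simulate_pattern
from standthin.spatial import compute_structure, stand_structure_summary

cfg = StandConfig()
rng = np.random.default_rng(1)
stand = assign_attributes(simulate_pattern(cfg, rng), cfg, rng, plot_id="demo")

structure = compute_structure(stand, n=4, alpha=72.0, buffer=5.0)
_, plot_means = stand_structure_summary(structure, stand)

print(structure.head().to_string(index=False))
print()
print("plot means over interior reference trees:")
print(plot_means.round(3).to_string())
print()
print("A mean W inside [0.475, 0.517] indicates random spacing; the high "
      "mean M reflects the many-species mixture; mean U near 0.5 says the "
      "average tree is neither dominant nor suppressed.")
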