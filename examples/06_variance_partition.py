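"""Hierarchical partitioning of the growth model's explained variance.

Splits the fitted model's marginal R^2 into the independent (Shapley)
contributions of the individual, competition, and stand predictor
groups; contributions telescope so shares sum to 100 %.
"""

from standthin.model import build_model_frame
from standthin.partition import hierarchical_partition
from standthin.pipeline import build_interval_table
from standthin.simulate import default_species_pool, simulate_experiment

exp = simulate_experiment(thinning_levels=(0.2,), seed=42)
pool = default_species_pool()
traits = dict(zip(pool["species"], pool["sst"]))
tab = build_interval_table(exp.censuses["plot20"], traits)
frame = build_model_frame(
    tab, predictors=["DBH", "DBH3", "BAL", "FSS", "Dg", "N", "Ddom"])

out = hierarchical_partition(frame, {
    "individual": ["DBH", "DBH3"],
    "competition": ["BAL", "FSS"],
    "stand": ["Dg", "N", "Ddom"],
})
print(out.round(3).to_string(index=False))
print(f"\nfull-model R2 partitioned: {out.attrs['full_r2']:.3f}; "
      "each share is the group's ordering-averaged R2 increment as a "
      "percentage of it — here tree size dominates, as expected when the "
      "growth law is driven by DBH.")
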