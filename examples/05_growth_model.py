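"""Mixed-effects model of log basal-area increment.

Builds the tree-interval frame from a simulated experiment, screens
collinearity by VIF, fits ln(BAI) with crossed subplot and census-year
random intercepts, and reports coefficients, variance components, fit
metrics, and subplot-stratified 10-fold cross-validation.
"""

from standthin.model import (
    build_model_frame,
    cross_validate,
    evaluate_fit,
    fit_lmm,
    vif_screen,
)
from standthin.pipeline import build_interval_table
from standthin.simulate import default_species_pool, simulate_experiment

exp = simulate_experiment(thinning_levels=(0.2,), seed=42)
pool = default_species_pool()
traits = dict(zip(pool["species"], pool["sst"]))
tab = build_interval_table(exp.censuses["plot20"], traits)

frame = build_model_frame(
    tab, predictors=["DBH", "DBH3", "BAL", "FSS", "Dg", "N", "Ddom", "SST"])
print(f"model frame: {len(frame.data)} tree-intervals "
      f"({frame.n_excluded} non-growing intervals excluded)")

retained, vif_table = vif_screen(frame, threshold=5.0)
print("predictors retained by the VIF screen:", retained)

fit = fit_lmm(frame, predictors=retained)
print("\nfixed effects (standardized scale):")
print(fit.params.round(3).to_string())
print("random-intercept variances:", {k: round(v, 4) for k, v in fit.vcomp.items()},
      f"residual {fit.resid_var:.3f}")
metrics = evaluate_fit(fit, frame)
print({k: round(v, 3) for k, v in metrics.items()})

cv = cross_validate(frame, folds=10, predictors=retained, seed=0)
print(f"10-fold CV (subplot-stratified): RMSE {cv['rmse'].mean():.3f}, "
      f"MAE {cv['mae'].mean():.3f}")
print("\nDBH carries the dominant positive effect with a mild negative "
      "cubic correction; marginal vs conditional R2 separates what fixed "
      "effects explain from what the subplot/year intercepts absorb.")
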