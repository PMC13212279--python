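"""Basal-area recovery trajectories and extrapolated crossing times.

Fits an OLS line to each treated plot's basal-area series and reports
when the fitted trend crosses (a) the plot's own pre-thinning baseline
and (b) the control plot's fitted trajectory.
"""

from standthin.growth import basal_area, plot_ba_series, recovery_fit
from standthin.simulate import simulate_experiment

exp = simulate_experiment(seed=42)

ctrl_series = plot_ba_series(exp.censuses["plot00"])
ctrl_fit = recovery_fit(ctrl_series["year"], ctrl_series["ba_m2_ha"], "plot00")
print(f"control: slope {ctrl_fit.slope:.2f} m2/ha/yr, R2 {ctrl_fit.r_squared:.3f}")

for plot_id in ("plot20", "plot40", "plot60"):
    censuses = exp.censuses[plot_id]
    baseline = basal_area(censuses[0].trees["dbh"].to_numpy()).sum() / 1e4  # pre-thinning
    series = plot_ba_series(censuses)
    fit = recovery_fit(series["year"], series["ba_m2_ha"], plot_id,
                       baseline=baseline, control_fit=ctrl_fit, thinning_year=0)
    to_base = ("%.1f yr" % fit.years_to_baseline
               if fit.years_to_baseline is not None else "not reached")
    to_ctrl = ("%.1f yr" % fit.years_to_control
               if fit.years_to_control is not None else "not reached")
    print(f"{plot_id}: slope {fit.slope:.2f}, R2 {fit.r_squared:.3f}, "
          f"baseline crossing {to_base}, control crossing {to_ctrl}")

print("\nLight thinning regains its pre-treatment basal area quickly; the "
      "heavier removals need proportionally longer, and a plot whose fitted "
      "line stays below the control's is reported as 'not reached'.")
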