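# Methods

This note documents the statistical machinery, the defaults, the
numerical choices, and what the synthetic generator does and does not
emulate.

## Data model

A census is a table of mapped stems (id, species, subplot row/column,
local x/y within the 20 m subplot, DBH in cm, status live / removed by
thinning / dead) for one plot in one year. Plot coordinates are
reconstructed as `x = col·s + x_local`, `y = row·s + y_local` with
subplot size s = 20 m, origin at the SW corner; cells are half-open
`[0, s)` except the final edge, so the subplot partition is exact and
invertible. The inventory threshold is DBH ≥ 5 cm; smaller records are
flagged aside rather than dropped silently.

Censuses are linked by tree id. Between-census DBH decreases of at most
0.5 cm are kept as measurement noise; larger decreases exclude that
interval from growth statistics (logged). Trees found dead contribute
no growth interval ending at that census but remain neighbours while
last recorded live. Removed trees keep their marking-census
measurement and never reappear.

## Neighbourhood structure indices

For each reference tree the 4 nearest live neighbours by Euclidean
distance are found with a k-d tree; candidates are re-sorted by
(distance, tree id) so distance ties resolve deterministically to the
smaller id. Coincident stems are an error (angular gaps undefined).
Mingling, uniform angle index (gaps between sorted neighbour azimuths
including the wrap-around, each taken as min(θ, 360°−θ), compared
against α = 72°), and dominance (strict DBH inequality) all take values
k/4, k = 0..4.

Standardized scores follow a piecewise map: mingling keeps its measured
value; W scores 1.0 inside the random interval [0.475, 0.517], keeps
its measured value below it, and scores 0.5 above (clumping is
penalized less than regularity is rewarded); U is rewarded for local
dominance, stepping 1.0 / 0.75 / 0.5 / 0.25 / 0.0 across breakpoints
0.47 / 0.49 / 0.51 / 0.53. The published form of the U table contains a
typeset interval (`0.47 ≤ U ≥ 0.9`) that only yields a coherent,
monotone five-level partition when read as 0.47–0.49; that reading is
implemented. The composite is the root-mean-square
`FSS = sqrt((1/3) Σ R_k²)`, which stays on [0, 1] and matches the
unit-circle framing; a mean-of-squares variant is available via
`fss(..., method="mean_sq")` because the defining expression can be
parsed either way.

Edge correction uses a buffer (default 5 m): trees inside the buffer
are neighbours but not reference trees in summaries. The buffer is the
standard conservative choice for nearest-neighbour statistics; toroidal
wrapping is deliberately out of scope. The standardization is applied
per tree (FSS is an individual-resolution competition variable); a
subplot-mean mode can be had by averaging raw indices first and
applying `standardize_scores` to the means.

## Growth statistics

Pressler's rate normalizes the periodic change by the period-average
basal area, making rates comparable across tree sizes; it is
antisymmetric in the endpoints and equals 200/(3n) for a doubling over
n years. The same form is applied to subplot basal-area totals for the
stand-level period summaries (mean ± SD over the 25 subplots); a
compound annual rate `((BA_t/BA_{t−n})^{1/n} − 1)·100` is available as
a flag for sensitivity. Stand series include ingrowth by default (a
re-inventory measures whatever is there); a cohort-fixed mode restricts
to baseline survivors for growth-only decomposition. For the first
post-thinning period the residual (post-thinning) basal area is the
starting value — the pre-thinning stock was removed by management, not
lost to growth.

Recovery fits are plain OLS of plot basal area on calendar year
(≥ 3 censuses). Crossing times are computed against a constant
pre-thinning baseline and against the control's *fitted* line (not its
raw values, matching how extrapolated trajectories are usually drawn);
geometries that do not approach from below, or crossings before the
thinning year, are reported as not reached rather than as negative
times.

## Functional grouping

Species-level features are unweighted means of per-tree(-interval)
values pooled over censuses (a census-weighted mode would down-weight
sparse censuses; pooling is the simpler default and the difference is
second-order for balanced designs). PCA is run on the correlation
matrix of z-scored features; components with eigenvalue > 1 are
retained (Kaiser rule), each loading vector oriented so its
largest-magnitude loading is positive, making scores reproducible
across eigensolvers. Ward clustering (scipy linkage, merge heights =
Ward costs) is cut at k groups; the silhouette profile over k = 2..8 is
always reported, but k is a configuration value defaulting to 3 — the
cluster count is an interpretive choice and the package never silently
takes the argmax. Singleton clusters contribute silhouette 0.

## Growth model

One row per tree × interval with BAI > 0; the response is ln(BAI).
Non-growing intervals are excluded before the log (they carry no
information on that scale); `offset=1.0` gives the ln(BAI + 1 cm²/yr)
sensitivity variant. Continuous predictors are z-standardized; DBH³ is
the standardized DBH cubed and re-standardized, taming the cubic
term's scale while keeping it collinear with DBH by design — the VIF
screen therefore exempts the DBH/DBH³ pair and otherwise drops the
highest-VIF predictor iteratively until all VIF ≤ 5 (VIF computed by
auxiliary regressions).

Random intercepts for subplot and census year are crossed (the model
adds them additively), implemented as variance components over a single
constant group and estimated by REML through statsmodels MixedLM; the
default optimizer is used with a Powell retry, since L-BFGS was
observed to stall on a spurious boundary optimum in variance-component
space. A random factor observed at a single level is dropped (it is
confounded with the intercept), so a one-subplot one-year frame
degenerates cleanly to OLS. R² is reported both marginally
(fixed-effects variance share, Nakagawa-style) and conditionally
(fixed plus random); a single undifferentiated R² is never printed.
RMSE/MAE are computed on the ln(BAI) scale from conditional predictions
(BLUPs obtained directly as `σ²_c Z_c' V⁻¹ (y − Xβ)`), with a
fixed-effects-only mode. Cross-validation deals whole subplots into
folds (no subplot spans folds); held-out subplots are predicted with
their random intercept at its prior mean of zero. When a thinning
treatment factor is included, the package warns that treatments are
unreplicated at plot level.

## Variance partitioning

The contribution of a predictor group is its Shapley value over group
orderings: the average R² increment when the group enters, over all
orderings (computed by exact subset enumeration, ≤ 8 groups). Averaged
increments telescope, so contributions sum to the full-model R² exactly
and shares sum to 100 %. Subset R² honours the mixed-model structure by
GLS: the full model's estimated covariance
`V = σ²_ε I + σ²_subplot Z_s Z_s' + σ²_year Z_y Z_y'` whitens the
response and design once (Cholesky), and every subset model is an OLS
fit on the whitened data — i.e. the random structure is held fixed at
the full-model estimate rather than refit per submodel. Plain-OLS and
refit-per-submodel modes exist for comparison. The default grouping is
individual {DBH, DBH³}, competition {BAL, FSS}, stand {Dg, N, Ddom},
plus treatment and species-cluster groups when present; a four-group
preset folds species into a single categorical group.

## Synthetic stands

The generator emulates the study conditions: 1-ha plots, 25 subplots,
~600 trees/ha, 19 species with geometrically decaying abundances (the
two rarest below any realistic retention count), shade-tolerance scores
spanning 0.5–4.5, per-species Weibull DBH distributions truncated at
5 cm and rescaled multiplicatively until stand basal area is within 5 %
of the 30 m²/ha pre-treatment target, censuses at years 0/2/4/7/11, and
one plot per thinning intensity 0/20/40/60 %.

Spatial pattern is CSR by default or a Thomas cluster process (parents
simulated in a 3σ guard buffer to avoid edge thinning). The thinning
operator follows target-tree marking rules: independent Bernoulli
defect marks (p = 0.05; prevalence is not documented, this is a
plausible managed-stand rate) are removed first, then trees drawn with
probability ∝ exp(w·(W_i − 0.5)) so clustered individuals go first,
subject to never removing species with fewer than 3 stems on the plot
and capping each subplot's removal at 1.5× the plot-level fraction,
until the removed fraction is within ±2 points of the target.
Residual + removed basal area equals the initial exactly by
construction.

Growth is simulated on the log scale with the same functional form the
analysis fits, with predictors recomputed on the residual stand at each
interval start and scaled by *fixed reference means/SDs* stored in the
config — not by sample z-scores — so the generating coefficients are a
well-defined estimand; `build_model_frame(..., scaling=...)` lets the
fit use the same reference. The default truth (β_DBH = 0.8 dominant,
γ_DBH³ = −0.12 as a mild size asymptote, positive BAL/FSS effects,
negative density effects, SDs 0.15/0.10/0.50 for subplot/year/residual)
produces realistic rate magnitudes and an R² in the 0.6–0.8 range. Year
intercepts are shared across plots (a common climate signal); subplot
intercepts and residuals are plot-specific. All output is a pure
function of (config, seed).

What the generator does **not** emulate: recruitment and natural
mortality (neither is quantified in the reference design; an optional
recruitment mode is out of the default path), measurement error on DBH,
crown/light competition mechanisms, climate trends, or topography.
Passing tests therefore demonstrate that the estimators recover the
assumed data-generating process at field-like sizes — not that the
model is correctly specified for any particular real forest.

## Problem sizes and tolerances

Default test and acceptance runs use one to four 1-ha plots
(~600 trees each, ~2,000 tree-intervals per plot), 20–25 replicate
stands for the CSR calibration of W, and 50 replicates for
coefficient-coverage checks — sizes chosen to match the reference
design while keeping a full run in minutes on one core. Numerical
tolerances: exact-arithmetic identities are asserted to 1e-9–1e-12;
eigenvalue and silhouette oracles to 1e-8–1e-10; REML-dependent
comparisons to optimizer tolerance (~1e-4); stochastic calibrations use
the documented reference intervals.
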