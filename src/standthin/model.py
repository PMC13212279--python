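"""Mixed-effects model of log basal-area increment.

The response is ln(BAI) per tree-interval; fixed effects are the
z-standardized predictors DBH, DBH^3, BAL, FSS, Dg, N, Ddom and optional
categorical terms (species cluster, thinning treatment); crossed random
intercepts for subplot and census year absorb within-plot spatial
grouping and between-census climate. The cubic diameter term captures
the decline of growth efficiency in the largest trees. Intervals with
BAI <= 0 carry no information on the log scale and are excluded (an
offset mode ln(BAI + 1) is available for sensitivity analysis).

Estimation is by REML through statsmodels' MixedLM, with the crossed
intercepts expressed as variance components over a single constant
group. Fit quality is summarized by marginal / conditional R^2
(fixed-effects-only vs fixed-plus-random variance shares), RMSE and MAE
on the ln(BAI) scale, AIC, and subplot-stratified 10-fold
cross-validation.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
import statsmodels.api as sm
import statsmodels.formula.api as smf

logger = logging.getLogger(__name__)

DEFAULT_PREDICTORS = ["DBH", "DBH3", "BAL", "FSS", "Dg", "N", "Ddom"]
#: designed polynomial pair, never dropped by the VIF screen
VIF_EXEMPT = frozenset({"DBH", "DBH3"})


@dataclass
class ModelFrame:
    """Standardized tree-interval design for the growth model."""

    data: pd.DataFrame  # ln_bai, predictors, subplot, year (+ factors)
    predictors: list[str]
    factors: list[str]
    scaling: pd.DataFrame  # rows mean/sd per standardized column
    n_excluded: int  # BAI <= 0 rows dropped before the log


@dataclass
class ModelFit:
    params: pd.Series
    se: pd.Series
    conf_int: pd.DataFrame
    vcomp: dict[str, float]  # random-intercept variances
    resid_var: float
    r2_marginal: float
    r2_conditional: float
    aic: float
    converged: bool
    formula: str
    result: object = field(repr=False)  # statsmodels MixedLMResults

    def predict_fixed(self, data: pd.DataFrame) -> np.ndarray:
        return np.asarray(self.result.predict(exog=data))


def build_model_frame(
    interval_table: pd.DataFrame,
    predictors: list[str] | None = None,
    factors: list[str] | None = None,
    scaling: pd.DataFrame | None = None,
    offset: float = 0.0,
) -> ModelFrame:
    """Assemble the standardized model frame from a tree-interval table.

    ``interval_table`` needs columns ``bai``, ``subplot``, ``year``, the
    raw predictors, and any factor columns. Rows with BAI <= offset are
    excluded (logged); the response is ln(BAI + offset). Continuous
    predictors are z-standardized with sample statistics unless an
    explicit ``scaling`` table (index mean/sd) is given — e.g. the
    reference scaling of a simulation's growth law, so fitted
    coefficients are directly comparable with the generating ones.
    DBH3 is the standardized DBH cubed and re-standardized, taming the
    scale of the polynomial term.
    """
    predictors = list(predictors) if predictors is not None else list(DEFAULT_PREDICTORS)
    factors = list(factors or [])
    df = interval_table.copy()
    usable = df["bai"] > -offset if offset > 0 else df["bai"] > 0
    n_excluded = int((~usable).sum())
    if n_excluded:
        logger.info("build_model_frame: %d interval(s) with BAI <= %g excluded",
                    n_excluded, -offset if offset else 0)
    df = df[usable].copy()
    if df.empty:
        raise ValueError("no usable tree-interval rows (all BAI <= 0)")
    df["ln_bai"] = np.log(df["bai"] + offset)

    base = [p for p in predictors if p != "DBH3"]
    missing = [p for p in base if p not in df.columns]
    if missing:
        raise ValueError(f"interval table missing predictors: {missing}")

    if scaling is None:
        means = df[base].mean()
        sds = df[base].std(ddof=1)
    else:
        means = scaling.loc["mean"].reindex(base)
        sds = scaling.loc["sd"].reindex(base)
    for p in base:
        if sds[p] == 0 or not np.isfinite(sds[p]):
            raise ValueError(f"predictor {p} has zero/invalid spread")
        df[p] = (df[p] - means[p]) / sds[p]

    if "DBH3" in predictors:
        cube = df["DBH"] ** 3
        if scaling is not None and "DBH3" in scaling.columns:
            m3, s3 = scaling.loc["mean", "DBH3"], scaling.loc["sd", "DBH3"]
        else:
            m3, s3 = cube.mean(), cube.std(ddof=1)
        df["DBH3"] = (cube - m3) / s3
        means["DBH3"], sds["DBH3"] = m3, s3

    scaling_out = pd.DataFrame({p: [means[p], sds[p]] for p in predictors},
                               index=["mean", "sd"])
    cols = ["ln_bai", *predictors, *factors, "subplot", "year", "tree_id"]
    cols = [c for c in cols if c in df.columns]
    return ModelFrame(
        data=df[cols].reset_index(drop=True),
        predictors=predictors,
        factors=factors,
        scaling=scaling_out,
        n_excluded=n_excluded,
    )


def vif_screen(
    frame: ModelFrame | pd.DataFrame,
    threshold: float = 5.0,
    exempt=VIF_EXEMPT,
):
    """Iteratively drop the highest-VIF predictor until all VIF <= threshold.

    VIF_j = 1 / (1 - R^2) of the auxiliary regression of predictor j on
    the remaining predictors. The designed polynomial pair DBH / DBH^3 is
    exempt from dropping (its collinearity is intentional). Returns
    (retained predictor list, VIF history table).
    """
    if isinstance(frame, ModelFrame):
        data, predictors = frame.data, list(frame.predictors)
    else:
        data, predictors = frame, [c for c in frame.columns]
    history = []
    step = 0
    while True:
        vifs = _vif_table(data, predictors)
        for name, v in vifs.items():
            history.append({"step": step, "predictor": name, "vif": v})
        droppable = {p: v for p, v in vifs.items() if p not in exempt and v > threshold}
        if not droppable:
            break
        worst = max(droppable, key=lambda p: (droppable[p], p))
        logger.info("vif_screen: dropping %s (VIF=%.2f)", worst, droppable[worst])
        predictors.remove(worst)
        step += 1
        if len(predictors) < 2:
            break
    return predictors, pd.DataFrame(history)


def _vif_table(data: pd.DataFrame, predictors: list[str]) -> dict[str, float]:
    x = data[predictors].to_numpy(dtype=float)
    out = {}
    for j, name in enumerate(predictors):
        others = np.delete(x, j, axis=1)
        X = sm.add_constant(others)
        r2 = sm.OLS(x[:, j], X).fit().rsquared
        out[name] = np.inf if r2 >= 1.0 else 1.0 / (1.0 - r2)
    return out


def _fixed_formula(predictors, factors) -> str:
    terms = list(predictors) + [f"C({f})" for f in factors]
    return "ln_bai ~ " + (" + ".join(terms) if terms else "1")


def fit_lmm(
    frame: ModelFrame,
    predictors: list[str] | None = None,
    factors: list[str] | None = None,
    reml: bool = True,
) -> ModelFit:
    """REML fit of ln(BAI) with crossed subplot and year random intercepts."""
    predictors = predictors if predictors is not None else frame.predictors
    factors = factors if factors is not None else frame.factors
    if "treatment" in factors:
        warnings.warn(
            "thinning treatment is applied at the whole-plot level and is "
            "unreplicated there; interpret its fixed effect cautiously",
            stacklevel=2,
        )
    data = frame.data.copy()
    data["_g"] = 1
    formula = _fixed_formula(predictors, factors)
    # a random factor with a single observed level is confounded with the
    # intercept; drop it so the fit degenerates gracefully (to OLS if both go)
    vc = {key: f"0 + C({key})" for key in ("subplot", "year")
          if data[key].nunique() > 1}
    if not vc:  # single subplot and single year: plain fixed-effects regression
        ols = smf.ols(formula, data).fit()
        var_f = float(np.var(np.asarray(ols.fittedvalues), ddof=0))
        denom = var_f + float(ols.mse_resid)
        return ModelFit(
            params=ols.params, se=ols.bse, conf_int=ols.conf_int(),
            vcomp={}, resid_var=float(ols.mse_resid),
            r2_marginal=var_f / denom, r2_conditional=var_f / denom,
            aic=float(ols.aic), converged=True, formula=formula, result=ols,
        )
    model = smf.mixedlm(formula, data, groups="_g", re_formula="0", vc_formula=vc)
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        result = model.fit(reml=reml)
        if not result.converged:
            result = model.fit(reml=reml, method="powell")
    if not result.converged:
        raise RuntimeError(
            f"mixed model did not converge; formula={formula!r}, "
            f"params so far: {result.params.to_dict()}"
        )
    vcomp = dict(zip(model.exog_vc.names, np.maximum(result.vcomp, 0.0)))
    for name, v in vcomp.items():
        if v < 1e-10:
            warnings.warn(f"random-intercept variance for {name} is ~0 (singular)",
                          stacklevel=2)
    fe_names = list(result.fe_params.index)
    var_f = float(np.var(np.asarray(result.predict(exog=data)), ddof=0))
    var_re = float(sum(vcomp.values()))
    var_e = float(result.scale)
    denom = var_f + var_re + var_e
    ci = result.conf_int().loc[fe_names]
    return ModelFit(
        params=result.fe_params,
        se=result.bse.loc[fe_names],
        conf_int=ci,
        vcomp=vcomp,
        resid_var=var_e,
        r2_marginal=var_f / denom,
        r2_conditional=(var_f + var_re) / denom,
        # statsmodels leaves AIC undefined under REML; -2 llf + 2 k on the
        # (restricted) likelihood with k = fixed effects + variance params
        aic=float(-2.0 * result.llf + 2.0 * (len(fe_names) + len(vcomp) + 1)),
        converged=bool(result.converged),
        formula=formula,
        result=result,
    )


def _blups(fit: ModelFit, frame: ModelFrame) -> tuple[pd.Series, pd.Series]:
    """Empirical best linear unbiased predictors of the random intercepts.

    u_hat_c = sigma2_c Z_c' V^-1 (y - X beta) with
    V = sigma2_e I + sum_c sigma2_c Z_c Z_c'.
    """
    data = frame.data
    y = data["ln_bai"].to_numpy()
    r = y - fit.predict_fixed(data)
    z_sub = pd.get_dummies(data["subplot"]).to_numpy(dtype=float)
    z_yr = pd.get_dummies(data["year"]).to_numpy(dtype=float)
    s_sub = fit.vcomp.get("subplot", 0.0)
    s_yr = fit.vcomp.get("year", 0.0)
    n = len(y)
    V = fit.resid_var * np.eye(n) + s_sub * z_sub @ z_sub.T + s_yr * z_yr @ z_yr.T
    vinv_r = np.linalg.solve(V, r)
    u_sub = pd.Series(s_sub * z_sub.T @ vinv_r, index=pd.get_dummies(data["subplot"]).columns)
    u_yr = pd.Series(s_yr * z_yr.T @ vinv_r, index=pd.get_dummies(data["year"]).columns)
    return u_sub, u_yr


def evaluate_fit(fit: ModelFit, frame: ModelFrame, conditional: bool = True) -> dict:
    """R^2 (marginal & conditional), RMSE and MAE on the ln(BAI) scale, AIC.

    RMSE/MAE use conditional predictions (fixed effects plus predicted
    random intercepts) by default; ``conditional=False`` for
    fixed-effects-only errors.
    """
    data = frame.data
    y = data["ln_bai"].to_numpy()
    pred = fit.predict_fixed(data)
    if conditional:
        u_sub, u_yr = _blups(fit, frame)
        pred = pred + data["subplot"].map(u_sub).to_numpy() + data["year"].map(u_yr).to_numpy()
    resid = y - pred
    return {
        "r2_marginal": fit.r2_marginal,
        "r2_conditional": fit.r2_conditional,
        "rmse": float(np.sqrt(np.mean(resid**2))),
        "mae": float(np.mean(np.abs(resid))),
        "aic": fit.aic,
    }


def cross_validate(
    frame: ModelFrame,
    folds: int = 10,
    predictors: list[str] | None = None,
    factors: list[str] | None = None,
    seed: int = 0,
) -> pd.DataFrame:
    """Subplot-stratified k-fold CV: no subplot spans folds.

    Subplots are shuffled once and dealt round-robin into folds; for each
    fold the model is refit on the remaining subplots and held-out rows
    are predicted from fixed effects plus the year intercepts (the
    subplot intercept of an unseen subplot is 0 by definition). Returns
    per-fold RMSE/MAE.
    """
    data = frame.data
    subplots = np.array(sorted(data["subplot"].unique()))
    if folds > len(subplots):
        raise ValueError(f"folds={folds} exceeds number of subplots ({len(subplots)})")
    rng = np.random.default_rng(seed)
    rng.shuffle(subplots)
    assignment = {sp: i % folds for i, sp in enumerate(subplots)}
    fold_of = data["subplot"].map(assignment)

    rows = []
    for f in range(folds):
        train = ModelFrame(
            data=data[fold_of != f].reset_index(drop=True),
            predictors=frame.predictors, factors=frame.factors,
            scaling=frame.scaling, n_excluded=0,
        )
        test = data[fold_of == f]
        fit = fit_lmm(train, predictors=predictors, factors=factors)
        _, u_yr = _blups(fit, train)
        pred = fit.predict_fixed(test) + test["year"].map(u_yr).fillna(0.0).to_numpy()
        resid = test["ln_bai"].to_numpy() - pred
        rows.append({
            "fold": f, "n_test": len(test),
            "rmse": float(np.sqrt(np.mean(resid**2))),
            "mae": float(np.mean(np.abs(resid))),
        })
    return pd.DataFrame(rows)
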