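"""Hierarchical partitioning of a growth model's explained variance.

Fixed-effect predictors are organised into named groups (default:
individual = {DBH, DBH3}, competition = {BAL, FSS}, treatment, stand =
{Dg, N, Ddom}, species = {cluster factor}); each group's independent
contribution is its Shapley value over group orderings — the average,
over all orderings, of the R^2 increase when the group enters the model.
Averaged increments telescope, so the contributions sum exactly to the
full-model R^2; shares are reported as percentages of it.

Subset R^2 values honour the mixed-model structure by generalized
least squares: the full model's estimated random-intercept covariance
whitens the response and design once, and every subset model is an OLS
fit on the whitened data. Plain OLS and refit-per-submodel mixed-model
modes are also available. Enumeration over the 2^g subsets is exact and
limited to g <= 8 groups.
"""

from __future__ import annotations

from itertools import combinations
from math import comb

import numpy as np
import pandas as pd

from .model import ModelFrame, _fixed_formula, fit_lmm

DEFAULT_GROUPING = {
    "individual": ["DBH", "DBH3"],
    "competition": ["BAL", "FSS"],
    "stand": ["Dg", "N", "Ddom"],
}

MAX_GROUPS = 8


def _design(frame: ModelFrame, predictors, factors) -> np.ndarray:
    """Design columns (no intercept) for a set of predictors/factors."""
    data = frame.data
    cols = [data[p].to_numpy(dtype=float) for p in predictors]
    for f in factors:
        dummies = pd.get_dummies(data[f], drop_first=True)
        cols.extend(dummies[c].to_numpy(dtype=float) for c in dummies.columns)
    if not cols:
        return np.empty((len(data), 0))
    return np.column_stack(cols)


def _whitener(frame: ModelFrame, full_fit) -> np.ndarray:
    """Inverse Cholesky factor of the full model's marginal covariance."""
    data = frame.data
    z_sub = pd.get_dummies(data["subplot"]).to_numpy(dtype=float)
    z_yr = pd.get_dummies(data["year"]).to_numpy(dtype=float)
    V = (
        full_fit.resid_var * np.eye(len(data))
        + full_fit.vcomp.get("subplot", 0.0) * z_sub @ z_sub.T
        + full_fit.vcomp.get("year", 0.0) * z_yr @ z_yr.T
    )
    L = np.linalg.cholesky(V)
    return np.linalg.inv(L)


def _r2_ols(y: np.ndarray, X: np.ndarray) -> float:
    """R^2 of y on [1, X] by least squares."""
    X1 = np.column_stack([np.ones(len(y)), X])
    beta, *_ = np.linalg.lstsq(X1, y, rcond=None)
    resid = y - X1 @ beta
    tss = float(np.sum((y - y.mean()) ** 2))
    return 1.0 - float(np.sum(resid**2)) / tss


def subset_r2(
    frame: ModelFrame,
    grouping: dict[str, list[str]],
    subset: tuple[str, ...],
    method: str = "gls",
    whitener: np.ndarray | None = None,
) -> float:
    """R^2 of the model containing exactly the given groups' fixed effects.

    ``gls`` (default): OLS on data whitened by the full model's random
    structure (pass a precomputed ``whitener`` to amortize the Cholesky).
    ``ols``: plain OLS R^2. ``lmm``: refit the mixed model for the subset
    and report its marginal R^2 (falls back to OLS on non-convergence).
    The empty subset gives 0 by definition.
    """
    if not subset:
        return 0.0
    predictors = [p for g in subset for p in grouping[g] if p in frame.data.columns
                  and frame.data[p].dtype.kind in "fiu"]
    factors = [p for g in subset for p in grouping[g] if p not in predictors]
    y = frame.data["ln_bai"].to_numpy(dtype=float)
    X = _design(frame, predictors, factors)
    if method == "ols":
        return _r2_ols(y, X)
    if method == "gls":
        if whitener is None:
            whitener = _whitener(frame, fit_lmm(frame))
        return _r2_ols(whitener @ y, whitener @ X)
    if method == "lmm":
        try:
            fit = fit_lmm(frame, predictors=predictors, factors=factors)
            return fit.r2_marginal
        except RuntimeError:
            return _r2_ols(y, X)
    raise ValueError(f"unknown method {method!r}")


def hierarchical_partition(
    frame: ModelFrame,
    grouping: dict[str, list[str]] | None = None,
    method: str = "gls",
) -> pd.DataFrame:
    """Independent contribution and share of each predictor group.

    Returns a table with, per group, the standalone R^2, the Shapley
    (ordering-averaged) independent contribution, and the share as a
    percentage of the full-model R^2. A ``subset_r2_table`` attribute on
    the result records every subset's R^2.
    """
    grouping = dict(grouping or _default_grouping(frame))
    groups = list(grouping)
    g = len(groups)
    if g > MAX_GROUPS:
        raise ValueError(
            f"{g} groups would need {2**g} submodels; merge groups (max {MAX_GROUPS})"
        )
    seen: set[str] = set()
    for name, preds in grouping.items():
        dup = seen & set(preds)
        if dup:
            raise ValueError(f"predictor(s) {sorted(dup)} appear in multiple groups")
        seen |= set(preds)

    whitener = _whitener(frame, fit_lmm(frame)) if method == "gls" else None
    r2: dict[frozenset, float] = {}
    subset_rows = []
    for size in range(g + 1):
        for subset in combinations(groups, size):
            val = subset_r2(frame, grouping, subset, method=method, whitener=whitener)
            r2[frozenset(subset)] = val
            subset_rows.append({"subset": "+".join(subset) or "(none)", "r2": val})

    total = r2[frozenset(groups)]
    rows = []
    for grp in groups:
        others = [x for x in groups if x != grp]
        contrib = 0.0
        for size in range(g):
            weight = 1.0 / (g * comb(g - 1, size))
            for subset in combinations(others, size):
                s = frozenset(subset)
                contrib += weight * (r2[s | {grp}] - r2[s])
        rows.append({
            "group": grp,
            "standalone_r2": r2[frozenset([grp])],
            "contribution": contrib,
            "share_pct": 100.0 * contrib / total if total > 0 else np.nan,
        })
    out = pd.DataFrame(rows)
    out.attrs["subset_r2_table"] = pd.DataFrame(subset_rows)
    out.attrs["full_r2"] = total
    return out


def _default_grouping(frame: ModelFrame) -> dict[str, list[str]]:
    grouping = {k: [p for p in v if p in frame.predictors]
                for k, v in DEFAULT_GROUPING.items()}
    if "treatment" in frame.factors:
        grouping["treatment"] = ["treatment"]
    if "cluster" in frame.factors:
        grouping["species"] = ["cluster"]
    return {k: v for k, v in grouping.items() if v}


def four_group_preset(frame: ModelFrame) -> dict[str, list[str]]:
    """Four-group scheme: species folded into the categorical/treatment group."""
    grouping = _default_grouping(frame)
    cats = grouping.pop("treatment", []) + grouping.pop("species", [])
    if cats:
        grouping["categorical"] = cats
    return grouping
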