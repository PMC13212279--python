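"""Tree- and stand-level growth statistics and recovery trajectories.

Tree level: basal area from DBH, periodic annual basal-area increment
(BAI, cm2/yr), and the Pressler mean annual growth percentage

    BA_rate = (BA_t - BA_{t-n}) / (BA_t + BA_{t-n}) * 200 / n   (%/yr),

a relative rate against the period-average basal area. Competition is
summarized by BAL, the summed basal area of strictly larger trees.

Stand level: per-subplot density N (trees/ha), quadratic mean diameter
Dg = sqrt(mean d^2), dominant diameter Ddom (mean DBH of the four
largest trees per 400 m2 subplot, i.e. one dominant per 100 m2), and
total basal area (m2/ha); annualized percentage change of subplot basal
area per study period; and OLS recovery fits of plot basal area against
year with extrapolated crossing times versus a pre-thinning baseline or
a control trajectory.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats

logger = logging.getLogger(__name__)

SUBPLOT_AREA_HA = 0.04  # 20 m x 20 m
N_DOMINANT = 4  # one dominant tree per 100 m2 in a 400 m2 subplot


@dataclass(frozen=True)
class GrowthInterval:
    """Growth of one tree over one census interval."""

    tree_id: str
    start_year: int
    end_year: int
    ba_start: float  # cm2
    ba_end: float
    n: float  # yr

    @property
    def bai(self) -> float:
        """Periodic annual basal-area increment, cm2/yr."""
        return (self.ba_end - self.ba_start) / self.n

    @property
    def ba_rate(self) -> float:
        """Pressler mean annual growth percentage, %/yr."""
        return pressler_rate(self.ba_start, self.ba_end, self.n)


@dataclass
class StandSummary:
    subplot: tuple[int, int] | None
    census_year: int
    n_per_ha: float
    ba_m2_ha: float
    dg: float
    ddom: float
    ddom_flagged: bool = False  # fewer than 4 trees available


@dataclass
class RecoveryFit:
    plot_id: str
    slope: float  # m2 ha-1 yr-1
    intercept: float
    r_squared: float
    baseline_crossing_year: float | None = None  # calendar year, None = not reached
    control_crossing_year: float | None = None
    years_to_baseline: float | None = field(default=None)
    years_to_control: float | None = field(default=None)

    def predict(self, year) -> np.ndarray:
        return self.intercept + self.slope * np.asarray(year, dtype=float)


def basal_area(dbh):
    """Basal area pi (d/2)^2 in cm2 from DBH in cm."""
    d = np.asarray(dbh, dtype=float)
    if np.any(d <= 0):
        raise ValueError("DBH must be positive")
    out = np.pi * (d / 2.0) ** 2
    return float(out) if np.isscalar(dbh) else out


def dbh_from_basal_area(ba):
    """Inverse of :func:`basal_area`: d = 2 sqrt(BA / pi)."""
    ba = np.asarray(ba, dtype=float)
    if np.any(ba <= 0):
        raise ValueError("basal area must be positive")
    out = 2.0 * np.sqrt(ba / np.pi)
    return float(out) if out.ndim == 0 else out


def pressler_rate(ba_start, ba_end, n):
    """Mean annual growth percentage relative to the period-average basal area."""
    ba_start = np.asarray(ba_start, dtype=float)
    ba_end = np.asarray(ba_end, dtype=float)
    if np.any(ba_start <= 0) or np.any(ba_end <= 0):
        raise ValueError("basal areas must be positive")
    if np.any(np.asarray(n) <= 0):
        raise ValueError("interval length must be positive")
    out = (ba_end - ba_start) / (ba_end + ba_start) * 200.0 / n
    return float(out) if out.ndim == 0 else out


def growth_intervals(histories) -> list[GrowthInterval]:
    """Per-tree census-pair growth intervals from linked histories.

    Trees lacking either endpoint of a pair (recruited, removed, dead, or
    an excluded shrinkage interval) are skipped and counted in the log.
    """
    out: list[GrowthInterval] = []
    skipped = 0
    for h in histories.values():
        ivals = h.intervals()
        skipped += max(len(h.years) - 1, 0) - len(ivals)
        for (y0, y1, d0, d1) in ivals:
            out.append(
                GrowthInterval(
                    tree_id=h.tree_id,
                    start_year=y0,
                    end_year=y1,
                    ba_start=basal_area(d0),
                    ba_end=basal_area(d1),
                    n=float(y1 - y0),
                )
            )
    if skipped:
        logger.info("growth_intervals: %d interval(s) excluded", skipped)
    return out


def bal(trees: pd.DataFrame, scope: str = "subplot") -> pd.Series:
    """Basal area of larger trees (cm2) for every live tree of one census.

    For each subject, the summed basal area of live trees with strictly
    greater DBH, within the subject's subplot (default) or the whole plot.
    """
    live = trees[trees["status"] == "live"] if "status" in trees.columns else trees
    ba = basal_area(live["dbh"].to_numpy())
    if scope == "plot":
        keys = pd.Series(0, index=live.index)
    elif scope == "subplot":
        keys = live["subplot_row"].astype(int) * 1000 + live["subplot_col"].astype(int)
    else:
        raise ValueError(f"unknown scope {scope!r}")

    out = np.empty(len(live))
    df = pd.DataFrame({"dbh": live["dbh"].to_numpy(), "ba": ba, "key": np.asarray(keys)})
    for _, grp in df.groupby("key"):
        # sort descending by DBH; cumulative BA of strictly larger trees
        order = np.argsort(-grp["dbh"].to_numpy(), kind="stable")
        d_sorted = grp["dbh"].to_numpy()[order]
        ba_sorted = grp["ba"].to_numpy()[order]
        cum = np.concatenate([[0.0], np.cumsum(ba_sorted)[:-1]])
        # equal DBH values share the BAL of the first of their run
        vals = np.empty(len(grp))
        i = 0
        while i < len(grp):
            j = i
            while j < len(grp) and d_sorted[j] == d_sorted[i]:
                j += 1
            vals[i:j] = cum[i]
            i = j
        res = np.empty(len(grp))
        res[order] = vals
        out[df.index.get_indexer(grp.index)] = res
    return pd.Series(out, index=live.index, name="bal")


def stand_summary(trees: pd.DataFrame, census_year: int,
                  subplot: tuple[int, int] | None = None,
                  area_ha: float = SUBPLOT_AREA_HA) -> StandSummary:
    """Summary statistics for the live trees of one subplot (0.04 ha) census."""
    live = trees[trees["status"] == "live"] if "status" in trees.columns else trees
    d = live["dbh"].to_numpy(dtype=float)
    n = len(d)
    if n == 0:
        return StandSummary(subplot, census_year, 0.0, 0.0, np.nan, np.nan, True)
    dg = float(np.sqrt(np.mean(d * d)))
    flagged = n < N_DOMINANT
    if flagged:
        logger.warning("stand_summary: only %d tree(s) for Ddom (needs %d)", n, N_DOMINANT)
    # ties among the four largest broken by tree id for determinism
    order = sorted(range(n), key=lambda i: (-d[i], str(live["tree_id"].iloc[i])))
    ddom = float(np.mean(d[order[:N_DOMINANT]]))
    ba_total = float(np.sum(basal_area(d)))  # cm2
    return StandSummary(
        subplot=subplot,
        census_year=census_year,
        n_per_ha=n / area_ha,
        ba_m2_ha=ba_total / 1e4 / area_ha,
        dg=dg,
        ddom=ddom,
        ddom_flagged=flagged,
    )


def subplot_ba_table(inventories, include_recruits: bool = True) -> pd.DataFrame:
    """Total live basal area (m2/ha) per subplot per census.

    ``include_recruits=False`` restricts every census to the ids present
    live at the earliest census (cohort-fixed mode for growth-only
    decomposition).
    """
    invs = sorted(inventories, key=lambda inv: inv.census_year)
    baseline_ids = set(invs[0].live()["tree_id"].astype(str))
    rows = []
    for inv in invs:
        live = inv.live()
        if not include_recruits:
            live = live[live["tree_id"].astype(str).isin(baseline_ids)]
        grp = live.groupby(["subplot_row", "subplot_col"])
        for (r, c), g in grp:
            ba = float(np.sum(basal_area(g["dbh"].to_numpy()))) / 1e4 / SUBPLOT_AREA_HA
            rows.append({"subplot_row": r, "subplot_col": c,
                         "year": inv.census_year, "ba_m2_ha": ba})
    return pd.DataFrame(rows)


def ba_change_series(
    inventories,
    periods: list[tuple[int, int]] | None = None,
    include_recruits: bool = True,
    method: str = "pressler",
) -> pd.DataFrame:
    """Annualized percentage change of subplot basal area per study period.

    For each period, the rate is computed per subplot from its total live
    basal area at the period endpoints — by default with the Pressler
    form, alternatively as a compound rate ((BA_t/BA_{t-n})^(1/n) - 1)*100
    — then summarized as mean +/- SD over the subplots. Subplots with zero
    basal area at either endpoint are excluded and logged.
    """
    table = subplot_ba_table(inventories, include_recruits=include_recruits)
    years = sorted(table["year"].unique())
    if periods is None:
        periods = [(years[i], years[i + 1]) for i in range(len(years) - 1)]
        if len(years) > 2:
            periods.append((years[0], years[-1]))
    wide = table.pivot_table(index=["subplot_row", "subplot_col"],
                             columns="year", values="ba_m2_ha")
    rows = []
    for (y0, y1) in periods:
        if y0 not in wide.columns or y1 not in wide.columns:
            raise ValueError(f"no census for period {y0}-{y1}")
        b0, b1 = wide[y0], wide[y1]
        ok = (b0 > 0) & (b1 > 0)
        if (~ok).any():
            logger.warning("period %d-%d: %d subplot(s) with zero BA excluded",
                           y0, y1, int((~ok).sum()))
        n = y1 - y0
        if method == "pressler":
            rates = pressler_rate(b0[ok].to_numpy(), b1[ok].to_numpy(), n)
        elif method == "compound":
            rates = ((b1[ok] / b0[ok]) ** (1.0 / n) - 1.0).to_numpy() * 100.0
        else:
            raise ValueError(f"unknown method {method!r}")
        rows.append({
            "period": f"{y0}-{y1}", "start_year": y0, "end_year": y1,
            "mean": float(np.mean(rates)),
            "sd": float(np.std(rates, ddof=1)) if len(rates) > 1 else 0.0,
            "n_subplots": int(ok.sum()),
        })
    return pd.DataFrame(rows)


def plot_ba_series(inventories, include_recruits: bool = True) -> pd.DataFrame:
    """Plot-level live basal area (m2/ha) per census year."""
    tab = subplot_ba_table(inventories, include_recruits=include_recruits)
    out = tab.groupby("year")["ba_m2_ha"].mean()  # mean of per-ha subplot values
    return out.reset_index()


def recovery_fit(
    years,
    ba,
    plot_id: str = "plot",
    baseline: float | None = None,
    control_fit: "RecoveryFit | None" = None,
    thinning_year: float | None = None,
) -> RecoveryFit:
    """OLS trend of plot basal area vs year, with extrapolated crossings.

    ``baseline`` is a constant pre-thinning basal area; the crossing with
    the control is taken against the control's fitted line, not its raw
    values. A crossing is reported only if it lies at or after the
    thinning year and the treated line approaches from below; parallel or
    diverging geometries give ``None`` (not reached).
    """
    years = np.asarray(years, dtype=float)
    ba = np.asarray(ba, dtype=float)
    if len(years) < 3:
        raise ValueError("need at least 3 census points")
    res = stats.linregress(years, ba)
    fit = RecoveryFit(
        plot_id=plot_id,
        slope=float(res.slope),
        intercept=float(res.intercept),
        r_squared=float(res.rvalue ** 2),
    )
    t0 = thinning_year if thinning_year is not None else years[0]

    if baseline is not None:
        if fit.slope > 0 or (fit.slope == 0 and fit.intercept >= baseline):
            if fit.slope == 0:
                cross = t0 if fit.intercept >= baseline else None
            else:
                cross = (baseline - fit.intercept) / fit.slope
            if cross is not None and cross >= t0:
                fit.baseline_crossing_year = float(cross)
                fit.years_to_baseline = float(cross - t0)
        if fit.baseline_crossing_year is None:
            logger.info("%s: baseline not reached under fitted trend", plot_id)

    if control_fit is not None:
        ds = fit.slope - control_fit.slope
        di = control_fit.intercept - fit.intercept
        below_now = fit.predict(t0) < control_fit.predict(t0)
        if ds != 0:
            cross = di / ds
            # a meaningful catch-up crossing: ahead of thinning, treated
            # approaching the control from below
            if cross >= t0 and below_now and ds > 0:
                fit.control_crossing_year = float(cross)
                fit.years_to_control = float(cross - t0)
            elif not below_now:
                fit.control_crossing_year = float(t0)
                fit.years_to_control = 0.0
        elif not below_now:
            fit.control_crossing_year = float(t0)
            fit.years_to_control = 0.0
        if fit.control_crossing_year is None:
            logger.info("%s: control trajectory not reached", plot_id)
    return fit
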