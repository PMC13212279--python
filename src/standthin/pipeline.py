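"""End-to-end glue: censuses -> per-interval predictor/response table.

For each consecutive census pair of a plot, every tree live at both
endpoints contributes one row: its basal-area increment (BAI) over the
interval as the response, and the start-of-interval predictors — DBH,
BAL (subplot scope), the composite structure score FSS, the subplot's
Dg / N / Ddom, and the species' shade-tolerance score — following the
convention that tree size and competition are measured at the beginning
of the period.
"""

from __future__ import annotations

import numpy as np
import pandas as pd

from .growth import bal as bal_fn
from .growth import basal_area, stand_summary
from .inventory import CensusInventory
from .spatial import compute_structure


def interval_predictor_table(inv: CensusInventory, traits: dict) -> pd.DataFrame:
    """Start-of-interval predictors for every live tree of one census."""
    live = inv.live()
    structure = compute_structure(inv).set_index("tree_id")
    bal_series = bal_fn(inv.trees, scope="subplot")
    sub_stats = {}
    for (r, c), grp in live.groupby(["subplot_row", "subplot_col"]):
        s = stand_summary(grp, inv.census_year, subplot=(r, c))
        sub_stats[(r, c)] = (s.dg, s.n_per_ha, s.ddom)
    ids = live["tree_id"].astype(str)
    stats = [sub_stats[(r, c)] for r, c in zip(live["subplot_row"], live["subplot_col"])]
    dg, n_ha, ddom = map(np.array, zip(*stats))
    missing = sorted(set(live["species"]) - set(traits))
    if missing:
        raise ValueError(f"species absent from trait table: {missing}")
    return pd.DataFrame({
        "tree_id": ids.to_numpy(),
        "species": live["species"].to_numpy(),
        "subplot_row": live["subplot_row"].to_numpy(),
        "subplot_col": live["subplot_col"].to_numpy(),
        "DBH": live["dbh"].to_numpy(dtype=float),
        "BAL": bal_series.loc[live.index].to_numpy(),
        "M": structure["M"].reindex(ids).to_numpy(),
        "W": structure["W"].reindex(ids).to_numpy(),
        "U": structure["U"].reindex(ids).to_numpy(),
        "FSS": structure["FSS"].reindex(ids).to_numpy(),
        "Dg": dg, "N": n_ha, "Ddom": ddom,
        "SST": np.array([traits[s] for s in live["species"]]),
    })


def build_interval_table(
    inventories: list[CensusInventory],
    traits: dict,
    cluster_map: dict | None = None,
) -> pd.DataFrame:
    """One row per tree x interval for the censuses of one plot.

    Adds ``bai`` (cm2/yr), plot-qualified ``subplot`` and end-year
    ``year`` grouping keys, and the plot's ``treatment``; ``cluster_map``
    (species -> functional group) adds a ``cluster`` factor column.
    """
    invs = sorted(inventories, key=lambda inv: inv.census_year)
    if len(invs) < 2:
        raise ValueError("need at least two censuses")
    plot_id = invs[0].plot_id
    rows = []
    for inv0, inv1 in zip(invs[:-1], invs[1:]):
        pred = interval_predictor_table(inv0, traits)
        live1 = inv1.live()
        dbh1 = dict(zip(live1["tree_id"].astype(str), live1["dbh"].astype(float)))
        n = inv1.census_year - inv0.census_year
        pred = pred[pred["tree_id"].isin(dbh1)].copy()
        ba0 = basal_area(pred["DBH"].to_numpy())
        ba1 = basal_area(np.array([dbh1[t] for t in pred["tree_id"]]))
        pred["bai"] = (ba1 - ba0) / n
        pred["year"] = inv1.census_year
        pred["subplot"] = [
            f"{plot_id}:{r}{c}" for r, c in zip(pred["subplot_row"], pred["subplot_col"])
        ]
        pred["treatment"] = inv0.treatment
        rows.append(pred)
    out = pd.concat(rows, ignore_index=True)
    if cluster_map is not None:
        out["cluster"] = out["species"].map(cluster_map)
        if out["cluster"].isna().any():
            miss = sorted(out.loc[out["cluster"].isna(), "species"].unique())
            raise ValueError(f"species without cluster assignment: {miss}")
    return out
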