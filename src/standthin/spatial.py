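"""Nearest-neighbour stand-structure indices and their composite.

For each reference tree and its n = 4 nearest neighbours:

* mingling M — fraction of neighbours of a different species
  (spatial segregation of species);
* uniform angle index W — fraction of angular gaps between successive
  neighbour directions smaller than the standard angle alpha = 72 deg
  (low = regular, ~0.5 = random, high = clumped; the random-pattern
  reference interval is [0.475, 0.517]);
* dominance U — fraction of neighbours with strictly larger DBH
  (low = locally dominant reference tree).

The three raw indices are mapped onto standardized 0-1 scores (a
piecewise table that rewards randomness of W and local dominance) and
combined into a composite forest-spatial-structure score FSS by the
unit-circle (root-mean-square) method.

Edge effects are handled with a buffer: trees within ``buffer`` metres
of the plot boundary serve as neighbours but not as reference trees.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.spatial import cKDTree

logger = logging.getLogger(__name__)

W_RANDOM_LOW = 0.475
W_RANDOM_HIGH = 0.517


@dataclass(frozen=True)
class NeighborSet:
    """The n nearest neighbours of one reference tree, ordered by distance."""

    tree_id: str
    neighbor_ids: tuple[str, ...]
    distances: tuple[float, ...]
    azimuths: tuple[float, ...]  # degrees in [0, 360)


def _azimuth_deg(dx: np.ndarray, dy: np.ndarray) -> np.ndarray:
    """Bearing from reference to neighbour, clockwise from north, [0, 360)."""
    return np.degrees(np.arctan2(dx, dy)) % 360.0


def nearest_neighbors(
    coords: np.ndarray,
    tree_ids,
    n: int = 4,
) -> list[NeighborSet]:
    """n nearest neighbours of every tree by Euclidean distance.

    Distance ties are broken by the smaller tree id. Raises if any two
    trees share coordinates (the angular gaps would be undefined) or if
    fewer than ``n`` candidates exist.
    """
    coords = np.asarray(coords, dtype=float)
    tree_ids = list(map(str, tree_ids))
    n_trees = len(coords)
    if n_trees < n + 1:
        raise ValueError(f"need at least {n + 1} trees, have {n_trees}")

    tree = cKDTree(coords)
    # query extra candidates so float-equal distances can be re-ordered by id
    k = min(n_trees, n + 5)
    dists, idx = tree.query(coords, k=k)

    out: list[NeighborSet] = []
    for i in range(n_trees):
        cand = [(dists[i, j], tree_ids[idx[i, j]], idx[i, j])
                for j in range(k) if idx[i, j] != i]
        cand.sort(key=lambda c: (c[0], c[1]))
        chosen = cand[:n]
        if chosen[0][0] == 0.0:
            raise ValueError(
                f"coincident coordinates: trees {tree_ids[i]} and {chosen[0][1]}"
            )
        # ties across the candidate horizon are resolved exactly as long as
        # the (n+1)-th distinct distance is inside the queried k; with k=n+5
        # that covers any realistic field data and all lattice fixtures
        js = np.array([c[2] for c in chosen])
        d = coords[js] - coords[i]
        out.append(
            NeighborSet(
                tree_id=tree_ids[i],
                neighbor_ids=tuple(tree_ids[j] for j in js),
                distances=tuple(float(c[0]) for c in chosen),
                azimuths=tuple(_azimuth_deg(d[:, 0], d[:, 1])),
            )
        )
    return out


def mingling(reference_species: str, neighbor_species) -> float:
    """Fraction of neighbours belonging to a different species."""
    ns = list(neighbor_species)
    return sum(s != reference_species for s in ns) / len(ns)


def uniform_angle_index(azimuths, alpha: float = 72.0) -> float:
    """Fraction of angular gaps between successive neighbour directions < alpha.

    The directions are sorted; the n gaps (including the wrap-around one)
    are each taken as min(theta, 360 - theta).
    """
    az = np.sort(np.asarray(azimuths, dtype=float) % 360.0)
    gaps = np.diff(np.concatenate([az, [az[0] + 360.0]]))
    gaps = np.minimum(gaps, 360.0 - gaps)
    return float(np.mean(gaps < alpha))


def dominance(reference_dbh: float, neighbor_dbh) -> float:
    """Fraction of neighbours with DBH strictly greater than the reference."""
    nd = np.asarray(list(neighbor_dbh), dtype=float)
    return float(np.mean(nd > reference_dbh))


def standardize_scores(m: float, w: float, u: float) -> tuple[float, float, float]:
    """Map raw (M, W, U) onto standardized 0-1 scores.

    M is taken at its measured value. W keeps its measured value below the
    random interval, scores 1.0 inside [0.475, 0.517] (random spacing is
    the ideal), and 0.5 above (clumped). U is rewarded for local dominance:
    1.0 below 0.47, stepping down 0.75 / 0.5 / 0.25 across 0.47-0.49 /
    0.49-0.51 / 0.51-0.53, and 0.0 above 0.53.
    """
    for name, v in (("M", m), ("W", w), ("U", u)):
        if not 0.0 <= v <= 1.0:
            raise ValueError(f"{name}={v} outside [0, 1]")
    r_m = m
    if w < W_RANDOM_LOW:
        r_w = w
    elif w <= W_RANDOM_HIGH:
        r_w = 1.0
    else:
        r_w = 0.5
    if u < 0.47:
        r_u = 1.0
    elif u < 0.49:
        r_u = 0.75
    elif u <= 0.51:
        r_u = 0.5
    elif u <= 0.53:
        r_u = 0.25
    else:
        r_u = 0.0
    return r_m, r_w, r_u


def fss(r_m: float, r_w: float, r_u: float, method: str = "rms") -> float:
    """Composite structure score from the standardized scores.

    ``rms`` (default): sqrt(mean of squares), the unit-circle form, so the
    score stays in [0, 1]. ``mean_sq``: plain mean of squares.
    """
    sq = (r_m * r_m + r_w * r_w + r_u * r_u) / 3.0
    if method == "rms":
        return float(np.sqrt(sq))
    if method == "mean_sq":
        return float(sq)
    raise ValueError(f"unknown method {method!r}")


def compute_structure(
    inventory,
    n: int = 4,
    alpha: float = 72.0,
    buffer: float = 5.0,
    fss_method: str = "rms",
) -> pd.DataFrame:
    """Per-tree structure table for the live trees of one census.

    Returns one row per live tree: M, W, U, the standardized scores,
    FSS, and ``edge_flag`` (True = inside the buffered core, usable as a
    reference tree). Indices are computed for every tree; stand summaries
    should average over ``edge_flag`` trees only.
    """
    from .inventory import to_plot_coordinates

    live = inventory.live()
    if "x_global" not in live.columns:
        live = to_plot_coordinates(inventory).live()
    coords = live[["x_global", "y_global"]].to_numpy(dtype=float)
    ids = live["tree_id"].astype(str).to_numpy()
    species = dict(zip(ids, live["species"].astype(str)))
    dbh = dict(zip(ids, live["dbh"].astype(float)))

    ex, ey = inventory.plot_extent
    x, y = coords[:, 0], coords[:, 1]
    interior = (x >= buffer) & (x <= ex - buffer) & (y >= buffer) & (y <= ey - buffer)

    neigh = nearest_neighbors(coords, ids, n=n)
    rows = []
    for ns, inside in zip(neigh, interior):
        m = mingling(species[ns.tree_id], [species[j] for j in ns.neighbor_ids])
        w = uniform_angle_index(ns.azimuths, alpha=alpha)
        u = dominance(dbh[ns.tree_id], [dbh[j] for j in ns.neighbor_ids])
        r_m, r_w, r_u = standardize_scores(m, w, u)
        rows.append(
            {
                "tree_id": ns.tree_id,
                "M": m, "W": w, "U": u,
                "R_M": r_m, "R_W": r_w, "R_U": r_u,
                "FSS": fss(r_m, r_w, r_u, method=fss_method),
                "edge_flag": bool(inside),
            }
        )
    out = pd.DataFrame(rows)
    out.insert(1, "census_year", inventory.census_year)
    return out


def stand_structure_summary(
    structure: pd.DataFrame,
    inventory=None,
) -> tuple[pd.DataFrame, pd.Series]:
    """Subplot and plot means of M, W, U, FSS over interior reference trees.

    Returns ``(per_subplot, per_plot)``; counts of contributing trees are
    included. Raises if the buffered interior is empty.
    """
    core = structure[structure["edge_flag"]]
    if core.empty:
        raise ValueError("no interior reference trees inside the buffer")
    cols = ["M", "W", "U", "FSS"]
    plot_means = core[cols].mean()
    plot_means["n_trees"] = len(core)
    if inventory is None:
        return pd.DataFrame(), plot_means
    sub = inventory.trees[["tree_id", "subplot_row", "subplot_col"]].copy()
    sub["tree_id"] = sub["tree_id"].astype(str)
    merged = core.merge(sub, on="tree_id", how="left")
    per_subplot = (
        merged.groupby(["subplot_row", "subplot_col"])[cols]
        .agg(["mean", "count"])
    )
    return per_subplot, plot_means
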