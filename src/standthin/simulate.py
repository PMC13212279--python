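"""Synthetic multi-census stand generator with a thinning operator.

Emulates the study system end to end with known ground truth: 1-ha
plots (25 subplots of 20 m x 20 m) holding a 19-species mixture at
~600 trees/ha and ~30 m2/ha basal area, censused at years 0/2/4/7/11,
with a structure-based thinning at year 0 targeting 0/20/40/60 %
basal-area removal.

Spatial pattern is complete spatial randomness (homogeneous Poisson) or
a Thomas cluster process. Species are drawn by configured abundances,
diameters from per-species Weibull distributions truncated at the 5-cm
inventory threshold and rescaled to hit the basal-area target. Growth
follows the same log-linear law the analysis model assumes —
ln(BAI) = beta0 + beta.x + gamma DBH^3 + u_subplot + v_year + eps — with
predictors recomputed on the residual stand each interval and scaled by
FIXED reference means/SDs, so the generating coefficients are a
well-defined truth for parameter-recovery tests.

The thinning operator follows the marking rules of target-tree
silviculture: defect-marked trees are removed first, then clustered
individuals (removal probability increasing in the uniform angle
index), while rare species are never removed below a retention count
and no subplot loses disproportionately more than the plot-level
fraction.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd

from .growth import basal_area, dbh_from_basal_area
from .inventory import CensusInventory, from_plot_coordinates
from .spatial import compute_structure

DEFAULT_CENSUS_OFFSETS = (0, 2, 4, 7, 11)


def default_species_pool() -> pd.DataFrame:
    """A 19-species mixture with contrasting abundance/size/tolerance profiles.

    Abundances decay roughly geometrically (a few dominants, a long tail
    with two rare species below any realistic retention threshold); shade
    tolerance spans the 0-5 score range; pioneer (low-tolerance) species
    get larger Weibull scales, mimicking large early colonists.
    """
    codes = [f"SP{i:02d}" for i in range(1, 20)]
    raw = 0.72 ** np.arange(19)
    raw[-2:] = raw[-2:] * 0.5  # push the two rarest below ~3 expected stems
    abundance = raw / raw.sum()
    sst = np.round(np.linspace(0.5, 4.5, 19)[::-1], 2)  # dominants more tolerant
    shape = np.full(19, 2.0)
    scale = np.round(np.linspace(18.0, 10.0, 19)[::-1] + 4.0 * (sst < 2.0), 2)
    return pd.DataFrame({
        "species": codes, "abundance": abundance, "sst": sst,
        "weibull_shape": shape, "weibull_scale": scale,
    })


@dataclass
class StandConfig:
    extent: tuple[float, float] = (100.0, 100.0)
    subplot_size: float = 20.0
    process: str = "csr"  # or "thomas"
    density: float = 600.0  # trees/ha
    thomas_parent_density: float = 30.0  # parents/ha
    thomas_sigma: float = 4.0  # offspring displacement SD, m
    species_pool: pd.DataFrame = field(default_factory=default_species_pool)
    ba_target_m2_ha: float = 30.0
    ba_tolerance: float = 0.05
    dbh_min: float = 5.0

    def __post_init__(self) -> None:
        ab = self.species_pool["abundance"].to_numpy()
        if not np.isclose(ab.sum(), 1.0):
            raise ValueError("species abundances must sum to 1")
        if self.density <= 0:
            raise ValueError("density must be positive")


@dataclass
class GrowthLawConfig:
    """True coefficients of the generating log-linear growth law.

    Coefficients apply to predictors scaled by ``reference_scaling``
    (fixed means/SDs, not sample z-scores). The default truth has a
    strong positive size effect with a mild negative cubic asymptote,
    positive competition-structure effects, and negative stand-density
    effects.
    """

    coefficients: dict = field(default_factory=lambda: {
        "beta0": 1.6, "DBH": 0.8, "DBH3": -0.12, "BAL": 0.15, "FSS": 0.10,
        "Dg": -0.10, "N": -0.15, "Ddom": -0.05, "SST": 0.10,
    })
    sd_subplot: float = 0.15
    sd_year: float = 0.10
    sd_resid: float = 0.50
    census_offsets: tuple = DEFAULT_CENSUS_OFFSETS
    reference_scaling: pd.DataFrame = field(default_factory=lambda: pd.DataFrame(
        {
            "DBH": [15.0, 7.0], "DBH3": [0.0, 4.0], "BAL": [2000.0, 1800.0],
            "FSS": [0.55, 0.18], "Dg": [16.0, 3.0], "N": [600.0, 150.0],
            "Ddom": [28.0, 6.0], "SST": [2.5, 1.2],
        },
        index=["mean", "sd"],
    ))

    def __post_init__(self) -> None:
        if self.sd_resid < 0 or self.sd_subplot < 0 or self.sd_year < 0:
            raise ValueError("random-effect SDs must be non-negative")


@dataclass
class ThinningConfig:
    target_fraction: float = 0.2
    defect_probability: float = 0.05
    rare_retention_count: int = 3
    clustering_weight: float = 2.0
    tolerance: float = 0.02
    max_subplot_factor: float = 1.5

    def __post_init__(self) -> None:
        if not 0.0 <= self.target_fraction < 1.0:
            raise ValueError("target fraction must be in [0, 1)")


def simulate_pattern(config: StandConfig, rng) -> np.ndarray:
    """Tree coordinates on the plot from the configured point process."""
    rng = np.random.default_rng(rng)
    ex, ey = config.extent
    area_ha = ex * ey / 1e4
    if config.process == "csr":
        n = rng.poisson(config.density * area_ha)
        if n == 0:
            raise ValueError("zero trees drawn; density too low")
        return np.column_stack([rng.uniform(0, ex, n), rng.uniform(0, ey, n)])
    if config.process == "thomas":
        # parents in a 3-sigma guard buffer so edge clusters are not thinned out
        b = 3.0 * config.thomas_sigma
        area_ext = (ex + 2 * b) * (ey + 2 * b) / 1e4
        n_par = rng.poisson(config.thomas_parent_density * area_ext)
        parents = np.column_stack([
            rng.uniform(-b, ex + b, n_par), rng.uniform(-b, ey + b, n_par),
        ])
        mean_offspring = config.density / config.thomas_parent_density
        pts = []
        for px, py in parents:
            m = rng.poisson(mean_offspring)
            if m:
                pts.append(np.column_stack([
                    rng.normal(px, config.thomas_sigma, m),
                    rng.normal(py, config.thomas_sigma, m),
                ]))
        if not pts:
            raise ValueError("zero trees drawn; density too low")
        coords = np.concatenate(pts)
        inside = (
            (coords[:, 0] >= 0) & (coords[:, 0] <= ex)
            & (coords[:, 1] >= 0) & (coords[:, 1] <= ey)
        )
        return coords[inside]
    raise ValueError(f"unknown process {config.process!r}")


def _draw_truncated_weibull(rng, shape: float, scale: float, n: int, lo: float) -> np.ndarray:
    """Weibull(shape, scale) conditioned on >= lo by inverse-CDF sampling."""
    p_lo = 1.0 - np.exp(-((lo / scale) ** shape))
    u = rng.uniform(p_lo, 1.0, n)
    return scale * (-np.log1p(-u)) ** (1.0 / shape)


def assign_attributes(
    coords: np.ndarray,
    config: StandConfig,
    rng,
    plot_id: str = "plot",
    census_year: int = 0,
    treatment: float = 0.0,
) -> CensusInventory:
    """Species, diameters, and subplot coordinates for the simulated points.

    Diameters are rescaled (multiplicatively, re-truncated at the 5-cm
    threshold) until stand basal area hits the configured target within
    its tolerance; an unattainable target raises.
    """
    rng = np.random.default_rng(rng)
    n = len(coords)
    pool = config.species_pool
    sp_idx = rng.choice(len(pool), size=n, p=pool["abundance"].to_numpy())
    species = pool["species"].to_numpy()[sp_idx]
    dbh = np.empty(n)
    for i in range(len(pool)):
        mask = sp_idx == i
        if mask.any():
            dbh[mask] = _draw_truncated_weibull(
                rng, pool["weibull_shape"].iloc[i], pool["weibull_scale"].iloc[i],
                int(mask.sum()), config.dbh_min,
            )

    area_ha = config.extent[0] * config.extent[1] / 1e4
    target_cm2 = config.ba_target_m2_ha * 1e4 * area_ha
    for _ in range(40):
        total = basal_area(dbh).sum()
        if abs(total - target_cm2) / target_cm2 <= config.ba_tolerance:
            break
        dbh = np.maximum(dbh * np.sqrt(target_cm2 / total), config.dbh_min)
    else:
        raise ValueError(
            f"cannot reach BA target {config.ba_target_m2_ha} m2/ha "
            f"(achieved {basal_area(dbh).sum() / 1e4 / area_ha:.1f})"
        )

    row, col, x_loc, y_loc = from_plot_coordinates(
        coords[:, 0], coords[:, 1], config.subplot_size,
        n_cells=int(round(config.extent[0] / config.subplot_size)),
    )
    trees = pd.DataFrame({
        "tree_id": [f"{plot_id}-T{i + 1:04d}" for i in range(n)],
        "species": species,
        "subplot_row": row, "subplot_col": col,
        "x": x_loc, "y": y_loc,
        "dbh": dbh, "year": census_year, "status": "live",
        "x_global": coords[:, 0], "y_global": coords[:, 1],
    })
    return CensusInventory(
        plot_id=plot_id, census_year=census_year, trees=trees,
        treatment=treatment, plot_extent=config.extent,
        subplot_size=config.subplot_size,
    )


def apply_thinning(
    inventory: CensusInventory,
    config: ThinningConfig,
    rng,
):
    """Structure-based thinning marking on a baseline census.

    Marking order: defect-marked trees first, then trees drawn with
    probability increasing in their uniform angle index (clustered
    individuals), until the removed basal-area fraction is inside
    ``target +/- tolerance``. Rare species (fewer than the retention
    count on the plot) are never removed, and no subplot loses more than
    ``max_subplot_factor`` times the plot-level removal fraction of its
    basal area. Returns (residual inventory, removal table); the removed
    trees keep their measurements with status ``removed_by_thinning``, so
    residual + removed basal area equals the initial exactly.
    """
    rng = np.random.default_rng(rng)
    out = inventory.copy()
    if config.target_fraction == 0.0:
        return out, out.trees.iloc[0:0].copy()

    live_mask = out.trees["status"] == "live"
    live = out.trees[live_mask]
    ba = basal_area(live["dbh"].to_numpy())
    total = ba.sum()
    target = config.target_fraction

    counts = live["species"].value_counts()
    protected_species = set(counts[counts < config.rare_retention_count].index)
    protected = live["species"].isin(protected_species).to_numpy()

    defect = rng.random(len(live)) < config.defect_probability
    structure = compute_structure(out, buffer=0.0)
    w = structure.set_index("tree_id")["W"].reindex(live["tree_id"].astype(str)).to_numpy()

    # weighted permutation: defect trees first, then clustered-preference draw
    weight = np.exp(config.clustering_weight * (w - 0.5))
    order_defect = np.flatnonzero(defect & ~protected)
    rng.shuffle(order_defect)
    rest = np.flatnonzero(~defect & ~protected)
    if len(rest):
        p = weight[rest] / weight[rest].sum()
        rest = rng.choice(rest, size=len(rest), replace=False, p=p)
    candidates = np.concatenate([order_defect, rest]).astype(int)

    sub_key = (live["subplot_row"].astype(int) * 100 + live["subplot_col"].astype(int)).to_numpy()
    sub_ba = pd.Series(ba).groupby(sub_key).sum()
    sub_removed = {k: 0.0 for k in sub_ba.index}
    sub_cap = {k: config.max_subplot_factor * target * v for k, v in sub_ba.items()}

    removed_ba = 0.0
    removed_idx = []
    for i in candidates:
        if removed_ba >= target * total:
            break
        if (removed_ba + ba[i]) / total > target + config.tolerance:
            continue
        k = sub_key[i]
        if sub_removed[k] + ba[i] > sub_cap[k]:
            continue
        removed_idx.append(i)
        removed_ba += ba[i]
        sub_removed[k] += ba[i]

    realized = removed_ba / total
    if abs(realized - target) > config.tolerance:
        raise ValueError(
            f"thinning target {target:.0%} unreachable under retention/dispersion "
            f"constraints; achieved {realized:.1%}"
        )
    rows = live.index[removed_idx]
    out.trees.loc[rows, "status"] = "removed_by_thinning"
    removal = out.trees.loc[rows].copy()
    removal["ba_cm2"] = ba[removed_idx]
    return out, removal


@dataclass
class ExperimentResult:
    """Censuses per plot plus the generating ground truth."""

    censuses: dict  # plot_id -> list[CensusInventory], chronological
    ground_truth: dict


def _interval_predictors(inv: CensusInventory, pool: pd.DataFrame) -> pd.DataFrame:
    """Start-of-interval predictors (shared with the analysis pipeline)."""
    from .pipeline import interval_predictor_table

    return interval_predictor_table(inv, dict(zip(pool["species"], pool["sst"])))


def simulate_experiment(
    stand_config: StandConfig | None = None,
    growth_config: GrowthLawConfig | None = None,
    thinning_levels=(0.0, 0.2, 0.4, 0.6),
    seed: int = 0,
    thinning_config: ThinningConfig | None = None,
) -> ExperimentResult:
    """Full multi-plot thinning experiment with known ground truth.

    One plot per thinning level: baseline stand, thinning at year 0, then
    growth of the survivors over the census intervals with predictors
    recomputed on the residual stand at each interval start. Identical
    (configs, seed) give identical output.
    """
    stand_config = stand_config or StandConfig()
    growth_config = growth_config or GrowthLawConfig()
    base_thin = thinning_config or ThinningConfig()
    ss = np.random.SeedSequence(seed)
    plot_streams = ss.spawn(len(thinning_levels) + 1)
    master = np.random.default_rng(plot_streams[-1])

    offsets = growth_config.census_offsets
    years = list(offsets)
    # year random intercepts shared across plots (a common climate signal),
    # indexed by interval end year
    v_year = {y: master.normal(0.0, growth_config.sd_year) for y in years[1:]}

    coef = growth_config.coefficients
    scaling = growth_config.reference_scaling
    pool = stand_config.species_pool

    censuses: dict[str, list[CensusInventory]] = {}
    truth_plots = {}
    for level, stream in zip(thinning_levels, plot_streams):
        rng = np.random.default_rng(stream)
        plot_id = f"plot{int(round(level * 100)):02d}"
        coords = simulate_pattern(stand_config, rng)
        baseline = assign_attributes(
            coords, stand_config, rng, plot_id=plot_id,
            census_year=years[0], treatment=level,
        )
        thin_cfg = replace(base_thin, target_fraction=level)
        marked, removal = apply_thinning(baseline, thin_cfg, rng)
        plot_censuses = [marked]

        n_rows = int(round(stand_config.extent[1] / stand_config.subplot_size))
        u_sub = {
            (r, c): rng.normal(0.0, growth_config.sd_subplot)
            for r in range(n_rows)
            for c in range(int(round(stand_config.extent[0] / stand_config.subplot_size)))
        }

        current = marked
        for t0, t1 in zip(years[:-1], years[1:]):
            pred = _interval_predictors(current, pool)
            z = {}
            for name in ["DBH", "BAL", "FSS", "Dg", "N", "Ddom", "SST"]:
                z[name] = (pred[name].to_numpy() - scaling.loc["mean", name]) / scaling.loc["sd", name]
            z["DBH3"] = (z["DBH"] ** 3 - scaling.loc["mean", "DBH3"]) / scaling.loc["sd", "DBH3"]
            eta = coef["beta0"] + sum(coef[k] * z[k] for k in coef if k != "beta0")
            eta = eta + np.array([u_sub[(r, c)] for r, c in
                                  zip(pred["subplot_row"], pred["subplot_col"])])
            eta = eta + v_year[t1]
            eta = eta + rng.normal(0.0, growth_config.sd_resid, len(pred))
            bai = np.exp(eta)  # cm2/yr, strictly positive by construction

            nxt = current.copy()
            nxt.census_year = t1
            live_mask = nxt.trees["status"] == "live"
            order = nxt.trees.loc[live_mask, "tree_id"].astype(str)
            bai_by_id = pd.Series(bai, index=pred["tree_id"]).reindex(order)
            ba_now = basal_area(nxt.trees.loc[live_mask, "dbh"].to_numpy())
            ba_next = ba_now + (t1 - t0) * bai_by_id.to_numpy()
            nxt.trees.loc[live_mask, "dbh"] = dbh_from_basal_area(ba_next)
            nxt.trees["year"] = t1
            # removed trees do not reappear in later censuses
            nxt.trees = nxt.trees[live_mask].reset_index(drop=True)
            plot_censuses.append(nxt)
            current = nxt

        censuses[plot_id] = plot_censuses
        truth_plots[plot_id] = {
            "treatment": level,
            "subplot_intercepts": {f"{r}{c}": v for (r, c), v in u_sub.items()},
            "removed_ids": removal["tree_id"].tolist(),
            "realized_removal_fraction": (
                float(removal["ba_cm2"].sum()
                      / basal_area(baseline.trees["dbh"].to_numpy()).sum())
                if len(removal) else 0.0
            ),
        }

    return ExperimentResult(
        censuses=censuses,
        ground_truth={
            "coefficients": dict(coef),
            "reference_scaling": scaling,
            "sd_subplot": growth_config.sd_subplot,
            "sd_year": growth_config.sd_year,
            "sd_resid": growth_config.sd_resid,
            "year_intercepts": v_year,
            "plots": truth_plots,
            "seed": seed,
        },
    )
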