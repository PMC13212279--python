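"""Census data model, file I/O, coordinates, and cross-census tree linking.

A census is a table of trees measured on one 1-ha plot (100 m x 100 m,
subdivided into 25 subplots of 20 m x 20 m) in one year. Tree positions
are recorded as subplot indices plus local coordinates within the
subplot; :func:`to_plot_coordinates` reconstructs plot-level coordinates.
Repeated censuses of the same plot are linked into per-tree diameter
histories by :func:`link_censuses`.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

logger = logging.getLogger(__name__)

#: Minimum DBH measured in the inventory (cm).
DBH_THRESHOLD = 5.0

#: Canonical census-table columns.
CANONICAL_COLUMNS = [
    "tree_id",
    "species",
    "subplot_row",
    "subplot_col",
    "x",
    "y",
    "dbh",
    "year",
    "status",
]

VALID_STATUS = frozenset({"live", "removed_by_thinning", "dead"})

#: Tolerated between-census DBH shrinkage (cm) treated as measurement noise.
SHRINK_TOLERANCE = 0.5


class SchemaError(ValueError):
    """A census table is missing required columns or has invalid values."""


@dataclass(frozen=True)
class TreeRecord:
    """One tree at one census."""

    tree_id: str
    species: str
    subplot: tuple[int, int]  # (row, col), each 0-4
    x_local: float  # m within the 20 m subplot
    y_local: float
    dbh: float  # cm
    census_year: int
    status: str = "live"


@dataclass
class CensusInventory:
    """All trees of one plot at one census.

    ``trees`` holds the canonical columns; records failing the DBH
    threshold are kept aside in ``flagged`` rather than silently dropped.
    """

    plot_id: str
    census_year: int
    trees: pd.DataFrame
    treatment: float = 0.0  # nominal basal-area removal fraction
    plot_extent: tuple[float, float] = (100.0, 100.0)
    subplot_size: float = 20.0
    flagged: pd.DataFrame | None = None

    def __post_init__(self) -> None:
        missing = [c for c in CANONICAL_COLUMNS if c not in self.trees.columns]
        if missing:
            raise SchemaError(f"census table missing columns: {missing}")

    @property
    def n_trees(self) -> int:
        return len(self.trees)

    def live(self) -> pd.DataFrame:
        return self.trees[self.trees["status"] == "live"]

    def copy(self) -> "CensusInventory":
        return CensusInventory(
            plot_id=self.plot_id,
            census_year=self.census_year,
            trees=self.trees.copy(),
            treatment=self.treatment,
            plot_extent=self.plot_extent,
            subplot_size=self.subplot_size,
            flagged=None if self.flagged is None else self.flagged.copy(),
        )


@dataclass
class TreeHistory:
    """One tree tracked across censuses."""

    tree_id: str
    species: str
    years: list[int]
    dbh: list[float]
    removal_year: int | None = None
    recruit: bool = False

    def intervals(self) -> list[tuple[int, int, float, float]]:
        """(start_year, end_year, dbh_start, dbh_end) per census pair.

        Intervals with DBH shrinkage beyond the measurement tolerance are
        excluded (the larger decrease is treated as a data defect, not
        growth); tolerated small decreases are kept as-is.
        """
        out = []
        for i in range(len(self.years) - 1):
            d0, d1 = self.dbh[i], self.dbh[i + 1]
            if d1 - d0 < -SHRINK_TOLERANCE:
                logger.warning(
                    "tree %s: DBH shrank %.2f cm between %d and %d; interval excluded",
                    self.tree_id, d0 - d1, self.years[i], self.years[i + 1],
                )
                continue
            out.append((self.years[i], self.years[i + 1], d0, d1))
        return out


@dataclass
class ValidationReport:
    duplicates: list[str] = field(default_factory=list)
    coordinate_violations: list[str] = field(default_factory=list)
    dbh_violations: list[str] = field(default_factory=list)

    @property
    def ok(self) -> bool:
        return not (self.duplicates or self.coordinate_violations or self.dbh_violations)


def read_census_table(
    path,
    plot_id: str = "plot",
    census_year: int | None = None,
    treatment: float = 0.0,
    column_map: dict[str, str] | None = None,
    sep: str = ",",
) -> CensusInventory:
    """Read a delimited census table into a validated :class:`CensusInventory`.

    ``column_map`` maps alternative file column names onto the canonical
    schema, e.g. ``{"diameter_cm": "dbh"}``. Trees below the 5-cm DBH
    inventory threshold are moved to ``inventory.flagged``.
    """
    df = pd.read_csv(path, sep=sep)
    if column_map:
        df = df.rename(columns=column_map)
    missing = [c for c in CANONICAL_COLUMNS if c not in df.columns]
    if missing:
        raise SchemaError(f"{path}: missing columns {missing}")
    df = df[CANONICAL_COLUMNS].copy()
    df["tree_id"] = df["tree_id"].astype(str)
    df["species"] = df["species"].astype(str)
    if (df["species"].str.len() == 0).any():
        raise SchemaError(f"{path}: empty species codes")
    bad_status = set(df["status"].unique()) - VALID_STATUS
    if bad_status:
        raise SchemaError(f"{path}: unknown status values {sorted(bad_status)}")

    under = df["dbh"] < DBH_THRESHOLD
    flagged = df[under].copy()
    if len(flagged):
        logger.warning("%s: %d record(s) below %.0f cm DBH threshold flagged",
                       path, len(flagged), DBH_THRESHOLD)
    df = df[~under].reset_index(drop=True)

    if census_year is None:
        years = df["year"].unique()
        if len(years) != 1:
            raise SchemaError(f"{path}: multiple census years {sorted(years)}; pass census_year")
        census_year = int(years[0])
    return CensusInventory(
        plot_id=plot_id,
        census_year=census_year,
        trees=df,
        treatment=treatment,
        flagged=flagged if len(flagged) else None,
    )


def write_census_table(inventory: CensusInventory, path) -> None:
    """Write the canonical CSV dialect (round-trips bit-identically)."""
    inventory.trees[CANONICAL_COLUMNS].to_csv(path, index=False)


def to_plot_coordinates(inventory: CensusInventory) -> CensusInventory:
    """Add plot-level ``x_global``/``y_global`` columns.

    Convention: origin at the plot SW corner, column index maps to x and
    row index to y, so ``x_global = col * s + x_local``. Local coordinates
    outside [0, s] raise, naming the offending tree.
    """
    inv = inventory.copy()
    s = inv.subplot_size
    t = inv.trees
    bad = t[(t["x"] < 0) | (t["x"] > s) | (t["y"] < 0) | (t["y"] > s)]
    if len(bad):
        raise ValueError(
            f"local coordinates outside [0, {s}] for tree(s): "
            f"{bad['tree_id'].tolist()}"
        )
    n_rows = int(round(inv.plot_extent[1] / s))
    n_cols = int(round(inv.plot_extent[0] / s))
    bad_sub = t[
        (t["subplot_row"] < 0) | (t["subplot_row"] >= n_rows)
        | (t["subplot_col"] < 0) | (t["subplot_col"] >= n_cols)
    ]
    if len(bad_sub):
        raise ValueError(f"subplot indices out of range for tree(s): {bad_sub['tree_id'].tolist()}")
    inv.trees["x_global"] = t["subplot_col"] * s + t["x"]
    inv.trees["y_global"] = t["subplot_row"] * s + t["y"]
    return inv


def from_plot_coordinates(x_global, y_global, subplot_size: float = 20.0, n_cells: int = 5):
    """Invert :func:`to_plot_coordinates` on the 20-m grid.

    Cells are half-open [0, s) except the final edge, so boundaries belong
    to the lower-index subplot and the partition is exact.
    """
    x = np.asarray(x_global, dtype=float)
    y = np.asarray(y_global, dtype=float)
    col = np.minimum((x // subplot_size).astype(int), n_cells - 1)
    row = np.minimum((y // subplot_size).astype(int), n_cells - 1)
    return row, col, x - col * subplot_size, y - row * subplot_size


def validate_inventory(inventory: CensusInventory) -> ValidationReport:
    """Report duplicate ids, coordinate violations, and DBH violations."""
    t = inventory.trees
    report = ValidationReport()
    dup = t["tree_id"][t["tree_id"].duplicated()]
    report.duplicates = sorted(set(dup.astype(str)))
    s = inventory.subplot_size
    bad_xy = t[(t["x"] < 0) | (t["x"] > s) | (t["y"] < 0) | (t["y"] > s)]
    report.coordinate_violations = bad_xy["tree_id"].astype(str).tolist()
    bad_dbh = t[t["dbh"] < DBH_THRESHOLD]
    report.dbh_violations = bad_dbh["tree_id"].astype(str).tolist()
    return report


def link_censuses(inventories: list[CensusInventory]) -> dict[str, TreeHistory]:
    """Link >= 2 censuses of one plot into per-tree histories.

    Every tree id appears in exactly one history. Trees whose status turns
    ``removed_by_thinning`` get a removal year and no later measurements;
    ids first seen after the baseline census are flagged as recruits.
    A species-code change across censuses is a warning; the first code is
    kept.
    """
    if len(inventories) < 2:
        raise ValueError("need at least two censuses to link")
    plot_ids = {inv.plot_id for inv in inventories}
    if len(plot_ids) > 1:
        raise ValueError(f"censuses from different plots: {sorted(plot_ids)}")
    invs = sorted(inventories, key=lambda inv: inv.census_year)
    baseline_year = invs[0].census_year

    histories: dict[str, TreeHistory] = {}
    for inv in invs:
        t = inv.trees
        if t["tree_id"].duplicated().any():
            dups = sorted(set(t["tree_id"][t["tree_id"].duplicated()]))
            raise ValueError(f"duplicate tree_id(s) in census {inv.census_year}: {dups}")
        for tid, sp, dbh, status in zip(
            t["tree_id"], t["species"], t["dbh"], t["status"]
        ):
            h = histories.get(tid)
            if h is None:
                h = TreeHistory(
                    tree_id=tid, species=sp, years=[], dbh=[],
                    recruit=inv.census_year > baseline_year,
                )
                histories[tid] = h
            elif sp != h.species:
                warnings.warn(
                    f"tree {tid}: species changed {h.species!r} -> {sp!r}; keeping first",
                    stacklevel=2,
                )
            if status == "removed_by_thinning":
                h.removal_year = inv.census_year
                continue
            if status == "dead":
                # found dead at this census: no usable growth to it
                continue
            if h.removal_year is not None:
                raise ValueError(f"tree {tid}: measurement after removal in {h.removal_year}")
            h.years.append(int(inv.census_year))
            h.dbh.append(float(dbh))
    return histories
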