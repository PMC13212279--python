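import numpy as np
import pandas as pd
import pytest

from standthin.inventory import CensusInventory
from standthin.simulate import StandConfig, assign_attributes, simulate_pattern


def make_inventory(records, plot_id="p", census_year=0, treatment=0.0):
    """Inventory from (tree_id, species, row, col, x, y, dbh[, status]) tuples."""
    rows = []
    for rec in records:
        status = rec[7] if len(rec) > 7 else "live"
        rows.append({
            "tree_id": str(rec[0]), "species": rec[1],
            "subplot_row": rec[2], "subplot_col": rec[3],
            "x": float(rec[4]), "y": float(rec[5]), "dbh": float(rec[6]),
            "year": census_year, "status": status,
        })
    return CensusInventory(plot_id=plot_id, census_year=census_year,
                           trees=pd.DataFrame(rows), treatment=treatment)


def global_inventory(coords, species=None, dbh=None, plot_id="p", census_year=0):
    """Inventory directly from plot-level coordinates."""
    coords = np.asarray(coords, dtype=float)
    n = len(coords)
    species = list(species) if species is not None else ["SP01"] * n
    dbh = np.asarray(dbh, dtype=float) if dbh is not None else np.full(n, 10.0)
    row = np.minimum((coords[:, 1] // 20).astype(int), 4)
    col = np.minimum((coords[:, 0] // 20).astype(int), 4)
    trees = pd.DataFrame({
        "tree_id": [f"t{i:04d}" for i in range(n)],
        "species": species,
        "subplot_row": row, "subplot_col": col,
        "x": coords[:, 0] - col * 20, "y": coords[:, 1] - row * 20,
        "dbh": dbh, "year": census_year, "status": "live",
        "x_global": coords[:, 0], "y_global": coords[:, 1],
    })
    return CensusInventory(plot_id=plot_id, census_year=census_year, trees=trees)


@pytest.fixture
def csr_stand():
    """One reproducible ~600-tree CSR stand with mixed species and sizes."""
    cfg = StandConfig()
    rng = np.random.default_rng(42)
    coords = simulate_pattern(cfg, rng)
    return assign_attributes(coords, cfg, rng, plot_id="csr", census_year=0)
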