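"""Functional grouping of species: PCA reduction + Ward clustering.

Species are described by per-species means of 11 tree-, competition-,
stand-, and trait-level variables (DBH, BAL, M, W, U, FSS, Dg, N, Ddom,
SST, BAI). The z-scored matrix is reduced by PCA on the correlation
matrix, retaining components with eigenvalue > 1 (Kaiser rule), and
species are clustered on the retained scores with Ward's minimum
variance method. The number of groups is a configuration value
(default 3); a silhouette profile over a k range is reported alongside
so the choice is transparent, but the profile argmax is never applied
silently.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.cluster.hierarchy import fcluster, linkage
from sklearn.metrics import silhouette_samples

logger = logging.getLogger(__name__)

FEATURE_VARIABLES = ["DBH", "BAL", "M", "W", "U", "FSS", "Dg", "N", "Ddom", "SST", "BAI"]


@dataclass
class GroupingResult:
    eigenvalues: np.ndarray
    n_retained: int
    explained_fraction: np.ndarray  # per retained component
    scores: pd.DataFrame  # species x retained PCs
    linkage_matrix: np.ndarray
    labels: pd.Series  # cluster label per species at chosen k
    silhouette_by_k: dict[int, float]
    chosen_k: int


def species_feature_matrix(
    tree_table: pd.DataFrame,
    traits: pd.Series | dict,
    variables: list[str] | None = None,
) -> pd.DataFrame:
    """Per-species feature rows from a per-tree(-interval) variable table.

    ``tree_table`` has one row per tree observation with a ``species``
    column and the tree-level variables; rows are pooled over censuses by
    unweighted means. ``traits`` maps species code to its shade-tolerance
    score (SST, 0-5); species missing from the trait table raise, listing
    the codes, because imputation from congeners is the user's input.
    """
    variables = variables or [v for v in FEATURE_VARIABLES if v != "SST"]
    missing_cols = [v for v in variables if v not in tree_table.columns]
    if missing_cols:
        raise ValueError(f"tree table missing variables: {missing_cols}")
    traits = pd.Series(traits)
    species = tree_table["species"].astype(str)
    absent = sorted(set(species) - set(traits.index.astype(str)))
    if absent:
        raise ValueError(f"species absent from trait table: {absent}")
    mat = tree_table.groupby(species)[variables].mean()
    mat["SST"] = traits.reindex(mat.index).astype(float)
    return mat


def zscore(matrix: pd.DataFrame) -> pd.DataFrame:
    """Column z-scores; constant columns are dropped with a warning."""
    sd = matrix.std(ddof=1)
    constant = sd[sd == 0].index.tolist()
    if constant:
        warnings.warn(f"constant column(s) dropped: {constant}", stacklevel=2)
        matrix = matrix.drop(columns=constant)
        sd = sd.drop(constant)
    return (matrix - matrix.mean()) / sd


def pca_reduce(matrix: pd.DataFrame, eigenvalue_min: float = 1.0):
    """PCA on the correlation matrix with Kaiser retention.

    Returns (eigenvalues descending, retained scores DataFrame, explained
    variance fractions of the retained components). Loadings are oriented
    so each component's largest-magnitude loading is positive, making
    scores reproducible across eigensolvers.
    """
    z = zscore(matrix)
    n, p = z.shape
    if n < 2:
        raise ValueError("need at least 2 rows")
    corr = np.corrcoef(z.to_numpy(), rowvar=False)
    eigval, eigvec = np.linalg.eigh(corr)
    order = np.argsort(eigval)[::-1]
    eigval, eigvec = eigval[order], eigvec[:, order]
    # sign convention: largest |loading| positive
    for j in range(p):
        i = np.argmax(np.abs(eigvec[:, j]))
        if eigvec[i, j] < 0:
            eigvec[:, j] = -eigvec[:, j]
    retained = int(np.sum(eigval > eigenvalue_min))
    retained = max(retained, 1)
    scores = z.to_numpy() @ eigvec[:, :retained]
    cols = [f"PC{j + 1}" for j in range(retained)]
    return (
        eigval,
        pd.DataFrame(scores, index=matrix.index, columns=cols),
        eigval[:retained] / eigval.sum(),
    )


def ward_cluster(scores: pd.DataFrame, k: int):
    """Ward minimum-variance clustering of PC scores, cut at k groups.

    Returns (labels Series with values 1..k, scipy linkage matrix whose
    heights are the Ward merge costs).
    """
    n = len(scores)
    if not 2 <= k <= n:
        raise ValueError(f"k={k} outside [2, {n}]")
    lm = linkage(scores.to_numpy(), method="ward")
    labels = fcluster(lm, t=k, criterion="maxclust")
    return pd.Series(labels, index=scores.index, name="cluster"), lm


def silhouette_profile(
    scores: pd.DataFrame,
    k_range=range(2, 9),
    chosen_k: int = 3,
):
    """Mean silhouette per k from Ward partitions; k is never auto-picked.

    Singleton clusters contribute a silhouette of 0 for their point (and
    are logged). Returns (profile dict k -> mean silhouette, chosen_k).
    """
    x = scores.to_numpy()
    n = len(x)
    profile: dict[int, float] = {}
    for k in k_range:
        if not 2 <= k <= n - 1:
            raise ValueError(f"k={k} outside [2, {n - 1}]")
        labels, _ = ward_cluster(scores, k)
        counts = labels.value_counts()
        if (counts == 1).any():
            logger.info("k=%d: %d singleton cluster(s), silhouette 0 for those points",
                        k, int((counts == 1).sum()))
        profile[k] = float(np.mean(silhouette_samples(x, labels.to_numpy())))
    return profile, chosen_k


def functional_grouping(
    matrix: pd.DataFrame,
    k: int = 3,
    k_range=range(2, 9),
) -> GroupingResult:
    """Full grouping pipeline: z-score, PCA (eigenvalue > 1), Ward, silhouette."""
    eigval, scores, frac = pca_reduce(matrix)
    k_range = [kk for kk in k_range if kk <= len(matrix) - 1]
    profile, _ = silhouette_profile(scores, k_range=k_range, chosen_k=k)
    labels, lm = ward_cluster(scores, k)
    return GroupingResult(
        eigenvalues=eigval,
        n_retained=scores.shape[1],
        explained_fraction=frac,
        scores=scores,
        linkage_matrix=lm,
        labels=labels,
        silhouette_by_k=profile,
        chosen_k=k,
    )
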