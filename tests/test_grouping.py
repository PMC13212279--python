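import numpy as np
import pandas as pd
import pytest
from sklearn.decomposition import PCA

from standthin.grouping import (
    functional_grouping,
    pca_reduce,
    silhouette_profile,
    species_feature_matrix,
    ward_cluster,
    zscore,
)


def lance_williams_ward(points):
    """Textbook Ward agglomeration via the Lance-Williams update.

    Returns the merge order as a list of frozensets of original indices,
    using squared-Euclidean ward distances d(i,j) = |i|·|j|/(|i|+|j|) ||ci-cj||^2.
    """
    points = np.asarray(points, dtype=float)
    clusters = {i: frozenset([i]) for i in range(len(points))}
    sizes = {i: 1 for i in range(len(points))}
    d = {}
    for i in range(len(points)):
        for j in range(i + 1, len(points)):
            d[(i, j)] = 0.5 * np.sum((points[i] - points[j]) ** 2)
    merges = []
    nxt = len(points)
    while len(clusters) > 1:
        (a, b), _ = min(d.items(), key=lambda kv: kv[1])
        merges.append(clusters[a] | clusters[b])
        na, nb = sizes[a], sizes[b]
        new = {}
        for k in clusters:
            if k in (a, b):
                continue
            nk = sizes[k]
            dak = d[tuple(sorted((a, k)))]
            dbk = d[tuple(sorted((b, k)))]
            dab = d[tuple(sorted((a, b)))]
            new[k] = ((na + nk) * dak + (nb + nk) * dbk - nk * dab) / (na + nb + nk)
        clusters[nxt] = clusters.pop(a) | clusters.pop(b)
        sizes[nxt] = na + nb
        d = {k: v for k, v in d.items() if a not in k and b not in k}
        for k, v in new.items():
            d[tuple(sorted((k, nxt)))] = v
        nxt += 1
    return merges


def brute_force_silhouette(points, labels):
    """Direct a(i)/b(i) silhouette computation."""
    points = np.asarray(points, dtype=float)
    labels = np.asarray(labels)
    out = np.zeros(len(points))
    for i in range(len(points)):
        same = (labels == labels[i]) & (np.arange(len(points)) != i)
        if not same.any():
            out[i] = 0.0  # singleton
            continue
        dists = np.sqrt(((points - points[i]) ** 2).sum(axis=1))
        a = dists[same].mean()
        b = min(dists[labels == other].mean()
                for other in set(labels) if other != labels[i])
        out[i] = (b - a) / max(a, b)
    return out


class TestSpeciesFeatureMatrix:
    def test_single_tree_row_equals_tree_values(self):
        tab = pd.DataFrame({"species": ["A"], "DBH": [17.0], "BAI": [3.0]})
        mat = species_feature_matrix(tab, {"A": 2.5}, variables=["DBH", "BAI"])
        assert mat.loc["A", "DBH"] == 17.0
        assert mat.loc["A", "SST"] == 2.5

    def test_identical_species_give_identical_rows(self):
        tab = pd.DataFrame({
            "species": ["A", "A", "B", "B"],
            "DBH": [10.0, 20.0, 10.0, 20.0],
            "BAI": [1.0, 3.0, 1.0, 3.0],
        })
        mat = species_feature_matrix(tab, {"A": 1.0, "B": 1.0}, variables=["DBH", "BAI"])
        np.testing.assert_allclose(mat.loc["A"], mat.loc["B"])

    def test_groupby_means_match_oracle(self):
        rng = np.random.default_rng(0)
        tab = pd.DataFrame({
            "species": rng.choice(["A", "B", "C"], 60),
            "DBH": rng.uniform(5, 50, 60),
            "BAI": rng.uniform(0.5, 8, 60),
        })
        mat = species_feature_matrix(tab, {"A": 1, "B": 2, "C": 3},
                                     variables=["DBH", "BAI"])
        for sp in "ABC":
            sub = tab[tab.species == sp]
            assert mat.loc[sp, "DBH"] == pytest.approx(sub["DBH"].mean())

    def test_missing_trait_species_listed(self):
        tab = pd.DataFrame({"species": ["A", "B"], "DBH": [10.0, 12.0]})
        with pytest.raises(ValueError, match="B"):
            species_feature_matrix(tab, {"A": 1.0}, variables=["DBH"])


class TestPca:
    def fixture_matrix(self, n=40, p=6, seed=1):
        rng = np.random.default_rng(seed)
        base = rng.normal(size=(n, 3))
        x = np.column_stack([base, base[:, 0] + 0.1 * rng.normal(size=n),
                             rng.normal(size=(n, p - 4))])
        return pd.DataFrame(x, columns=[f"v{i}" for i in range(p)])

    def test_perfectly_correlated_pair_gives_one_component(self):
        rng = np.random.default_rng(2)
        a = rng.normal(size=30)
        mat = pd.DataFrame({"a": a, "b": 2 * a + 1})
        eigval, scores, frac = pca_reduce(mat)
        assert scores.shape[1] == 1
        assert frac[0] == pytest.approx(1.0)

    def test_eigenvalues_match_direct_eigensolver(self):
        mat = self.fixture_matrix()
        eigval, _, _ = pca_reduce(mat)
        corr = np.corrcoef(zscore(mat).to_numpy(), rowvar=False)
        oracle = np.sort(np.linalg.eigvalsh(corr))[::-1]
        np.testing.assert_allclose(eigval, oracle, atol=1e-8)

    def test_trace_preservation(self):
        mat = self.fixture_matrix()
        eigval, _, _ = pca_reduce(mat)
        assert eigval.sum() == pytest.approx(mat.shape[1])

    def test_scores_match_sklearn_up_to_sign(self):
        mat = self.fixture_matrix()
        _, scores, _ = pca_reduce(mat)
        z = zscore(mat).to_numpy()
        # sklearn PCA on standardized data (correlation PCA), same retained count
        sk = PCA(n_components=scores.shape[1]).fit(z)
        sk_scores = sk.transform(z) * np.sqrt(len(z) / (len(z) - 1.0)) ** 0  # raw projections
        for j in range(scores.shape[1]):
            ours = scores.iloc[:, j].to_numpy()
            theirs = sk_scores[:, j]
            agree = np.allclose(ours, theirs, atol=1e-8)
            flipped = np.allclose(ours, -theirs, atol=1e-8)
            assert agree or flipped

    def test_kaiser_retention_near_identity_correlation(self):
        rng = np.random.default_rng(3)
        mat = pd.DataFrame(rng.normal(size=(2000, 4)), columns=list("abcd"))
        eigval, scores, _ = pca_reduce(mat)
        assert np.allclose(eigval, 1.0, atol=0.15)
        assert scores.shape[1] == int((eigval > 1.0).sum())

    def test_constant_column_dropped_with_warning(self):
        rng = np.random.default_rng(4)
        mat = pd.DataFrame({"a": rng.normal(size=20), "b": rng.normal(size=20),
                            "c": np.ones(20)})
        with pytest.warns(UserWarning, match="constant"):
            eigval, _, _ = pca_reduce(mat)
        assert len(eigval) == 2


class TestWard:
    def test_two_separated_clouds_split_perfectly(self):
        rng = np.random.default_rng(5)
        pts = np.vstack([rng.normal(0, 0.3, size=(10, 2)),
                         rng.normal(10, 0.3, size=(10, 2))])
        scores = pd.DataFrame(pts, index=[f"s{i}" for i in range(20)])
        labels, _ = ward_cluster(scores, 2)
        assert len(set(labels.iloc[:10])) == 1
        assert len(set(labels.iloc[10:])) == 1
        assert labels.iloc[0] != labels.iloc[10]

    def test_k_equal_n_gives_singletons(self):
        rng = np.random.default_rng(6)
        scores = pd.DataFrame(rng.normal(size=(6, 2)))
        labels, _ = ward_cluster(scores, 6)
        assert labels.nunique() == 6

    def test_merge_order_matches_lance_williams_oracle(self):
        rng = np.random.default_rng(7)
        pts = rng.normal(size=(10, 3))
        scores = pd.DataFrame(pts)
        _, lm = ward_cluster(scores, 2)
        oracle = lance_williams_ward(pts)
        # reconstruct scipy's merge sets
        members = {i: frozenset([i]) for i in range(10)}
        for step, (a, b, *_rest) in enumerate(lm):
            members[10 + step] = members[int(a)] | members[int(b)]
        scipy_merges = [members[10 + s] for s in range(len(lm))]
        assert scipy_merges == oracle

    def test_k_out_of_range_raises(self):
        scores = pd.DataFrame(np.eye(4))
        with pytest.raises(ValueError):
            ward_cluster(scores, 1)

    def test_labels_invariant_to_row_order_and_rotation(self):
        rng = np.random.default_rng(8)
        pts = np.vstack([rng.normal(0, 0.5, size=(8, 2)),
                         rng.normal(6, 0.5, size=(8, 2)),
                         rng.normal((0, 8), 0.5, size=(8, 2))])
        idx = [f"s{i}" for i in range(24)]
        scores = pd.DataFrame(pts, index=idx)
        labels, _ = ward_cluster(scores, 3)
        perm = rng.permutation(24)
        labels_p, _ = ward_cluster(scores.iloc[perm], 3)
        theta = np.radians(40)
        rot = np.array([[np.cos(theta), -np.sin(theta)], [np.sin(theta), np.cos(theta)]])
        labels_r, _ = ward_cluster(pd.DataFrame(pts @ rot.T, index=idx), 3)
        for other in (labels_p.sort_index(), labels_r):
            tab = pd.crosstab(labels.sort_index(), other)
            assert (tab.gt(0).sum(axis=1) == 1).all()  # same partition


class TestSilhouette:
    def test_three_tight_blobs_maximal_at_three(self):
        rng = np.random.default_rng(9)
        pts = np.vstack([rng.normal(c, 0.2, size=(10, 2)) for c in [(0, 0), (8, 0), (0, 8)]])
        scores = pd.DataFrame(pts)
        profile, chosen = silhouette_profile(scores, k_range=range(2, 6), chosen_k=3)
        assert chosen == 3
        assert profile[3] > 0.9
        assert profile[3] == max(profile.values())

    def test_single_gaussian_cloud_low_everywhere(self):
        # a structureless cloud in 5-D (the dimensionality of retained PC
        # scores) admits no partition with silhouette near the blob regime
        rng = np.random.default_rng(10)
        scores = pd.DataFrame(rng.normal(size=(60, 5)))
        profile, _ = silhouette_profile(scores, k_range=range(2, 6))
        assert all(v < 0.3 for v in profile.values())

    def test_matches_brute_force_oracle(self):
        rng = np.random.default_rng(11)
        pts = rng.normal(size=(20, 2))
        scores = pd.DataFrame(pts)
        labels, _ = ward_cluster(scores, 4)
        from sklearn.metrics import silhouette_samples
        ours = silhouette_samples(pts, labels.to_numpy())
        oracle = brute_force_silhouette(pts, labels.to_numpy())
        np.testing.assert_allclose(ours, oracle, atol=1e-10)


class TestEndToEnd:
    def test_archetype_recovery_at_low_noise(self):
        # 3 trait archetypes + small noise -> k=3 partition matches generation
        rng = np.random.default_rng(12)
        archetypes = np.array([[10.0, 1.0, 4.0], [25.0, 4.0, 1.0], [15.0, 8.0, 2.5]])
        truth = np.repeat([0, 1, 2], [6, 6, 7])
        x = archetypes[truth] + rng.normal(0, 0.05, size=(19, 3))
        mat = pd.DataFrame(x, columns=["DBH", "BAI", "SST"],
                           index=[f"sp{i}" for i in range(19)])
        res = functional_grouping(mat, k=3, k_range=range(2, 8))
        tab = pd.crosstab(pd.Series(truth, index=mat.index), res.labels)
        assert (tab.gt(0).sum(axis=1) == 1).all()
        assert res.chosen_k == 3
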