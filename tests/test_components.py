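"""Compatibility Components: profiles, distances, PCA, matching, clustering."""

import numpy as np
import pytest
from scipy.spatial.distance import cdist

from sicomp.components import (
    CCResult,
    build_profiles,
    cluster_genotypes,
    diallel_components,
    distance_matrix,
    match_components,
    pca_components,
    PollinationProfile,
)
from sicomp.errors import NoSharedCoordinatesError, ValidationError
from tests.conftest import make_matrix

import pandas as pd


class TestBuildProfiles:
    def test_full_matrix_profile_lengths(self):
        m = make_matrix(np.arange(9).reshape(3, 3) % 11)
        profiles = build_profiles(m)
        assert len(profiles) == 3
        assert all(len(p.values) == 6 for p in profiles)
        assert not any(np.isnan(p.values).any() for p in profiles)

    def test_missing_cell_propagates_to_both_profiles(self):
        s = np.array([[0.0, np.nan], [5.0, 0.0]])
        profiles = build_profiles(make_matrix(s))
        assert np.isnan(profiles[0].values[1])  # row segment of genotype 1
        assert np.isnan(profiles[1].values[2])  # column segment of genotype 2

    def test_symmetric_matrix_row_equals_column_segment(self):
        s = np.array([[0, 5, 7], [5, 0, 9], [7, 9, 0]], dtype=float)
        for p in build_profiles(make_matrix(s)):
            np.testing.assert_array_equal(p.values[:3], p.values[3:])

    def test_mode_switch(self):
        m = make_matrix(np.zeros((3, 3)))
        assert len(build_profiles(m, mode="row")[0].values) == 3
        with pytest.raises(ValidationError):
            build_profiles(m, mode="bogus")


class TestDistanceMatrix:
    def test_identical_profiles_distance_zero(self):
        p = [PollinationProfile("a", np.array([1.0, 2, 3])),
             PollinationProfile("b", np.array([1.0, 2, 3]))]
        d = distance_matrix(p)
        assert d.loc["a", "b"] == 0.0

    def test_hand_computed_rescaled_distance(self):
        p = [PollinationProfile("a", np.array([1.0, 2.0, np.nan])),
             PollinationProfile("b", np.array([1.0, 0.0, 5.0]))]
        d = distance_matrix(p)
        assert d.loc["a", "b"] == pytest.approx(np.sqrt(6.0))

    def test_no_missing_equals_textbook_euclidean(self):
        rng = np.random.default_rng(4)
        X = rng.integers(0, 11, size=(5, 8)).astype(float)
        profiles = [PollinationProfile(f"g{i}", X[i]) for i in range(5)]
        d = distance_matrix(profiles)
        np.testing.assert_allclose(d.to_numpy(), cdist(X, X), atol=1e-12)

    def test_disjoint_observations_hard_error(self):
        p = [PollinationProfile("a", np.array([1.0, np.nan])),
             PollinationProfile("b", np.array([np.nan, 2.0]))]
        with pytest.raises(NoSharedCoordinatesError):
            distance_matrix(p)


class TestPCAComponents:
    def _dist(self, n=6, seed=0):
        rng = np.random.default_rng(seed)
        X = rng.random((n, 4)) * 10
        d = cdist(X, X)
        return pd.DataFrame(d, index=[f"g{i}" for i in range(n)],
                            columns=[f"g{i}" for i in range(n)])

    def test_variance_fractions_ordered_and_bounded(self):
        res = pca_components(self._dist(), k=4)
        v = res.variance_fraction
        assert np.all(np.diff(v) <= 1e-12)
        assert v.sum() <= 1 + 1e-12
        assert res.cumulative_variance[-1] <= 1 + 1e-12

    def test_variances_match_eigendecomposition(self):
        d = self._dist(n=4, seed=1)
        res = pca_components(d, k=4)
        X = d.to_numpy()
        Xc = X - X.mean(axis=0)
        eig = np.sort(np.linalg.eigvalsh(Xc.T @ Xc))[::-1]
        np.testing.assert_allclose(
            res.variance_fraction, eig[:4] / eig.sum(), atol=1e-10
        )

    def test_duplicated_genotypes_get_identical_scores(self):
        d = self._dist(n=5, seed=2).to_numpy()
        d2 = np.zeros((6, 6))
        d2[:5, :5] = d
        d2[5, :5] = d[0, :5]
        d2[:5, 5] = d[:5, 0]
        ids = [f"g{i}" for i in range(5)] + ["dup"]
        res = pca_components(pd.DataFrame(d2, index=ids, columns=ids), k=3)
        np.testing.assert_allclose(
            res.scores.loc["g0"].to_numpy(), res.scores.loc["dup"].to_numpy(),
            atol=1e-8,
        )

    def test_k_larger_than_n_rejected(self):
        with pytest.raises(ValidationError):
            pca_components(self._dist(n=3), k=4)


class TestMatchComponents:
    def _result(self, scores, tag="r"):
        n, k = scores.shape
        return CCResult(
            scores=pd.DataFrame(
                scores, index=[f"g{i}" for i in range(n)],
                columns=[f"PC{j + 1}" for j in range(k)],
            ),
            variance_fraction=np.linspace(0.4, 0.1, k),
            replicate_tag=tag,
        )

    def test_swapped_components_are_unswapped(self):
        rng = np.random.default_rng(6)
        s1 = rng.normal(size=(10, 4))
        s2 = s1[:, [0, 1, 3, 2]]  # components 3 and 4 switch order
        match, m1, m2 = match_components(self._result(s1), self._result(s2))
        assert match.mapping == {1: 1, 2: 2, 3: 4, 4: 3}
        assert all(c == pytest.approx(1.0) for c in match.correlation.values())
        np.testing.assert_allclose(m1.scores.to_numpy(), m2.scores.to_numpy())

    def test_sign_flips_recovered(self):
        rng = np.random.default_rng(7)
        s1 = rng.normal(size=(8, 4))
        match, m1, m2 = match_components(self._result(s1), self._result(-s1))
        assert match.mapping == {i: i for i in range(1, 5)}
        assert all(s == -1 for s in match.sign.values())
        np.testing.assert_allclose(m1.scores.to_numpy(), m2.scores.to_numpy())

    def test_independent_scores_still_bijection(self):
        rng = np.random.default_rng(8)
        match, *_ = match_components(
            self._result(rng.normal(size=(12, 4))),
            self._result(rng.normal(size=(12, 4))),
        )
        assert sorted(match.mapping.keys()) == [1, 2, 3, 4]
        assert sorted(match.mapping.values()) == [1, 2, 3, 4]

    def test_different_genotypes_rejected(self):
        rng = np.random.default_rng(9)
        r1 = self._result(rng.normal(size=(5, 4)))
        r2 = self._result(rng.normal(size=(5, 4)))
        r2.scores.index = [f"h{i}" for i in range(5)]
        with pytest.raises(ValidationError):
            match_components(r1, r2)


class TestClusterGenotypes:
    def test_separated_blobs_recovered(self):
        rng = np.random.default_rng(10)
        centers = np.array(
            [[0, 0, 0, 0], [50, 0, 0, 0], [0, 50, 0, 0], [0, 0, 50, 0]],
            dtype=float,
        )
        pts, truth = [], []
        for c, center in enumerate(centers):
            pts.append(center + rng.normal(0, 0.5, size=(6, 4)))
            truth += [c] * 6
        scores = pd.DataFrame(np.vstack(pts),
                              index=[f"g{i}" for i in range(24)])
        labels = cluster_genotypes(scores, n_clusters=4)
        # perfect recovery up to label renaming
        mapping = {}
        for lab, t in zip(labels, truth):
            mapping.setdefault(t, lab)
            assert mapping[t] == lab
        assert len(set(mapping.values())) == 4

    def test_n_clusters_equals_n_gives_singletons(self):
        rng = np.random.default_rng(11)
        scores = pd.DataFrame(rng.normal(size=(5, 4)))
        labels = cluster_genotypes(scores, n_clusters=5)
        assert len(set(labels)) == 5

    def test_order_permutation_invariance(self):
        rng = np.random.default_rng(12)
        scores = pd.DataFrame(
            rng.normal(size=(9, 4)) + np.repeat([[0], [20], [40]], 3, axis=0),
            index=[f"g{i}" for i in range(9)],
        )
        labels = cluster_genotypes(scores, n_clusters=3)
        perm = rng.permutation(9)
        labels_p = cluster_genotypes(scores.iloc[perm], n_clusters=3)
        # same partition up to relabeling
        for i in range(9):
            for j in range(9):
                a, b = scores.index[i], scores.index[j]
                assert (labels[a] == labels[b]) == (labels_p[a] == labels_p[b])


class TestEndToEnd:
    def test_no_missing_matches_complete_pipeline(self):
        rng = np.random.default_rng(13)
        scores = rng.integers(0, 11, size=(8, 8)).astype(float)
        m = make_matrix(scores)
        res = diallel_components(m, k=3)
        X = np.hstack([scores, scores.T])
        d = cdist(X, X)
        res2 = pca_components(
            pd.DataFrame(d, index=m.ids, columns=m.ids), k=3
        )
        np.testing.assert_allclose(
            np.abs(res.scores.to_numpy()), np.abs(res2.scores.to_numpy()),
            atol=1e-8,
        )

    def test_shared_si_genotypes_sit_closer_in_cc_space(self, tiny_pop):
        from sicomp.simulate import simulate_diallel
        from tests.conftest import tiny_sim_config

        cfg = tiny_sim_config(11, missing_rate=0.0)
        d = simulate_diallel(tiny_pop, cfg, "y")
        res = diallel_components(d, k=3)
        S = res.scores.to_numpy()
        same, diff = [], []
        recs = tiny_pop.records
        for i in range(len(recs)):
            for j in range(i + 1, len(recs)):
                dist = np.linalg.norm(S[i] - S[j])
                shared = all(
                    recs[i].si_genotype(l.name) == recs[j].si_genotype(l.name)
                    for l in tiny_pop.loci
                )
                none_shared = all(
                    not (recs[i].si_genotype(l.name) & recs[j].si_genotype(l.name))
                    for l in tiny_pop.loci
                )
                if shared:
                    same.append(dist)
                elif none_shared:
                    diff.append(dist)
        if same and diff:
            assert np.median(same) < np.median(diff)
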