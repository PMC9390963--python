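"""Profile construction, z-normalisation, FCM behaviour (against an
independent multi-restart reference), trend matching and the recovery of
the on/fast-off cluster pair across the two tumour models."""

import warnings

import numpy as np
import pandas as pd
import pytest
from hypothesis import given
from hypothesis import strategies as st
from hypothesis.extra.numpy import arrays

from onoffgrn.clustering import (
    FuzzyCMeans,
    ProfileMatrix,
    average_replicates,
    fuzzy_cmeans,
    log_transform,
    match_clusters,
    overlap_genes,
    znormalize,
)
from ._oracles import best_fcm_objective


def profile(values, arm=("AB1", "responder"), layer="mean", genes=None, tps=None):
    values = np.atleast_2d(np.asarray(values, dtype=float))
    genes = genes or [f"g{i}" for i in range(values.shape[0])]
    tps = tps or list(range(values.shape[1]))
    return ProfileMatrix(pd.DataFrame(values, index=genes, columns=tps), arm=arm, layer=layer)


class TestAverageReplicates:
    @pytest.fixture()
    def toy(self):
        matrix = pd.DataFrame(
            {"s1": [4.0, 1.0], "s2": [6.0, 3.0], "s3": [10.0, 7.0]},
            index=["gA", "gB"],
        )
        meta = pd.DataFrame(
            {
                "sample_id": ["s1", "s2", "s3"],
                "model": ["AB1"] * 3,
                "timepoint_day": [2, 2, 4],
                "response": ["responder"] * 3,
            }
        )
        return matrix, meta

    def test_mean_of_two_replicates(self, toy):
        prof = average_replicates(*toy, model="AB1", response="responder")
        assert prof.values.loc["gA", 2] == 5.0
        assert prof.values.loc["gA", 4] == 10.0  # single replicate: identity

    def test_sample_order_irrelevant(self, toy):
        matrix, meta = toy
        shuffled = matrix[["s3", "s1", "s2"]]
        a = average_replicates(matrix, meta, "AB1", "responder")
        b = average_replicates(shuffled, meta, "AB1", "responder")
        pd.testing.assert_frame_equal(a.values, b.values)

    def test_missing_timepoint_named_in_error(self, toy):
        matrix, meta = toy
        meta2 = meta.copy()
        meta2.loc[2, "response"] = "non_responder"  # day 4 now lacks a responder
        with pytest.raises(ValueError, match="timepoint 4"):
            average_replicates(matrix, meta2, "AB1", "responder")


class TestZnormalize:
    def test_hand_computed_row(self):
        z = znormalize(profile([[1, 2, 3, 4]]))
        np.testing.assert_allclose(
            z.values.iloc[0], [-1.161895, -0.387298, 0.387298, 1.161895], atol=1e-6
        )

    def test_constant_row_flagged_all_zero(self):
        z = znormalize(profile([[5, 5, 5, 5], [1, 2, 3, 4]]))
        assert (z.values.iloc[0] == 0).all()
        assert z.constant_genes == frozenset({"g0"})

    def test_rows_standardised(self):
        rng = np.random.default_rng(0)
        z = znormalize(profile(rng.uniform(0, 50, (20, 4))))
        np.testing.assert_allclose(z.values.mean(axis=1), 0, atol=1e-10)
        np.testing.assert_allclose(z.values.std(axis=1, ddof=1), 1, atol=1e-10)

    def test_log_transform_requires_mean_layer(self):
        z = znormalize(profile([[1, 2, 3, 4]]))
        with pytest.raises(ValueError, match="mean"):
            log_transform(z)


class TestFuzzyCMeans:
    def test_near_hard_limit_separable_groups(self):
        rng = np.random.default_rng(1)
        X = np.vstack(
            [np.tile([1.0, 1.0, -1.0, -1.0], (15, 1)), np.tile([-1.0, -1.0, 1.0, 1.0], (15, 1))]
        ) + rng.normal(0, 0.05, (30, 4))
        fcm = FuzzyCMeans(n_clusters=2, m=1.05, random_state=0).fit(X)
        assert (fcm.membership_.max(axis=1) > 0.99).all()
        truth = np.repeat([0, 1], 15)
        labels = fcm.labels_
        agree = max((labels == truth).mean(), (labels != truth).mean())
        assert agree == 1.0

    def test_duplicated_rows_get_identical_memberships(self):
        rng = np.random.default_rng(2)
        X = rng.normal(size=(10, 4))
        X = np.vstack([X, X[3]])
        fcm = FuzzyCMeans(n_clusters=3, m=1.5, random_state=0).fit(X)
        np.testing.assert_allclose(fcm.membership_[3], fcm.membership_[-1], atol=1e-9)

    def test_objective_matches_multi_restart_reference(self):
        """Final objective within 1e-6 of the best of 200 random restarts of
        an independent straightforward FCM implementation."""
        rng = np.random.default_rng(3)
        templates = np.array([[1, 0.8, -0.8, -1], [-1, -0.4, 0.4, 1], [1, -1, 1, -1]], dtype=float)
        X = np.vstack([t + rng.normal(0, 0.15, (13, 4)) for t in templates])
        ours = FuzzyCMeans(n_clusters=3, m=1.5, random_state=0).fit(X).objective_
        best = best_fcm_objective(X, k=3, m=1.5, n_restarts=200, seed=100)
        assert ours == pytest.approx(best, abs=1e-6)

    def test_objective_non_increasing_across_iterations(self):
        rng = np.random.default_rng(4)
        X = rng.normal(size=(25, 4))
        m = 1.8
        centers = X[:3].copy()
        objs = []
        for _ in range(20):
            u = FuzzyCMeans._memberships(X, centers, m)
            um = u**m
            centers = (um.T @ X) / um.sum(axis=0)[:, None]
            objs.append(FuzzyCMeans._objective(X, centers, u, m))
        assert all(b <= a + 1e-9 for a, b in zip(objs, objs[1:]))

    @given(
        arrays(np.float64, (12, 4), elements=st.floats(-5, 5, allow_nan=False)),
    )
    def test_membership_rows_sum_to_one(self, X):
        if np.unique(X, axis=0).shape[0] < 3:
            return
        fcm = FuzzyCMeans(n_clusters=3, m=2.0, n_init=2, random_state=0).fit(X)
        np.testing.assert_allclose(fcm.membership_.sum(axis=1), 1.0, atol=1e-8)

    def test_k_larger_than_distinct_profiles_rejected(self):
        X = np.tile([1.0, 2.0, 3.0, 4.0], (5, 1))
        with pytest.raises(ValueError, match="distinct"):
            FuzzyCMeans(n_clusters=3).fit(X)


class TestMatchClusters:
    def _fc(self, centroids):
        n = len(centroids)
        memb = pd.DataFrame(np.eye(n), index=[f"g{i}" for i in range(n)])
        from onoffgrn.clustering import FuzzyClustering

        return FuzzyClustering(
            k=n, m=2.0, centroids=pd.DataFrame(centroids), membership=memb,
            objective=0.0, seed=0, n_iter=1,
        )

    def test_identical_centroids_r_one(self):
        a = self._fc([[0, 1, 2, 3]])
        assert match_clusters(a, a, r_min=0.8)[0].pearson_r == pytest.approx(1.0)

    def test_negated_centroid_excluded(self):
        a = self._fc([[0, 1, 2, 3]])
        b = self._fc([[0, -1, -2, -3]])
        assert match_clusters(a, b, r_min=0.8) == []
        assert match_clusters(a, b, r_min=-1.0)[0].pearson_r == pytest.approx(-1.0)

    def test_affine_invariance(self):
        a = self._fc([[0, 1, 2, 3]])
        b = self._fc([[1, 3, 5, 7]])
        assert match_clusters(a, b, r_min=0.8)[0].pearson_r == pytest.approx(1.0)

    def test_constant_centroid_skipped_with_warning(self):
        a = self._fc([[1, 1, 1, 1]])
        b = self._fc([[0, 1, 2, 3]])
        with pytest.warns(UserWarning, match="constant centroid"):
            assert match_clusters(a, b, r_min=-1.0) == []

    def test_symmetry_mirrored(self):
        a = self._fc([[0, 1, 2, 3], [3, 2, 1, 0]])
        b = self._fc([[0, 2, 4, 6]])
        fwd = {(m.cluster_a, m.cluster_b) for m in match_clusters(a, b, r_min=0.8)}
        rev = {(m.cluster_b, m.cluster_a) for m in match_clusters(b, a, r_min=0.8)}
        assert fwd == rev

    def test_overlap_is_set_intersection(self):
        from onoffgrn.clustering import FuzzyClustering

        memb_a = pd.DataFrame(
            [[1, 0], [1, 0], [1, 0], [0, 1]], index=["g1", "g2", "g3", "g4"]
        )
        memb_b = pd.DataFrame(
            [[0, 1], [1, 0], [1, 0], [1, 0]], index=["g1", "g2", "g3", "g4"]
        )
        a = FuzzyClustering(k=2, m=2, centroids=pd.DataFrame(np.zeros((2, 4))), membership=memb_a, objective=0, seed=0, n_iter=1)
        b = FuzzyClustering(k=2, m=2, centroids=pd.DataFrame(np.zeros((2, 4))), membership=memb_b, objective=0, seed=0, n_iter=1)
        assert overlap_genes(a, 0, b, 0) == {"g2", "g3"}
        assert overlap_genes(a, 1, b, 1) == set()


def is_fast_onoff_shape(centroid: np.ndarray) -> bool:
    """Early peak, still high at the second timepoint, low at the end."""
    c = np.asarray(centroid, dtype=float)
    return int(c.argmax()) <= 1 and c[1] >= 0.5 and c[-1] <= -0.5


class TestCrossModelRecovery:
    def test_single_onoff_matched_pair_recovers_fast_isgs(self, default_sim):
        """Across AB1 and Renca responder clusterings exactly one matched
        pair shows the on/fast-off shape, and its overlap recovers >= 90% of
        the true fast ISGs."""
        matrix, meta, truth = default_sim
        fcs = {}
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            for model in ("AB1", "Renca"):
                prof = average_replicates(matrix, meta, model, "responder")
                fcs[model] = fuzzy_cmeans(znormalize(log_transform(prof)), k=6, seed=17)
        matches = match_clusters(fcs["AB1"], fcs["Renca"], r_min=0.8)
        shaped = [
            m
            for m in matches
            if is_fast_onoff_shape(fcs["AB1"].centroids.iloc[m.cluster_a].to_numpy())
            and is_fast_onoff_shape(fcs["Renca"].centroids.iloc[m.cluster_b].to_numpy())
        ]
        assert len(shaped) == 1
        ov = overlap_genes(fcs["AB1"], shaped[0].cluster_a, fcs["Renca"], shaped[0].cluster_b)
        fast = truth.fast_isg_genes
        assert len(ov & fast) / len(fast) >= 0.9

    def test_cluster_relabelling_leaves_overlap_invariant(self):
        rng = np.random.default_rng(5)
        X = znormalize(profile(rng.uniform(0, 10, (30, 4))))
        fc = fuzzy_cmeans(X, k=3, m=1.6, seed=0)
        perm = [2, 0, 1]
        from onoffgrn.clustering import FuzzyClustering

        relabelled = FuzzyClustering(
            k=fc.k, m=fc.m,
            centroids=fc.centroids.iloc[perm].reset_index(drop=True),
            membership=fc.membership.iloc[:, perm].set_axis(range(3), axis=1),
            objective=fc.objective, seed=fc.seed, n_iter=fc.n_iter,
        )
        for c in range(3):
            assert overlap_genes(fc, perm[c], fc, perm[c]) == overlap_genes(relabelled, c, relabelled, c)
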