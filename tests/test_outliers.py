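"""Five-detector consensus outlier framework: oracles and contracts."""

import itertools

import numpy as np
import pandas as pd
import pytest

from nirhsi.errors import ConfigError, EmptyInputError, IdMismatchError
from nirhsi.outliers import (
    METHODS,
    consensus,
    detect_outliers,
    iqr_flags,
    isolation_forest_flags,
    lof_flags,
    mahalanobis_estimates,
    mahalanobis_flags,
    remove_strong,
    standardize_features,
    zscore_flags,
)


def table_of(arr, ids=None):
    arr = np.atleast_2d(np.asarray(arr, dtype=float))
    ids = ids or [f"s{i}" for i in range(arr.shape[0])]
    return pd.DataFrame(arr, index=pd.Index(ids, name="sample_id"))


class TestStandardize:
    def test_closed_form_population_z(self):
        z, means, sds, zero = standardize_features(table_of([[1], [2], [3]]))
        np.testing.assert_allclose(
            z.to_numpy().ravel(), [-1.224745, 0, 1.224745], atol=1e-5
        )
        assert means.iloc[0] == 2 and zero == []

    def test_constant_column_passes_through_as_zeros(self):
        t = table_of([[1, 5], [2, 5], [3, 5]])
        z, _, _, zero = standardize_features(t)
        assert np.all(z[1] == 0) and zero == [1]

    def test_idempotent(self, rng):
        t = table_of(rng.normal(size=(10, 4)))
        z1, *_ = standardize_features(t)
        z2, *_ = standardize_features(z1)
        np.testing.assert_allclose(z1.to_numpy(), z2.to_numpy(), atol=1e-10)

    def test_too_few_samples(self):
        with pytest.raises(EmptyInputError):
            standardize_features(table_of([[1], [2]]))


class TestZscore:
    def test_planted_10sd_sample_flagged(self, rng):
        X = rng.normal(size=(20, 6))
        X[3, 2] = 10 * X[:, 2].std() * 5  # gross outlier on one feature
        z, *_ = standardize_features(table_of(X))
        assert zscore_flags(z).loc["s3"]

    def test_no_flags_when_all_within_3sd(self):
        z, *_ = standardize_features(table_of([[0.0], [1.0], [2.0], [1.0]]))
        assert not zscore_flags(z).any()

    def test_matches_exhaustive_scan(self, rng):
        z, *_ = standardize_features(table_of(rng.standard_t(3, size=(30, 8))))
        got = zscore_flags(z, z_max=2.5)
        brute = pd.Series(
            [(np.abs(z.iloc[i].to_numpy()) > 2.5).any() for i in range(len(z))],
            index=z.index,
        )
        pd.testing.assert_series_equal(got, brute, check_names=False)

    def test_sample_order_invariance(self, rng):
        z, *_ = standardize_features(table_of(rng.normal(size=(12, 5))))
        flags = zscore_flags(z)
        perm = z.sample(frac=1, random_state=0)
        pd.testing.assert_series_equal(
            zscore_flags(perm).sort_index(), flags.sort_index(), check_names=False
        )


class TestIqr:
    def test_sample_outside_all_fences_flagged(self, rng):
        X = rng.normal(size=(20, 5))
        X[0] = 50.0
        assert iqr_flags(table_of(X)).loc["s0"]

    def test_sample_inside_fences_not_flagged(self, rng):
        X = rng.uniform(size=(20, 5))
        X[0] = 0.5
        assert not iqr_flags(table_of(X)).loc["s0"]

    def test_fraction_matches_brute_force_fence_test(self, rng):
        X = rng.standard_t(3, size=(24, 7))
        t = table_of(X)
        got = iqr_flags(t, fence_k=1.5, feature_fraction=0.2)
        q25, q75 = np.percentile(X, [25, 75], axis=0)
        iqr = q75 - q25
        lo, hi = q25 - 1.5 * iqr, q75 + 1.5 * iqr
        frac = ((X < lo) | (X > hi)).mean(axis=1)
        brute = pd.Series(frac > 0.2, index=t.index)
        pd.testing.assert_series_equal(got, brute, check_names=False)


class TestMahalanobis:
    def test_distances_match_dense_inverse_quadratic_form(self, rng):
        t = table_of(rng.normal(size=(10, 3)))
        _, d2 = mahalanobis_flags(t)
        scores, loc, cov, q = mahalanobis_estimates(t)
        prec = np.linalg.inv(cov)
        brute = [
            float((scores[i] - loc) @ prec @ (scores[i] - loc))
            for i in range(10)
        ]
        np.testing.assert_allclose(d2.to_numpy(), brute, rtol=1e-10)

    def test_identity_covariance_reduces_to_euclidean_norm(self, rng):
        # whitened data: sample covariance exactly identity, mean zero.
        # PCA rotation preserves norms, so d2 = ||z||^2 (non-robust path).
        X = rng.normal(size=(40, 3))
        X -= X.mean(axis=0)
        L = np.linalg.cholesky(np.cov(X.T, bias=True))
        Z = X @ np.linalg.inv(L).T
        t = table_of(Z)
        _, d2 = mahalanobis_flags(t, robust=False)
        np.testing.assert_allclose(d2.to_numpy(), (Z**2).sum(axis=1), rtol=0.05)

    def test_gross_outlier_flagged_at_alpha_001(self, rng):
        X = rng.normal(size=(30, 5))
        X[7] = 10.0
        flags, _ = mahalanobis_flags(table_of(X), alpha=0.001)
        assert flags.loc["s7"]

    def test_order_invariance(self, rng):
        t = table_of(rng.normal(size=(15, 4)))
        f1, _ = mahalanobis_flags(t)
        shuffled = t.sample(frac=1, random_state=3)
        f2, _ = mahalanobis_flags(shuffled)
        pd.testing.assert_series_equal(
            f1.sort_index(), f2.sort_index(), check_names=False
        )


class TestEnsembleDetectors:
    def test_isolation_forest_flag_count_and_determinism(self, rng):
        t = table_of(rng.normal(size=(30, 4)))
        f1 = isolation_forest_flags(t, contamination=0.1, seed=5)
        f2 = isolation_forest_flags(t, contamination=0.1, seed=5)
        assert f1.sum() == round(0.1 * 30)
        pd.testing.assert_series_equal(f1, f2)

    def test_isolation_forest_ranks_gross_outlier_first(self):
        for seed in range(10):
            rng = np.random.default_rng(seed)
            X = rng.normal(size=(40, 3))
            X[11] = 12.0
            flags = isolation_forest_flags(table_of(X), contamination=0.05, seed=seed)
            assert flags.loc["s11"], f"seed {seed}"

    def test_lof_flag_count_and_far_point(self, rng):
        X = rng.uniform(size=(30, 3))
        X[4] = 8.0
        flags = lof_flags(table_of(X), contamination=0.1)
        assert flags.sum() == 3 and flags.loc["s4"]

    def test_lof_duplicated_dataset_symmetric_flags(self, rng):
        X = rng.normal(size=(15, 3))
        X[:3] += 15.0  # three clear outliers
        dup = np.vstack([X, X])
        flags = lof_flags(table_of(dup), contamination=0.2)
        first, second = flags.to_numpy()[:15], flags.to_numpy()[15:]
        np.testing.assert_array_equal(first, second)


class TestConsensus:
    @pytest.mark.parametrize(
        "votes,category",
        [
            ((True, True, True, False, False), "strong"),
            ((True, True, False, False, False), "moderate"),
            ((True, False, False, False, False), "normal"),
            ((False,) * 5, "normal"),
            ((True,) * 5, "strong"),
        ],
    )
    def test_category_rule(self, votes, category):
        df = pd.DataFrame([votes], columns=list(METHODS), index=["a"])
        assert consensus(df).category.loc["a"] == category

    def test_all_32_vote_patterns_partition_correctly(self):
        rows = list(itertools.product([False, True], repeat=5))
        df = pd.DataFrame(rows, columns=list(METHODS))
        report = consensus(df)
        for pattern, cat, cnt in zip(rows, report.category, report.vote_count):
            expected = "strong" if sum(pattern) >= 3 else (
                "moderate" if sum(pattern) == 2 else "normal"
            )
            assert cat == expected and cnt == sum(pattern)

    def test_wrong_column_count_rejected(self):
        with pytest.raises(ConfigError):
            consensus(pd.DataFrame([[True, False]], columns=["zscore", "iqr"]))


class DummySample:
    def __init__(self, sid):
        self.sample_id = sid


class TestRemoveStrong:
    def make_report(self, ids, strong):
        votes = pd.DataFrame(
            [[sid in strong] * 3 + [False, False] for sid in ids],
            columns=list(METHODS),
            index=ids,
        )
        return consensus(votes)

    def test_survivors_equal_set_difference(self):
        ids = [f"s{i}" for i in range(12)]
        strong = {"s2", "s7", "s9"}
        cohort = [DummySample(i) for i in ids]
        report = self.make_report(ids, strong)
        survivors = remove_strong(cohort, report)
        assert [c.sample_id for c in survivors] == [
            i for i in ids if i not in strong
        ]

    def test_identity_when_no_strong(self):
        ids = ["a", "b", "c"]
        cohort = [DummySample(i) for i in ids]
        assert remove_strong(cohort, self.make_report(ids, set())) == cohort

    def test_uncovered_id_raises(self):
        report = self.make_report(["a", "b"], set())
        with pytest.raises(IdMismatchError):
            remove_strong([DummySample("zz")], report)


def test_detect_outliers_report_is_consistent(rng):
    X = rng.normal(size=(30, 6))
    X[1] += 20.0
    report = detect_outliers(table_of(X), seed=0)
    assert (report.vote_count == report.votes.sum(axis=1)).all()
    assert report.category.loc["s1"] == "strong"
    cats = set(report.category.unique())
    assert cats <= {"normal", "moderate", "strong"}
    assert set(report.method_params) >= {"z_max", "alpha", "contamination", "seed"}
    # serialization round-trips through JSON
    import json

    payload = json.loads(json.dumps(report.to_dict()))
    assert payload["strong_ids"] == report.strong_ids
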