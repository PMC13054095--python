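"""Patch extraction, autoencoder training, embedding and aggregation."""

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from nirhsi import (
    AutoencoderConfig,
    HyperCube,
    aggregate_features,
    encode_patches,
    extract_patches,
    features_table,
    train_autoencoder,
)
from nirhsi.errors import EmptyInputError, ShapeMismatchError
from nirhsi.features import EmbeddingSet

from conftest import cohort_features, make_cohort


def cube_of(h, w, b, rng=None, fill=None):
    data = (
        np.full((h, w, b), fill, dtype=np.float32)
        if fill is not None
        else rng.random((h, w, b)).astype(np.float32)
    )
    return HyperCube("c", data, np.linspace(1000, 1700, b))


def brute_force_origins(h, w, p, stride):
    return [
        (r, c)
        for r in range(0, h - p + 1, stride)
        for c in range(0, w - p + 1, stride)
    ]


class TestExtractPatches:
    def test_exact_fit_yields_single_patch_at_origin(self, rng):
        ps = extract_patches(cube_of(5, 5, 4, rng), patch_size=5, stride=1)
        assert len(ps) == 1 and tuple(ps.origins[0]) == (0, 0)

    def test_six_by_six_stride_one_yields_four_patches(self, rng):
        ps = extract_patches(cube_of(6, 6, 4, rng), patch_size=5, stride=1)
        assert len(ps) == 4  # (6 - 5 + 1)^2 by enumeration

    def test_patch_too_large_raises(self, rng):
        with pytest.raises(ShapeMismatchError):
            extract_patches(cube_of(4, 4, 3, rng), patch_size=5)

    @settings(max_examples=25, deadline=None)
    @given(
        h=st.integers(5, 20),
        w=st.integers(5, 20),
        stride=st.integers(1, 4),
    )
    def test_count_and_origins_match_exhaustive_enumeration(self, h, w, stride):
        cube = cube_of(h, w, 3, np.random.default_rng(0))
        ps = extract_patches(cube, patch_size=5, stride=stride)
        expected = brute_force_origins(h, w, 5, stride)
        assert len(ps) == len(expected)
        assert [tuple(o) for o in ps.origins] == expected

    def test_patch_content_matches_direct_slice(self, rng):
        cube = cube_of(9, 8, 3, rng)
        ps = extract_patches(cube, patch_size=5, stride=2)
        for patch, (r, c) in zip(ps.patches, ps.origins):
            np.testing.assert_array_equal(patch, cube.data[r : r + 5, c : c + 5, :])


class TestTrainAutoencoder:
    def test_constant_patches_reconstructed_to_numerical_zero_loss(self):
        patches = np.full((64, 5, 5, 12), 0.7, dtype=np.float32)
        model = train_autoencoder(
            patches,
            AutoencoderConfig(
                latent_dim=8,
                epochs=80,
                batch_size=16,
                learning_rate=0.01,
                dropout=0.0,
                early_stop_patience=80,
                min_delta=0.0,
                seed=0,
            ),
        )
        assert min(model.loss_history) < 1e-4

    def test_noise_patches_hit_irreducible_floor(self):
        sigma = 0.3
        rng = np.random.default_rng(0)
        patches = (sigma * rng.standard_normal((512, 5, 5, 12))).astype(np.float32)
        model = train_autoencoder(patches, AutoencoderConfig(latent_dim=8, epochs=15, seed=0))
        # compressing i.i.d. noise cannot beat the noise variance by much
        assert model.loss_history[-1] >= 0.5 * sigma**2

    def test_final_loss_never_exceeds_first_epoch(self, tiny_features):
        _, _, model, _ = tiny_features
        assert model.loss_history[-1] <= model.loss_history[0]

    def test_same_seed_same_data_identical_loss(self):
        rng = np.random.default_rng(3)
        patches = rng.random((128, 5, 5, 12)).astype(np.float32)
        cfg = AutoencoderConfig(latent_dim=8, epochs=4, seed=5)
        a = train_autoencoder(patches, cfg)
        b = train_autoencoder(patches, cfg)
        assert a.loss_history == b.loss_history

    def test_empty_pool_raises(self):
        with pytest.raises(EmptyInputError):
            train_autoencoder(np.zeros((0, 5, 5, 12), dtype=np.float32))

    def test_save_load_round_trip(self, tmp_path, tiny_features):
        _, _, model, _ = tiny_features
        rng = np.random.default_rng(0)
        patches = rng.random((8, *model.patch_shape)).astype(np.float32)
        model.save(tmp_path / "ae.npz")
        from nirhsi.features import EncoderModel

        back = EncoderModel.load(tmp_path / "ae.npz")
        np.testing.assert_allclose(back.encode(patches), model.encode(patches))
        assert back.descriptor == model.descriptor


class TestEncodePatches:
    def test_row_count_and_duplicates(self, tiny_cohort, tiny_features):
        cubes, _ = tiny_cohort
        _, _, model, _ = tiny_features
        ps = extract_patches(cubes[0])
        ps.patches[1] = ps.patches[0]  # plant a duplicate
        emb = encode_patches(model, ps)
        assert len(emb) == len(ps)
        np.testing.assert_array_equal(emb.vectors[0], emb.vectors[1])

    def test_batch_partitioning_invariance(self, tiny_cohort, tiny_features):
        cubes, _ = tiny_cohort
        _, _, model, _ = tiny_features
        ps = extract_patches(cubes[0])
        one = model.encode(ps.patches, batch_size=len(ps))
        many = model.encode(ps.patches, batch_size=7)
        np.testing.assert_allclose(one, many, atol=1e-5)

    def test_shape_mismatch_raises(self, tiny_features):
        _, _, model, _ = tiny_features
        with pytest.raises(ShapeMismatchError):
            model.encode(np.zeros((2, 4, 4, 3), dtype=np.float32))


def embset(rows):
    rows = np.asarray(rows, dtype=float)
    origins = np.stack([np.arange(len(rows)), np.zeros(len(rows), int)], axis=1)
    return EmbeddingSet(rows, origins, "e")


class TestAggregateFeatures:
    def test_mean_max_on_hand_instance(self):
        gf = aggregate_features(embset([[0, 2], [2, 0]]))
        np.testing.assert_allclose(gf.block("mean"), [1, 1])
        np.testing.assert_allclose(gf.block("max"), [2, 2])

    def test_population_sd_convention(self):
        # population SD of {0, 2} is 1 (ddof 0), not sqrt(2)
        gf = aggregate_features(embset([[0, 2], [2, 0]]))
        np.testing.assert_allclose(gf.block("sd"), [1, 1])

    def test_linear_interpolation_iqr(self):
        # q75 - q25 of {0, 2} under linear interpolation = 1.5 - 0.5 = 1
        gf = aggregate_features(embset([[0, 2], [2, 0]]))
        np.testing.assert_allclose(gf.block("iqr"), [1, 1])

    def test_matches_numpy_oracle_on_random_rows(self, rng):
        rows = rng.normal(size=(13, 4))
        gf = aggregate_features(embset(rows))
        np.testing.assert_allclose(gf.block("mean"), rows.mean(axis=0))
        np.testing.assert_allclose(gf.block("max"), rows.max(axis=0))
        np.testing.assert_allclose(gf.block("sd"), rows.std(axis=0, ddof=0))
        q75, q25 = np.percentile(rows, [75, 25], axis=0)
        np.testing.assert_allclose(gf.block("iqr"), q75 - q25)

    def test_single_row_degenerate_statistics(self):
        gf = aggregate_features(embset([[3.0, -1.0, 2.0]]))
        np.testing.assert_allclose(gf.block("mean"), [3, -1, 2])
        np.testing.assert_allclose(gf.block("max"), [3, -1, 2])
        np.testing.assert_allclose(gf.block("sd"), 0)
        np.testing.assert_allclose(gf.block("iqr"), 0)

    def test_permutation_invariance(self, rng):
        rows = rng.normal(size=(9, 3))
        a = aggregate_features(embset(rows)).vector
        b = aggregate_features(embset(rows[rng.permutation(9)])).vector
        np.testing.assert_allclose(a, b)

    def test_block_order_and_invariants(self, tiny_features):
        feats, _, _, _ = tiny_features
        d = feats.shape[1] // 4
        mean_blk = feats.iloc[:, :d].to_numpy()
        max_blk = feats.iloc[:, d : 2 * d].to_numpy()
        assert np.all(max_blk >= mean_blk - 1e-6)
        assert np.all(feats.iloc[:, 2 * d :].to_numpy() >= -1e-9)  # SD, IQR >= 0

    def test_empty_set_raises(self):
        with pytest.raises(EmptyInputError):
            aggregate_features(embset(np.zeros((0, 3))))


class TestClassSeparation:
    def test_global_features_separate_classes_at_high_effect_size(self):
        """Energy-distance permutation test on the class clouds, 10 cohorts.

        With effect_size 6 the two classes' standardized global-feature
        clouds are separated: per-cohort permutation p-values combined
        over 10 seeds (Fisher's method) are significant at alpha 0.01.
        """
        from scipy import stats
        from scipy.spatial.distance import cdist

        from nirhsi.outliers import standardize_features

        def energy_stat(X, Y):
            return (
                2 * cdist(X, Y).mean()
                - cdist(X, X).mean()
                - cdist(Y, Y).mean()
            )

        pvals = []
        for seed in range(10):
            cubes, labels = make_cohort(n=14, seed=seed)
            feats, _, _ = cohort_features(cubes, seed=seed, epochs=5)
            z, _, _, _ = standardize_features(feats)
            X = z.to_numpy()[labels == 1]
            Y = z.to_numpy()[labels == 0]
            obs = energy_stat(X, Y)
            rng = np.random.default_rng(seed)
            pooled = z.to_numpy()
            n1 = len(X)
            null = []
            for _ in range(199):
                perm = rng.permutation(len(pooled))
                null.append(energy_stat(pooled[perm[:n1]], pooled[perm[n1:]]))
            pvals.append((1 + sum(v >= obs for v in null)) / 200)
        fisher = -2 * np.log(pvals).sum()
        p_combined = stats.chi2.sf(fisher, df=2 * len(pvals))
        assert p_combined < 0.01, f"per-seed p-values {pvals}"


def test_features_table_layout(tiny_features):
    feats, _, model, _ = tiny_features
    d = model.latent_dim
    assert feats.shape[1] == 4 * d
    assert list(feats.columns[:2]) == ["mean_000", "mean_001"]
    assert feats.columns[3 * d] == "iqr_000"
    assert feats.index.name == "sample_id"
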