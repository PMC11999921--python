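"""Loss oracles, architecture widths, PCA and training behaviour."""

import numpy as np
import pytest
from scipy import stats

from realign.alignment import (LossConfig, alignment_loss, attach_encoders,
                               classification_loss, contrastive_pair_count,
                               generation_loss, generation_loss_train,
                               reduce_voxels_pca, teacher_labels, train_alignment,
                               AlignedModel)
from realign.backbone import BackboneConfig, build_backbone
from realign.minidiff import Tensor


def brute_force_generation_loss(S, S_hat):
    """From-first-principles pairwise loop with scipy rank correlations."""
    n = S.shape[0]
    mse = np.mean((S - S_hat) ** 2)
    pos = 1 - np.mean([stats.spearmanr(S[i], S_hat[i]).statistic for i in range(n)])
    neg = np.mean([stats.spearmanr(S[i], S_hat[j]).statistic
                   for i in range(n) for j in range(n) if i != j])
    return mse + pos + neg


class TestGenerationLoss:
    def test_perfect_generation_rank_orthogonal_stimuli(self):
        S = np.array([[1.0, 2, 3, 4], [2, 4, 1, 3]])
        total, terms = generation_loss(S, S)
        assert total == 0.0
        assert terms["mse"] == 0.0 and terms["positive"] == 0.0 and terms["negative"] == 0.0

    def test_anticorrelated_limit(self):
        S = np.array([[1.0, 2, 3, 4], [4, 3, 2, 1]])
        total, terms = generation_loss(S, S)
        assert total == -1.0 and terms["negative"] == -1.0

    def test_pair_count_at_batch_16(self):
        rng = np.random.default_rng(0)
        _, terms = generation_loss(rng.normal(size=(16, 8)), rng.normal(size=(16, 8)))
        assert terms["n_pairs"] == 256
        assert contrastive_pair_count(16) == 16 + 16 * 15

    def test_matches_brute_force_on_random_batches(self):
        rng = np.random.default_rng(1)
        for _ in range(40):
            n, d = rng.integers(2, 7), rng.integers(3, 11)
            S, Sh = rng.normal(size=(n, d)), rng.normal(size=(n, d))
            total, _ = generation_loss(S, Sh)
            assert abs(total - brute_force_generation_loss(S, Sh)) < 1e-10

    def test_bounds_and_permutation_invariance(self):
        rng = np.random.default_rng(2)
        for _ in range(25):
            n, d = rng.integers(2, 8), rng.integers(3, 12)
            S, Sh = rng.normal(size=(n, d)), rng.normal(size=(n, d))
            total, terms = generation_loss(S, Sh)
            assert terms["mse"] >= 0
            assert 0 <= terms["positive"] <= 2
            assert -1 <= terms["negative"] <= 1
            assert total >= -1
            perm = rng.permutation(n)
            total_p, _ = generation_loss(S[perm], Sh[perm])
            assert total_p == pytest.approx(total, abs=1e-12)

    def test_constant_row_defined_as_zero_correlation(self):
        S = np.array([[1.0, 1, 1, 1], [1, 2, 3, 4]])
        Sh = np.array([[1.0, 2, 3, 4], [1, 2, 3, 4]])
        with pytest.warns(UserWarning):
            _, terms = generation_loss(S, Sh)
        # row 0 is constant: rho(S_0, .) == 0 for both its pairs
        assert terms["positive"] == pytest.approx(1 - (0 + 1) / 2)

    def test_shape_errors(self):
        with pytest.raises(ValueError):
            generation_loss(np.zeros((2, 3)), np.zeros((3, 2)))
        with pytest.raises(ValueError):
            generation_loss(np.zeros((1, 3)), np.zeros((1, 3)))

    def test_train_surrogate_tracks_exact_loss_on_gaussian_data(self):
        """The Pearson surrogate approximates Spearman for near-Gaussian rows."""
        rng = np.random.default_rng(3)
        S = rng.normal(size=(6, 64))
        Sh = rng.normal(size=(6, 64))
        exact, _ = generation_loss(S, Sh)
        surrogate, _ = generation_loss_train(Tensor(S), Sh, LossConfig())
        assert abs(exact - surrogate.item()) < 0.25


class TestClassificationLoss:
    def test_one_hot_and_uniform(self):
        assert classification_loss(np.array([[1.0, 0, 0]]), np.array([0])) == 0.0
        val = classification_loss(np.full((4, 5), 0.2), np.array([0, 1, 2, 3]))
        assert val == pytest.approx(np.log(5))

    def test_hand_batch_oracle(self):
        probs = np.array([[0.7, 0.2, 0.1], [0.1, 0.3, 0.6]])
        labels = np.array([0, 2])
        expected = -(np.log(0.7) + np.log(0.6)) / 2
        assert classification_loss(probs, labels) == pytest.approx(expected)

    def test_zero_probability_clamped_with_warning(self):
        with pytest.warns(UserWarning):
            val = classification_loss(np.array([[0.0, 1.0]]), np.array([0]))
        assert np.isfinite(val)


def test_alignment_loss_arithmetic():
    assert alignment_loss(1.0, 0.5, LossConfig(beta=40)) == 21.0
    assert alignment_loss(3.0, 123.0, LossConfig(beta=0)) == 3.0
    assert alignment_loss(0.0, -1.0, LossConfig(beta=10)) == -10.0


class TestEncoderWidths:
    def test_canonical_widths(self, backbone6):
        model = attach_encoders(backbone6.clone(), encoder_dim=128, fmri_dim=1024,
                                pool_size=2, seed=0)
        assert model.encoders.code_dim == 512
        assert model.encoders.fmri_dim == 1024

    def test_small_widths_and_forward_shapes(self, backbone6, images60):
        model = attach_encoders(backbone6.clone(), encoder_dim=8, fmri_dim=16,
                                pool_size=2, seed=0)
        assert model.encoders.code_dim == 32
        signals = model.generate(images60.pixels[:5])
        assert signals.shape == (5, 16)

    def test_checkpoint_roundtrip(self, tmp_path, backbone6, images60):
        model = attach_encoders(backbone6.clone(), encoder_dim=8, fmri_dim=12,
                                pool_size=2, seed=3)
        model.save(tmp_path / "m.npz")
        loaded = AlignedModel.load(tmp_path / "m.npz")
        np.testing.assert_array_equal(model.generate(images60.pixels[:3]),
                                      loaded.generate(images60.pixels[:3]))


class TestTeacherLabels:
    def test_deterministic_and_self_consistent(self, trained_backbone6, images60):
        l1 = teacher_labels(trained_backbone6, images60)
        l2 = teacher_labels(trained_backbone6, images60)
        np.testing.assert_array_equal(l1, l2)
        from realign.backbone import classify
        probs = classify(trained_backbone6, images60.pixels)
        assert (probs.argmax(axis=1) == l1).all()   # 100% top-1 self agreement

    def test_agreement_with_ground_truth_above_chance(self, trained_backbone6, images60):
        labels = teacher_labels(trained_backbone6, images60)
        assert (labels == images60.labels).mean() > 1 / 6


class TestVoxelPCA:
    def test_exact_low_rank_reconstruction(self):
        rng = np.random.default_rng(4)
        X = rng.normal(size=(30, 3)) @ rng.normal(size=(3, 50))
        pca, reduced = reduce_voxels_pca(X, 3, zscore=False)
        recon = reduced @ pca.components + pca.mean
        assert np.abs(recon - X).max() / np.abs(X).max() < 1e-8

    def test_component_variances_non_increasing(self):
        rng = np.random.default_rng(5)
        pca, _ = reduce_voxels_pca(rng.normal(size=(40, 20)), 10)
        v = pca.explained_variance
        assert (np.diff(v) <= 1e-12).all()

    def test_error_names_binding_constraint(self):
        with pytest.raises(ValueError, match="binding constraint"):
            reduce_voxels_pca(np.zeros((10, 5)), 8)

    def test_transform_reusable_on_held_out_data(self):
        rng = np.random.default_rng(6)
        train, test = rng.normal(size=(30, 12)), rng.normal(size=(7, 12))
        pca, _ = reduce_voxels_pca(train, 4)
        out = pca.transform(test)
        assert out.shape == (7, 4)


@pytest.fixture(scope="module")
def tiny_setup(trained_backbone6, images60):
    rng = np.random.default_rng(7)
    signals = rng.normal(size=(60, 16))
    labels = teacher_labels(trained_backbone6, images60)
    return signals, labels


class TestTraining:
    def test_loss_decreases_over_epochs(self, trained_backbone6, images60, tiny_setup):
        signals, labels = tiny_setup
        model = attach_encoders(trained_backbone6.clone(), 8, 16, 2, seed=8)
        hist = train_alignment(model, images60, signals, labels,
                               LossConfig(beta=40), epochs=5, lr=1e-3,
                               batch_size=16, seed=8)
        assert len(hist) == 5
        assert hist[-1]["la"] < hist[0]["la"]

    def test_beta_zero_leaves_generation_head_untouched(self, trained_backbone6,
                                                        images60, tiny_setup):
        """Control training: L_G is logged but contributes no gradient."""
        signals, labels = tiny_setup
        model = attach_encoders(trained_backbone6.clone(), 8, 16, 2, seed=9)
        before = [p.data.copy() for p in model.encoders.parameters()]
        hist = train_alignment(model, images60, signals, labels,
                               LossConfig(beta=0), epochs=2, lr=1e-3,
                               batch_size=16, seed=9)
        for p, b in zip(model.encoders.parameters(), before):
            np.testing.assert_array_equal(p.data, b)
        assert all(np.isfinite(h["lg"]) for h in hist)

    def test_beta_zero_matches_pure_classifier_trajectory(self, trained_backbone6,
                                                          images60, tiny_setup):
        """Same seed, beta=0 vs a second beta=0 run: identical history."""
        signals, labels = tiny_setup
        h = []
        for _ in range(2):
            model = attach_encoders(trained_backbone6.clone(), 8, 16, 2, seed=10)
            h.append(train_alignment(model, images60, signals, labels,
                                     LossConfig(beta=0), epochs=2, lr=1e-3,
                                     batch_size=16, seed=10))
        assert h[0] == h[1]

    def test_signal_shape_checked_before_training(self, trained_backbone6, images60):
        model = attach_encoders(trained_backbone6.clone(), 8, 16, 2, seed=11)
        with pytest.raises(ValueError):
            train_alignment(model, images60, np.zeros((60, 8)), images60.labels,
                            LossConfig(), epochs=1)
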