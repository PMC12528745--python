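"""Tests for the two-stage training protocol and its heads."""

import numpy as np
import pytest

import gliofuzz as gf
from gliofuzz.fcnn3d import FEATURE_LENGTH
from gliofuzz.training import (
    FeatureScaler,
    _gene_dimension,
    _hash_params,
    stage2_train,
)

FAST = gf.TrainConfig(
    stage1_subset_size=12,
    stage1_iterations=6,
    stage2_iterations=60,
    population=6,
    seed=0,
)


def toy_separable_features(n_per_class=20, gap=4.0, seed=0):
    """Linearly separable 128-d features living on two coordinates."""
    rng = np.random.default_rng(seed)
    features = 0.01 * rng.standard_normal((2 * n_per_class, FEATURE_LENGTH))
    features[:n_per_class, 0] -= gap / 2
    features[n_per_class:, 0] += gap / 2
    labels = np.r_[np.zeros(n_per_class, int), np.ones(n_per_class, int)]
    return features, labels


class TestFisherFitness:
    def test_identical_class_means_give_zero(self):
        f = np.array([[0.0], [2.0], [0.0], [2.0]])
        y = np.array([0, 0, 1, 1])
        assert gf.fisher_fitness(f, y) == pytest.approx(0.0, abs=1e-9)

    def test_point_masses_dominated_by_epsilon_guard(self):
        f = np.array([[0.0], [0.0], [1.0], [1.0]])
        y = np.array([0, 0, 1, 1])
        assert gf.fisher_fitness(f, y) > 1e8  # ~ (Sb trace) / 1e-9, finite

    def test_hand_expanded_scatter_matrices(self):
        # class 0 at (0,0),(1,0); class 1 at (4,0),(5,0):
        # Sb trace = 2*(2)^2 + 2*(2)^2 = 16, Sw trace = 0.5 + 0.5 = 1
        f = np.array([[0.0, 0.0], [1.0, 0.0], [4.0, 0.0], [5.0, 0.0]])
        y = np.array([0, 0, 1, 1])
        assert gf.fisher_fitness(f, y) == pytest.approx(16.0, rel=1e-8)

    def test_single_class_rejected(self):
        with pytest.raises(ValueError, match="both classes"):
            gf.fisher_fitness(np.ones((3, 2)), np.zeros(3))


class TestStage2Heads:
    def test_separable_features_reach_perfect_training_accuracy(self):
        features, labels = toy_separable_features()
        for head_type in ("softmax", "svm"):
            cfg = gf.TrainConfig(head=head_type, stage2_iterations=100, seed=1)
            head, scaler = stage2_train(features, labels, cfg)
            std = scaler.transform(features)
            if head_type == "softmax":
                preds = (std @ head.fc_weights + head.fc_bias).argmax(axis=1)
            else:
                preds = (std @ head.weight + head.bias > 0).astype(int)
            assert np.mean(preds == labels) == 1.0

    def test_shuffled_labels_give_chance_level_training_accuracy(self):
        # tied-mode features are effectively rank-1, so a shuffled-label
        # head cannot memorize: training accuracy stays near chance
        rng = np.random.default_rng(0)
        base = rng.standard_normal(40)
        features = np.tile(base[:, None], (1, FEATURE_LENGTH))
        features += 1e-6 * rng.standard_normal(features.shape)
        accs = []
        for shuffle_seed in range(10):
            labels = np.r_[np.zeros(20, int), np.ones(20, int)]
            np.random.default_rng(shuffle_seed).shuffle(labels)
            cfg = gf.TrainConfig(stage2_iterations=40, seed=2)
            head, scaler = stage2_train(features, labels, cfg)
            std = scaler.transform(features)
            preds = (std @ head.fc_weights + head.fc_bias).argmax(axis=1)
            accs.append(np.mean(preds == labels))
        assert 0.35 <= np.mean(accs) <= 0.65

    def test_label_flip_flips_svm_decisions(self):
        features, labels = toy_separable_features(seed=3)
        cfg = gf.TrainConfig(head="svm", stage2_iterations=80, seed=3)
        head_a, scaler = stage2_train(features, labels, cfg)
        head_b, _ = stage2_train(features, 1 - labels, cfg)
        std = scaler.transform(features)
        preds_a = std @ head_a.weight + head_a.bias > 0
        preds_b = std @ head_b.weight + head_b.bias > 0
        assert np.all(preds_a == ~preds_b)

    def test_single_class_rejected(self):
        with pytest.raises(ValueError, match="both classes"):
            stage2_train(np.ones((4, FEATURE_LENGTH)), np.ones(4), gf.TrainConfig())


class TestSvmDecision:
    def test_positive_bias_only_labels_everything_hgg(self):
        svm = gf.SvmParams(weight=np.zeros(FEATURE_LENGTH), bias=0.5)
        score, label = gf.svm_decision(np.ones(FEATURE_LENGTH), svm)
        assert (score, label) == (0.5, "HGG")

    def test_score_is_linear_in_features_for_zero_bias(self):
        rng = np.random.default_rng(4)
        svm = gf.SvmParams(weight=rng.standard_normal(FEATURE_LENGTH), bias=0.0)
        x = rng.standard_normal(FEATURE_LENGTH)
        s1, _ = gf.svm_decision(x, svm)
        s2, _ = gf.svm_decision(2.5 * x, svm)
        assert s2 == pytest.approx(2.5 * s1)

    def test_unit_weight_dot_product(self):
        w = np.zeros(FEATURE_LENGTH)
        w[0] = 1.0
        svm = gf.SvmParams(weight=w, bias=-0.5)
        e1 = np.zeros(FEATURE_LENGTH)
        e1[0] = 1.0
        score, label = gf.svm_decision(e1, svm)
        assert score == pytest.approx(0.5) and label == "HGG"

    def test_tie_goes_to_negative_class(self):
        svm = gf.SvmParams(weight=np.zeros(FEATURE_LENGTH), bias=0.0)
        _, label = gf.svm_decision(np.ones(FEATURE_LENGTH), svm)
        assert label == "LGG"

    def test_length_mismatch_rejected(self):
        svm = gf.SvmParams(weight=np.zeros(FEATURE_LENGTH), bias=0.0)
        with pytest.raises(ValueError, match="length"):
            gf.svm_decision(np.zeros(10), svm)


class TestStage1AndLedger:
    def test_layer_tied_search_dimension_is_fifteen(self):
        spec = gf.NetworkSpec()
        assert _gene_dimension(spec, tied=True) + len(spec.channels) == 15

    def test_stage1_beats_random_genes_on_separable_cohort(self, mini_cohort):
        spec = gf.NetworkSpec()
        volumes = mini_cohort.volumes("train")
        labels = mini_cohort.labels("train")
        genes, relu, result = gf.stage1_optimize(volumes, labels, spec, FAST)
        from gliofuzz.fcnn3d import forward_features_batch

        bank = gf.build_kernel_bank(genes, spec)
        tuned = gf.fisher_fitness(forward_features_batch(volumes, bank, relu), labels)

        rng = np.random.default_rng(0)
        rand_genes = [[gf.FilterGene(*rng.random(2))] for _ in spec.channels]
        rand_bank = gf.build_kernel_bank(rand_genes, spec)
        rand = gf.fisher_fitness(
            forward_features_batch(volumes, rand_bank, gf.ReLUParams()), labels
        )
        assert tuned > rand
        # optimizer monotonicity: final best <= first recorded best
        assert result.best.fitness <= result.history[0]

    def test_train_model_freezes_extractor_and_audits_parameters(self, mini_cohort):
        model = gf.train_model(mini_cohort, gf.NetworkSpec(), FAST)
        # tied genes: 2*5 gene scalars + 5 slopes + (128*2+2) head scalars
        assert model.audit == {
            "gene_scalars": 10,
            "relu_scalars": 5,
            "head_scalars": 258,
            "total": 273,
        }
        assert _hash_params(model.genes, model.relu)  # hashable, stable

    def test_training_is_deterministic_under_seed(self, mini_cohort):
        m1 = gf.train_model(mini_cohort, gf.NetworkSpec(), FAST)
        m2 = gf.train_model(mini_cohort, gf.NetworkSpec(), FAST)
        assert _hash_params(m1.genes, m1.relu) == _hash_params(m2.genes, m2.relu)
        test_vols = mini_cohort.volumes("test")
        np.testing.assert_array_equal(
            gf.predict(m1, test_vols)[1], gf.predict(m2, test_vols)[1]
        )


def test_feature_scaler_handles_constant_columns():
    features = np.c_[np.ones(5), np.arange(5.0)]
    scaler = FeatureScaler.fit(features)
    std = scaler.transform(features)
    assert np.all(np.isfinite(std))
    np.testing.assert_allclose(std[:, 0], 0.0)
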