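import numpy as np
import pandas as pd
import pytest

from radtex.features import HaralickTransformer
from radtex.models import (CNNConfig, GLCMConvNetClassifier, RFConfig,
                           build_network, cnn_forward,
                           network_parameter_count, pirads_cla, predict_rf,
                           train_rf)
from radtex.phantoms import PhantomConfig, generate_cohort
from radtex.stats import auc


def _stack_arrays(stacks):
    return np.stack([s.matrices for s in stacks]).astype(np.float32)


class TestNetworkStructure:
    def test_parameter_count_for_default_config(self):
        # conv(26->32): 26*9*32+32; BN: 2*32; conv(32->64): 32*9*64+64;
        # BN: 2*64; FC 16384->256 (+256); FC 256->2 (+2)
        expected = (26 * 9 * 32 + 32) + 64 + (32 * 9 * 64 + 64) + 128 \
            + (64 * 16 * 16 * 256 + 256) + (256 * 2 + 2)
        assert network_parameter_count(CNNConfig()) == expected == 4221282

    def test_spatial_arithmetic_64_to_16(self):
        rng = np.random.default_rng(0)
        net = build_network(CNNConfig(), rng)
        x = rng.standard_normal((2, 64, 64, 26)).astype(np.float32)
        net.layers[3].forward(net.layers[2].forward(
            net.layers[1].forward(net.layers[0].forward(x))))
        after_pool1 = net.layers[3].forward(net.layers[2].forward(
            net.layers[1].forward(net.layers[0].forward(x))))
        assert after_pool1.shape == (2, 32, 32, 32)
        after_pool2 = net.layers[7].forward(net.layers[6].forward(
            net.layers[5].forward(net.layers[4].forward(after_pool1))))
        assert after_pool2.shape == (2, 16, 16, 64)

    def test_softmax_scores_and_eval_determinism(self, small_stacks):
        rng = np.random.default_rng(1)
        net = build_network(CNNConfig(), rng).eval()
        X = _stack_arrays(small_stacks[:4])
        import radtex.nn as nn
        logits = net.forward(np.ascontiguousarray(X.transpose(0, 2, 3, 1)))
        probs = nn.softmax(logits.astype(np.float64))
        np.testing.assert_allclose(probs.sum(1), 1.0, atol=1e-6)
        s1 = cnn_forward(small_stacks[0], net)
        s2 = cnn_forward(small_stacks[0], net)
        assert s1 == s2 and 0.0 <= s1 <= 1.0

    def test_wrong_channel_count_rejected(self):
        clf = GLCMConvNetClassifier(epochs=1)
        X = np.zeros((4, 13, 64, 64), dtype=np.float32)
        with pytest.raises(ValueError):
            clf.fit(X, np.array([0, 1, 0, 1]))


class TestCNNTraining:
    def test_zero_lr_keeps_initialization(self, small_stacks, small_cohort):
        _, records = small_cohort
        y = records["label"].to_numpy()
        X = _stack_arrays(small_stacks)
        clf = GLCMConvNetClassifier(epochs=1, lr=0.0, random_state=3)
        clf.fit(X[:20], y[:20])
        init = build_network(clf._config(), np.random.default_rng(3))
        for (_, a, _), (_, b, _) in zip(clf.network_.params(), init.params()):
            np.testing.assert_array_equal(a, b)

    def test_short_training_separates_phantom_classes(self, small_stacks,
                                                      small_cohort):
        _, records = small_cohort
        y = records["label"].to_numpy()
        split = records["split"].to_numpy()
        X = _stack_arrays(small_stacks)
        tr, va = split == "train", split == "validation"
        clf = GLCMConvNetClassifier(epochs=12, random_state=0)
        clf.fit(X[tr], y[tr], X[va], y[va])
        assert np.isfinite(clf.history_["train_loss"]).all()
        scores = clf.predict_proba(X[split == "test"])[:, 1]
        assert auc(scores, y[split == "test"]) > 0.8

    def test_single_class_training_rejected(self, small_stacks, small_cohort):
        _, records = small_cohort
        y = np.ones(6, int)
        with pytest.raises(ValueError):
            GLCMConvNetClassifier(epochs=1).fit(_stack_arrays(small_stacks[:6]), y)

    def test_fit_is_seeded_and_reproducible(self, small_stacks, small_cohort):
        _, records = small_cohort
        y = records["label"].to_numpy()[:14]
        X = _stack_arrays(small_stacks[:14])
        s1 = GLCMConvNetClassifier(epochs=2, random_state=5).fit(X, y) \
            .predict_proba(X)[:, 1]
        s2 = GLCMConvNetClassifier(epochs=2, random_state=5).fit(X, y) \
            .predict_proba(X)[:, 1]
        np.testing.assert_array_equal(s1, s2)

    @pytest.mark.parametrize("seed", [0, 1, 2, 3, 4])
    def test_training_loss_finite_across_seeds(self, seed, small_stacks,
                                               small_cohort):
        _, records = small_cohort
        y = records["label"].to_numpy()[:20]
        X = _stack_arrays(small_stacks[:20])
        clf = GLCMConvNetClassifier(epochs=3, random_state=seed).fit(X, y)
        assert np.isfinite(clf.history_["train_loss"]).all()

    def test_weight_roundtrip(self, tmp_path, small_stacks, small_cohort):
        _, records = small_cohort
        y = records["label"].to_numpy()[:14]
        X = _stack_arrays(small_stacks[:14])
        clf = GLCMConvNetClassifier(epochs=1, random_state=6).fit(X, y)
        ref = clf.predict_proba(X)[:, 1]
        clf.save_weights(tmp_path / "weights.npz")
        loaded = GLCMConvNetClassifier(random_state=6).load_weights(
            tmp_path / "weights.npz")
        np.testing.assert_array_equal(loaded.predict_proba(X)[:, 1], ref)


@pytest.fixture(scope="module")
def feature_table(small_stacks, small_cohort):
    _, records = small_cohort
    table = HaralickTransformer().fit(small_stacks).transform(small_stacks)
    return table, records["label"].to_numpy(), records["split"].to_numpy()


class TestRandomForest:
    def test_memorizes_training_data(self, feature_table):
        table, y, _ = feature_table
        forest = train_rf(table, y, RFConfig(seed=0))
        assert auc(predict_rf(forest, table), y) >= 0.99

    def test_seeded_reproducibility(self, feature_table):
        table, y, _ = feature_table
        s1 = predict_rf(train_rf(table, y, RFConfig(seed=4)), table)
        s2 = predict_rf(train_rf(table, y, RFConfig(seed=4)), table)
        np.testing.assert_array_equal(s1, s2)

    def test_generalizes_across_split(self, feature_table):
        table, y, split = feature_table
        tr, te = split == "train", split == "test"
        forest = train_rf(table[tr], y[tr], RFConfig(seed=1))
        assert auc(predict_rf(forest, table[te]), y[te]) > 0.8

    def test_nan_features_rejected(self, feature_table):
        table, y, _ = feature_table
        bad = table.copy()
        bad.iloc[0, 0] = np.nan
        with pytest.raises(ValueError):
            train_rf(bad, y)


class TestPIRADSRule:
    def test_cutoff_at_four(self):
        records = pd.DataFrame({"pirads": [3, 4, 5]})
        np.testing.assert_array_equal(pirads_cla(records), [0, 1, 1])

    def test_degenerate_all_fives(self):
        records = pd.DataFrame({"pirads": [5] * 8, "label": [1] * 4 + [0] * 4})
        preds = pirads_cla(records)
        labels = records["label"].to_numpy()
        sens = (preds[labels == 1] == 1).mean()
        spec = (preds[labels == 0] == 0).mean()
        assert sens == 1.0 and spec == 0.0

    def test_missing_score_rejected(self):
        with pytest.raises(ValueError):
            pirads_cla(pd.DataFrame({"pirads": [3, np.nan]}))
        with pytest.raises(ValueError):
            pirads_cla(pd.DataFrame({"other": [1]}))

    def test_sensitivity_specificity_track_confusion_table(self):
        """Law of large numbers: rule performance converges to the phantom
        generator's PI-RADS confusion parameters."""
        _, records = generate_cohort(PhantomConfig(
            n_patients=2000, lesions_per_patient=(1, 1), seed=13))
        preds = pirads_cla(records)
        labels = records["label"].to_numpy()
        sens = (preds[labels == 1] == 1).mean()
        spec = (preds[labels == 0] == 0).mean()
        assert sens == pytest.approx(0.83, abs=0.03)
        assert spec == pytest.approx(0.47, abs=0.03)


def test_learned_models_beat_pirads_rule(small_stacks, small_cohort):
    """Texture separation stronger than PI-RADS label noise: both learned
    classifiers should out-rank the rule baseline on the test split."""
    _, records = small_cohort
    y = records["label"].to_numpy()
    split = records["split"].to_numpy()
    X = _stack_arrays(small_stacks)
    table = HaralickTransformer().fit(small_stacks).transform(small_stacks)
    tr, va, te = split == "train", split == "validation", split == "test"
    cnn = GLCMConvNetClassifier(epochs=12, random_state=0).fit(
        X[tr], y[tr], X[va], y[va])
    forest = train_rf(table[tr], y[tr], RFConfig(seed=0))
    auc_rule = auc(pirads_cla(records[te]).astype(float), y[te])
    assert auc(cnn.predict_proba(X[te])[:, 1], y[te]) > auc_rule
    assert auc(predict_rf(forest, table[te]), y[te]) > auc_rule
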