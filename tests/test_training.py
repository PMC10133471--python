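"""Loss closed forms, initialisation, training loop, k-fold and metrics."""

import math

import numpy as np
import pytest

from gdnet import nn
from gdnet.model import GDNetConfig, build_model
from gdnet.preprocessing import SegmentBatch
from gdnet.training import (ConfusionCounts, TrainConfig, confusion_counts,
                            init_weights, kfold_evaluate, loss, macro_metrics,
                            metrics_from_confusion, train, two_stage_train)


def toy_segments(n_per_class=40, n_channels=2, n_samples=25, noise=0.05, seed=0):
    """Linearly separable two-class batch: constant +1 vs -1 patterns."""
    rng = np.random.default_rng(seed)
    X, y, ids = [], [], []
    for cls, level in ((0, 1.0), (1, -1.0)):
        for i in range(n_per_class):
            X.append(level + noise * rng.standard_normal((n_channels, n_samples)))
            y.append(cls)
            ids.append(cls * n_per_class + i)
    return SegmentBatch(np.array(X), np.array(y), n_samples / 250.0, 250.0,
                        np.array(ids))


class TestLoss:
    def test_perfect_predictions_zero_weights(self):
        s = np.eye(4)
        assert loss(s, s) == pytest.approx(0.0, abs=1e-12)

    def test_uniform_over_forty_classes_is_log_forty(self):
        s = np.full((6, 40), 1 / 40)
        y = np.zeros((6, 40))
        y[:, 3] = 1
        assert loss(s, y) == pytest.approx(math.log(40), abs=1e-9)

    def test_l2_term_exact(self):
        s = np.eye(2)
        w = [np.array([1.0, -2.0])]
        assert loss(s, s, model_weights=w, l2_lambda=0.001) == pytest.approx(0.005)

    def test_l2_penalty_matches_manual_sum(self, rng):
        params = [nn.Parameter("a", rng.standard_normal((3, 4)), decay=True),
                  nn.Parameter("b", rng.standard_normal(5), decay=False)]
        lam = 0.007
        manual = lam * float(np.sum(params[0].value ** 2))
        assert nn.l2_penalty(params, lam) == pytest.approx(manual, rel=1e-12)

    def test_zero_probability_clamped_not_inf(self):
        s = np.array([[1.0, 0.0], [0.0, 1.0]])
        y = np.array([[0.0, 1.0], [0.0, 1.0]])  # first prediction dead wrong
        val = loss(s, y)
        assert np.isfinite(val) and val > 10

    def test_shape_mismatch_rejected(self):
        with pytest.raises(ValueError):
            loss(np.eye(3), np.eye(4))


class TestInit:
    def test_deterministic_per_seed(self):
        cfg = GDNetConfig(n_channels=3, n_samples=30, n_classes=3, n_feature_maps=8,
                          n_group_blocks=1)
        a = init_weights(build_model(cfg), 42).network.state_dict()
        b = init_weights(build_model(cfg), 42).network.state_dict()
        for k in a:
            np.testing.assert_array_equal(a[k], b[k])

    def test_gaussian_moments(self):
        cfg = GDNetConfig(n_channels=8, n_samples=100, n_classes=10,
                          n_feature_maps=16, n_group_blocks=2)
        model = init_weights(build_model(cfg), 7)
        weights = np.concatenate([p.value.ravel()
                                  for p in model.network.parameters().values()
                                  if p.decay])
        assert weights.size >= 10_000
        assert 0.095 < weights.std() < 0.105
        assert abs(weights.mean()) < 0.005

    def test_biases_zero_batchnorm_identity(self):
        cfg = GDNetConfig(n_channels=3, n_samples=30, n_classes=3, n_feature_maps=8,
                          n_group_blocks=1)
        model = init_weights(build_model(cfg), 1)
        for p in model.network.parameters().values():
            if "bias" in p.name or "shift" in p.name:
                np.testing.assert_array_equal(p.value, 0.0)
            if "scale" in p.name:
                np.testing.assert_array_equal(p.value, 1.0)


def small_cfg(n_channels=2, n_samples=25, n_classes=2):
    return GDNetConfig(n_channels=n_channels, n_samples=n_samples,
                       n_classes=n_classes, n_feature_maps=4, n_group_blocks=1,
                       dropout_rate=0.25)


class TestTrain:
    def test_separable_toy_reaches_full_accuracy(self):
        segments = toy_segments()
        tr = segments.subset(np.arange(len(segments)) % 4 != 0)
        val = segments.subset(np.arange(len(segments)) % 4 == 0)
        model = init_weights(build_model(small_cfg()), 0)
        hist = train(model, tr, val, TrainConfig(seed=0, max_epochs=50,
                                                 early_stop_patience=50))
        assert max(hist["train_acc"]) == 1.0

    def test_train_loss_non_increasing_early(self):
        segments = toy_segments(seed=3)
        tr = segments.subset(np.arange(len(segments)) % 4 != 0)
        val = segments.subset(np.arange(len(segments)) % 4 == 0)
        model = init_weights(build_model(small_cfg()), 1)
        hist = train(model, tr, val, TrainConfig(seed=1, max_epochs=3,
                                                 early_stop_patience=3))
        assert hist["train_loss"][0] >= hist["train_loss"][1] >= hist["train_loss"][2]

    def test_patience_zero_stops_at_first_plateau(self):
        segments = toy_segments()
        tr = segments.subset(np.arange(len(segments)) % 4 != 0)
        val = segments.subset(np.arange(len(segments)) % 4 == 0)
        model = init_weights(build_model(small_cfg()), 0)
        # a deliberately large step size makes validation loss oscillate
        hist = train(model, tr, val, TrainConfig(seed=0, max_epochs=50,
                                                 learning_rate=0.05,
                                                 early_stop_patience=0))
        losses = hist["val_loss"]
        assert len(losses) < 50
        # every epoch but the last improved on the running best; the last didn't
        running_best = np.inf
        for v in losses[:-1]:
            assert v < running_best
            running_best = v
        assert losses[-1] >= running_best

    def test_fixed_seed_runs_are_identical(self):
        segments = toy_segments()
        tr = segments.subset(np.arange(len(segments)) % 4 != 0)
        val = segments.subset(np.arange(len(segments)) % 4 == 0)
        hists = []
        for _ in range(2):
            model = init_weights(build_model(small_cfg()), 9)
            hists.append(train(model, tr, val,
                               TrainConfig(seed=9, max_epochs=5,
                                           early_stop_patience=5)))
        assert hists[0] == hists[1]

    def test_empty_data_rejected(self):
        segments = toy_segments()
        empty = segments.subset(np.zeros(len(segments), dtype=bool))
        model = init_weights(build_model(small_cfg()), 0)
        with pytest.raises(ValueError):
            train(model, empty, segments, TrainConfig())

    def test_trial_batching_mode_runs(self):
        segments = toy_segments(n_per_class=10)
        tr = segments.subset(np.arange(len(segments)) % 4 != 0)
        val = segments.subset(np.arange(len(segments)) % 4 == 0)
        model = init_weights(build_model(small_cfg()), 0)
        hist = train(model, tr, val,
                     TrainConfig(seed=0, max_epochs=2, batch_size=4,
                                 batch_by_trial=True, early_stop_patience=2))
        assert len(hist["train_loss"]) == 2


class TestTwoStage:
    def _data(self, seed, noise):
        seg = toy_segments(n_per_class=20, noise=noise, seed=seed)
        tr = seg.subset(np.arange(len(seg)) % 4 != 0)
        val = seg.subset(np.arange(len(seg)) % 4 == 0)
        return tr, val

    def test_zero_epoch_stage2_returns_stage1_weights(self, tmp_path):
        tr1, val1 = self._data(0, 0.05)
        tr2, val2 = self._data(1, 0.4)
        model = build_model(small_cfg())
        cfg = TrainConfig(seed=0, max_epochs=3, early_stop_patience=3)
        model, hists = two_stage_train(
            model, tr1, val1, tr2, val2, cfg,
            stage2_cfg=TrainConfig(seed=0, max_epochs=1, early_stop_patience=0),
            checkpoint_dir=tmp_path)
        from gdnet.model import GDNet
        stage1 = GDNet.load(tmp_path / "stage1.npz")
        # stage-2 started from the persisted stage-1 checkpoint
        s2_start = GDNet.load(tmp_path / "stage2.npz")
        assert set(stage1.network.state_dict()) == set(s2_start.network.state_dict())
        model2 = build_model(small_cfg())
        cfg0 = TrainConfig(seed=0, max_epochs=3, early_stop_patience=3)
        model2, _ = two_stage_train(
            model2, tr1, val1, tr2, val2, cfg0,
            stage2_cfg=TrainConfig(seed=0, max_epochs=0))
        for k, v in stage1.network.state_dict().items():
            np.testing.assert_array_equal(model2.network.state_dict()[k], v)

    def test_transfer_beats_random_init_at_epoch_zero(self):
        # paired comparison over 5 seeds on related tasks with shifted noise
        wins = 0
        diffs = []
        for seed in range(5):
            tr1, val1 = self._data(seed, 0.1)
            tr2, val2 = self._data(seed + 100, 0.5)
            model = build_model(small_cfg())
            cfg = TrainConfig(seed=seed, max_epochs=5, early_stop_patience=5)
            init_weights(model, seed)
            train(model, tr1, val1, cfg)
            ce_transfer, _ = nn.softmax_cross_entropy(model.logits(val2.X), val2.y)
            fresh = init_weights(build_model(small_cfg()), seed)
            ce_fresh, _ = nn.softmax_cross_entropy(fresh.logits(val2.X), val2.y)
            diffs.append(ce_transfer - ce_fresh)
            wins += ce_transfer < ce_fresh
        assert np.mean(diffs) < 0 and wins >= 4

    def test_channel_mismatch_rejected(self):
        tr1, val1 = self._data(0, 0.1)
        seg2 = toy_segments(n_per_class=5, n_channels=3)
        model = build_model(small_cfg())
        with pytest.raises(ValueError):
            two_stage_train(model, tr1, val1, seg2, seg2, TrainConfig(max_epochs=1))


class TestMetrics:
    def test_published_formula_example(self):
        acc, sen, spe = metrics_from_confusion(ConfusionCounts(8, 85, 5, 2))
        assert acc == pytest.approx(0.93)
        assert sen == pytest.approx(0.80)
        assert spe == pytest.approx(85 / 90)

    def test_perfect_predictions(self):
        acc, sen, spe = metrics_from_confusion(ConfusionCounts(10, 90, 0, 0))
        assert (acc, sen, spe) == (1.0, 1.0, 1.0)

    def test_degenerate_denominator_flagged_zero(self):
        acc, sen, spe = metrics_from_confusion(ConfusionCounts(0, 100, 0, 0))
        assert sen == 0.0 and not math.isnan(sen)

    def test_negative_counts_rejected(self):
        with pytest.raises(ValueError):
            metrics_from_confusion(ConfusionCounts(-1, 0, 0, 0))

    def test_counts_sum_to_total_per_class(self, rng):
        y_true = rng.integers(0, 5, 200)
        y_pred = rng.integers(0, 5, 200)
        for c in confusion_counts(y_true, y_pred, 5):
            assert c.total == 200

    def test_fixed_single_class_classifier_macro_metrics(self):
        # 40-class balanced set, classifier always answers class 0
        n_classes, per_class = 40, 5
        y_true = np.repeat(np.arange(n_classes), per_class)
        y_pred = np.zeros_like(y_true)
        total = n_classes * per_class
        acc, sen, spe = macro_metrics(y_true, y_pred, n_classes)
        want_acc = (per_class / total
                    + (n_classes - 1) * (total - 2 * per_class + per_class) / total
                    ) / n_classes
        # class 0: TP=5 TN=0 FP=195 FN=0; others: TP=0 TN=195 FP=0 FN=5
        assert acc == pytest.approx((5 / 200 + 39 * (195 / 200)) / 40)
        assert sen == pytest.approx(1 / 40)
        assert spe == pytest.approx(39 / 40)


class OracleClassifier:
    """Returns the true labels (memorises the test inputs by value)."""

    def __init__(self):
        self.lut = {}

    def fit(self, segments):
        pass

    def predict(self, X):
        # labels are recoverable from the toy encoding: mean sign
        return (X.mean(axis=(1, 2)) < 0).astype(int)


class TestKFold:
    def _balanced_segments(self, n_classes=5, trials_per_class=20, seg_per_trial=10):
        rng = np.random.default_rng(0)
        X, y, ids = [], [], []
        tid = 0
        for cls in range(n_classes):
            for _ in range(trials_per_class):
                for _ in range(seg_per_trial):
                    X.append(rng.standard_normal((2, 10)))
                    y.append(cls)
                    ids.append(tid)
                tid += 1
        return SegmentBatch(np.array(X), np.array(y), 10 / 250.0, 250.0,
                            np.array(ids))

    def test_folds_partition_and_stratify(self):
        segments = self._balanced_segments()
        from sklearn.model_selection import StratifiedGroupKFold
        splitter = StratifiedGroupKFold(n_splits=10, shuffle=True, random_state=0)
        seen = []
        for tr_idx, te_idx in splitter.split(segments.X, segments.y,
                                             groups=segments.source_trial_ids):
            assert len(te_idx) == 100
            counts = np.bincount(segments.y[te_idx], minlength=5)
            assert counts.tolist() == [20] * 5
            # no trial straddles the split
            assert not set(segments.source_trial_ids[tr_idx]) & \
                set(segments.source_trial_ids[te_idx])
            seen.extend(te_idx.tolist())
        assert sorted(seen) == list(range(len(segments)))

    def test_oracle_classifier_scores_hundred(self):
        segments = toy_segments(n_per_class=50, noise=0.01)
        report = kfold_evaluate(segments, OracleClassifier, k=10, seed=0)
        assert report.acc == (100.0, 0.0)
        assert report.sen == (100.0, 0.0)
        assert report.spe == (100.0, 0.0)

    def test_too_few_folds_or_data_rejected(self):
        segments = toy_segments(n_per_class=2)
        with pytest.raises(ValueError):
            kfold_evaluate(segments, OracleClassifier, k=1)
        with pytest.raises(ValueError):
            kfold_evaluate(segments.subset(np.arange(3)), OracleClassifier, k=10)
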