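"""CNN architectures, metric computation and the cross-validated trainer."""

import numpy as np
import pandas as pd
import pytest

import vibrotissue as vt
from vibrotissue import nn


class TestNeedleNet:
    @pytest.mark.parametrize("shape", [(8, 1, 64, 44), (1, 1, 224, 160), (2, 1, 17, 100)])
    def test_output_is_batch_by_five_for_any_admissible_size(self, shape):
        model = vt.build_needlenet(seed=0).eval()
        out = model(np.zeros(shape, dtype=np.float32))
        assert out.shape == (shape[0], 5)

    def test_feature_map_shape_arithmetic(self):
        # 64 -> 32 -> 16 -> 8 -> 4 and 44 -> 22 -> 11 -> 6 -> 3 under k3/s2/p1
        model = vt.build_needlenet(seed=0).eval()
        x = np.zeros((1, 1, 64, 44), dtype=np.float32)
        feat = model.body(x)
        assert feat.shape == (1, 512, 4, 3)

    def test_too_small_input_rejected(self):
        model = vt.build_needlenet(seed=0)
        with pytest.raises(ValueError, match="stride-2"):
            model(np.zeros((1, 1, 8, 44), dtype=np.float32))

    def test_parameter_count_matches_independent_tally(self):
        model = vt.build_needlenet(seed=0)
        # independent closed-form tally, written out term by term
        expected = 0
        filters = [1, 64, 128, 256, 512]
        for cin, cout in zip(filters, filters[1:]):
            expected += 3 * 3 * cin * cout + cout  # conv weights + bias
            expected += 2 * cout  # batch-norm affine
        expected += 512 * 5 + 5  # fully connected head
        assert model.num_parameters() == expected
        assert vt.needlenet_parameter_count() == expected

    def test_seeded_construction_is_deterministic(self, rng):
        x = rng.normal(size=(2, 1, 32, 32)).astype(np.float32)
        a = vt.build_needlenet(seed=5).eval()(x)
        b = vt.build_needlenet(seed=5).eval()(x)
        np.testing.assert_array_equal(a, b)
        c = vt.build_needlenet(seed=6).eval()(x)
        assert not np.array_equal(a, c)

    def test_invalid_configs_rejected(self):
        with pytest.raises(ValueError):
            vt.NeedleNetConfig(block_filters=(64, 128, 256)).validate()
        with pytest.raises(ValueError):
            vt.NeedleNetConfig(block_filters=(64, 32, 256, 512)).validate()
        with pytest.raises(ValueError):
            vt.NeedleNetConfig(dropout_p=1.0).validate()


class TestResNet34:
    def test_single_channel_input_yields_five_scores(self):
        model = vt.build_resnet34_adapter(n_classes=5, seed=0).eval()
        out = model(np.zeros((2, 1, 224, 160), dtype=np.float32))
        assert out.shape == (2, 5)

    def test_head_width_follows_n_classes(self):
        model = vt.build_resnet34_adapter(n_classes=7, seed=0)
        assert model.fc.weight.value.shape == (512, 7)

    def test_pretrained_raises_with_advice(self):
        with pytest.raises(RuntimeError, match="no-pretrained"):
            vt.build_resnet34_adapter(n_classes=5, pretrained=True)

    def test_seeded_init_gives_deterministic_forward(self, rng):
        x = rng.normal(size=(1, 1, 64, 64)).astype(np.float32)
        a = vt.build_resnet34_adapter(seed=3).eval()(x)
        b = vt.build_resnet34_adapter(seed=3).eval()(x)
        np.testing.assert_array_equal(a, b)


class TestComputeMetrics:
    def test_perfect_prediction(self):
        y = np.array([0, 1, 2, 3, 4, 0, 1, 2, 3, 4])
        assert vt.compute_metrics(y, y) == (1.0, 1.0, 1.0)

    def test_two_class_hand_computed_confusion(self):
        acc, prec, f1 = vt.compute_metrics([0, 1, 0, 1], [0, 0, 1, 1], n_classes=2)
        assert acc == pytest.approx(0.5)
        assert prec == pytest.approx(0.5)
        assert f1 == pytest.approx(0.5)

    def test_matches_confusion_matrix_oracle(self, rng):
        def oracle(pred, true, k):
            cm = np.zeros((k, k))
            for p, t in zip(pred, true):
                cm[t, p] += 1
            precs, f1s = [], []
            for c in range(k):
                tp = cm[c, c]
                prec = tp / cm[:, c].sum() if cm[:, c].sum() else 0.0
                rec = tp / cm[c, :].sum() if cm[c, :].sum() else 0.0
                precs.append(prec)
                f1s.append(2 * prec * rec / (prec + rec) if prec + rec else 0.0)
            return (cm.trace() / cm.sum(), float(np.mean(precs)), float(np.mean(f1s)))

        for trial in range(1000):
            n = int(rng.integers(1, 30))
            pred = rng.integers(0, 5, n)
            true = rng.integers(0, 5, n)
            got = vt.compute_metrics(pred, true)
            want = oracle(pred, true, 5)
            np.testing.assert_allclose(got, want, atol=1e-9)

    def test_length_mismatch_rejected(self):
        with pytest.raises(ValueError):
            vt.compute_metrics([0, 1], [0])


def tiny_archive_and_folds(rng, n_rec=10, segs_per_rec=3, side=20):
    """Random-feature archive where class c has mean offset c (learnable)."""
    feats, labels, rids, fold_map = [], [], [], {}
    for r in range(n_rec):
        cid = r % 5
        rid = f"rec{r}"
        fold_map[rid] = r % 5
        for s in range(segs_per_rec):
            feats.append(rng.normal(cid, 1.0, (side, side)).astype(np.float32))
            labels.append(cid)
            rids.append(rid)
    archive = vt.FeatureArchive(np.stack(feats), np.array(labels),
                                np.array(rids, dtype=object), "mel")
    folds = vt.FoldAssignment(5, fold_map, pd.DataFrame(), seed=0)
    return archive, folds


class TestTrainCrossval:
    def test_report_shape_and_aggregates(self, rng):
        archive, folds = tiny_archive_and_folds(rng)
        config = vt.TrainConfig(epochs=2, batch_size=8, seed=1)
        report = vt.train_crossval(archive, folds, model_spec="needlenet", config=config)
        df = report.per_fold_per_epoch
        assert len(df) == 5 * 2 * 2  # folds x epochs x {train, test}
        for m in ("accuracy", "precision", "f1"):
            assert 0.0 <= report.average_final[m] <= report.best[m] <= 1.0

    def test_identical_seeds_identical_reports(self, rng):
        archive, folds = tiny_archive_and_folds(rng)
        config = vt.TrainConfig(epochs=2, batch_size=8, seed=7)
        a = vt.train_crossval(archive, folds, config=config)
        b = vt.train_crossval(archive, folds, config=config)
        pd.testing.assert_frame_equal(a.per_fold_per_epoch, b.per_fold_per_epoch)

    def test_invalid_train_config_rejected(self):
        with pytest.raises(ValueError):
            vt.TrainConfig(epochs=0).validate()
        with pytest.raises(ValueError):
            vt.TrainConfig(learning_rate=-1).validate()
        with pytest.raises(ValueError):
            vt.TrainConfig(momentum=1.0).validate()


class TestSummarizeRuns:
    def _fake_report(self, label, best_acc, final_acc):
        rows = []
        for fold in range(2):
            for epoch, acc in [(1, best_acc), (2, final_acc)]:
                rows.append({"fold": fold, "epoch": epoch, "split": "test", "loss": 1.0,
                             "accuracy": acc, "precision": acc, "f1": acc})
        return vt.MetricsReport(pd.DataFrame(rows), label=label)

    def test_eight_configuration_table_layout(self):
        reports = [self._fake_report(f"cfg{i}", 0.9, 0.7) for i in range(8)]
        table = vt.summarize_runs(reports)
        assert len(table) == 8
        assert list(table.columns) == ["Configuration", "Accuracy", "Precision", "F1 Score"]
        assert table.loc[0, "Accuracy"] == "90.00% (70.00%)"

    def test_known_values_pass_through(self):
        rep = self._fake_report("x", 0.8299, 0.6768)
        assert rep.best["accuracy"] == pytest.approx(0.8299)
        assert rep.average_final["accuracy"] == pytest.approx(0.6768)
        table = vt.summarize_runs([rep], ["x"])
        assert table.loc[0, "Accuracy"] == "82.99% (67.68%)"

    def test_empty_rejected(self):
        with pytest.raises(ValueError):
            vt.summarize_runs([])


class TestNnEngine:
    def test_conv_gradients_match_finite_differences(self, rng):
        conv = nn.Conv2d(2, 3, 3, stride=2, padding=1, rng=rng)
        x = rng.normal(size=(2, 2, 7, 6)).astype(np.float32)
        out = conv(x)
        g = rng.normal(size=out.shape).astype(np.float32)
        dx = conv.backward(g)
        eps = 1e-3
        for idx in [(0, 0, 0, 0), (1, 1, 3, 2), (0, 1, 6, 5)]:
            xp, xm = x.copy(), x.copy()
            xp[idx] += eps
            xm[idx] -= eps
            num = (np.sum(conv(xp) * g) - np.sum(conv(xm) * g)) / (2 * eps)
            assert num == pytest.approx(dx[idx], abs=2e-2)

    def test_batchnorm_normalizes_in_train_mode(self, rng):
        bn = nn.BatchNorm2d(4)
        x = rng.normal(3.0, 2.0, (8, 4, 5, 5)).astype(np.float32)
        out = bn(x)
        assert np.abs(out.mean(axis=(0, 2, 3))).max() < 1e-5
        assert np.abs(out.std(axis=(0, 2, 3)) - 1).max() < 1e-3

    def test_dropout_identity_in_eval(self, rng):
        drop = nn.Dropout(0.5, rng=rng)
        drop.eval()
        x = rng.normal(size=(4, 4)).astype(np.float32)
        np.testing.assert_array_equal(drop(x), x)

    def test_sgd_momentum_update_rule(self):
        p = nn.Parameter(np.array([1.0]))
        opt = nn.SGD([p], lr=0.1, momentum=0.9)
        p.grad[...] = 1.0
        opt.step()  # v=1, p = 1 - 0.1
        assert p.value[0] == pytest.approx(0.9)
        p.grad[...] = 1.0
        opt.step()  # v=1.9, p = 0.9 - 0.19
        assert p.value[0] == pytest.approx(0.71)
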