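"""Training schedule, reproducibility, confusion matrices and AAMI metrics."""

import numpy as np
import pytest

from focalbeat import (
    LossConfig,
    TrainConfig,
    build_model,
    confusion_matrix,
    evaluate,
    lr_at_epoch,
    per_class_metrics,
    predict,
    train,
)
from focalbeat.train_eval import REFERENCE_CONFUSION_FOCAL, format_report


class TestSchedule:
    @pytest.mark.parametrize(
        "epoch,expected",
        [(0, 1e-3), (9, 1e-3), (10, 1e-4), (20, 1e-5), (49, 1e-7)],
    )
    def test_lr_decays_tenfold_every_ten_epochs(self, epoch, expected):
        assert lr_at_epoch(epoch, TrainConfig()) == pytest.approx(expected)

    def test_negative_epoch_rejected(self):
        with pytest.raises(ValueError):
            lr_at_epoch(-1, TrainConfig())


class TestConfusionMatrix:
    def test_perfect_predictions_are_diagonal(self):
        y = np.array([0, 1, 2, 3, 0, 2])
        m = confusion_matrix(y, y)
        assert np.array_equal(m, np.diag([2, 1, 2, 1]))

    def test_cross_errors_land_off_diagonal(self):
        m = confusion_matrix([0, 3], [3, 0])
        assert m[0, 3] == 1 and m[3, 0] == 1 and m.trace() == 0

    def test_grand_total_is_conserved(self, rng):
        y_true = rng.integers(0, 4, 1000)
        y_pred = rng.integers(0, 4, 1000)
        assert confusion_matrix(y_true, y_pred).sum() == 1000

    def test_length_mismatch_rejected(self):
        with pytest.raises(ValueError, match="mismatch"):
            confusion_matrix([0, 1], [0])


class TestMetrics:
    def test_diagonal_matrix_scores_100_everywhere(self):
        report = per_class_metrics(np.diag([50, 20, 20, 10]))
        assert np.allclose(report.ppv_pct, 100.0)
        assert np.allclose(report.se_pct, 100.0)
        assert np.allclose(report.f1_pct, 100.0)
        assert report.overall_accuracy_pct == 100.0

    def test_f1_is_zero_when_ppv_plus_se_is_zero(self):
        m = np.array([[10, 0, 0, 0], [0, 10, 0, 0], [0, 0, 10, 0], [10, 0, 0, 0]])
        report = per_class_metrics(m)  # class F never true-positive
        assert report.f1_pct[3] == 0.0

    def test_metrics_are_permutation_equivariant(self, rng):
        m = rng.integers(0, 500, size=(4, 4))
        perm = rng.permutation(4)
        base = per_class_metrics(m)
        permuted = per_class_metrics(m[np.ix_(perm, perm)])
        assert np.allclose(permuted.ppv_pct, base.ppv_pct[perm])
        assert np.allclose(permuted.se_pct, base.se_pct[perm])
        assert permuted.overall_accuracy_pct == pytest.approx(
            base.overall_accuracy_pct
        )
        assert permuted.avg_f1_pct == pytest.approx(base.avg_f1_pct)

    def test_tp_plus_fn_partitions_the_total(self, rng):
        m = rng.integers(0, 300, size=(4, 4))
        tp = np.diag(m)
        fn = m.sum(axis=1) - tp
        assert (tp + fn).sum() == m.sum()

    def test_averages_are_means_of_per_class_values(self):
        report = per_class_metrics(REFERENCE_CONFUSION_FOCAL)
        assert report.avg_f1_pct == pytest.approx(report.f1_pct.mean(), abs=0.005)
        assert report.avg_acc_pct == pytest.approx(report.acc_pct.mean(), abs=0.005)

    def test_empty_matrix_rejected(self):
        with pytest.raises(ValueError, match="empty"):
            per_class_metrics(np.zeros((4, 4)))

    def test_report_formatting_round_trips_the_counts(self):
        report = per_class_metrics(REFERENCE_CONFUSION_FOCAL)
        text = format_report(REFERENCE_CONFUSION_FOCAL, report)
        assert "45952" in text and "92.53" in text


class TestTraining:
    def test_same_seed_gives_identical_final_loss(self, balanced_small_set):
        cfg = TrainConfig(max_epochs=2, batch_size=64, seed=9)
        histories = []
        for _ in range(2):
            model = build_model(seed=9)
            histories.append(train(model, balanced_small_set, cfg, LossConfig()))
        assert abs(histories[0]["epoch_loss"][-1] - histories[1]["epoch_loss"][-1]) < 1e-9

    def test_l2_penalty_changes_the_weights(self, balanced_small_set):
        finals = {}
        for l2 in (0.0, 1e-3):
            model = build_model(seed=9)
            train(
                model,
                balanced_small_set,
                TrainConfig(max_epochs=1, batch_size=64, seed=9, l2_penalty=l2),
                LossConfig(),
            )
            finals[l2] = model.params["W4"].copy()
        assert not np.array_equal(finals[0.0], finals[1e-3])

    def test_separable_classes_are_learnable_in_5_epochs(self, balanced_small_set):
        model = build_model(seed=0)
        train(
            model,
            balanced_small_set,
            TrainConfig(max_epochs=5, batch_size=64, seed=0),
            LossConfig(kind="focal", gamma=2.0),
        )
        preds = predict(model, balanced_small_set["segments"], balanced_small_set["rr"])
        assert (preds == balanced_small_set["labels"]).mean() >= 0.95

    def test_empty_training_set_rejected(self):
        empty = {"segments": np.zeros((0, 200)), "rr": np.zeros((0, 4)),
                 "labels": np.zeros(0, dtype=int)}
        with pytest.raises(ValueError, match="empty"):
            train(build_model(seed=0), empty)

    def test_missing_class_warns(self, caplog, balanced_small_set):
        import logging
        subset = {
            k: v[np.asarray(balanced_small_set["labels"]) != 3][:64]
            for k, v in balanced_small_set.items()
            if k in ("segments", "rr", "labels")
        }
        with caplog.at_level(logging.WARNING, logger="focalbeat.train_eval"):
            train(build_model(seed=0), subset, TrainConfig(max_epochs=1, seed=0))
        assert "classes" in caplog.text


class TestEvaluate:
    def test_overlapping_patients_are_refused(self, balanced_small_set):
        model = build_model(seed=0)
        rid = str(balanced_small_set["record_ids"][0])
        with pytest.raises(ValueError, match="inter-patient"):
            evaluate(model, balanced_small_set, train_record_ids={rid})

    def test_trace_equals_correct_predictions(self, balanced_small_set):
        model = build_model(seed=0)
        matrix, report = evaluate(model, balanced_small_set)
        preds = predict(model, balanced_small_set["segments"], balanced_small_set["rr"])
        assert report.n_correct == matrix.trace()
        assert report.n_correct == int((preds == balanced_small_set["labels"]).sum())
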